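"""Ranking queries: peptide intensity tables grouped per protein.

The learning-to-rank view treats each protein as one *query* whose
candidate documents are its proteotypic, fully tryptic peptides. The
observed relevance of a peptide is its relative XIC intensity: the
integrated extracted-ion-chromatogram area divided by the area of the most
abundant peptide of the same protein. Peptides of a retained protein that
were never quantified enter the query with XIC 0 — the equimolarity
assumption says they *should* have been seen, so their absence is signal.

Input is a tab-delimited table with columns ``protein_id``,
``peptide_sequence``, ``xic_area`` and optional ``study_id`` and ``pep``
(posterior error probability). When a protein was measured in several
studies only the study with the most identified (XIC > 0) peptides is kept,
ties broken by lexicographically smallest study id.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .digestion import PeptideRecord, proteotypic_peptides, tryptic_parent_map
from .proteins import ProteinRecord

REQUIRED_COLUMNS = ("protein_id", "peptide_sequence", "xic_area")


@dataclass
class QueryEntry:
    """One peptide of a query with its observed intensity and relevance."""

    peptide: PeptideRecord
    xic: float
    relevance: float


@dataclass
class QueryGroup:
    """All proteotypic peptides of one protein, max-normalized to [0, 1]."""

    protein_id: str
    entries: list[QueryEntry]

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def relevances(self) -> np.ndarray:
        return np.array([e.relevance for e in self.entries])

    @property
    def peptides(self) -> list[PeptideRecord]:
        return [e.peptide for e in self.entries]


@dataclass
class LoadLog:
    """Bookkeeping from table ingestion (skipped rows, excluded groups)."""

    unknown_protein_rows: int = 0
    non_candidate_rows: int = 0
    pep_filtered_rows: int = 0
    dropped_study_rows: int = 0
    all_zero_groups: list[str] = field(default_factory=list)
    no_candidate_proteins: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def make_query_group(
    protein_id: str,
    peptides: Sequence[PeptideRecord],
    xics: Sequence[float],
) -> Optional[QueryGroup]:
    """Assemble a group, computing relevance = xic / max(xic).

    Returns None when every XIC is zero (the group carries no ranking
    information and is excluded from training and evaluation).
    """
    xics = [float(x) for x in xics]
    if any(x < 0 for x in xics):
        raise ValueError(f"negative XIC in group {protein_id!r}")
    top = max(xics, default=0.0)
    if top <= 0:
        return None
    entries = [
        QueryEntry(peptide=p, xic=x, relevance=x / top)
        for p, x in zip(peptides, xics)
    ]
    return QueryGroup(protein_id=protein_id, entries=entries)


def load_intensity_table(
    path: Union[str, Path],
    database: Sequence[ProteinRecord],
    min_length: int = 6,
    max_length: int = 30,
    pep_threshold: float = 0.01,
    il_equivalent: bool = False,
) -> tuple[list[QueryGroup], LoadLog]:
    """Ingest a peptide intensity TSV into per-protein ranking queries.

    Rows are restricted to proteotypic, fully tryptic, length-bounded
    peptides of database proteins; unobserved candidate peptides of retained
    proteins are appended with XIC 0; groups whose maximum XIC is 0 are
    excluded and logged. Duplicate rows for the same peptide within the kept
    study are collapsed to their maximum XIC.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str,
                                            "peptide_sequence": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"intensity table missing columns: {missing}")
    if (df["xic_area"] < 0).any():
        bad = df.index[df["xic_area"] < 0][0]
        raise ValueError(f"negative xic_area at row {bad}")

    log = LoadLog()
    if "pep" in df.columns:
        keep = df["pep"].isna() | (df["pep"] <= pep_threshold)
        log.pep_filtered_rows = int((~keep).sum())
        df = df[keep]

    by_id = {p.id: p for p in database}
    parent_map = tryptic_parent_map(database, il_equivalent=il_equivalent)
    known = df["protein_id"].isin(by_id)
    log.unknown_protein_rows = int((~known).sum())
    if log.unknown_protein_rows:
        for pid in sorted(df.loc[~known, "protein_id"].unique()):
            log.warnings.append(f"unknown protein id {pid!r}: rows skipped")
    df = df[known]

    groups: list[QueryGroup] = []
    for pid in sorted(df["protein_id"].unique()):
        sub = df[df["protein_id"] == pid]
        candidates = proteotypic_peptides(
            by_id[pid], database, min_length=min_length,
            max_length=max_length, il_equivalent=il_equivalent,
            parent_map=parent_map,
        )
        if not candidates:
            log.no_candidate_proteins.append(pid)
            continue
        candidate_seqs = {p.sequence for p in candidates}
        in_cand = sub["peptide_sequence"].isin(candidate_seqs)
        log.non_candidate_rows += int((~in_cand).sum())
        sub = sub[in_cand]
        if "study_id" in sub.columns and sub["study_id"].notna().any():
            identified = (
                sub[sub["xic_area"] > 0]
                .groupby("study_id")["peptide_sequence"].nunique()
            )
            all_studies = sorted(sub["study_id"].dropna().unique())
            # most identified peptides wins; ties go to the lexicographically
            # smallest study id
            best = min(all_studies,
                       key=lambda s: (-identified.get(s, 0), s))
            dropped = sub["study_id"] != best
            log.dropped_study_rows += int(dropped.sum())
            sub = sub[~dropped]
        xic_by_seq = sub.groupby("peptide_sequence")["xic_area"].max()
        xics = [float(xic_by_seq.get(p.sequence, 0.0)) for p in candidates]
        group = make_query_group(pid, candidates, xics)
        if group is None:
            log.all_zero_groups.append(pid)
        else:
            groups.append(group)
    return groups, log


@dataclass(frozen=True)
class SplitSpec:
    """Protein-level train/validation split specification."""

    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must lie in (0, 1)")


def split_proteins(
    groups: Sequence[QueryGroup], spec: SplitSpec
) -> tuple[list[QueryGroup], list[QueryGroup]]:
    """Random protein-level partition into (train, validation).

    ``|validation| = round(fraction * n)``; deterministic for a fixed seed;
    never splits peptides of one protein across partitions.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to split")
    n_val = int(round(spec.validation_fraction * len(groups)))
    n_val = min(max(n_val, 1), len(groups) - 1)
    order = np.random.default_rng(spec.seed).permutation(len(groups))
    val_idx = set(order[:n_val].tolist())
    train = [g for i, g in enumerate(groups) if i not in val_idx]
    validation = [g for i, g in enumerate(groups) if i in val_idx]
    return train, validation


def training_targets(groups: Sequence[QueryGroup]) -> tuple[list[PeptideRecord], np.ndarray, list[str]]:
    """Flatten query groups into (peptides, relevance targets, protein ids)."""
    peptides: list[PeptideRecord] = []
    targets: list[float] = []
    pids: list[str] = []
    for g in groups:
        for e in g.entries:
            peptides.append(e.peptide)
            targets.append(e.relevance)
            pids.append(g.protein_id)
    return peptides, np.asarray(targets, dtype=float), pids
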