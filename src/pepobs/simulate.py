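"""Synthetic proteomes and peptide-intensity tables.

The generator produces data with the statistical structure the rank
regressor assumes: proteins digest into proteotypic peptides whose relative
intensities are a noisy monotone function of a few physicochemical
features. For each candidate peptide a latent observability

    o = logistic( Σ_f  w_f · z_f )

is computed from globally standardized feature values z_f under configured
signal weights w_f; the simulated XIC area is o scaled by multiplicative
lognormal noise (XIC areas are positive and right-skewed), and with
probability ``zero_fraction`` a peptide is censored to 0 — "identified but
not quantified". Instrument effects, retention time and spectra are not
simulated.

The standard fixture (750 proteins, 600 train / 150 held out, signal on
the hydrophobicity index and peptide length, noise_sd 0.2, zero_fraction
0.1) is the canonical end-to-end test bed: a model that learns the two
signal features recovers near-ideal rankings when noise is switched off.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .digestion import proteotypic_peptides, tryptic_parent_map
from .features import FeatureRegistry, Standardizer, default_registry
from .proteins import AMINO_ACIDS, ProteinRecord, write_fasta
from .queries import QueryGroup, SplitSpec, make_query_group, split_proteins

#: Cosmetic scale so simulated areas resemble instrument XIC magnitudes.
XIC_SCALE = 1.0e6


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the generator; defaults are the standard-fixture conditions."""

    n_proteins: int = 750
    protein_length: tuple[int, int] = (120, 600)
    residue_distribution: tuple[float, ...] = tuple([1.0 / 20] * 20)
    signal_weights: dict = field(
        default_factory=lambda: {"hydrophobicity_index": 2.0,
                                 "peptide_length": -1.0})
    noise_sd: float = 0.2
    zero_fraction: float = 0.1
    seed: int = 42
    min_peptide_length: int = 6
    max_peptide_length: int = 30

    def __post_init__(self) -> None:
        if len(self.residue_distribution) != 20:
            raise ValueError("residue_distribution needs 20 probabilities")
        if abs(sum(self.residue_distribution) - 1.0) > 1e-9:
            raise ValueError("residue_distribution must sum to 1")
        if not self.signal_weights or all(
                w == 0 for w in self.signal_weights.values()):
            raise ValueError("need at least one nonzero signal weight")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.zero_fraction < 1.0):
            raise ValueError("zero_fraction must lie in [0, 1)")
        lo, hi = self.protein_length
        if lo < 1 or hi < lo:
            raise ValueError("invalid protein_length range")


def generate_proteome(config: SimulationConfig,
                      fasta_path: Optional[Union[str, Path]] = None
                      ) -> list[ProteinRecord]:
    """i.i.d. random proteins; deterministic per seed; optional FASTA output."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length
    probs = np.asarray(config.residue_distribution)
    alphabet = np.array(list(AMINO_ACIDS))
    width = len(str(config.n_proteins))
    records = []
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(alphabet, size=length, p=probs))
        records.append(ProteinRecord(id=f"sim{i + 1:0{width}d}", sequence=seq))
    if fasta_path is not None:
        write_fasta(records, fasta_path)
    return records


def simulate_intensities(
    proteome: Sequence[ProteinRecord],
    config: SimulationConfig,
    registry: Optional[FeatureRegistry] = None,
    tsv_path: Optional[Union[str, Path]] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Simulated intensity table over all proteotypic tryptic peptides.

    Returns (table, skipped) where ``skipped`` lists proteins without any
    proteotypic candidate. The table uses the ingestion dialect: columns
    protein_id, peptide_sequence, xic_area (tab-delimited when written).
    """
    registry = registry or default_registry()
    rng = np.random.default_rng([config.seed, 0x51])
    parent_map = tryptic_parent_map(proteome)
    by_id = {p.id: p for p in proteome}

    peptides, pids = [], []
    skipped: list[str] = []
    for prot in proteome:
        cands = proteotypic_peptides(
            prot, proteome, min_length=config.min_peptide_length,
            max_length=config.max_peptide_length, parent_map=parent_map)
        if not cands:
            skipped.append(prot.id)
            continue
        peptides.extend(cands)
        pids.extend([prot.id] * len(cands))

    X = np.array([registry.featurize(p, by_id[pid])
                  for p, pid in zip(peptides, pids)])
    z = Standardizer.fit(X).apply(X)
    names = registry.names
    signal = np.zeros(len(peptides))
    for fname, w in config.signal_weights.items():
        signal += w * z[:, names.index(fname)]
    observability = 1.0 / (1.0 + np.exp(-signal))

    noise = (np.exp(config.noise_sd * rng.standard_normal(len(peptides)))
             if config.noise_sd > 0 else 1.0)
    xic = observability * noise * XIC_SCALE
    if config.zero_fraction > 0:
        censored = rng.random(len(peptides)) < config.zero_fraction
        xic = np.where(censored, 0.0, xic)

    table = pd.DataFrame({
        "protein_id": pids,
        "peptide_sequence": [p.sequence for p in peptides],
        "xic_area": xic,
    })
    if tsv_path is not None:
        table.to_csv(tsv_path, sep="\t", index=False)
    return table, skipped


def groups_from_table(table: pd.DataFrame,
                      proteome: Sequence[ProteinRecord],
                      config: SimulationConfig) -> list[QueryGroup]:
    """Assemble query groups directly from a simulated table.

    Equivalent to writing the TSV and re-reading it with
    ``load_intensity_table`` (the peptides already are the proteotypic
    fully-tryptic candidates); groups whose peptides were all censored to
    zero are dropped.
    """
    parent_map = tryptic_parent_map(proteome)
    by_id = {p.id: p for p in proteome}
    groups = []
    for pid, sub in table.groupby("protein_id", sort=True):
        cands = proteotypic_peptides(
            by_id[pid], proteome, min_length=config.min_peptide_length,
            max_length=config.max_peptide_length, parent_map=parent_map)
        xic_by_seq = dict(zip(sub["peptide_sequence"], sub["xic_area"]))
        group = make_query_group(
            pid, cands, [float(xic_by_seq.get(p.sequence, 0.0))
                         for p in cands])
        if group is not None:
            groups.append(group)
    return groups


STANDARD_CONFIG = SimulationConfig()
STANDARD_SPLIT = SplitSpec(validation_fraction=0.2, seed=11)


@dataclass
class FixtureBundle:
    """The canonical synthetic benchmark: fixed data, fixed split."""

    train: list[QueryGroup]
    heldout: list[QueryGroup]
    proteome: list[ProteinRecord]
    config: SimulationConfig


def standard_fixture(noise_sd: float = STANDARD_CONFIG.noise_sd,
                     zero_fraction: float = STANDARD_CONFIG.zero_fraction,
                     registry: Optional[FeatureRegistry] = None
                     ) -> FixtureBundle:
    """750 simulated proteins split 600 train / 150 held out (split seed 11).

    Signal weights put +2.0 on the hydrophobicity index and −1.0 on peptide
    length; noise_sd 0.2 and zero_fraction 0.1 unless overridden (the
    noiseless variant uses 0 for both). Regenerates bit-identically.
    """
    config = replace(STANDARD_CONFIG, noise_sd=noise_sd,
                     zero_fraction=zero_fraction)
    proteome = generate_proteome(config)
    table, _ = simulate_intensities(proteome, config, registry=registry)
    groups = groups_from_table(table, proteome, config)
    train, heldout = split_proteins(groups, STANDARD_SPLIT)
    return FixtureBundle(train=train, heldout=heldout, proteome=proteome,
                         config=config)
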