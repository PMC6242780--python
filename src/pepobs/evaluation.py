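"""Ranking-quality evaluation with nDCG@k.

The normalized discounted cumulative gain credits a prediction for placing
the truly most observable peptides at the top of the list and discounts
mistakes further down:

    DCG@k  = Σ_{i=1..k} gain(s(p_i)) / log2(1 + i)
    nDCG@k = DCG@k / IDCG@k

where s(p_i) is the observed relevance (relative XIC intensity) of the
peptide predicted at position i and IDCG is the DCG of the ideal
(descending-relevance) ordering.

A literal log2 of the relevance score is undefined at s = 0 and negative
for s < 1, so the default gain is the shifted transform gain(s) =
log2(1 + s): zero at s = 0, positive otherwise, and preserving the
logarithmic shape. A graded-levels alternative (relevance binned into L
integer grades, gain = log2(grade)) is available via
:class:`GainTransform`. Groups smaller than k are scored at the effective
cutoff k' = min(k, n). When every gain in a group is zero the ideal DCG
vanishes; such groups score 1.0 by convention and are flagged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .network import TrainedModel, predict
from .proteins import ProteinRecord
from .queries import QueryGroup


@dataclass(frozen=True)
class GainTransform:
    """Maps a relevance score in [0, 1] to a non-negative gain.

    ``log2_shift`` (default): gain(s) = log2(1 + s).
    ``graded_levels``: s is binned to integer grades 1..levels and the gain
    is log2(grade) — monotone non-decreasing, zero on the lowest grade.
    """

    mode: str = "log2_shift"
    levels: int = 5

    def __post_init__(self) -> None:
        if self.mode not in ("log2_shift", "graded_levels"):
            raise ValueError(f"unknown gain mode {self.mode!r}")
        if self.mode == "graded_levels" and self.levels < 2:
            raise ValueError("graded_levels needs at least 2 levels")

    def __call__(self, s: float) -> float:
        if s < 0:
            raise ValueError("relevance must be non-negative")
        if self.mode == "log2_shift":
            return math.log2(1.0 + s)
        grade = 1 + int(round(min(s, 1.0) * (self.levels - 1)))
        return math.log2(grade)


DEFAULT_GAIN = GainTransform()


@dataclass
class RankedPrediction:
    """Peptide sequences in predicted order with *observed* relevances attached."""

    protein_id: str
    sequences: list[str]
    relevances: list[float]

    def __post_init__(self) -> None:
        if len(self.sequences) != len(self.relevances):
            raise ValueError("sequences and relevances differ in length")


def dcg(relevances: Sequence[float], k: int, gain: GainTransform = DEFAULT_GAIN
        ) -> float:
    return sum(
        gain(s) / math.log2(1 + i)
        for i, s in enumerate(relevances[:k], start=1)
    )


def ndcg_at_k(
    prediction: RankedPrediction,
    k: int,
    gain: GainTransform = DEFAULT_GAIN,
) -> float:
    value, _ = ndcg_with_flag(prediction, k, gain)
    return value


def ndcg_with_flag(
    prediction: RankedPrediction,
    k: int,
    gain: GainTransform = DEFAULT_GAIN,
) -> tuple[float, bool]:
    """nDCG@k plus a flag marking the degenerate all-zero-gain case.

    The effective cutoff is min(k, group size). Returns (value, degenerate);
    degenerate groups score 1.0 by convention.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not prediction.sequences:
        raise ValueError(f"empty group {prediction.protein_id!r}")
    kk = min(k, len(prediction.sequences))
    ideal = sorted(prediction.relevances, reverse=True)
    idcg = dcg(ideal, kk, gain)
    if idcg == 0.0:
        return 1.0, True
    return dcg(prediction.relevances, kk, gain) / idcg, False


def rank_group(
    model: TrainedModel,
    group: QueryGroup,
    database: dict[str, ProteinRecord],
) -> RankedPrediction:
    """Order a query group by the model's predicted observability.

    Ties in the predicted score are broken lexicographically by peptide
    sequence before scoring, so the result is deterministic.
    """
    X = model.registry.featurize_many(group.peptides, database)
    if model.standardizer is not None:
        X = model.standardizer.apply(X)
    scores = predict(model, X)
    order = sorted(range(len(group)),
                   key=lambda i: (-scores[i], group.entries[i].peptide.sequence))
    return RankedPrediction(
        protein_id=group.protein_id,
        sequences=[group.entries[i].peptide.sequence for i in order],
        relevances=[group.entries[i].relevance for i in order],
    )


def random_baseline(
    group: QueryGroup,
    k: int,
    n_permutations: int,
    seed: int,
    gain: GainTransform = DEFAULT_GAIN,
) -> np.ndarray:
    """nDCG@k of uniformly random orderings of the group (seeded)."""
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    rel = np.array([e.relevance for e in group.entries])
    seqs = [e.peptide.sequence for e in group.entries]
    values = np.empty(n_permutations)
    for r in range(n_permutations):
        order = rng.permutation(len(rel))
        pred = RankedPrediction(
            protein_id=group.protein_id,
            sequences=[seqs[i] for i in order],
            relevances=[float(rel[i]) for i in order],
        )
        values[r] = ndcg_at_k(pred, k, gain)
    return values


@dataclass
class GroupScore:
    protein_id: str
    n_peptides: int
    ndcg: float
    degenerate: bool
    single_peptide: bool


@dataclass
class EvaluationReport:
    """Per-protein nDCG table plus distribution summary."""

    k: int
    scores: list[GroupScore]
    median: float
    quartiles: tuple[float, float]
    ecdf: list[tuple[float, float]]
    n_single_peptide: int

    def values(self) -> np.ndarray:
        return np.array([s.ndcg for s in self.scores])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "protein_id": [s.protein_id for s in self.scores],
                "n_peptides": [s.n_peptides for s in self.scores],
                f"ndcg_at_{self.k}": [s.ndcg for s in self.scores],
                "degenerate": [s.degenerate for s in self.scores],
                "single_peptide": [s.single_peptide for s in self.scores],
            }
        )

    def summary_dict(self) -> dict:
        return {
            "k": self.k,
            "n_groups": len(self.scores),
            "n_single_peptide": self.n_single_peptide,
            "median": self.median,
            "q1": self.quartiles[0],
            "q3": self.quartiles[1],
            "ecdf": self.ecdf,
        }


def summarize_scores(protein_ids: Sequence[str], ns: Sequence[int],
                     values: Sequence[float], flags: Sequence[bool],
                     k: int) -> EvaluationReport:
    scores = [
        GroupScore(pid, n, float(v), bool(f), n == 1)
        for pid, n, v, f in zip(protein_ids, ns, values, flags)
    ]
    arr = np.array([s.ndcg for s in scores])
    ordered = np.sort(arr)
    ecdf = [(float(v), float((i + 1) / len(ordered)))
            for i, v in enumerate(ordered)]
    return EvaluationReport(
        k=k,
        scores=scores,
        median=float(np.median(arr)),
        quartiles=(float(np.percentile(arr, 25)),
                   float(np.percentile(arr, 75))),
        ecdf=ecdf,
        n_single_peptide=sum(s.single_peptide for s in scores),
    )


def evaluate_dataset(
    model: TrainedModel,
    groups: Sequence[QueryGroup],
    database: Sequence[ProteinRecord] | dict[str, ProteinRecord],
    k: int = 4,
    gain: GainTransform = DEFAULT_GAIN,
) -> EvaluationReport:
    """One nDCG@k per query group under the model's predicted ordering.

    Single-peptide groups score 1.0 (only one ordering exists); they are
    included in the summary but counted separately.
    """
    if not groups:
        raise ValueError("no groups to evaluate")
    if not isinstance(database, dict):
        database = {p.id: p for p in database}
    pids, ns, values, flags = [], [], [], []
    for group in groups:
        pred = rank_group(model, group, database)
        value, degenerate = ndcg_with_flag(pred, k, gain)
        pids.append(group.protein_id)
        ns.append(len(group))
        values.append(value)
        flags.append(degenerate)
    return summarize_scores(pids, ns, values, flags, k)
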