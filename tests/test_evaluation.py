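"""nDCG@k scoring, permutation oracles, and random baselines."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import pepobs as pb
from pepobs.evaluation import (
    DEFAULT_GAIN,
    GainTransform,
    RankedPrediction,
    dcg,
    summarize_scores,
)


def prediction(relevances, protein_id="p"):
    seqs = [f"PEP{i}" for i in range(len(relevances))]
    return RankedPrediction(protein_id, seqs, list(relevances))


def brute_force_ndcg(relevances, k, gain=DEFAULT_GAIN):
    """Direct evaluation of the formula, independent of the implementation."""
    kk = min(k, len(relevances))
    num = sum(gain(s) / math.log2(1 + i)
              for i, s in enumerate(relevances[:kk], start=1))
    ideal = sorted(relevances, reverse=True)
    den = sum(gain(s) / math.log2(1 + i)
              for i, s in enumerate(ideal[:kk], start=1))
    return num / den if den else 1.0


def make_group(relevances, protein_id="p"):
    prot = pb.ProteinRecord("src", "MAAAGLK")
    pep = pb.digest(prot, 0)[0]
    entries = [pb.QueryEntry(pep, float(r), float(r)) for r in relevances]
    return pb.QueryGroup(protein_id, entries)


# --- gain transforms -------------------------------------------------------


def test_default_gain_is_zero_at_zero_and_increasing():
    assert DEFAULT_GAIN(0.0) == 0.0
    grid = np.linspace(0, 1, 50)
    values = [DEFAULT_GAIN(s) for s in grid]
    assert all(b > a for a, b in zip(values, values[1:]))
    assert all(v >= 0 for v in values)


def test_graded_gain_levels():
    gain = GainTransform(mode="graded_levels", levels=4)
    assert gain(0.0) == 0.0  # grade 1 -> log2(1)
    assert gain(1.0) == pytest.approx(2.0)  # grade 4
    assert gain(0.5) >= gain(0.0)


def test_unknown_gain_mode_rejected():
    with pytest.raises(ValueError):
        GainTransform(mode="linear")


# --- nDCG ------------------------------------------------------------------


def test_ideal_ordering_scores_one():
    pred = prediction([1.0, 0.8, 0.6, 0.4, 0.2])
    assert pb.ndcg_at_k(pred, 4) == pytest.approx(1.0)


def test_single_peptide_group_scores_one():
    assert pb.ndcg_at_k(prediction([0.4]), 4) == 1.0


def test_derived_three_peptide_example():
    """Relevances (1, .5, 0) predicted in order (.5, 1, 0), k = 3."""
    pred = prediction([0.5, 1.0, 0.0])
    expected = (
        (math.log2(1.5) / math.log2(2) + math.log2(2.0) / math.log2(3))
        / (math.log2(2.0) / math.log2(2) + math.log2(1.5) / math.log2(3))
    )
    value = pb.ndcg_at_k(pred, 3)
    assert value == pytest.approx(expected)
    assert value == pytest.approx(brute_force_ndcg([0.5, 1.0, 0.0], 3))
    # no non-ideal permutation beats the ideal one
    best = max(brute_force_ndcg(list(p), 3)
               for p in itertools.permutations([1.0, 0.5, 0.0]))
    assert value < best == pytest.approx(1.0)


def test_all_zero_gains_score_one_with_flag():
    value, degenerate = pb.ndcg_with_flag(prediction([0.0, 0.0]), 2)
    assert value == 1.0 and degenerate
    value, degenerate = pb.ndcg_with_flag(prediction([1.0, 0.0]), 2)
    assert not degenerate


def test_empty_group_is_an_error():
    with pytest.raises(ValueError):
        pb.ndcg_at_k(prediction([]), 4)


def test_ndcg_matches_exhaustive_permutation_oracle():
    """All orderings of groups of <= 6 peptides, against the direct formula."""
    rng = np.random.default_rng(8)
    for size in range(2, 7):
        rel = np.round(rng.random(size), 3)
        rel[rng.integers(size)] = 1.0  # groups always contain the max
        for perm in itertools.permutations(rel):
            pred = prediction(list(perm))
            for k in (1, 4, size):
                value = pb.ndcg_at_k(pred, k)
                assert value == pytest.approx(
                    brute_force_ndcg(list(perm), k))
                assert 0.0 <= value <= 1.0 + 1e-12


def test_ideal_uniquely_maximizes_ndcg_for_distinct_gains():
    rel = [1.0, 0.7, 0.4, 0.1]
    scores = {
        perm: pb.ndcg_at_k(prediction(list(perm)), 4)
        for perm in itertools.permutations(rel)
    }
    ideal = tuple(sorted(rel, reverse=True))
    best = max(scores.values())
    assert scores[ideal] == pytest.approx(1.0)
    assert all(v < best for perm, v in scores.items() if perm != ideal)


def test_swapping_correct_adjacent_pair_never_increases_ndcg():
    rng = np.random.default_rng(4)
    for _ in range(50):
        rel = sorted(rng.random(5), reverse=True)
        base = pb.ndcg_at_k(prediction(rel), 4)
        for i in range(4):
            swapped = rel.copy()
            swapped[i], swapped[i + 1] = swapped[i + 1], swapped[i]
            assert pb.ndcg_at_k(prediction(swapped), 4) <= base + 1e-12


def test_ndcg_depends_only_on_relevances_not_intensity_units():
    # identical relevance profiles from different raw intensity scales
    g1 = make_group([1.0, 0.5, 0.25])
    xics = [8000.0, 4000.0, 2000.0]
    g2 = pb.make_query_group("q", [e.peptide for e in g1.entries], xics)
    assert [e.relevance for e in g2.entries] == [1.0, 0.5, 0.25]


# --- random baseline -------------------------------------------------------


def test_baseline_single_peptide_always_one():
    values = pb.random_baseline(make_group([0.7]), 4, 10, seed=0)
    assert np.all(values == 1.0)


def test_baseline_mean_below_one_with_distinct_relevances():
    group = make_group([1.0, 0.3, 0.1])
    values = pb.random_baseline(group, 3, 300, seed=1)
    assert values.mean() < 1.0


def test_baseline_two_peptides_matches_exact_enumeration():
    group = make_group([1.0, 0.0])
    exact = (1.0 + brute_force_ndcg([0.0, 1.0], 2)) / 2
    values = pb.random_baseline(group, 2, 4000, seed=3)
    assert values.mean() == pytest.approx(exact, abs=0.02)


def test_baseline_converges_to_exhaustive_average():
    rng = np.random.default_rng(6)
    for size in (3, 4, 5):
        rel = list(np.round(rng.random(size), 3))
        group = make_group(rel)
        exact = np.mean([
            brute_force_ndcg(list(p), 4)
            for p in itertools.permutations(rel)
        ])
        values = pb.random_baseline(group, 4, 3000, seed=size)
        assert values.mean() == pytest.approx(exact, abs=0.02)


# --- dataset evaluation ----------------------------------------------------


class RelevanceOracle:
    """A stand-in model whose prediction is the observed relevance itself."""


def test_perfect_model_scores_median_one(small_sim, small_model):
    proteome, groups, _ = small_sim
    # oracle: replace predicted ordering by ideal ordering per group
    pids, ns, vals, flags = [], [], [], []
    for g in groups[:20]:
        order = np.argsort(-g.relevances, kind="stable")
        pred = RankedPrediction(
            g.protein_id,
            [g.entries[i].peptide.sequence for i in order],
            [g.entries[i].relevance for i in order],
        )
        v, f = pb.ndcg_with_flag(pred, 4)
        pids.append(g.protein_id), ns.append(len(g))
        vals.append(v), flags.append(f)
    report = summarize_scores(pids, ns, vals, flags, 4)
    assert report.median == pytest.approx(1.0)


def test_evaluate_dataset_report_structure(small_sim, small_model):
    proteome, groups, _ = small_sim
    report = pb.evaluate_dataset(small_model, groups, proteome, k=4)
    assert len(report.scores) == len(groups)
    values = report.values()
    assert np.all((0 <= values) & (values <= 1 + 1e-12))
    assert report.ecdf[-1][1] == pytest.approx(1.0)
    assert report.ecdf[-1][0] == pytest.approx(values.max())
    frame = report.to_frame()
    assert list(frame.columns)[:3] == ["protein_id", "n_peptides",
                                       "ndcg_at_4"]


def test_constant_model_ranks_by_lexicographic_tiebreak(small_sim):
    proteome, groups, _ = small_sim
    cfg = pb.ModelConfig(hidden_layers=1, nodes_per_layer=4)
    model = pb.build_network(cfg, n_features=45)
    for w in model.weights:
        w[:] = 0.0
    group = groups[0]
    by_id = {p.id: p for p in proteome}
    pred = pb.rank_group(model, group, by_id)
    assert pred.sequences == sorted(pred.sequences)
    # hand-check on a 3-peptide slice: lexicographic order decides the score
    rel = dict(zip(pred.sequences, pred.relevances))
    expected = brute_force_ndcg([rel[s] for s in sorted(rel)], 4)
    assert pb.ndcg_at_k(pred, 4) == pytest.approx(expected)
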