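"""Physicochemical features: correctness against independent oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pepobs as pb
from pepobs.aaindex_tables import KYTE_DOOLITTLE, WOLFENDEN_HYDRATION
from pepobs.features import (
    CleavagePropensityTable,
    MONOISOTOPIC_MASS,
    PKA_NEGATIVE,
    PKA_POSITIVE,
    PKA_CTERM,
    PKA_NTERM,
    WATER_MONOISOTOPIC,
)
from pepobs.proteins import AMINO_ACIDS

peptide_seq = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=60)


# --- registry --------------------------------------------------------------


def test_default_registry_has_45_uniquely_named_entries():
    reg = pb.default_registry()
    assert len(reg) == 45
    names = reg.names
    assert len(set(names)) == 45
    kinds = [e.kind.value for e in reg.entries]
    assert kinds.count("aa_frequency") == 20
    assert kinds.count("general") == 9
    assert kinds.count("aaindex_mean") == 12
    assert kinds.count("digestion") == 4


def test_featurize_is_pure_and_ordered(toy_database):
    reg = pb.default_registry()
    prot = toy_database[0]
    pep = pb.digest(prot, 0, min_length=4)[0]
    v1 = reg.featurize(pep, prot)
    v2 = reg.featurize(pep, prot)
    assert v1.shape == (45,)
    assert np.array_equal(v1, v2)
    assert v1[reg.index_of("peptide_length")] == len(pep.sequence)


def test_registry_round_trips_through_dict():
    reg = pb.default_registry().with_propensities(
        CleavagePropensityTable({("K", "A"): 0.7}, default=0.4))
    restored = pb.FeatureRegistry.from_dict(reg.to_dict())
    assert restored.names == reg.names
    assert restored.checksum() == reg.checksum()
    assert restored.propensities.lookup("K", "A") == 0.7


# --- amino-acid frequencies ------------------------------------------------


def test_aa_frequency_counting():
    freqs = pb.aa_frequencies("AAG")
    lookup = dict(zip(AMINO_ACIDS, freqs))
    assert lookup["A"] == pytest.approx(2 / 3)
    assert lookup["G"] == pytest.approx(1 / 3)
    assert sum(v for k, v in lookup.items() if k not in "AG") == 0


def test_aa_frequency_empty_sequence_error():
    with pytest.raises(ValueError):
        pb.aa_frequencies("")


@settings(max_examples=150, deadline=None)
@given(peptide_seq)
def test_aa_frequencies_sum_to_one(seq):
    assert abs(pb.aa_frequencies(seq).sum() - 1.0) < 1e-12


# --- molecular weight ------------------------------------------------------


def test_molecular_weight_of_glycine():
    assert pb.molecular_weight("G") == pytest.approx(75.03202, abs=1e-4)


def test_molecular_weight_additivity_and_composition():
    assert pb.molecular_weight("GG") == pytest.approx(
        pb.molecular_weight("G") + MONOISOTOPIC_MASS["G"])
    assert pb.molecular_weight("AG") == pb.molecular_weight("GA")


@settings(max_examples=50, deadline=None)
@given(peptide_seq)
def test_molecular_weight_matches_pyteomics(seq):
    """Cross-check the embedded constants against an independent library."""
    from pyteomics import mass

    assert pb.molecular_weight(seq) == pytest.approx(
        mass.fast_mass(seq), abs=5e-3)


# --- charge and isoelectric point ------------------------------------------


def grid_isoelectric_point(seq: str, step: float = 1e-4) -> float:
    """Brute-force oracle: vectorized charge over a dense pH grid."""
    phs = np.arange(0.0, 14.0 + step, step)
    charge = 1.0 / (1.0 + 10.0 ** (phs - PKA_NTERM))
    charge = charge - 1.0 / (1.0 + 10.0 ** (PKA_CTERM - phs))
    for aa, pka in PKA_POSITIVE.items():
        charge = charge + seq.count(aa) / (1.0 + 10.0 ** (phs - pka))
    for aa, pka in PKA_NEGATIVE.items():
        charge = charge - seq.count(aa) / (1.0 + 10.0 ** (pka - phs))
    return float(phs[np.argmin(np.abs(charge))])


def test_charge_sign_at_ph_extremes_and_monotonicity():
    seq = "MAVLKDDE"
    assert pb.net_charge(seq, 0.0) > 0
    assert pb.net_charge(seq, 14.0) < 0
    values = [pb.net_charge(seq, ph) for ph in np.linspace(0, 14, 30)]
    assert all(a > b for a, b in zip(values, values[1:]))


def test_isoelectric_point_zeroes_the_charge():
    for seq in ["MAVLK", "DDEEY", "GGHRK", "W"]:
        assert abs(pb.net_charge(seq, pb.isoelectric_point(seq))) < 1e-2


def test_basic_peptides_have_higher_pi_than_acidic():
    assert pb.isoelectric_point("KKKKK") > pb.isoelectric_point("DDDDD")


def test_isoelectric_point_matches_grid_oracle():
    rng = np.random.default_rng(11)
    for _ in range(100):
        seq = "".join(rng.choice(list(AMINO_ACIDS),
                                 size=int(rng.integers(1, 40))))
        assert abs(pb.isoelectric_point(seq)
                   - grid_isoelectric_point(seq)) < 2e-3


# --- index means -----------------------------------------------------------


def test_aaindex_mean_homopolymer_equals_table_value():
    assert pb.aaindex_mean("AAAA", KYTE_DOOLITTLE) == KYTE_DOOLITTLE["A"]


def test_aaindex_mean_is_composition_only():
    assert pb.aaindex_mean("AG", WOLFENDEN_HYDRATION) == pytest.approx(
        (WOLFENDEN_HYDRATION["A"] + WOLFENDEN_HYDRATION["G"]) / 2)
    assert pb.aaindex_mean("AGW", KYTE_DOOLITTLE) == pytest.approx(
        pb.aaindex_mean("WGA", KYTE_DOOLITTLE))


def test_index_table_tsv_round_trip(tmp_path):
    from pepobs.aaindex_tables import read_index_table

    f = tmp_path / "scale.tsv"
    f.write_text("".join(f"{aa}\t{i / 7.0}\n"
                         for i, aa in enumerate(AMINO_ACIDS)))
    table = read_index_table(f, name="custom")
    assert table["C"] == pytest.approx(1 / 7.0)


# --- digestion probabilities -----------------------------------------------


def test_protein_terminal_peptides_get_probability_one(toy_database):
    prot = toy_database[0]
    peps = pb.digest(prot, 0)
    first, last = peps[0], peps[-1]
    n0, _ = pb.digestion_probabilities(first, prot)
    _, c1 = pb.digestion_probabilities(last, prot)
    assert n0 == 1.0 and c1 == 1.0


def test_uniform_table_gives_unit_probabilities(toy_database):
    prot = toy_database[0]
    for pep in pb.digest(prot, 0):
        assert pb.digestion_probabilities(pep, prot) == (1.0, 1.0)


def test_constructed_zero_propensity_table_is_looked_up():
    prot = pb.ProteinRecord("p", "AAKGGR")
    table = CleavagePropensityTable({("K", "G"): 0.0}, default=1.0)
    first, second = pb.digest(prot, 0)
    assert pb.digestion_probabilities(first, prot, table) == (1.0, 0.0)
    assert pb.digestion_probabilities(second, prot, table) == (0.0, 1.0)


def test_estimated_propensities_reflect_observed_cleavage():
    db = [pb.ProteinRecord("p", "AAKGGKTTR")]
    peps = pb.digest(db[0], 0)  # AAK GGK TTR
    group = pb.make_query_group("p", peps, [5.0, 0.0, 0.0])
    table = pb.estimate_cleavage_propensities([group], db)
    # site after AAK (K|G) observed as a terminus; site after GGK (K|T) not
    assert table.lookup("K", "G") == pytest.approx(2 / 3)
    assert table.lookup("K", "T") == pytest.approx(1 / 3)


# --- standardizer ----------------------------------------------------------


def test_standardizer_centers_and_scales():
    rng = np.random.default_rng(0)
    X = rng.normal(3.0, 2.0, size=(50, 4))
    std = pb.Standardizer.fit(X)
    Z = std.apply(X)
    assert np.abs(Z.mean(axis=0)).max() < 1e-9
    assert np.allclose(Z.std(axis=0), 1.0)


def test_constant_feature_standardizes_to_zero():
    X = np.column_stack([np.arange(5.0), np.full(5, 7.0)])
    Z = pb.Standardizer.fit(X).apply(X)
    assert np.all(Z[:, 1] == 0.0)


def test_standardizer_round_trip_is_stable():
    X = np.random.default_rng(1).normal(size=(10, 3))
    std = pb.Standardizer.fit(X)
    restored = pb.Standardizer.from_dict(std.to_dict())
    assert np.array_equal(std.apply(X), restored.apply(X))


# --- whole-vector properties -----------------------------------------------


@settings(max_examples=100, deadline=None)
@given(peptide_seq)
def test_all_features_finite_for_any_valid_peptide(seq):
    prot = pb.ProteinRecord("p", seq)
    reg = pb.default_registry()
    for pep in pb.digest(prot, 0):
        vec = reg.featurize(pep, prot)
        assert np.all(np.isfinite(vec))
        assert abs(vec[:20].sum() - 1.0) < 1e-9


def test_composition_features_permutation_invariant():
    """Only terminal digestion probabilities depend on peptide position."""
    reg = pb.default_registry().with_propensities(
        CleavagePropensityTable({("K", "W"): 0.3, ("K", "G")            : 0.8},
                                default=0.5))
    p1 = pb.ProteinRecord("a", "AAKWGVMR")
    p2 = pb.ProteinRecord("b", "AAKGVWMR")
    pep1 = pb.digest(p1, 0)[1]  # WGVMR
    pep2 = pb.digest(p2, 0)[1]  # GVWMR, same composition
    v1, v2 = reg.featurize(pep1, p1), reg.featurize(pep2, p2)
    dig_idx = {reg.index_of("n_term_digestion_probability"),
               reg.index_of("c_term_digestion_probability")}
    same = [i for i in range(45) if i not in dig_idx]
    assert np.allclose(v1[same], v2[same])
    assert v1[reg.index_of("n_term_digestion_probability")] == 0.3
    assert v2[reg.index_of("n_term_digestion_probability")] == 0.8
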