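"""Physicochemical feature vectors for peptides.

Each candidate peptide is converted into an ordered 45-entry numerical
footprint:

* 20 amino-acid relative frequencies (alphabetical residue order),
* 9 general properties: monoisotopic molecular weight, isoelectric point,
  peptide length, net charge at pH 7, counts of positively and negatively
  charged residues, relative frequencies of polar, hydrophobic and
  negatively charged residues,
* 12 per-residue index scales averaged over the peptide
  (:mod:`pepobs.aaindex_tables`),
* 4 digestion-related entries: a second hydrophobicity scale
  (Kyte–Doolittle mean), the missed-cleavage frequency (missed cleavages
  per residue, retained as a negative control since candidates are fully
  tryptic), and the C- and N-terminal digestion probabilities from a
  flanking-residue cleavage-propensity table.

Feature order is fixed by the registry and serialized with any trained
model; prediction refuses vectors from a different registry version.
"""

from __future__ import annotations

import enum
import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .aaindex_tables import (
    DEFAULT_AAINDEX_FEATURES,
    KYTE_DOOLITTLE,
    ResidueIndexTable,
)
from .digestion import PeptideRecord, cleavage_sites
from .proteins import AMINO_ACIDS, ProteinRecord

# Monoisotopic residue masses (Da), standard values; peptide mass adds one
# water (18.010565 Da) for the termini.
MONOISOTOPIC_MASS = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}
WATER_MONOISOTOPIC = 18.010565

# EMBOSS pKa values (iep program defaults).
PKA_NTERM = 8.6
PKA_CTERM = 3.6
PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}

POSITIVE_RESIDUES = frozenset("KRH")
NEGATIVE_RESIDUES = frozenset("DE")
POLAR_RESIDUES = frozenset("STNQYH")
HYDROPHOBIC_RESIDUES = frozenset("AVLIMFWC")


def aa_frequencies(sequence: str) -> np.ndarray:
    """Relative residue frequencies in alphabetical residue order; sums to 1."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = np.array([sequence.count(aa) for aa in AMINO_ACIDS], dtype=float)
    return counts / len(sequence)


def molecular_weight(sequence: str) -> float:
    """Monoisotopic peptide mass in Da (residue masses + one water)."""
    return sum(MONOISOTOPIC_MASS[aa] for aa in sequence) + WATER_MONOISOTOPIC


def net_charge(sequence: str, pH: float) -> float:
    """Henderson–Hasselbalch net charge over termini and ionizable side chains."""
    charge = 1.0 / (1.0 + 10.0 ** (pH - PKA_NTERM))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_CTERM - pH))
    for aa in sequence:
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10.0 ** (pH - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE[aa] - pH))
    return charge


def isoelectric_point(sequence: str, tol: float = 1e-3) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, positive at 0 and
    negative at 14, so the root exists and is unique.
    """
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(sequence, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def aaindex_mean(sequence: str, table: ResidueIndexTable,
                 aggregate: str = "mean") -> float:
    """Per-residue index aggregated over the peptide (arithmetic mean or sum)."""
    total = sum(table[aa] for aa in sequence)
    if aggregate == "sum":
        return total
    return total / len(sequence)


# ---------------------------------------------------------------------------
# Cleavage propensities


@dataclass(frozen=True)
class CleavagePropensityTable:
    """Probability that trypsin cleaves a site, by flanking residue pair.

    Keyed by (P1, P1') — the residue before and after the scissile bond.
    Pairs absent from the table fall back to ``default`` (1.0 for the
    unfitted identity table).
    """

    probabilities: Mapping[tuple[str, str], float] = field(default_factory=dict)
    default: float = 1.0

    def lookup(self, p1: str, p1_prime: str) -> float:
        return float(self.probabilities.get((p1, p1_prime), self.default))

    def to_dict(self) -> dict:
        return {
            "default": self.default,
            "probabilities": {f"{a}{b}": v
                              for (a, b), v in self.probabilities.items()},
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "CleavagePropensityTable":
        probs = {(k[0], k[1]): float(v)
                 for k, v in payload.get("probabilities", {}).items()}
        return cls(probabilities=probs, default=float(payload.get("default", 1.0)))


UNIFORM_PROPENSITIES = CleavagePropensityTable()


def digestion_probabilities(
    peptide: PeptideRecord,
    parent: ProteinRecord,
    table: CleavagePropensityTable = UNIFORM_PROPENSITIES,
) -> tuple[float, float]:
    """(n_term, c_term) probabilities of the cleavage events creating the peptide.

    A terminus coinciding with the protein boundary requires no cleavage and
    gets probability 1.0.
    """
    seq = parent.sequence
    if not (0 <= peptide.start < peptide.end <= len(seq)):
        raise ValueError("peptide coordinates outside parent")
    if seq[peptide.start:peptide.end] != peptide.sequence:
        raise ValueError("peptide sequence does not match parent coordinates")
    n_term = (1.0 if peptide.start == 0
              else table.lookup(seq[peptide.start - 1], seq[peptide.start]))
    c_term = (1.0 if peptide.end == len(seq)
              else table.lookup(seq[peptide.end - 1], seq[peptide.end]))
    return n_term, c_term


def estimate_cleavage_propensities(groups, database: Sequence[ProteinRecord]
                                   ) -> CleavagePropensityTable:
    """Empirical cleavage propensities from an ingested intensity table.

    For each retained protein, a tryptic site counts as *cleaved* when it is
    a terminus of at least one quantified (XIC > 0) peptide, otherwise as
    uncleaved; probabilities per (P1, P1') pair use add-one smoothing.
    """
    by_id = {p.id: p for p in database}
    cleaved: dict[tuple[str, str], int] = {}
    total: dict[tuple[str, str], int] = {}
    for group in groups:
        parent = by_id.get(group.protein_id)
        if parent is None:
            continue
        seq = parent.sequence
        observed: set[int] = set()
        for entry in group.entries:
            if entry.xic > 0:
                observed.update((entry.peptide.start, entry.peptide.end))
        for site in cleavage_sites(seq):
            pair = (seq[site - 1], seq[site])
            total[pair] = total.get(pair, 0) + 1
            if site in observed:
                cleaved[pair] = cleaved.get(pair, 0) + 1
    probs = {
        pair: (cleaved.get(pair, 0) + 1) / (n + 2)
        for pair, n in total.items()
    }
    return CleavagePropensityTable(probabilities=probs, default=0.5)


# ---------------------------------------------------------------------------
# Registry


class FeatureKind(enum.Enum):
    AA_FREQUENCY = "aa_frequency"
    GENERAL = "general"
    AAINDEX_MEAN = "aaindex_mean"
    DIGESTION = "digestion"


@dataclass(frozen=True)
class FeatureEntry:
    name: str
    kind: FeatureKind


GENERAL_FEATURES = (
    "molecular_weight",
    "isoelectric_point",
    "peptide_length",
    "net_charge",
    "positive_residue_count",
    "negative_residue_count",
    "polar_residue_fraction",
    "hydrophobic_residue_fraction",
    "negative_residue_fraction",
)

DIGESTION_FEATURES = (
    "hydrophobicity_index_2",
    "missed_cleavage_frequency",
    "c_term_digestion_probability",
    "n_term_digestion_probability",
)


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered, named feature definition shared by training and prediction.

    The registry owns the per-residue index tables, the cleavage-propensity
    table, the aggregation mode for index features, and a version string.
    ``version`` plus the table checksums identify the feature space a model
    was trained in.
    """

    aaindex: tuple[ResidueIndexTable, ...] = DEFAULT_AAINDEX_FEATURES
    propensities: CleavagePropensityTable = UNIFORM_PROPENSITIES
    aggregate: str = "mean"
    version: str = "pepobs-45-v1"
    net_charge_ph: float = 7.0

    @property
    def entries(self) -> list[FeatureEntry]:
        out = [FeatureEntry(f"frequency_{aa}", FeatureKind.AA_FREQUENCY)
               for aa in AMINO_ACIDS]
        out += [FeatureEntry(n, FeatureKind.GENERAL) for n in GENERAL_FEATURES]
        out += [FeatureEntry(t.name, FeatureKind.AAINDEX_MEAN)
                for t in self.aaindex]
        out += [FeatureEntry(n, FeatureKind.DIGESTION)
                for n in DIGESTION_FEATURES]
        names = [e.name for e in out]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in registry")
        return out

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return 20 + len(GENERAL_FEATURES) + len(self.aaindex) + len(DIGESTION_FEATURES)

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def with_propensities(self, table: CleavagePropensityTable) -> "FeatureRegistry":
        return replace(self, propensities=table)

    def featurize(self, peptide: PeptideRecord, parent: ProteinRecord
                  ) -> np.ndarray:
        """One ordered feature vector for one peptide; pure and deterministic."""
        seq = peptide.sequence
        freqs = aa_frequencies(seq)
        n_term, c_term = digestion_probabilities(peptide, parent,
                                                 self.propensities)
        general = [
            molecular_weight(seq),
            isoelectric_point(seq),
            float(len(seq)),
            net_charge(seq, self.net_charge_ph),
            float(sum(seq.count(aa) for aa in POSITIVE_RESIDUES)),
            float(sum(seq.count(aa) for aa in NEGATIVE_RESIDUES)),
            sum(seq.count(aa) for aa in POLAR_RESIDUES) / len(seq),
            sum(seq.count(aa) for aa in HYDROPHOBIC_RESIDUES) / len(seq),
            sum(seq.count(aa) for aa in NEGATIVE_RESIDUES) / len(seq),
        ]
        indices = [aaindex_mean(seq, t, self.aggregate) for t in self.aaindex]
        dig = [
            aaindex_mean(seq, KYTE_DOOLITTLE, self.aggregate),
            peptide.missed_cleavages / len(seq),
            c_term,
            n_term,
        ]
        vec = np.concatenate([freqs, general, indices, dig])
        if not np.all(np.isfinite(vec)):
            raise ValueError(f"non-finite feature for peptide {seq!r}")
        return vec

    def featurize_many(self, peptides: Sequence[PeptideRecord],
                       database: Sequence[ProteinRecord] | Mapping[str, ProteinRecord]
                       ) -> np.ndarray:
        if not isinstance(database, Mapping):
            database = {p.id: p for p in database}
        return np.array([self.featurize(p, database[p.parent_id])
                         for p in peptides])

    def checksum(self) -> str:
        payload = json.dumps(
            {
                "version": self.version,
                "aggregate": self.aggregate,
                "tables": [t.checksum() for t in self.aaindex],
                "propensities": self.propensities.to_dict(),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "aggregate": self.aggregate,
            "net_charge_ph": self.net_charge_ph,
            "aaindex": [
                {"name": t.name, "source": t.source,
                 "values": {aa: t.values[aa] for aa in AMINO_ACIDS}}
                for t in self.aaindex
            ],
            "propensities": self.propensities.to_dict(),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "FeatureRegistry":
        tables = tuple(
            ResidueIndexTable(name=t["name"], values=t["values"],
                              source=t.get("source", "user"))
            for t in payload["aaindex"]
        )
        return cls(
            aaindex=tables,
            propensities=CleavagePropensityTable.from_dict(
                payload.get("propensities", {})),
            aggregate=payload.get("aggregate", "mean"),
            version=payload["version"],
            net_charge_ph=float(payload.get("net_charge_ph", 7.0)),
        )


def default_registry() -> FeatureRegistry:
    """The 45-entry registry (20 frequencies + 9 general + 12 indices + 4 digestion)."""
    return FeatureRegistry()


# ---------------------------------------------------------------------------
# Standardization


@dataclass(frozen=True)
class Standardizer:
    """Per-feature z-scaling fitted on the training matrix.

    Features with zero spread get sd 1.0 so they standardize to zero instead
    of dividing by zero. Parameters travel with the trained model.
    """

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, matrix: np.ndarray) -> "Standardizer":
        matrix = np.asarray(matrix, dtype=float)
        if matrix.ndim != 2 or matrix.shape[0] < 2:
            raise ValueError("need a 2-D matrix with at least 2 rows")
        mean = matrix.mean(axis=0)
        sd = matrix.std(axis=0, ddof=0)
        sd = np.where(sd == 0.0, 1.0, sd)
        return cls(mean=mean, sd=sd)

    def apply(self, matrix: np.ndarray) -> np.ndarray:
        return (np.asarray(matrix, dtype=float) - self.mean) / self.sd

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "sd": self.sd.tolist()}

    @classmethod
    def from_dict(cls, payload: dict) -> "Standardizer":
        return cls(mean=np.asarray(payload["mean"], dtype=float),
                   sd=np.asarray(payload["sd"], dtype=float))
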