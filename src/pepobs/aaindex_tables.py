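"""Per-residue physicochemical index tables.

A :class:`ResidueIndexTable` maps every canonical residue to one real value,
the shape of an AAindex-style scale. The default registry averages twelve of
these over a peptide, plus a second hydrophobicity scale in the
digestion-related block.

Two scales are standard published tables embedded verbatim:

* ``hydrophobicity_index`` — Wolfenden et al. (1981) water-to-vapor hydration
  potentials, kcal/mol (hydrophobic side chains positive, charged/polar
  strongly negative; glycine side chain = H, proline taken as 0 since the
  imino acid was not measured).
* ``hydrophobicity_index_2`` — Kyte & Doolittle (1982) hydropathy index.

The remaining eleven named tables are SYNTHETIC stand-ins: hand-constructed
values reproducing the qualitative character of the named property (which
residues score high or low) but not any published accession, which is not
bundled with this package. They are deterministic constants and can be
replaced by a user-supplied two-column TSV via :func:`read_index_table`;
``source`` in each table says which kind it is.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import math

from .proteins import AMINO_ACIDS


@dataclass(frozen=True)
class ResidueIndexTable:
    """A complete, finite scale over the 20 canonical residues."""

    name: str
    values: Mapping[str, float]
    source: str = "user"

    def __post_init__(self) -> None:
        missing = set(AMINO_ACIDS) - set(self.values)
        if missing:
            raise ValueError(f"table {self.name!r} missing residues {sorted(missing)}")
        for aa, v in self.values.items():
            if not math.isfinite(v):
                raise ValueError(f"table {self.name!r}: non-finite value for {aa}")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]

    def checksum(self) -> str:
        import hashlib

        payload = ";".join(f"{aa}={self.values[aa]!r}" for aa in AMINO_ACIDS)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_index_table(path: Union[str, Path], name: str | None = None) -> ResidueIndexTable:
    """Read a two-column TSV (residue, value) with one row per residue."""
    values: dict[str, float] = {}
    path = Path(path)
    for i, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{i}: expected two tab-separated columns")
        values[parts[0].strip().upper()] = float(parts[1])
    return ResidueIndexTable(name=name or path.stem, values=values)


def _table(name: str, source: str, **values: float) -> ResidueIndexTable:
    return ResidueIndexTable(name=name, values=values, source=source)


# Wolfenden R, Andersson L, Cullis PM, Southgate CC (1981) Biochemistry
# 20:849-855, hydration potential kcal/mol (AAindex-style orientation).
WOLFENDEN_HYDRATION = _table(
    "hydrophobicity_index", "published: Wolfenden 1981 hydration potential",
    A=1.94, R=-19.92, N=-9.68, D=-10.95, C=-1.24, Q=-9.38, E=-10.20,
    G=2.39, H=-10.27, I=2.15, L=2.28, K=-9.52, M=-1.48, F=-0.76, P=0.00,
    S=-5.06, T=-4.88, W=-5.88, Y=-6.11, V=1.99,
)

# Kyte J, Doolittle RF (1982) J Mol Biol 157:105-132, hydropathy index.
KYTE_DOOLITTLE = _table(
    "hydrophobicity_index_2", "published: Kyte-Doolittle 1982 hydropathy",
    A=1.8, R=-4.5, N=-3.5, D=-3.5, C=2.5, Q=-3.5, E=-3.5, G=-0.4, H=-3.2,
    I=4.5, L=3.8, K=-3.9, M=1.9, F=2.8, P=-1.6, S=-0.8, T=-0.7, W=-0.9,
    Y=-1.3, V=4.2,
)

_SYN = "synthetic stand-in (no published accession bundled)"

# Activation Gibbs energy of unfolding at pH 9.0 — buried hydrophobics
# stabilize the fold, so they carry the larger values (arbitrary kJ/mol-like
# scale).
ACTIVATION_GIBBS_UNFOLDING = _table(
    "gibbs_energy_unfolding_ph9", _SYN,
    A=7.2, R=5.1, N=5.4, D=5.0, C=8.1, Q=5.6, E=5.2, G=6.1, H=6.3, I=9.0,
    L=8.8, K=4.8, M=8.3, F=8.9, P=5.9, S=6.0, T=6.4, W=8.6, Y=7.5, V=8.7,
)

# MEM amino-acid composition of single-spanning membrane proteins (mol%) —
# transmembrane helices are rich in L, I, V, F, A and depleted of charges.
MEM_COMPOSITION_SINGLE_SPANNING = _table(
    "mem_composition_single_spanning", _SYN,
    A=9.1, R=1.8, N=2.4, D=1.5, C=2.6, Q=2.0, E=1.6, G=6.8, H=1.4, I=11.2,
    L=16.0, K=1.7, M=3.9, F=9.3, P=2.5, S=5.4, T=5.2, W=3.1, Y=3.6, V=10.9,
)

# Sneath-style principal component II — a size/polarity contrast axis.
PRINCIPAL_COMPONENT_II = _table(
    "principal_component_ii", _SYN,
    A=-0.6, R=0.9, N=0.5, D=0.6, C=-0.3, Q=0.4, E=0.5, G=-0.9, H=0.3,
    I=-0.7, L=-0.7, K=0.8, M=-0.4, F=-0.5, P=0.1, S=0.0, T=-0.1, W=-0.2,
    Y=0.2, V=-0.8,
)

# Chou-Fasman-style coil conformation parameter — turn/coil formers G, P,
# N, S, D high; helix formers A, E, L, M low.
CHOU_FASMAN_COIL = _table(
    "chou_fasman_coil", _SYN,
    A=0.71, R=0.95, N=1.37, D=1.21, C=1.19, Q=0.87, E=0.84, G=1.52, H=0.95,
    I=0.66, L=0.69, K=0.99, M=0.67, F=0.71, P=1.61, S=1.34, T=1.08, W=0.76,
    Y=1.07, V=0.63,
)

# Average number of surrounding residues within 8 Å — a buriedness measure;
# hydrophobic cores are densely packed.
AVG_SURROUNDING_RESIDUES = _table(
    "avg_surrounding_residues", _SYN,
    A=6.1, R=4.6, N=4.8, D=4.7, C=7.0, Q=4.9, E=4.6, G=5.7, H=5.4, I=7.2,
    L=7.0, K=4.2, M=6.9, F=7.1, P=4.9, S=5.2, T=5.5, W=6.7, Y=6.0, V=7.1,
)

# Interior composition of intracellular proteins of mesophiles (mol%) —
# protein interiors favor aliphatics.
INTERIOR_COMPOSITION_MESOPHILE = _table(
    "interior_composition_mesophile", _SYN,
    A=10.3, R=2.3, N=2.9, D=3.1, C=2.0, Q=2.5, E=3.3, G=8.5, H=2.1, I=9.0,
    L=11.4, K=2.8, M=3.0, F=6.0, P=3.2, S=4.9, T=4.8, W=1.7, Y=3.9, V=12.3,
)

# Neural-network coil weight at window position −3 — small signed weights.
COIL_WEIGHT_POSITION_M3 = _table(
    "coil_weight_window_m3", _SYN,
    A=-0.12, R=0.05, N=0.18, D=0.21, C=0.02, Q=-0.03, E=-0.08, G=0.27,
    H=0.04, I=-0.19, L=-0.16, K=0.07, M=-0.10, F=-0.06, P=0.31, S=0.16,
    T=0.09, W=-0.04, Y=0.08, V=-0.21,
)

# Helix-formation ΔΔG (kcal/mol relative to alanine) — A most favorable,
# P and G strongly unfavorable.
HELIX_FORMATION_DDG = _table(
    "helix_formation_ddg", _SYN,
    A=0.00, R=0.21, N=0.65, D=0.69, C=0.68, Q=0.39, E=0.40, G=1.00, H=0.61,
    I=0.41, L=0.21, K=0.26, M=0.24, F=0.54, P=3.16, S=0.50, T=0.66, W=0.49,
    Y=0.53, V=0.61,
)

# Free energy in alpha-helical region (kcal/mol) — helix-propensity-like.
FREE_ENERGY_ALPHA_HELIX = _table(
    "free_energy_alpha_helix", _SYN,
    A=-0.86, R=-0.52, N=0.25, D=0.10, C=0.12, Q=-0.41, E=-0.55, G=0.71,
    H=0.02, I=-0.35, L=-0.62, K=-0.44, M=-0.58, F=-0.19, P=2.50, S=0.11,
    T=0.23, W=-0.17, Y=0.05, V=-0.25,
)

# Average relative fractional occurrence in extended-left EL(i) states.
AVG_FRACTIONAL_OCCURRENCE_EL = _table(
    "avg_fractional_occurrence_el", _SYN,
    A=0.90, R=0.95, N=1.05, D=1.02, C=1.14, Q=0.98, E=0.86, G=1.10, H=1.01,
    I=1.12, L=0.96, K=0.93, M=0.94, F=1.08, P=0.88, S=1.04, T=1.09, W=1.07,
    Y=1.13, V=1.16,
)

# Composition of extracellular proteins (mol%) — secreted proteins are
# enriched in C, S, T, G (disulfides, O-glycosylation sites).
EXTRACELLULAR_COMPOSITION = _table(
    "extracellular_composition", _SYN,
    A=7.1, R=3.6, N=5.3, D=5.5, C=4.8, Q=3.9, E=4.7, G=9.1, H=1.9, I=4.2,
    L=7.0, K=4.9, M=1.5, F=3.4, P=5.1, S=9.3, T=7.2, W=1.4, Y=4.3, V=5.8,
)

#: The twelve peptide-averaged scales of the default registry, in order.
DEFAULT_AAINDEX_FEATURES: tuple[ResidueIndexTable, ...] = (
    ACTIVATION_GIBBS_UNFOLDING,
    MEM_COMPOSITION_SINGLE_SPANNING,
    PRINCIPAL_COMPONENT_II,
    WOLFENDEN_HYDRATION,
    CHOU_FASMAN_COIL,
    AVG_SURROUNDING_RESIDUES,
    INTERIOR_COMPOSITION_MESOPHILE,
    COIL_WEIGHT_POSITION_M3,
    HELIX_FORMATION_DDG,
    FREE_ENERGY_ALPHA_HELIX,
    AVG_FRACTIONAL_OCCURRENCE_EL,
    EXTRACELLULAR_COMPOSITION,
)
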