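"""In-silico tryptic digestion and peptide uniqueness classification.

Trypsin cleaves C-terminal of lysine (K) or arginine (R) except when the
next residue is proline (P) — the standard "keep KP/RP intact" convention.
Peptides carry 0-based half-open coordinates in their parent protein and a
missed-cleavage count (internal K/R sites not followed by P that were left
uncut).

A peptide is *proteotypic* when its sequence occurs as a tryptic peptide in
exactly one protein of the database (the class-1a notion of a distinct
peptide, collapsed to a proteotypic/shared dichotomy at the parent-protein
level: a sequence repeated inside a single protein is still proteotypic).
By default isoleucine and leucine are distinct residues for uniqueness; pass
``il_equivalent=True`` to merge them.
"""

from __future__ import annotations

import enum
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .proteins import ProteinRecord


class UniquenessClass(enum.Enum):
    PROTEOTYPIC = "proteotypic"
    SHARED = "shared"
    UNCLASSIFIED = "unclassified"


@dataclass
class PeptideRecord:
    """A digestion product.

    ``start``/``end`` are 0-based half-open coordinates in the parent named
    by ``parent_id`` (the protein the peptide was digested from);
    ``parent_ids`` collects every database protein containing the sequence
    as a tryptic peptide once classified.
    """

    sequence: str
    parent_id: str
    start: int
    end: int
    missed_cleavages: int
    parent_ids: set[str] = field(default_factory=set)
    uniqueness_class: UniquenessClass = UniquenessClass.UNCLASSIFIED

    def __post_init__(self) -> None:
        if not self.parent_ids:
            self.parent_ids = {self.parent_id}

    def __len__(self) -> int:
        return len(self.sequence)


def cleavage_sites(sequence: str) -> list[int]:
    """Positions i such that trypsin cuts between i-1 and i.

    A site after K/R at index i-1 is suppressed when sequence[i] == 'P'.
    The protein C-terminus is not a site.
    """
    return [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in "KR" and sequence[i] != "P"
    ]


def count_missed_cleavages(sequence: str) -> int:
    """Internal K/R-not-before-P sites left uncut within a peptide."""
    return len(cleavage_sites(sequence))


def digest(
    protein: ProteinRecord,
    max_missed: int = 0,
    min_length: int = 0,
    max_length: Optional[int] = None,
) -> list[PeptideRecord]:
    """All tryptic peptides of ``protein`` with 0..max_missed missed cleavages.

    With ``max_missed=0`` the peptides tile the protein exactly. Length
    bounds apply to the emitted candidates only (defaults impose none, so the
    tiling invariant holds); training/prediction pipelines typically use
    6–30 residues.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = protein.sequence
    bounds = [0] + cleavage_sites(seq) + [len(seq)]
    peptides: list[PeptideRecord] = []
    for i in range(len(bounds) - 1):
        for m in range(max_missed + 1):
            j = i + 1 + m
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            pep = seq[start:end]
            if len(pep) < min_length:
                continue
            if max_length is not None and len(pep) > max_length:
                continue
            peptides.append(
                PeptideRecord(
                    sequence=pep,
                    parent_id=protein.id,
                    start=start,
                    end=end,
                    missed_cleavages=m,
                )
            )
    return peptides


def tryptic_parent_map(
    database: Sequence[ProteinRecord],
    max_missed: int = 2,
    il_equivalent: bool = False,
) -> dict[str, set[str]]:
    """Map each tryptic peptide sequence to the database proteins containing it.

    ``max_missed`` controls how many missed cleavages count as "occurring as
    a tryptic peptide" in another protein; two is the usual search-engine
    ceiling and is a superset of the fully-tryptic candidates being
    classified.
    """
    parents: dict[str, set[str]] = defaultdict(set)
    for prot in database:
        for pep in digest(prot, max_missed=max_missed):
            key = pep.sequence.replace("I", "L") if il_equivalent else pep.sequence
            parents[key].add(prot.id)
    return dict(parents)


def classify_peptides(
    peptides: Iterable[PeptideRecord],
    database: Sequence[ProteinRecord],
    max_missed: int = 2,
    il_equivalent: bool = False,
) -> list[PeptideRecord]:
    """Set the uniqueness class of every peptide against the database.

    Proteotypic iff the sequence occurs as a tryptic peptide in exactly one
    database protein.
    """
    parent_map = tryptic_parent_map(database, max_missed, il_equivalent)
    out = []
    for pep in peptides:
        key = pep.sequence.replace("I", "L") if il_equivalent else pep.sequence
        parents = parent_map.get(key, {pep.parent_id})
        cls = (
            UniquenessClass.PROTEOTYPIC
            if len(parents) == 1
            else UniquenessClass.SHARED
        )
        out.append(replace(pep, parent_ids=set(parents), uniqueness_class=cls))
    return out


def proteotypic_peptides(
    protein: ProteinRecord,
    database: Sequence[ProteinRecord],
    min_length: int = 6,
    max_length: int = 30,
    il_equivalent: bool = False,
    parent_map: Optional[dict[str, set[str]]] = None,
) -> list[PeptideRecord]:
    """Fully tryptic (0 missed cleavages) proteotypic candidates of one protein.

    This is the candidate set used for training and prediction: digestion at
    zero missed cleavages, length-bounded, then filtered to proteotypic
    peptides. Callers looping over many proteins should precompute
    ``parent_map = tryptic_parent_map(database)`` once and pass it in.
    """
    if parent_map is None:
        parent_map = tryptic_parent_map(database, il_equivalent=il_equivalent)
    peps = digest(protein, max_missed=0, min_length=min_length,
                  max_length=max_length)
    out = []
    for pep in peps:
        key = pep.sequence.replace("I", "L") if il_equivalent else pep.sequence
        parents = parent_map.get(key, {pep.parent_id})
        if len(parents) == 1:
            out.append(replace(pep, parent_ids=set(parents),
                               uniqueness_class=UniquenessClass.PROTEOTYPIC))
    return out
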