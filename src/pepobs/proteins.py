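"""Protein records and FASTA input.

A protein database is a list of :class:`ProteinRecord` objects over the
20-letter canonical amino-acid alphabet. Records with non-canonical residues
(B, J, O, U, X, Z, ``*`` stops, lowercase masking, gaps) are collected into a
rejection report instead of being silently dropped, so a user can see exactly
which database entries were unusable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


class FastaError(ValueError):
    """Raised for malformed or empty FASTA input."""


@dataclass(frozen=True)
class ProteinRecord:
    """One database entry: identifier plus amino-acid sequence.

    The sequence must be non-empty, uppercase, and restricted to the 20
    canonical residues.
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _AA_SET
        if bad:
            raise ValueError(
                f"protein {self.id!r}: non-canonical residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RejectedRecord:
    """A FASTA entry that failed validation, with the reason."""

    id: str
    reason: str


@dataclass
class FastaReport:
    """Outcome of reading a database: accepted records plus rejections."""

    records: list[ProteinRecord] = field(default_factory=list)
    rejected: list[RejectedRecord] = field(default_factory=list)


def read_fasta(path: Union[str, Path]) -> FastaReport:
    """Read a protein FASTA database, validating every entry.

    The header token before the first whitespace becomes the record id.
    Multi-line (wrapped) sequences are concatenated. Duplicate ids and an
    empty file raise :class:`FastaError`; entries with invalid residues are
    returned in ``report.rejected`` rather than raising.
    """
    path = Path(path)
    if not path.exists():
        raise FastaError(f"no such file: {path}")
    report = FastaReport()
    seen: set[str] = set()
    try:
        entries = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Bio raises assorted ValueErrors
        raise FastaError(f"malformed FASTA {path}: {exc}") from exc
    if not entries:
        raise FastaError(f"empty or non-FASTA file: {path}")
    for entry in entries:
        rid = entry.id
        if rid in seen:
            raise FastaError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        seq = str(entry.seq).upper()
        try:
            report.records.append(ProteinRecord(id=rid, sequence=seq))
        except ValueError as exc:
            report.rejected.append(RejectedRecord(id=rid, reason=str(exc)))
    return report


def parse_fasta(path: Union[str, Path]) -> list[ProteinRecord]:
    """Read a FASTA database, raising if any entry is invalid.

    Convenience wrapper around :func:`read_fasta` for pipelines that require
    a fully clean database.
    """
    report = read_fasta(path)
    if report.rejected:
        detail = "; ".join(f"{r.id}: {r.reason}" for r in report.rejected[:5])
        raise FastaError(
            f"{len(report.rejected)} invalid record(s): {detail}"
        )
    return report.records


def write_fasta(records: Iterable[ProteinRecord], path: Union[str, Path],
                width: int = 60) -> None:
    """Write records as wrapped FASTA (deterministic byte layout)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")
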