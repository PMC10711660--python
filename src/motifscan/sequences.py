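"""Protein sequences, residue spans and motif-residue lookup.

All residue coordinates in the package are 1-based and inclusive, matching
the convention in which interface residues are labelled (W99, S744, ...).
A :class:`SequenceRecord` may represent a subsequence of a longer protein;
its ``offset`` is the global index of its first residue, so global residue
numbering is preserved across slicing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .errors import AmbiguityError, BoundsError, ConfigError, FormatError, NotFoundError

#: The 20 standard one-letter codes plus 'X' for unknown residues.
AMINO_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY") | {"X"}


@dataclass(frozen=True, order=True)
class Span:
    """A 1-based inclusive residue range ``[start, end]``."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise BoundsError(f"span start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise BoundsError(f"empty or inverted span ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, index: int) -> bool:
        return self.start <= index <= self.end

    def contains_span(self, other: "Span") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlap(self, other: "Span") -> "Span | None":
        lo, hi = max(self.start, other.start), min(self.end, other.end)
        return Span(lo, hi) if lo <= hi else None

    def shift(self, delta: int) -> "Span":
        return Span(self.start + delta, self.end + delta)

    def indices(self) -> Iterator[int]:
        return iter(range(self.start, self.end + 1))


@dataclass(frozen=True)
class SequenceRecord:
    """A named amino-acid sequence with global 1-based numbering.

    ``offset`` is the global index of the first stored residue; a record
    parsed from FASTA has ``offset == 1`` while a record returned by
    :func:`subsequence` keeps the numbering of its parent.
    """

    id: str
    residues: str
    offset: int = 1

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.residues) - AMINO_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r} contains non-amino-acid letters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def span(self) -> Span:
        """The global span covered by this record."""
        return Span(self.offset, self.offset + len(self.residues) - 1)

    def residue_at(self, index: int) -> str:
        """One-letter code at global position ``index``."""
        if not self.span.contains(index):
            raise BoundsError(
                f"index {index} outside record {self.id!r} span "
                f"({self.span.start}, {self.span.end})"
            )
        return self.residues[index - self.offset]


def parse_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    Residues are uppercased, whitespace is stripped, record order is
    preserved. Duplicate ids, empty files and non-amino-acid letters raise
    :class:`~motifscan.errors.FormatError`.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = "".join(str(rec.seq).split()).upper()
        records.append(SequenceRecord(id=rec.id, residues=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records, wrapping lines at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def subsequence(record: SequenceRecord, span: Span) -> SequenceRecord:
    """Slice ``record`` to a global ``span``, keeping global numbering."""
    if not record.span.contains_span(span):
        raise BoundsError(
            f"span ({span.start}, {span.end}) outside record {record.id!r} "
            f"({record.span.start}, {record.span.end})"
        )
    start = span.start - record.offset
    return SequenceRecord(
        id=record.id,
        residues=record.residues[start : start + span.length],
        offset=span.start,
    )


def locate_unique_residue(record: SequenceRecord, span: Span, letter: str) -> int:
    """Global index of the single residue in ``span`` equal to ``letter``.

    Raises :class:`NotFoundError` for zero matches and
    :class:`AmbiguityError` (listing all positions) for several. Queries
    for the unknown-residue letter 'X' are rejected.
    """
    letter = letter.upper()
    if letter == "X" or letter not in AMINO_ALPHABET:
        raise ConfigError(f"cannot query for residue letter {letter!r}")
    if not record.span.contains_span(span):
        raise BoundsError(
            f"span ({span.start}, {span.end}) outside record {record.id!r}"
        )
    hits = [i for i in span.indices() if record.residue_at(i) == letter]
    if not hits:
        raise NotFoundError(
            f"no {letter!r} in {record.id!r} within ({span.start}, {span.end})"
        )
    if len(hits) > 1:
        raise AmbiguityError(
            f"{letter!r} occurs at positions {hits} in {record.id!r} "
            f"within ({span.start}, {span.end})"
        )
    return hits[0]


def bundled_sequences() -> dict[str, SequenceRecord]:
    """The packaged BmGtsf1L / BmVreteno sequences, keyed by id."""
    from importlib.resources import as_file, files

    fasta = files("motifscan").joinpath("data/sequences.fasta")
    with as_file(fasta) as p:
        return {rec.id: rec for rec in parse_fasta(p)}


#: Default C-terminal tail of the 101-residue prey sequence: the tail is 39
#: residues long, hence it starts at 101 - 39 + 1 = 63.
DEFAULT_TAIL_SPAN = Span(63, 101)
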