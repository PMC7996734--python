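"""Alignment and secondary-structure I/O.

Reads aligned FASTA and Clustal files into a normalized :class:`Alignment`
(uppercase RNA over ``{A,C,G,U,-}``), maintains per-row coordinate maps
between alignment columns and ungapped sequence positions, and parses /
writes dot-bracket secondary structures.

All coordinates are 1-based, closed intervals. Helix indices such as 55.5
arise as ``(i+j)/2`` of 1-based columns, so the half-integer convention of
the rest of the package depends on this choice.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "Alignment",
    "AlignmentFormatError",
    "CoordinateMap",
    "SecondaryStructure",
    "StructureError",
    "coordinate_map",
    "parse_dotbracket",
    "read_alignment",
    "write_dotbracket",
]

#: Gap characters accepted on input; all are normalized to '-'.
GAP_CHARS = {"-", ".", "~"}

#: Alphabet after normalization.
RNA_ALPHABET = frozenset("ACGU-")

#: IUPAC one-letter codes that are recognisably nucleotides but carry
#: ambiguity; they are rejected rather than silently mapped because the
#: covariance score is defined on concrete bases only.
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHVN")


class AlignmentFormatError(ValueError):
    """Raised for ragged rows, empty input, or characters outside the alphabet."""


class StructureError(ValueError):
    """Raised for unbalanced or geometrically invalid dot-bracket strings."""


def _normalize_row(raw: str, row_id: str) -> str:
    out = []
    for ch in raw.upper():
        if ch == "T":
            ch = "U"
        if ch in GAP_CHARS:
            ch = "-"
        if ch not in RNA_ALPHABET:
            if ch in IUPAC_AMBIGUITY:
                raise AlignmentFormatError(
                    f"row {row_id!r}: IUPAC ambiguity code {ch!r} is not supported "
                    "(covariance scoring needs concrete bases)"
                )
            raise AlignmentFormatError(
                f"row {row_id!r}: character {ch!r} is not a nucleotide or gap"
            )
        out.append(ch)
    return "".join(out)


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment of homologous RNAs.

    ``M == 1`` degenerates to single-sequence mode, in which the covariance
    contribution of the pseudo free energy is vacuous.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentFormatError("alignment has no rows")
        ref = len(self.rows[0])
        for rid, r in zip(self.ids, self.rows):
            if len(r) != ref:
                raise AlignmentFormatError(
                    f"ragged alignment: row {rid!r} has length {len(r)}, expected {ref}"
                )
        if len(self.rows[0]) < 1:
            raise AlignmentFormatError("alignment rows are empty")
        for rid, r in zip(self.ids, self.rows):
            bad = set(r) - RNA_ALPHABET
            if bad:
                raise AlignmentFormatError(f"row {rid!r}: invalid characters {sorted(bad)}")

    @property
    def M(self) -> int:
        """Number of rows (sequences)."""
        return len(self.rows)

    @property
    def L(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0])

    def column(self, i: int) -> str:
        """The alignment column *i* (1-based) as a string of length M."""
        if not 1 <= i <= self.L:
            raise IndexError(f"column {i} out of range 1..{self.L}")
        return "".join(r[i - 1] for r in self.rows)

    def ungapped(self, row: int) -> str:
        """Row *row* (1-based) with gaps removed."""
        if not 1 <= row <= self.M:
            raise IndexError(f"row {row} out of range 1..{self.M}")
        return self.rows[row - 1].replace("-", "")

    @classmethod
    def from_rows(cls, rows: Iterable[str], ids: Iterable[str] | None = None) -> "Alignment":
        rows = tuple(rows)
        if ids is None:
            ids = tuple(f"seq{i+1}" for i in range(len(rows)))
        else:
            ids = tuple(ids)
        norm = tuple(_normalize_row(r, rid) for rid, r in zip(ids, rows))
        return cls(ids=ids, rows=norm)


def _dedupe_ids(ids: list[str]) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for rid in ids:
        if rid in seen:
            seen[rid] += 1
            out.append(f"{rid}_{seen[rid]}")
        else:
            seen[rid] = 0
            out.append(rid)
    return out


def read_alignment(path: str | Path, format: str | None = None) -> Alignment:
    """Read an aligned FASTA or Clustal file into a normalized Alignment.

    ``format`` is ``"fasta"`` or ``"clustal"``; when omitted it is inferred
    from the first non-blank line (``CLUSTAL`` header vs ``>``). Rows of
    unequal length raise :class:`AlignmentFormatError` naming the offending
    row; an empty file raises as well. Clustal conservation lines are
    ignored by the underlying parser and duplicate identifiers receive
    numeric suffixes.
    """
    path = Path(path)
    text = path.read_text()
    if format is None:
        first = next((ln for ln in text.splitlines() if ln.strip()), "")
        format = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    if format not in {"fasta", "clustal"}:
        raise ValueError(f"unsupported format {format!r}")
    try:
        records = list(SeqIO.parse(io.StringIO(text), format))
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    if not records:
        raise AlignmentFormatError(f"{path}: no sequences found")
    ids = _dedupe_ids([rec.id for rec in records])
    rows = [str(rec.seq) for rec in records]
    ref_len = len(rows[0])
    for rid, row in zip(ids, rows):
        if len(row) != ref_len:
            raise AlignmentFormatError(
                f"{path}: ragged row {rid!r} (length {len(row)}, expected {ref_len})"
            )
    return Alignment.from_rows(rows, ids)


@dataclass(frozen=True)
class CoordinateMap:
    """Bijection between non-gap alignment columns and ungapped positions of one row."""

    row: int
    col_to_pos: dict[int, int] = field(hash=False)
    pos_to_col: dict[int, int] = field(hash=False)

    def pos(self, col: int) -> int | None:
        """Ungapped 1-based position for alignment column *col*, or None on a gap."""
        return self.col_to_pos.get(col)

    def col(self, pos: int) -> int:
        return self.pos_to_col[pos]


def coordinate_map(aln: Alignment, row: int) -> CoordinateMap:
    """Map alignment columns of *row* (1-based) to ungapped sequence positions.

    Gap columns have no image; non-gap columns map to 1..(ungapped length)
    in order, so alignment-born gaps shift helix indices between alignment
    and individual-sequence coordinates.
    """
    if not 1 <= row <= aln.M:
        raise IndexError(f"row {row} out of range 1..{aln.M}")
    c2p: dict[int, int] = {}
    p2c: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(aln.rows[row - 1], start=1):
        if ch != "-":
            pos += 1
            c2p[col] = pos
            p2c[pos] = col
    return CoordinateMap(row=row, col_to_pos=c2p, pos_to_col=p2c)


@dataclass(frozen=True)
class SecondaryStructure:
    """A set of non-crossing base pairs over 1-based positions/columns.

    ``min_hairpin`` is relaxed to 0 for structures produced by projecting a
    consensus structure onto a gapped row, where the geometric hairpin
    constraint no longer applies in sequence coordinates.
    """

    length: int
    pairs: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        _validate_pairs(self.length, self.pairs, min_hairpin=0)

    @staticmethod
    def make(length: int, pairs: Iterable[tuple[int, int]], min_hairpin: int = 3) -> "SecondaryStructure":
        pairs = frozenset((min(i, j), max(i, j)) for i, j in pairs)
        _validate_pairs(length, pairs, min_hairpin=min_hairpin)
        return SecondaryStructure(length=length, pairs=pairs)

    @property
    def is_open_chain(self) -> bool:
        return not self.pairs

    def sorted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.pairs)

    def dotbracket(self) -> str:
        return write_dotbracket(self)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.dotbracket()


def _validate_pairs(length: int, pairs: frozenset[tuple[int, int]], min_hairpin: int) -> None:
    occupied: set[int] = set()
    for i, j in pairs:
        if not (1 <= i < j <= length):
            raise StructureError(f"pair ({i},{j}) out of range 1..{length}")
        if i in occupied or j in occupied:
            raise StructureError(f"position reused by pair ({i},{j})")
        occupied.update((i, j))
    sp = sorted(pairs)
    for a in range(len(sp)):
        i, j = sp[a]
        for b in range(a + 1, len(sp)):
            k, l = sp[b]
            if k > j:
                break
            if i < k <= j < l:
                raise StructureError(f"crossing pairs ({i},{j}) and ({k},{l})")
    if min_hairpin > 0:
        paired_or_inner = sorted(pairs)
        for i, j in paired_or_inner:
            inner = [p for p in pairs if i < p[0] and p[1] < j]
            if not inner and j - i - 1 < min_hairpin:
                raise StructureError(
                    f"hairpin closed by ({i},{j}) has {j - i - 1} unpaired positions (< {min_hairpin})"
                )


def parse_dotbracket(text: str) -> SecondaryStructure:
    """Parse a dot-bracket string into a SecondaryStructure.

    Only ``(``, ``)`` and ``.`` are accepted; parentheses are matched
    innermost-first. Unbalanced strings and hairpins with fewer than three
    unpaired positions raise :class:`StructureError`.
    """
    text = text.strip()
    bad = set(text) - set("().")
    if bad:
        raise StructureError(f"invalid characters in dot-bracket: {sorted(bad)}")
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for idx, ch in enumerate(text, start=1):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {idx}")
            pairs.add((stack.pop(), idx))
    if stack:
        raise StructureError(f"unbalanced '(' at position {stack[-1]}")
    return SecondaryStructure.make(len(text), pairs, min_hairpin=3)


def write_dotbracket(s: SecondaryStructure) -> str:
    """Render a SecondaryStructure as a dot-bracket string (round-trips with the parser)."""
    chars = ["."] * s.length
    for i, j in s.pairs:
        chars[i - 1] = "("
        chars[j - 1] = ")"
    return "".join(chars)
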