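"""Alignment, group-table and residue-mapping primitives.

The analyses in this package all operate on a single master multiple sequence
alignment of a protein family.  Columns are addressed by 1-based *alignment
index*; individual residues are additionally addressed by their 1-based
position in the ungapped sequence (the *residue number*), so that a site can
be reported in the familiar "His25{142}" style — residue number 25 of a given
sequence, alignment index 142.

Input alignments may be GCG MSF (the interleaved PileUp format) or aligned
FASTA.  On input every sequence is normalized to the 20 canonical amino
acids, the gap symbol '-', and 'X' for unknown residues: the MSF gap dialects
'.' and '~' become '-', and the ambiguity codes B, Z, J, U, O become 'X'.
'X' is kept distinct from the gap because it occupies a real position in the
protein (it advances the residue number), but the scoring modules treat it as
missing data.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import AlignIO

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"
ALPHABET = frozenset(AA20 + GAP + UNKNOWN)

_GAP_TRANS = str.maketrans({".": GAP, "~": GAP,
                            "B": UNKNOWN, "Z": UNKNOWN, "J": UNKNOWN,
                            "U": UNKNOWN, "O": UNKNOWN})


class AlignmentFormatError(ValueError):
    """Raised when an input file violates its declared alignment format."""


class LookupError_(KeyError):
    """Raised for unknown sequence ids or out-of-range alignment indices."""


def normalize_sequence(seq: str) -> str:
    """Uppercase, map gap dialects to '-' and ambiguity codes to 'X'."""
    out = seq.upper().translate(_GAP_TRANS)
    bad = set(out) - ALPHABET
    if bad:
        raise AlignmentFormatError(
            f"illegal characters {sorted(bad)} in sequence (after normalization)")
    return out


@dataclass(frozen=True)
class Alignment:
    """A rectangular protein multiple sequence alignment.

    ``ids`` are unique, non-empty sequence identifiers in file order; ``rows``
    are equal-length residue strings over the normalized alphabet.  Columns
    are addressed 1..L.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise AlignmentFormatError("ids and rows differ in count")
        if not self.ids:
            raise AlignmentFormatError("empty alignment")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise AlignmentFormatError(f"duplicate sequence ids: {dupes}")
        if any(not i for i in self.ids):
            raise AlignmentFormatError("empty sequence id")
        L = len(self.rows[0])
        if L < 1:
            raise AlignmentFormatError("alignment has zero columns")
        ragged = {i: len(r) for i, r in zip(self.ids, self.rows) if len(r) != L}
        if ragged:
            raise AlignmentFormatError(
                f"ragged alignment, expected length {L}: {ragged}")
        for sid, row in zip(self.ids, self.rows):
            bad = set(row) - ALPHABET
            if bad:
                raise AlignmentFormatError(
                    f"sequence {sid!r} contains illegal characters {sorted(bad)}")

    @property
    def n_sequences(self) -> int:
        return len(self.ids)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def row(self, seq_id: str) -> str:
        try:
            return self.rows[self.ids.index(seq_id)]
        except ValueError:
            raise LookupError_(f"unknown sequence id {seq_id!r}") from None

    def column(self, index: int) -> str:
        """Residues of 1-based column ``index``, in sequence order."""
        self._check_index(index)
        return "".join(r[index - 1] for r in self.rows)

    def _check_index(self, index: int) -> None:
        if not 1 <= index <= self.n_columns:
            raise LookupError_(
                f"alignment index {index} out of range 1..{self.n_columns}")

    def subset(self, seq_ids: Iterable[str]) -> "Alignment":
        wanted = list(seq_ids)
        return Alignment(tuple(wanted), tuple(self.row(s) for s in wanted))

    def select_columns(self, indices: Sequence[int]) -> "Alignment":
        """New alignment keeping 1-based columns ``indices`` in given order."""
        for i in indices:
            self._check_index(i)
        rows = tuple("".join(r[i - 1] for i in indices) for r in self.rows)
        return Alignment(self.ids, rows)

    def ungapped(self, seq_id: str) -> str:
        return self.row(seq_id).replace(GAP, "")


@dataclass(frozen=True)
class ResidueRef:
    """One alignment cell with its ungapped residue number (None for gaps)."""

    seq_id: str
    alignment_index: int
    residue: str
    residue_number: int | None


@dataclass
class GroupPartition:
    """Assignment of sequence ids to named groups (e.g. enzyme families)."""

    assignment: dict[str, str]
    groups: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        labels = []
        for sid, g in self.assignment.items():
            if not g:
                raise ValueError(f"empty group label for sequence {sid!r}")
            if g not in labels:
                labels.append(g)
        if not labels:
            raise ValueError("empty partition: no sequences assigned")
        if not self.groups:
            self.groups = tuple(labels)
        missing = set(labels) - set(self.groups)
        if missing:
            raise ValueError(f"labels missing from group order: {sorted(missing)}")

    def members(self, group: str) -> list[str]:
        if group not in self.groups:
            raise KeyError(f"unknown group {group!r}")
        return [s for s, g in self.assignment.items() if g == group]

    def validate(self, alignment: Alignment) -> None:
        orphans = sorted(set(self.assignment) - set(alignment.ids))
        if orphans:
            raise ValueError(f"group table ids not in alignment: {orphans}")
        for g in self.groups:
            if not self.members(g):
                raise ValueError(f"group {g!r} has no members")


def map_residue(alignment: Alignment, seq_id: str, alignment_index: int) -> ResidueRef:
    """Resolve (sequence, column) to a :class:`ResidueRef`.

    The residue number is the count of non-gap characters in the row up to
    and including the column, i.e. the residue's 1-based position in the
    ungapped sequence; it is None when the cell is a gap.
    """
    row = alignment.row(seq_id)
    alignment._check_index(alignment_index)
    residue = row[alignment_index - 1]
    if residue == GAP:
        return ResidueRef(seq_id, alignment_index, residue, None)
    number = alignment_index - row.count(GAP, 0, alignment_index)
    return ResidueRef(seq_id, alignment_index, residue, number)


def alignment_span(alignment: Alignment, seq_id: str,
                   start_residue: int, length: int) -> tuple[int, int]:
    """Alignment-index span covered by ``length`` residues of the ungapped
    sequence starting at residue number ``start_residue`` (both 1-based)."""
    row = alignment.row(seq_id)
    positions = [i + 1 for i, c in enumerate(row) if c != GAP]
    if start_residue < 1 or start_residue + length - 1 > len(positions):
        raise LookupError_(
            f"residues {start_residue}..{start_residue + length - 1} out of "
            f"range for {seq_id!r} ({len(positions)} residues)")
    return positions[start_residue - 1], positions[start_residue + length - 2]


# ---------------------------------------------------------------------------
# I/O

def _from_biopython(records) -> Alignment:
    ids = tuple(r.id for r in records)
    rows = tuple(normalize_sequence(str(r.seq)) for r in records)
    return Alignment(ids, rows)


def read_msf(path: str | Path) -> Alignment:
    """Read a GCG MSF (PileUp) interleaved alignment."""
    text = Path(path).read_text()
    if "//" not in text:
        raise AlignmentFormatError(f"{path}: missing '//' header separator")
    try:
        msa = AlignIO.read(io.StringIO(text), "msf")
    except ValueError as exc:
        raise AlignmentFormatError(f"{path}: {exc}") from exc
    aln = _from_biopython(msa)
    m = re.search(r"MSF:\s*(\d+)", text)
    if m and int(m.group(1)) != aln.n_columns:
        raise AlignmentFormatError(
            f"{path}: header declares MSF: {m.group(1)} columns but "
            f"sequences have {aln.n_columns}")
    return aln


def read_fasta_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file (equal-length records)."""
    from Bio import SeqIO
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentFormatError(f"{path}: no FASTA records")
    lengths = {r.id: len(r.seq) for r in records}
    if len(set(lengths.values())) > 1:
        raise AlignmentFormatError(f"{path}: unequal record lengths {lengths}")
    return _from_biopython(records)


def write_fasta_alignment(alignment: Alignment, path: str | Path) -> None:
    """Write the alignment as FASTA, one sequence per line (byte-stable)."""
    with open(path, "w") as fh:
        for sid, row in zip(alignment.ids, alignment.rows):
            fh.write(f">{sid}\n{row}\n")


def read_groups(path: str | Path) -> GroupPartition:
    """Read a two-column (id, group) whitespace/tab table; '#' comments."""
    assignment: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'id group', got {line!r}")
        sid, group = parts
        if sid in assignment:
            raise ValueError(f"{path}:{lineno}: duplicate id {sid!r}")
        assignment[sid] = group
    if not assignment:
        raise ValueError(f"{path}: no group assignments found")
    return GroupPartition(assignment)


def write_groups(partition: GroupPartition, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, g in partition.assignment.items():
            fh.write(f"{sid}\t{g}\n")
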