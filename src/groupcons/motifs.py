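"""Motif pattern parsing and scanning.

Motifs are exact-match patterns over ungapped protein sequences in a compact
dialect: uppercase letters are literal residues, ``x`` is a single-position
wildcard (any residue, never a gap), and ``[...]`` is an alternation — one
position matching any residue inside the brackets.  ``Hx[ST]A`` matches
histidine, any residue, serine or threonine, then alanine.

Scanning reports every (possibly overlapping) match start, 1-based in the
ungapped sequence; presence analysis maps the first match of each sequence
back to alignment-index coordinates so motif locations can be compared
across a family alignment.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .alignment import AA20, UNKNOWN, Alignment, GroupPartition, alignment_span

WILDCARD = "x"
_MATCHABLE = AA20 + UNKNOWN  # wildcard accepts unknown residues too


class MotifParseError(ValueError):
    pass


@dataclass(frozen=True)
class MotifPattern:
    """Parsed motif: ordered elements, each a literal, alternation or None.

    ``elements[i]`` is a frozenset of admissible residues for position i, or
    None for the wildcard.  ``source`` is the normalized pattern string.
    """

    name: str
    elements: tuple[frozenset[str] | None, ...]

    def __post_init__(self) -> None:
        if not self.elements:
            raise MotifParseError(f"motif {self.name!r} has no positions")

    def __len__(self) -> int:
        return len(self.elements)

    @property
    def source(self) -> str:
        parts = []
        for el in self.elements:
            if el is None:
                parts.append(WILDCARD)
            elif len(el) == 1:
                parts.append(next(iter(el)))
            else:
                parts.append("[" + "".join(sorted(el)) + "]")
        return "".join(parts)

    def to_regex(self) -> re.Pattern:
        parts = []
        for el in self.elements:
            if el is None:
                parts.append(f"[{_MATCHABLE}]")
            else:
                parts.append("[" + "".join(sorted(el)) + "]")
        # lookahead makes overlapping matches visible to finditer
        return re.compile("(?=" + "".join(parts) + ")")


def parse_motif(pattern: str, name: str = "") -> MotifPattern:
    """Parse the motif dialect; errors carry the 0-based character offset."""
    elements: list[frozenset[str] | None] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == WILDCARD:
            elements.append(None)
            i += 1
        elif c in AA20:
            elements.append(frozenset(c))
            i += 1
        elif c == "[":
            end = pattern.find("]", i)
            if end == -1:
                raise MotifParseError(f"unclosed '[' at offset {i} in {pattern!r}")
            inner = pattern[i + 1:end]
            if not inner:
                raise MotifParseError(f"empty alternation at offset {i} in {pattern!r}")
            bad = set(inner) - set(AA20)
            if bad:
                raise MotifParseError(
                    f"illegal residues {sorted(bad)} in alternation at offset {i}")
            elements.append(frozenset(inner))
            i = end + 1
        else:
            raise MotifParseError(
                f"illegal character {c!r} at offset {i} in {pattern!r}")
    return MotifPattern(name or pattern, tuple(elements))


def scan_sequence(pattern: MotifPattern, sequence: str) -> list[int]:
    """1-based start positions of all (overlapping) exact matches."""
    return [m.start() + 1 for m in pattern.to_regex().finditer(sequence)]


def read_motif_file(path: str) -> list[MotifPattern]:
    """One 'name<TAB>pattern' per line; '#' comments and blanks ignored."""
    motifs = []
    for lineno, line in enumerate(open(path), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            name, pat = line.split("\t")
        except ValueError:
            raise MotifParseError(
                f"{path}:{lineno}: expected 'name<TAB>pattern'") from None
        motifs.append(parse_motif(pat.strip(), name.strip()))
    return motifs


def motif_presence(alignment: Alignment, partition: GroupPartition,
                   patterns: Sequence[MotifPattern]) -> pd.DataFrame:
    """Per-(group, motif) presence fractions with alignment-index spans.

    ``fraction`` is the share of the group's sequences whose ungapped
    sequence contains at least one match.  ``span_start``/``span_end`` give
    the alignment-index extent of the first match of the first matching
    sequence (the span absorbs any gap columns inside the motif).  A motif
    is ``group_exclusive`` when its fraction is positive in exactly one
    group.
    """
    partition.validate(alignment)
    records = []
    for pat in patterns:
        positive_groups = []
        rows = []
        for g in partition.groups:
            members = partition.members(g)
            n_hit = 0
            span = (None, None)
            for sid in members:
                starts = scan_sequence(pat, alignment.ungapped(sid))
                if starts:
                    n_hit += 1
                    if span == (None, None):
                        span = alignment_span(alignment, sid, starts[0], len(pat))
            frac = n_hit / len(members)
            if frac > 0:
                positive_groups.append(g)
            rows.append({"motif": pat.name, "group": g, "fraction": frac,
                         "span_start": span[0], "span_end": span[1]})
        for row in rows:
            row["group_exclusive"] = (len(positive_groups) == 1
                                      and row["fraction"] > 0)
            records.append(row)
    return pd.DataFrame.from_records(records)
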