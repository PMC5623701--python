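"""Per-column identity conservation and residue-class similarity.

*Identity conservation* of a column is the percentage of sequences carrying
the column's most frequent (modal) non-gap residue.  *Class similarity* pools
the counts of a set of physicochemically related residues (e.g. the
aliphatic hydrophobics I/V/L/M).  Both statistics use the full sequence
count, gapped sequences included, in the denominator, so a column that is
leucine in two thirds of the sequences and gapped elsewhere is ~67%
conserved, not 100%.  'X' cells count as gaps for these statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .alignment import AA20, GAP, UNKNOWN, Alignment


@dataclass(frozen=True)
class ColumnProfile:
    """Symbol tallies of one alignment column (20 amino acids + gap)."""

    counts: dict[str, int]
    n_total: int

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_total:
            raise ValueError("profile counts do not sum to n_total")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("negative count")

    @property
    def n_gap(self) -> int:
        return self.counts.get(GAP, 0)

    @property
    def n_nongap(self) -> int:
        return self.n_total - self.n_gap

    def count(self, symbol: str) -> int:
        return self.counts.get(symbol, 0)

    def nongap_frequencies(self) -> dict[str, float]:
        """Frequencies over the 20 amino acids among non-gap cells."""
        n = self.n_nongap
        if n == 0:
            return {a: 0.0 for a in AA20}
        return {a: self.counts.get(a, 0) / n for a in AA20}


@dataclass(frozen=True)
class ResidueClass:
    """A named set of amino acids treated as mutually similar."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"residue class {self.name!r} is empty")
        bad = set(self.members) - set(AA20)
        if bad:
            raise ValueError(f"class {self.name!r} has non-amino-acid members {bad}")


#: Similarity classes used in the family-wide census: aliphatic hydrophobic
#: residues, aromatics, and the acid-amide aspartate/asparagine pair.
DEFAULT_CLASSES: tuple[ResidueClass, ...] = (
    ResidueClass("aliphatic", frozenset("IVLM")),
    ResidueClass("aromatic", frozenset("FWY")),
    ResidueClass("acid-amide", frozenset("DN")),
)


def column_profile(alignment: Alignment, index: int) -> ColumnProfile:
    """Tally column ``index`` (1-based); 'X' cells are tallied as gaps."""
    col = alignment.column(index)
    counts = {a: 0 for a in AA20}
    counts[GAP] = 0
    for c in col:
        if c == UNKNOWN:
            c = GAP
        counts[c] += 1
    return ColumnProfile(counts, alignment.n_sequences)


def identity_conservation(profile: ColumnProfile) -> tuple[str | None, float]:
    """Modal non-gap residue and its exact percentage of all sequences.

    Ties between equally frequent residues are broken alphabetically.  An
    all-gap column has no modal residue and 0% conservation.
    """
    if profile.n_total == 0:
        raise ValueError("empty profile")
    best = max(AA20, key=lambda a: (profile.count(a), ))
    # max() above keeps the *first* maximal element, i.e. alphabetical order
    if profile.count(best) == 0:
        return None, 0.0
    return best, 100.0 * profile.count(best) / profile.n_total


def class_similarity(profile: ColumnProfile, residue_class: ResidueClass) -> float:
    """Pooled percentage of the class members, gaps in the denominator."""
    total = sum(profile.count(a) for a in residue_class.members)
    return 100.0 * total / profile.n_total


def round_percent(p: float) -> int:
    """Nearest-integer rounding, ties away from zero (reporting only)."""
    return int(math.floor(p + 0.5))


def conservation_table(alignment: Alignment) -> pd.DataFrame:
    """Per-column identity conservation: index, modal residue, exact percent."""
    rows = []
    for i in range(1, alignment.n_columns + 1):
        modal, pct = identity_conservation(column_profile(alignment, i))
        rows.append((i, modal, pct))
    return pd.DataFrame(rows, columns=["index", "modal_residue", "percent"])


def conservation_census(alignment: Alignment,
                        thresholds: Sequence[float] = (80.0, 60.0, 40.0),
                        ) -> dict[str, object]:
    """Count columns by identity-conservation band.

    With the default thresholds (t0=80, t1=60, t2=40) the bands are
    ``>=80``, ``>=60`` (which includes the first), and ``[40, 60)``.  Bands
    are computed on the exact, unrounded percentages.
    """
    t0, t1, t2 = thresholds
    table = conservation_table(alignment)
    pct = table["percent"]
    return {
        "table": table,
        f"ge_{round_percent(t0)}": int((pct >= t0).sum()),
        f"ge_{round_percent(t1)}": int((pct >= t1).sum()),
        f"between_{round_percent(t2)}_{round_percent(t1)}":
            int(((pct >= t2) & (pct < t1)).sum()),
    }


def similarity_census(alignment: Alignment,
                      class_set: Iterable[ResidueClass] = DEFAULT_CLASSES,
                      threshold: float = 60.0) -> pd.DataFrame:
    """Columns reaching ``threshold`` % pooled class similarity.

    Columns already identity-conserved at or above the threshold are
    excluded, so the census reports *additional* positions where no single
    residue dominates but a similarity class does.  Each selected column is
    reported with the winning class (highest pooled percentage).
    """
    classes = list(class_set)
    if not classes:
        raise ValueError("empty class set")
    rows = []
    for i in range(1, alignment.n_columns + 1):
        prof = column_profile(alignment, i)
        _, id_pct = identity_conservation(prof)
        if id_pct >= threshold:
            continue
        best = max(classes, key=lambda rc: class_similarity(prof, rc))
        best_pct = class_similarity(prof, best)
        if best_pct >= threshold:
            rows.append((i, best.name, best_pct, id_pct))
    return pd.DataFrame(
        rows, columns=["index", "class", "class_percent", "identity_percent"])
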