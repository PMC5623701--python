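"""Group Entropy / Family Entropy scan for group-specific conservation.

Given a family alignment partitioned into named groups (e.g. the four
structurally homologous enzyme families of a superfamily), each column is
scored twice with Kullback–Leibler divergences:

- **Group Entropy (GE)** of a group g — divergence of g's pseudocounted
  column residue distribution from the distribution of all sequences *not*
  in g.  GE is large when the group conserves a residue that the rest of
  the family does not use: group-private conservation.
- **Family Entropy (FE)** — divergence of the family-wide column
  distribution from a background composition.  FE is large when the column
  is conserved across the whole family.

A *group-specific* position is one with high GE and low FE: conserved in
its group but not family-wide.  Columns with too many gaps (fraction > gamma
within the group or its complement) are excluded from scoring — the scan
never silently scores a gap-dominated column; it marks it unscored.

Frequencies use a Dirichlet-style pseudocount: f_a = (n_a + beta*q_a) /
(N + beta), with beta = 1 and uniform q by default, so sparse groups cannot
produce infinite divergences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import AA20, GAP, UNKNOWN, Alignment, GroupPartition
from .estimators import BackgroundDistribution, get_background

_AA_INDEX = {a: i for i, a in enumerate(AA20)}

THREE_LETTER = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe", "G": "Gly",
    "H": "His", "I": "Ile", "K": "Lys", "L": "Leu", "M": "Met", "N": "Asn",
    "P": "Pro", "Q": "Gln", "R": "Arg", "S": "Ser", "T": "Thr", "V": "Val",
    "W": "Trp", "Y": "Tyr"}


@dataclass(frozen=True)
class GEntParams:
    """Scan parameters.

    beta — total pseudocount mass added to each frequency estimate;
    background — prior composition q used for the pseudocount and for
    Family Entropy; theta_g / theta_f — GE / FE selection thresholds (the
    defaults keep positions with GE >= 10 and FE <= 3); gap_max — maximum
    tolerated gap fraction (gamma) within the group and within its
    complement (0 = strict: any gap excludes the column); mode —
    'threshold' selects by the two thresholds, 'top_k' selects the top_k
    columns by GE among those passing the FE filter (scale-free
    alternative).
    """

    beta: float = 1.0
    background: str = "uniform"
    theta_g: float = 10.0
    theta_f: float = 3.0
    gap_max: float = 0.5
    mode: str = "threshold"
    top_k: int = 10
    second_residue_min_freq: float = 0.25

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0.0 <= self.gap_max <= 1.0:
            raise ValueError("gap_max must lie in [0, 1]")
        if self.theta_f < 0:
            raise ValueError("theta_f must be >= 0")
        if self.mode not in ("threshold", "top_k"):
            raise ValueError("mode must be 'threshold' or 'top_k'")

    @property
    def q(self) -> np.ndarray:
        return get_background(self.background).q


def _column_counts(alignment: Alignment, rows: list[int], index: int,
                   ) -> tuple[np.ndarray, int]:
    """(20-vector of residue counts, gap count) for the given sequences.

    'X' counts as a gap: it carries no residue information.
    """
    counts = np.zeros(20)
    n_gap = 0
    col = index - 1
    for r in rows:
        c = alignment.rows[r][col]
        if c == GAP or c == UNKNOWN:
            n_gap += 1
        else:
            counts[_AA_INDEX[c]] += 1
    return counts, n_gap


def _pseudocounted(counts: np.ndarray, beta: float, q: np.ndarray) -> np.ndarray:
    n = counts.sum()
    if n == 0:
        raise ValueError("no non-gap residues to estimate frequencies from")
    if beta == 0:
        return counts / n
    return (counts + beta * q) / (n + beta)


def _kl_bits(f: np.ndarray, r: np.ndarray) -> float:
    nz = f > 0
    if (r[nz] <= 0).any():
        raise ValueError("divergence undefined: reference has zero mass "
                         "where the group has support (use beta > 0)")
    return float((f[nz] * np.log2(f[nz] / r[nz])).sum())


def group_frequencies(alignment: Alignment, partition: GroupPartition,
                      group: str, index: int, beta: float = 1.0,
                      q: np.ndarray | None = None) -> np.ndarray:
    """Pseudocounted residue distribution of ``group`` at column ``index``."""
    if q is None:
        q = get_background("uniform").q
    rows = [alignment.ids.index(s) for s in partition.members(group)]
    counts, _ = _column_counts(alignment, rows, index)
    return _pseudocounted(counts, beta, q)


def group_entropy(alignment: Alignment, partition: GroupPartition,
                  group: str, index: int,
                  params: GEntParams = GEntParams()) -> float | None:
    """GE of ``group`` at ``index`` in bits, or None when unscored (gaps)."""
    member_ids = set(partition.members(group))
    in_rows = [i for i, s in enumerate(alignment.ids) if s in member_ids]
    out_rows = [i for i, s in enumerate(alignment.ids)
                if s in partition.assignment and s not in member_ids]
    if not out_rows:
        raise ValueError(f"group {group!r} has an empty complement")
    c_in, gap_in = _column_counts(alignment, in_rows, index)
    c_out, gap_out = _column_counts(alignment, out_rows, index)
    if gap_in > params.gap_max * len(in_rows):
        return None
    if gap_out > params.gap_max * len(out_rows):
        return None
    if c_in.sum() == 0 or c_out.sum() == 0:
        return None
    f = _pseudocounted(c_in, params.beta, params.q)
    r = _pseudocounted(c_out, params.beta, params.q)
    return _kl_bits(f, r)


def family_entropy(alignment: Alignment, index: int,
                   params: GEntParams = GEntParams()) -> float | None:
    """FE at ``index``: divergence of family-wide usage from background."""
    rows = list(range(alignment.n_sequences))
    counts, n_gap = _column_counts(alignment, rows, index)
    if counts.sum() == 0:
        return None
    big_f = _pseudocounted(counts, params.beta, params.q)
    return _kl_bits(big_f, params.q)


def _modal_residues(counts: np.ndarray, second_min_freq: float) -> str:
    """Top residue, plus the runner-up when it holds >= second_min_freq."""
    n = counts.sum()
    if n == 0:
        return ""
    order = np.argsort(-counts, kind="stable")
    out = [THREE_LETTER[AA20[order[0]]]]
    if counts[order[1]] >= second_min_freq * n and counts[order[1]] > 0:
        out.append(THREE_LETTER[AA20[order[1]]])
    return ", ".join(out)


def gent_scan(alignment: Alignment, partition: GroupPartition,
              params: GEntParams = GEntParams()) -> dict[str, pd.DataFrame]:
    """Full GE/FE scan: one ranked table per group.

    Each table holds, per scored column: GE, FE, the group's modal residue,
    the modal residue(s) of every other group, and a ``selected`` flag
    (GE >= theta_g and FE <= theta_f in threshold mode; top-k GE among
    FE <= theta_f in top_k mode).  Rows are sorted by GE descending, ties
    by ascending column index.  Columns excluded by the gap rule for a
    group are absent from that group's table.
    """
    if len(partition.groups) < 2:
        raise ValueError("gent_scan needs at least 2 groups")
    partition.validate(alignment)
    group_rows = {g: [alignment.ids.index(s) for s in partition.members(g)]
                  for g in partition.groups}
    tables: dict[str, pd.DataFrame] = {}
    fe_cache = [family_entropy(alignment, i, params)
                for i in range(1, alignment.n_columns + 1)]
    for g in partition.groups:
        others = [h for h in partition.groups if h != g]
        records = []
        for i in range(1, alignment.n_columns + 1):
            ge = group_entropy(alignment, partition, g, i, params)
            fe = fe_cache[i - 1]
            if ge is None or fe is None:
                continue
            c_in, _ = _column_counts(alignment, group_rows[g], i)
            rec = {"index": i, "group": g, "group_entropy": ge,
                   "family_entropy": fe,
                   "highest_group_residue": _modal_residues(
                       c_in, params.second_residue_min_freq)}
            for h in others:
                c_h, _ = _column_counts(alignment, group_rows[h], i)
                rec[f"common_{h}_residue"] = _modal_residues(
                    c_h, params.second_residue_min_freq)
            records.append(rec)
        df = pd.DataFrame.from_records(records)
        if df.empty:
            tables[g] = df
            continue
        df = df.sort_values(["group_entropy", "index"],
                            ascending=[False, True], kind="mergesort")
        df = df.reset_index(drop=True)
        low_fe = df["family_entropy"] <= params.theta_f
        if params.mode == "threshold":
            df["selected"] = (df["group_entropy"] >= params.theta_g) & low_fe
        else:
            eligible = df.index[low_fe][: params.top_k]
            df["selected"] = df.index.isin(eligible)
        tables[g] = df
    return tables
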