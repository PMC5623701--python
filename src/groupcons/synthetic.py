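"""Synthetic grouped alignments with planted ground truth.

The generator emulates the statistical structure of a protein superfamily
alignment partitioned into K groups, with four planted column types:

- ``FAMILY_CONSERVED`` — one residue at frequency ``c`` in *all* sequences
  (the family-invariant core);
- ``GROUP_SPECIFIC`` — a residue at frequency ``c`` within one owning
  group, while the other groups draw from a background that excludes that
  residue (sharp group-private conservation; a ``leak_probability`` softens
  the exclusion for harder benchmarks);
- ``CLASS_CONSERVED`` — residues drawn uniformly from a similarity class
  (e.g. I/V/L/M) at frequency ``c``, so the column is similar but not
  identical across the family;
- ``BACKGROUND`` — i.i.d. draws from a column-specific composition sampled
  from a Dirichlet(alpha) prior, giving realistic unconserved columns of
  varying skew.

Gaps are inserted i.i.d. at ``gap_rate``; optional contiguous indel blocks
gap a whole group over a run of columns, mimicking family-specific
insertions.  Everything is reproducible from a single integer seed, with
per-column substreams so any column can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .alignment import AA20, GAP, Alignment, GroupPartition

FAMILY_CONSERVED = "FAMILY_CONSERVED"
GROUP_SPECIFIC = "GROUP_SPECIFIC"
CLASS_CONSERVED = "CLASS_CONSERVED"
BACKGROUND = "BACKGROUND"

DEFAULT_CLASSES: dict[str, str] = {
    "aliphatic": "IVLM", "aromatic": "FWY", "acid-amide": "DN"}


@dataclass(frozen=True)
class SyntheticConfig:
    """Benchmark alignment layout and noise levels.

    Defaults give a 4-group x 50-sequence, 500-column family with 10
    family-conserved columns, 10 group-specific columns per group, 5
    class-conserved columns per similarity class, the rest background;
    within-site conservation 0.95 and 5% i.i.d. gaps.
    """

    n_groups: int = 4
    group_size: int = 50
    n_columns: int = 500
    n_family_conserved: int = 10
    n_group_specific: int = 10      # per group
    n_class_conserved: int = 5      # per class
    classes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES))
    conservation: float = 0.95
    dirichlet_alpha: float = 0.5
    gap_rate: float = 0.05
    indel_block_rate: float = 0.0
    indel_block_length: int = 10
    leak_probability: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.conservation <= 1.0:
            raise ValueError("conservation must lie in (0, 1]")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must lie in [0, 1)")
        if self.n_planted > self.n_columns:
            raise ValueError(
                f"site plan needs {self.n_planted} columns, only "
                f"{self.n_columns} available")
        if self.n_groups < 1 or self.group_size < 1:
            raise ValueError("need at least one group and one sequence")

    @property
    def n_planted(self) -> int:
        return (self.n_family_conserved
                + self.n_group_specific * self.n_groups
                + self.n_class_conserved * len(self.classes))

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(f"G{k + 1}" for k in range(self.n_groups))


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-column labels and per-sequence group labels."""

    columns: pd.DataFrame      # index, site_type, owner, residue
    groups: dict[str, str]     # sequence id -> group label

    def of_type(self, site_type: str, owner: str | None = None) -> list[int]:
        df = self.columns
        mask = df["site_type"] == site_type
        if owner is not None:
            mask &= df["owner"] == owner
        return df.loc[mask, "index"].tolist()


def _draw(rng: np.random.Generator, probs: np.ndarray, size: int) -> np.ndarray:
    return rng.choice(20, size=size, p=probs / probs.sum())


def generate_alignment(config: SyntheticConfig,
                       ) -> tuple[Alignment, GroupPartition, SyntheticTruth]:
    """Generate (alignment, partition, truth) from the config, seeded."""
    n_seq = config.n_groups * config.group_size
    master = np.random.default_rng([config.seed, 0])

    ids = tuple(f"{g}_seq{j + 1:03d}" for g in config.group_names
                for j in range(config.group_size))
    group_of = {sid: sid.split("_")[0] for sid in ids}
    group_slices = {g: slice(k * config.group_size, (k + 1) * config.group_size)
                    for k, g in enumerate(config.group_names)}

    # assign site types to shuffled column positions
    plan: list[tuple[str, str]] = []
    plan += [(FAMILY_CONSERVED, "")] * config.n_family_conserved
    for g in config.group_names:
        plan += [(GROUP_SPECIFIC, g)] * config.n_group_specific
    for cls in config.classes:
        plan += [(CLASS_CONSERVED, cls)] * config.n_class_conserved
    plan += [(BACKGROUND, "")] * (config.n_columns - len(plan))
    positions = master.permutation(config.n_columns)
    col_plan: list[tuple[str, str]] = [("", "")] * config.n_columns
    for pos, site in zip(positions, plan):
        col_plan[pos] = site

    matrix = np.empty((n_seq, config.n_columns), dtype="<U1")
    truth_rows = []
    c = config.conservation
    for j, (site_type, owner) in enumerate(col_plan):
        rng = np.random.default_rng([config.seed, 1, j])
        bg = rng.dirichlet(np.full(20, config.dirichlet_alpha))
        planted = ""
        if site_type == FAMILY_CONSERVED:
            res = rng.integers(20)
            planted = AA20[res]
            col = np.where(rng.random(n_seq) < c, res, _draw(rng, bg, n_seq))
        elif site_type == GROUP_SPECIFIC:
            res = rng.integers(20)
            planted = AA20[res]
            bg_excl = bg.copy()
            bg_excl[res] = 0.0
            col = _draw(rng, bg_excl, n_seq)
            if config.leak_probability > 0:
                leak = rng.random(n_seq) < config.leak_probability
                col = np.where(leak, _draw(rng, bg, n_seq), col)
            sl = group_slices[owner]
            inside = np.where(rng.random(config.group_size) < c,
                              res, _draw(rng, bg_excl, config.group_size))
            col[sl] = inside
        elif site_type == CLASS_CONSERVED:
            members = np.array([AA20.index(a) for a in config.classes[owner]])
            in_class = rng.random(n_seq) < c
            col = np.where(in_class, rng.choice(members, size=n_seq),
                           _draw(rng, bg, n_seq))
        else:
            col = _draw(rng, bg, n_seq)
        matrix[:, j] = [AA20[k] for k in col]
        truth_rows.append((j + 1, site_type, owner, planted))

    # i.i.d. gaps, then optional per-group indel blocks
    gap_rng = np.random.default_rng([config.seed, 2])
    matrix[gap_rng.random(matrix.shape) < config.gap_rate] = GAP
    for k, g in enumerate(config.group_names):
        block_rng = np.random.default_rng([config.seed, 3, k])
        if block_rng.random() < config.indel_block_rate:
            start = int(block_rng.integers(
                0, max(1, config.n_columns - config.indel_block_length)))
            matrix[group_slices[g], start:start + config.indel_block_length] = GAP

    rows = tuple("".join(r) for r in matrix)
    alignment = Alignment(ids, rows)
    partition = GroupPartition(dict(group_of), config.group_names)
    truth = SyntheticTruth(
        pd.DataFrame(truth_rows,
                     columns=["index", "site_type", "owner", "residue"]),
        dict(group_of))
    return alignment, partition, truth


def evaluate_recovery(scores: dict[int, float], truth: SyntheticTruth,
                      site_type: str, owner: str | None = None,
                      selected: set[int] | None = None) -> dict[str, float]:
    """Rank and set-based recovery of planted sites against background.

    ``auc`` is the Mann–Whitney probability that a planted column of the
    requested type outranks a background column under ``scores``; columns
    missing from ``scores`` (e.g. excluded by a gap rule) are ignored.
    When ``selected`` is given, precision and recall of that set against
    the planted columns are included.
    """
    planted = [i for i in truth.of_type(site_type, owner) if i in scores]
    background = [i for i in truth.of_type(BACKGROUND) if i in scores]
    if not planted:
        raise ValueError(f"no scored planted sites of type {site_type!r}")
    out: dict[str, float] = {}
    if background:
        u = mannwhitneyu([scores[i] for i in planted],
                         [scores[i] for i in background],
                         alternative="greater").statistic
        out["auc"] = float(u) / (len(planted) * len(background))
    if selected is not None:
        planted_all = set(truth.of_type(site_type, owner))
        tp = len(selected & planted_all)
        out["precision"] = tp / len(selected) if selected else 0.0
        out["recall"] = tp / len(planted_all)
    return out


# ---------------------------------------------------------------------------
# random phylogenies (for distance-method tests and benchmarks)


def random_phylogeny(n_leaves: int, rng: np.random.Generator,
                     min_branch: float = 0.1, max_branch: float = 1.0):
    """Random unrooted binary tree with uniform branch lengths.

    Built by sequential random attachment, the standard way to obtain
    arbitrary unrooted topologies with positive branch lengths; its
    patristic distance matrix is additive by construction.
    """
    import dendropy
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    taxa = dendropy.TaxonNamespace()

    def blen() -> float:
        return float(rng.uniform(min_branch, max_branch))

    labels = [f"t{i + 1}" for i in range(n_leaves)]
    root = dendropy.Node()
    edges = []
    for lab in labels[:3]:
        leaf = dendropy.Node(taxon=taxa.require_taxon(label=lab))
        leaf.edge.length = blen()
        root.add_child(leaf)
        edges.append(leaf)
    for lab in labels[3:]:
        target = edges[rng.integers(len(edges))]
        parent = target.parent_node
        mid = dendropy.Node()
        split = rng.uniform(0.25, 0.75) * target.edge.length
        parent.remove_child(target)
        parent.add_child(mid)
        mid.edge.length = target.edge.length - split
        mid.add_child(target)
        target.edge.length = split
        leaf = dendropy.Node(taxon=taxa.require_taxon(label=lab))
        leaf.edge.length = blen()
        mid.add_child(leaf)
        edges += [leaf, mid]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree
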