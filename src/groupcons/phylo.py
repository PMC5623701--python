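"""Distance-based phylogenetics: trimming, JTT distances, NJ, bootstrap.

The tree pipeline mirrors classical protein phylogenetics practice: trim
gap-rich columns from the master alignment, estimate pairwise evolutionary
distances by maximum likelihood under the Jones–Taylor–Thornton (JTT)
amino-acid replacement model, build an unrooted tree by neighbor joining,
assess branch support with a column bootstrap, and summarize the replicates
with a majority-rule consensus tree.

Trees are :class:`dendropy.Tree` objects throughout; edge support values
(percent of bootstrap replicates containing the bipartition) live on
``node.label`` of the consensus tree's internal nodes and in the returned
support table.  Distances are in expected substitutions per site, capped at
``D_MAX`` because the likelihood surface flattens for saturated pairs.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

import dendropy
import numpy as np
from scipy.cluster import hierarchy
from scipy.optimize import minimize_scalar

from .alignment import AA20, GAP, UNKNOWN, Alignment

D_MAX = 10.0

_AA_INDEX = {a: i for i, a in enumerate(AA20)}


class DistanceMatrixError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric matrix of evolutionary distances with taxon ids."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if d.shape != (n, n):
            raise DistanceMatrixError("distance matrix shape mismatch")
        if not np.allclose(d, d.T, atol=1e-12):
            raise DistanceMatrixError("distance matrix is not symmetric")
        if (np.diag(d) != 0).any():
            raise DistanceMatrixError("non-zero diagonal")
        if (d < 0).any() or not np.isfinite(d).all():
            raise DistanceMatrixError("negative or non-finite distances")
        object.__setattr__(self, "d", d)

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])


# ---------------------------------------------------------------------------
# trimming


def trim_alignment(alignment: Alignment, gap_fraction_max: float = 0.8,
                   ) -> tuple[Alignment, dict[int, int]]:
    """Drop columns whose gap fraction exceeds the threshold.

    Returns the trimmed alignment and a map from original 1-based column
    index to trimmed index for every surviving column.  'X' counts as a gap.
    """
    n = alignment.n_sequences
    keep = []
    for i in range(1, alignment.n_columns + 1):
        col = alignment.column(i)
        gaps = sum(1 for c in col if c in (GAP, UNKNOWN))
        if gaps / n <= gap_fraction_max:
            keep.append(i)
    if not keep:
        raise ValueError("trimming removed every column")
    index_map = {orig: new for new, orig in enumerate(keep, start=1)}
    return alignment.select_columns(keep), index_map


# ---------------------------------------------------------------------------
# JTT model


class JTTModel:
    """The JTT amino-acid replacement model, normalized to 1 sub/site/unit t.

    Built from the published exchangeability/frequency table bundled with
    the package.  ``transition(t)`` returns P(t) = exp(Qt) via the spectral
    decomposition of the reversible rate matrix.
    """

    def __init__(self) -> None:
        with resources.files("groupcons.data").joinpath("jtt.json").open() as fh:
            raw = json.load(fh)
        assert raw["alphabet"] == AA20
        s = np.asarray(raw["exchangeabilities"], dtype=float)
        pi = np.asarray(raw["frequencies"], dtype=float)
        pi = pi / pi.sum()
        q = s * pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        # scale: expected rate -sum_i pi_i q_ii = 1
        q /= -(pi * np.diag(q)).sum()
        self.pi = pi
        self.q = q
        # reversible => diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric
        sp = np.sqrt(pi)
        b = (sp[:, None] * q) / sp[None, :]
        w, v = np.linalg.eigh(0.5 * (b + b.T))
        self._w = w
        self._left = sp[:, None] ** -1 * v
        self._right = v.T * sp[None, :]

    def transition(self, t: float) -> np.ndarray:
        """P(t): 20x20 matrix of P(b at site | a at site, time t)."""
        p = (self._left * np.exp(self._w * t)[None, :]) @ self._right
        return np.clip(p, 1e-300, None)


_JTT: JTTModel | None = None


def jtt_model() -> JTTModel:
    global _JTT
    if _JTT is None:
        _JTT = JTTModel()
    return _JTT


def pair_count_matrix(seq_i: str, seq_j: str) -> np.ndarray:
    """20x20 counts of aligned residue pairs over co-non-gap sites."""
    counts = np.zeros((20, 20))
    for a, b in zip(seq_i, seq_j):
        ia = _AA_INDEX.get(a)
        ib = _AA_INDEX.get(b)
        if ia is not None and ib is not None:
            counts[ia, ib] += 1
    return counts


def jtt_distance(seq_i: str, seq_j: str, d_max: float = D_MAX,
                 tol: float = 1e-6) -> float:
    """ML evolutionary distance between two aligned rows under JTT.

    Maximizes sum over co-non-gap sites of log[pi_a P_ab(t)] by bounded 1-D
    optimization on t in [0, d_max].  Identical sequences give 0; a pair
    with no comparable sites is an error; an optimum at the cap is returned
    capped.
    """
    counts = pair_count_matrix(seq_i, seq_j)
    n = counts.sum()
    if n == 0:
        raise DistanceMatrixError("no co-non-gap sites between sequences")
    if counts.sum() == np.trace(counts):
        return 0.0
    model = jtt_model()
    log_pi = np.log(model.pi)

    def neg_ll(t: float) -> float:
        p = model.transition(t)
        return -float((counts * (log_pi[:, None] + np.log(p))).sum())

    res = minimize_scalar(neg_ll, bounds=(1e-9, d_max), method="bounded",
                          options={"xatol": tol})
    t_hat = float(res.x)
    return min(t_hat, d_max)


def jtt_distance_matrix(alignment: Alignment, d_max: float = D_MAX,
                        ) -> DistanceMatrix:
    """All-pairs JTT ML distances of an alignment."""
    n = alignment.n_sequences
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = jtt_distance(alignment.rows[i], alignment.rows[j],
                                         d_max)
    return DistanceMatrix(alignment.ids, d)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining; exact on additive distance matrices.

    Ties in the Q criterion are broken deterministically in favour of the
    pair whose (sorted) representative leaf names are smallest.  Negative
    branch-length estimates are clamped to zero with the deficit moved to
    the sister edge, preserving the joined pair's path length.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for name in dm.ids:
        taxon = taxa.require_taxon(label=name)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    reps = list(dm.ids)  # smallest leaf name under each active node
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12)
        best = min(
            ((ai, bi) for ai, bi in ties if ai < bi),
            key=lambda ab: tuple(sorted((reps[active[ab[0]]], reps[active[ab[1]]]))))
        ai, bi = best
        i, j = active[ai], active[bi]
        dij = d[i, j]
        li = 0.5 * dij + (r[ai] - r[bi]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj -= li
            li = 0.0
        if lj < 0:
            li -= lj
            lj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        new_d = 0.5 * (d[i, :] + d[j, :] - dij)
        d = np.vstack([d, new_d])
        new_col = np.append(new_d, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    # final 3-way join at an unrooted internal node
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = dendropy.Node()
    for node, ln in ((nodes[i], li), (nodes[j], lj), (nodes[k], lk)):
        root.add_child(node)
        node.edge.length = max(ln, 0.0)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def tree_distance_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic (path-length) distances between all leaf pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    ids = tuple(sorted(t.label for t in tree.taxon_namespace))
    n = len(ids)
    d = np.zeros((n, n))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for a, b in itertools.combinations(range(n), 2):
        d[a, b] = d[b, a] = pdm.patristic_distance(taxa[ids[a]], taxa[ids[b]])
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# UPGMA dendrogram (for the evolutionary trace)


@dataclass(frozen=True)
class Dendrogram:
    """Ultrametric UPGMA dendrogram: taxon ids + scipy linkage matrix."""

    ids: tuple[str, ...]
    linkage: np.ndarray


def upgma(dm: DistanceMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) dendrogram of a distance matrix."""
    from scipy.spatial.distance import squareform
    condensed = squareform(dm.d, checks=False)
    z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(dm.ids, z)


# ---------------------------------------------------------------------------
# bootstrap and consensus


def bootstrap_alignments(alignment: Alignment, n: int, seed: int,
                         ) -> Iterable[Alignment]:
    """Column-bootstrap replicates; replicate r uses rng seeded (seed, r)."""
    L = alignment.n_columns
    for rep in range(n):
        rng = np.random.default_rng([seed, rep])
        cols = rng.integers(1, L + 1, size=L)
        yield alignment.select_columns([int(c) for c in cols])


def bootstrap_trees(alignment: Alignment, n: int = 250, seed: int = 0,
                    d_max: float = D_MAX) -> list[dendropy.Tree]:
    """NJ trees of ``n`` column-bootstrap replicates (deterministic in seed)."""
    trees = []
    for boot in bootstrap_alignments(alignment, n, seed):
        dm = jtt_distance_matrix(boot, d_max)
        trees.append(neighbor_joining(dm))
    return trees


def _bipartitions(tree: dendropy.Tree, ref_taxon: str,
                  all_labels: frozenset[str]) -> set[frozenset[str]]:
    """Non-trivial splits as leaf-label sets on the side *not* holding
    ``ref_taxon`` (canonical orientation for unrooted comparison)."""
    splits = set()
    for node in tree.preorder_internal_node_iter():
        labels = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref_taxon in labels:
            labels = all_labels - labels
        if 2 <= len(labels) <= len(all_labels) - 2:
            splits.add(labels)
    return splits


def majority_consensus(trees: Sequence[dendropy.Tree],
                       min_fraction: float = 0.5) -> dendropy.Tree:
    """Strict majority-rule consensus with percent supports.

    Keeps exactly the bipartitions present in more than ``min_fraction`` of
    the input trees (strictly greater, so two conflicting trees yield an
    unresolved consensus).  Internal nodes of the returned tree carry the
    support percentage (100 x frequency) as ``node.label``; leaf edges are
    implicit (support 100 by definition and unlabeled).
    """
    if not trees:
        raise ValueError("no trees to summarize")
    label_sets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter())
                  for t in trees]
    all_labels = label_sets[0]
    if any(ls != all_labels for ls in label_sets):
        raise ValueError("trees have mismatched leaf sets")
    ref = min(all_labels)
    counts: dict[frozenset[str], int] = {}
    for t in trees:
        for split in _bipartitions(t, ref, all_labels):
            counts[split] = counts.get(split, 0) + 1
    n = len(trees)
    majority = {s: c / n for s, c in counts.items() if c / n > min_fraction}
    # splits above 50% are pairwise compatible: in the orientation away from
    # the reference taxon they form a laminar family (nested or disjoint)
    taxa = dendropy.TaxonNamespace()
    root = dendropy.Node()
    clade_nodes: dict[frozenset[str], dendropy.Node] = {}
    for split in sorted(majority, key=len):
        node = dendropy.Node()
        node.label = f"{100.0 * majority[split]:g}"
        clade_nodes[split] = node
    parent_of: dict[frozenset[str], dendropy.Node] = {}
    ordered = sorted(majority, key=len)
    for i, split in enumerate(ordered):
        enclosing = [s for s in ordered[i + 1:] if split < s]
        parent = clade_nodes[min(enclosing, key=len)] if enclosing else root
        parent.add_child(clade_nodes[split])
        parent_of[split] = parent
    for label in sorted(all_labels):
        enclosing = [s for s in ordered if label in s]
        parent = clade_nodes[min(enclosing, key=len)] if enclosing else root
        leaf = dendropy.Node(taxon=taxa.require_taxon(label=label))
        parent.add_child(leaf)
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = False
    return tree


def split_support(trees: Sequence[dendropy.Tree],
                  clade: Iterable[str]) -> float:
    """Percent of trees containing the bipartition isolating ``clade``."""
    clade = frozenset(clade)
    all_labels = frozenset(lf.taxon.label for lf in trees[0].leaf_node_iter())
    ref = min(all_labels)
    target = (all_labels - clade) if ref in clade else clade
    hits = sum(1 for t in trees if target in _bipartitions(t, ref, all_labels))
    return 100.0 * hits / len(trees)


# ---------------------------------------------------------------------------
# Newick I/O


def read_newick(source: str) -> dendropy.Tree:
    """Parse a Newick string or file path into a tree."""
    import os
    try:
        if os.path.exists(source):
            return dendropy.Tree.get(path=source, schema="newick")
        return dendropy.Tree.get(data=source, schema="newick")
    except Exception as exc:
        raise ValueError(f"newick parse error: {exc}") from exc


def write_newick(tree: dendropy.Tree, path: str | None = None) -> str:
    text = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
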