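import itertools

import dendropy
import numpy as np
import pytest

from groupcons.alignment import AA20, Alignment
from groupcons.phylo import (DistanceMatrix, bootstrap_trees, jtt_distance,
                             jtt_model, majority_consensus, neighbor_joining,
                             pair_count_matrix, read_newick, split_support,
                             tree_distance_matrix, trim_alignment, upgma,
                             write_newick)
from groupcons.synthetic import random_phylogeny


def simulate_jtt_pair(t, L, rng):
    model = jtt_model()
    anc = rng.choice(20, size=L, p=model.pi)
    P = model.transition(t)
    cum = P.cumsum(axis=1)
    u = rng.random(L)
    der = (cum[anc] < u[:, None]).sum(axis=1)
    s1 = "".join(AA20[i] for i in anc)
    s2 = "".join(AA20[i] for i in der)
    return s1, s2


class TestTrim:
    def test_gap_rich_column_removed(self):
        ids = tuple(f"s{i}" for i in range(10))
        rows = tuple("A-" if i > 0 else "AW" for i in range(10))
        aln = Alignment(ids, rows)
        trimmed, index_map = trim_alignment(aln, 0.8)
        assert trimmed.n_columns == 1 and index_map == {1: 1}

    def test_gapless_unchanged_and_map_bijective(self, toy_alignment):
        trimmed, index_map = trim_alignment(toy_alignment, 0.9)
        assert trimmed.n_columns == toy_alignment.n_columns
        assert sorted(index_map.values()) == list(
            range(1, trimmed.n_columns + 1))

    def test_everything_removed_is_error(self):
        aln = Alignment(("a", "b"), ("--", "A-"))
        with pytest.raises(ValueError):
            trim_alignment(aln, 0.3)


class TestJttDistance:
    def test_identical_sequences_zero(self):
        assert jtt_distance("ACDW", "ACDW") == 0.0

    def test_no_comparable_sites_error(self):
        with pytest.raises(ValueError):
            jtt_distance("A--", "-CC")

    def test_monotone_in_divergence(self):
        rng = np.random.default_rng(5)
        base = "".join(AA20[i] for i in rng.integers(0, 20, 400))
        last = -1.0
        for n_diff in (10, 60, 150):
            mutated = list(base)
            for pos in rng.choice(400, size=n_diff, replace=False):
                mutated[pos] = AA20[(AA20.index(mutated[pos]) + 7) % 20]
            d = jtt_distance(base, "".join(mutated))
            assert d > last
            last = d

    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        s1, s2 = simulate_jtt_pair(0.5, 5000, rng)
        assert jtt_distance(s1, s2) == pytest.approx(0.5, abs=0.08)

    def test_rate_matrix_normalized(self):
        m = jtt_model()
        assert -(m.pi * np.diag(m.q)).sum() == pytest.approx(1.0)
        assert m.q.sum(axis=1) == pytest.approx(np.zeros(20), abs=1e-12)


class TestNeighborJoining:
    def test_worked_quartet(self):
        # additive distances of ((A:1,B:2):1,C:3,D:4)
        ids = ("A", "B", "C", "D")
        d = np.array([[0, 3, 5, 6], [3, 0, 6, 7],
                      [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(ids, d))
        dm = tree_distance_matrix(tree)
        assert np.allclose(dm.d, d[np.ix_(range(4), range(4))])
        # AB|CD split present
        assert split_support([tree], ("A", "B")) == 100.0
        leaf = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
        assert leaf["A"].edge.length == pytest.approx(1.0)
        assert leaf["B"].edge.length == pytest.approx(2.0)

    def test_three_taxa_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = neighbor_joining(DistanceMatrix(("A", "B", "C"), d))
        leaf = {lf.taxon.label: lf.edge.length
                for lf in tree.leaf_node_iter()}
        assert leaf == {"A": pytest.approx(1.0), "B": pytest.approx(2.0),
                        "C": pytest.approx(3.0)}

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(("A", "B"), np.zeros((2, 2))))

    def test_additive_matrices_reconstructed(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            tree = random_phylogeny(int(rng.integers(5, 9)), rng)
            dm = tree_distance_matrix(tree)
            recon = tree_distance_matrix(neighbor_joining(dm))
            assert recon.ids == dm.ids
            assert np.abs(recon.d - dm.d).max() < 1e-9

    def test_taxon_order_invariance(self):
        rng = np.random.default_rng(9)
        tree = random_phylogeny(7, rng)
        dm = tree_distance_matrix(tree)
        perm = rng.permutation(len(dm.ids))
        dm2 = DistanceMatrix(tuple(dm.ids[i] for i in perm),
                             dm.d[np.ix_(perm, perm)])
        t1 = neighbor_joining(dm)
        t2 = neighbor_joining(dm2)
        d1 = tree_distance_matrix(t1)
        d2 = tree_distance_matrix(t2)
        assert d1.ids == d2.ids
        assert np.allclose(d1.d, d2.d)

    def test_matches_independent_nj_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj
        rng = np.random.default_rng(17)
        tree = random_phylogeny(8, rng)
        dm = tree_distance_matrix(tree)
        ours = tree_distance_matrix(neighbor_joining(dm))
        sk_tree = sk_nj(SkDM(dm.d, ids=list(dm.ids)))
        for a, b in itertools.combinations(dm.ids, 2):
            theirs = sk_tree.find(a).distance(sk_tree.find(b))
            assert ours.get(a, b) == pytest.approx(theirs, abs=1e-6)


class TestUpgma:
    def test_heights_monotone(self):
        rng = np.random.default_rng(2)
        tree = random_phylogeny(10, rng)
        dendro = upgma(tree_distance_matrix(tree))
        heights = dendro.linkage[:, 2]
        assert (np.diff(heights) >= -1e-12).all()


class TestBootstrap:
    def test_deterministic_given_seed(self):
        ids = tuple(f"s{i}" for i in range(5))
        rng = np.random.default_rng(0)
        rows = tuple("".join(AA20[j] for j in rng.integers(0, 20, 30))
                     for _ in ids)
        aln = Alignment(ids, rows)
        t1 = bootstrap_trees(aln, 3, seed=4)
        t2 = bootstrap_trees(aln, 3, seed=4)
        assert [write_newick(t) for t in t1] == [write_newick(t) for t in t2]

    def test_zero_replicates(self):
        aln = Alignment(("a", "b", "c"), ("AC", "AC", "AW"))
        assert bootstrap_trees(aln, 0, seed=1) == []


class TestConsensus:
    def _trees(self, newicks):
        tns = dendropy.TaxonNamespace()
        return [dendropy.Tree.get(data=nwk, schema="newick",
                                  taxon_namespace=tns) for nwk in newicks]

    def test_identical_trees_full_support(self):
        trees = self._trees(["((A:1,B:1):1,(C:1,D:1):1,E:1);"] * 4)
        cons = majority_consensus(trees)
        assert split_support(trees, ("A", "B")) == 100.0
        labels = [nd.label for nd in cons.preorder_internal_node_iter()
                  if nd.label]
        assert set(labels) == {"100"}

    def test_even_conflict_is_dropped(self):
        trees = self._trees(["((A,B),(C,D),E);", "((A,C),(B,D),E);"])
        cons = majority_consensus(trees)
        internal = [nd for nd in cons.preorder_internal_node_iter()]
        assert len(internal) == 1  # star tree: only the root remains

    def test_60_20_20_multiset(self):
        majority = "((A,B),(C,D),E);"
        trees = self._trees([majority] * 6
                            + ["((A,C),(B,D),E);"] * 2
                            + ["((A,D),(B,C),E);"] * 2)
        cons = majority_consensus(trees)
        labels = sorted(nd.label for nd in cons.preorder_internal_node_iter()
                        if nd.label)
        assert labels == ["60", "60"]
        assert split_support(trees, ("A", "B")) == 60.0

    def test_mismatched_leaf_sets_rejected(self):
        trees = self._trees(["((A,B),C,D);"])
        other = dendropy.Tree.get(data="((A,B),C,E);", schema="newick")
        with pytest.raises(ValueError, match="leaf sets"):
            majority_consensus(trees + [other])


class TestNewick:
    def test_round_trip(self):
        tree = read_newick("((A:1,B:2):1,C:3,D:4);")
        again = read_newick(write_newick(tree))
        d1, d2 = tree_distance_matrix(tree), tree_distance_matrix(again)
        assert d1.ids == d2.ids and np.allclose(d1.d, d2.d, atol=1e-9)

    def test_support_labels_parsed(self):
        tree = read_newick("((A:1,B:2)85:0.1,C:3,D:4);")
        labels = [nd.label for nd in tree.preorder_internal_node_iter()
                  if nd.label]
        assert labels == ["85"]

    def test_malformed_string_errors(self):
        with pytest.raises(ValueError):
            read_newick("((A,B,C;")
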