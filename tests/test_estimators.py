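import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from groupcons.alignment import AA20, Alignment
from groupcons.conservation import column_profile
from groupcons.estimators import (BACKGROUND_NAMES, LOG2_20, MATRIX_NAMES,
                                  METHOD_NAMES, consensus_identified,
                                  get_background, get_matrix,
                                  identified_columns, js_divergence,
                                  property_entropy, relative_entropy,
                                  score_alignment, shannon_entropy,
                                  sum_of_pairs, vn_entropy)

UNIFORM = np.full(20, 0.05)


def dist(**kw):
    p = np.zeros(20)
    for a, v in kw.items():
        p[AA20.index(a)] = v
    return p


random_dists = st.lists(
    st.floats(0.01, 10.0), min_size=20, max_size=20).map(
        lambda w: np.array(w) / np.sum(w))


class TestShannon:
    def test_point_mass_zero(self):
        assert shannon_entropy(dist(A=1.0)) == 0.0

    def test_uniform_is_log2_20(self):
        assert shannon_entropy(UNIFORM) == pytest.approx(LOG2_20, abs=1e-12)

    def test_two_state_one_bit(self):
        assert shannon_entropy(dist(A=0.5, C=0.5)) == pytest.approx(1.0)

    def test_rejects_non_distribution(self):
        with pytest.raises(ValueError):
            shannon_entropy(np.full(20, 0.1))


class TestRelativeEntropy:
    def test_zero_iff_equal(self):
        assert relative_entropy(UNIFORM, UNIFORM) == pytest.approx(0.0)

    def test_point_mass_vs_uniform(self):
        assert relative_entropy(dist(A=1.0), UNIFORM) == pytest.approx(LOG2_20)

    def test_two_term_hand_sum(self):
        p = dist(A=0.75, C=0.25)
        expected = 0.75 * math.log2(0.75 / 0.05) + 0.25 * math.log2(0.25 / 0.05)
        assert relative_entropy(p, UNIFORM) == pytest.approx(expected, abs=1e-12)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            relative_entropy(UNIFORM, dist(A=1.0))

    @settings(deadline=None, max_examples=100)
    @given(random_dists)
    def test_nonnegative(self, p):
        assert relative_entropy(p, UNIFORM) >= -1e-12


class TestJsDivergence:
    def test_identical_distributions(self):
        assert js_divergence(UNIFORM, UNIFORM) == pytest.approx(0.0)

    def test_disjoint_point_masses_one_bit(self):
        assert js_divergence(dist(A=1.0), dist(C=1.0)) == pytest.approx(1.0)

    def test_lambda_out_of_range(self):
        with pytest.raises(ValueError):
            js_divergence(UNIFORM, UNIFORM, lam=1.0)

    @settings(deadline=None, max_examples=100)
    @given(random_dists, random_dists)
    def test_symmetric_and_bounded(self, p, q):
        assert js_divergence(p, q) == pytest.approx(js_divergence(q, p))
        assert -1e-12 <= js_divergence(p, q) <= 1.0 + 1e-12


class TestPropertyEntropy:
    def test_single_class_column_is_zero(self):
        assert property_entropy(dist(K=0.6, R=0.4)) == pytest.approx(0.0)

    def test_two_class_even_split_one_bit(self):
        p = dist(K=0.25, R=0.25, D=0.25, E=0.25)
        assert property_entropy(p) == pytest.approx(1.0)

    def test_non_covering_partition_rejected(self):
        with pytest.raises(ValueError):
            property_entropy(UNIFORM, (frozenset("KR"),))

    @settings(deadline=None, max_examples=100)
    @given(random_dists)
    def test_pooling_never_raises_entropy(self, p):
        assert property_entropy(p) <= shannon_entropy(p) + 1e-12


class TestSumOfPairs:
    def test_identity_matrix_enumeration(self):
        # AACC: pairs AA, CC match (score 1); AC x4 mismatch -> 2/6
        assert sum_of_pairs("AACC", np.eye(20)) == pytest.approx(2 / 6)

    def test_all_identical_gives_diagonal(self):
        m = get_matrix("blosum62")
        assert sum_of_pairs("WWW", m) == m.scores[AA20.index("W"), AA20.index("W")]

    def test_permutation_invariance(self):
        m = get_matrix("blosum45")
        assert sum_of_pairs("ACDW", m) == pytest.approx(sum_of_pairs("WDCA", m))

    def test_under_two_residues_is_nan(self):
        assert math.isnan(sum_of_pairs("A--", np.eye(20)))


class TestVnEntropy:
    def test_reduces_to_shannon_under_identity(self):
        assert vn_entropy(dist(A=0.5, C=0.5), np.eye(20)) == pytest.approx(1.0)

    def test_point_mass_zero(self):
        assert vn_entropy(dist(A=1.0), get_matrix("blosum62")) == pytest.approx(0.0)

    @settings(deadline=None, max_examples=200)
    @given(random_dists)
    def test_identity_similarity_equals_shannon(self, p):
        assert vn_entropy(p, np.eye(20)) == pytest.approx(
            shannon_entropy(p), abs=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(random_dists)
    def test_eigenvalues_sum_to_one(self, p):
        s = get_matrix("blosum62").similarity
        d = np.sqrt(p)
        rho = s * np.outer(d, d)
        rho /= np.trace(rho)
        assert np.linalg.eigvalsh(rho).sum() == pytest.approx(1.0)


class TestMatricesAndBackgrounds:
    @pytest.mark.parametrize("name", MATRIX_NAMES)
    def test_similarity_transform_contract(self, name):
        s = get_matrix(name).similarity
        assert np.allclose(np.diag(s), 1.0)
        assert s.min() >= 0.0 and s.max() <= 1.0
        assert np.allclose(s, s.T)

    @pytest.mark.parametrize("name", BACKGROUND_NAMES + ("uniform",))
    def test_backgrounds_are_distributions(self, name):
        q = get_background(name).q
        assert q.sum() == pytest.approx(1.0, abs=1e-9)
        assert (q > 0).all()


class TestAlignmentScoring:
    @pytest.mark.parametrize("method", METHOD_NAMES)
    def test_conserved_outranks_uniform_column(self, method):
        # column 1 invariant, column 2 maximally mixed
        rows = tuple(AA20[i % 20] for i in range(20))
        aln = Alignment(tuple(f"s{i}" for i in range(20)),
                        tuple("W" + r for r in rows))
        df = score_alignment(aln, method)
        scores = dict(zip(df["index"], df["gap_adjusted"]))
        assert scores[1] > scores[2]

    @pytest.mark.parametrize("method", METHOD_NAMES)
    def test_gap_adjustment_monotone(self, method):
        base = ["WWWW"] * 16
        gapped = ["WWWW"] * 12 + ["-" * 4] * 4
        ids = tuple(f"s{i}" for i in range(16))
        a1 = Alignment(ids, tuple(base))
        a2 = Alignment(ids, tuple(gapped))
        s1 = score_alignment(a1, method)["gap_adjusted"]
        s2 = score_alignment(a2, method)["gap_adjusted"]
        assert (s2 <= s1 + 1e-12).all()

    def test_identified_is_floor_fraction_with_index_tie_break(self):
        import pandas as pd
        df = pd.DataFrame({"index": [1, 2, 3, 4],
                           "gap_adjusted": [1.0, 2.0, 1.0, 0.5]})
        assert identified_columns(df, 0.5) == {1, 2}

    def test_consensus_intersection_semantics(self):
        # a column identified under some but not all combos is excluded:
        # use two backgrounds that rank differently via relative entropy
        ids = tuple(f"s{i}" for i in range(10))
        # col1: all W (rare residue, high RE under any background)
        # col2: all L (common residue: high RE under uniform, lower vs blosum)
        rows = tuple("WL" + AA20[i % 20] * 0 + AA20[(3 * i) % 20]
                     for i in range(10))
        aln = Alignment(ids, rows)
        cons = consensus_identified(aln, "relative_entropy",
                                    top_fraction=1 / 3)
        per_combo = []
        for bg in BACKGROUND_NAMES:
            for mat in MATRIX_NAMES:
                df = score_alignment(aln, "relative_entropy", bg, mat)
                per_combo.append(identified_columns(df, 1 / 3))
        expected = set.intersection(*per_combo)
        assert cons == expected
        assert 1 in cons  # the invariant column always survives
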