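"""Rank-biased overlap: closed form vs brute-force oracle, p selection,
pairwise matrices and the combined-sides average."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rankfuse.containers import Signature
from rankfuse.rbo import (
    choose_p,
    combine_sides,
    pairwise_similarity,
    prefix_weight,
    rbo_ext,
    spearman_footrule_similarity,
)

from conftest import make_signature, random_signature_pair


def rbo_brute_force(s, t, p):
    """Independent oracle: enumerate prefix intersections with plain sets."""
    k = len(s)
    assert len(t) == k
    agreement = 0.0
    for d in range(1, k + 1):
        x_d = len(set(s[:d]) & set(t[:d]))
        agreement += x_d / d * p**d
    x_k = len(set(s) & set(t))
    return x_k / k * p**k + (1 - p) / p * agreement


class TestRboExt:
    def test_identical_lists_give_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = int(rng.integers(1, 30))
            p = float(rng.uniform(0.05, 0.99))
            s = [f"f{i}" for i in rng.choice(200, size=k, replace=False)]
            assert abs(rbo_ext(s, s, p) - 1.0) < 1e-12

    def test_disjoint_lists_give_zero(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            k = int(rng.integers(1, 30))
            p = float(rng.uniform(0.05, 0.99))
            s = [f"a{i}" for i in range(k)]
            t = [f"b{i}" for i in range(k)]
            assert rbo_ext(s, t, p) == 0.0

    def test_adjacent_swap_hand_case(self):
        # S=(a,b,c), T=(a,c,b): X_1=1, X_2=1, X_3=3
        p = 0.9
        expected = 3 / 3 * p**3 + (1 - p) / p * (1 / 1 * p + 1 / 2 * p**2 + 3 / 3 * p**3)
        assert abs(rbo_ext(list("abc"), list("acb"), p) - expected) < 1e-12

    def test_oracle_equivalence_200_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            k = int(rng.integers(1, 31))
            alphabet = int(rng.integers(k, 101))
            s, t = random_signature_pair(rng, k, alphabet)
            p = float(rng.uniform(0.05, 0.99))
            assert abs(rbo_ext(s, t, p) - rbo_brute_force(s, t, p)) < 1e-12

    def test_symmetry_exact(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            s, t = random_signature_pair(rng, 10, 40)
            p = float(rng.uniform(0.1, 0.95))
            assert rbo_ext(s, t, p) == rbo_ext(t, s, p)

    def test_unequal_lengths_error(self):
        with pytest.raises(ValueError, match="equal length"):
            rbo_ext(list("ab"), list("abc"), 0.9)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_p_errors(self, p):
        with pytest.raises(ValueError, match="p"):
            rbo_ext(list("ab"), list("ab"), p)

    @settings(derandomize=True, max_examples=100)
    @given(st.data())
    def test_substitution_monotonicity(self, data):
        """Copying S's element into T at the same position never lowers RBO."""
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        k = data.draw(st.integers(2, 15))
        s, t = random_signature_pair(rng, k, 3 * k)
        p = data.draw(st.floats(0.1, 0.95))
        non_shared = [i for i in range(k) if t[i] not in s and s[i] not in t]
        if not non_shared:
            return
        i = non_shared[0]
        t2 = list(t)
        t2[i] = s[i]
        assert rbo_ext(s, t2, p) >= rbo_ext(s, t, p) - 1e-12

    def test_top_weighting(self):
        """A shared element weighs more at the head than at the tail."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            k = int(rng.integers(3, 12))
            s = [f"a{i}" for i in range(k)]
            t = [f"b{i}" for i in range(k)]
            shared = "x"
            s_top, t_top = [shared] + s[1:], [shared] + t[1:]
            s_bot, t_bot = s[:-1] + [shared], t[:-1] + [shared]
            p = float(rng.uniform(0.1, 0.95))
            assert rbo_ext(s_top, t_top, p) >= rbo_ext(s_bot, t_bot, p) - 1e-12


class TestChooseP:
    def test_longer_lists_need_larger_p(self):
        assert choose_p(100, 0.8) > choose_p(20, 0.8)

    def test_weight_near_one_concentrates_on_head(self):
        # prefix weight is decreasing in p: demanding ~all mass inside the
        # top-k prefix forces a smaller p (faster decay), not a larger one
        assert choose_p(20, 0.99) < choose_p(20, 0.8)

    def test_self_consistency(self):
        for k in (5, 20, 100):
            p = choose_p(k, 0.8)
            assert abs(prefix_weight(p, k) - 0.8) < 1e-8

    def test_prefix_weight_monotone_decreasing_in_p(self):
        grid = np.linspace(0.05, 0.995, 40)
        w = [prefix_weight(p, 25) for p in grid]
        # tolerance absorbs cancellation noise near w = 1 at small p
        assert all(a >= b - 1e-9 for a, b in zip(w, w[1:]))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            choose_p(0, 0.8)
        with pytest.raises(ValueError):
            choose_p(10, 1.0)


class TestPairwiseSimilarity:
    def _sigs(self, lists, side="top"):
        return [make_signature(l, subject=f"s{i}", side=side) for i, l in enumerate(lists)]

    def test_identical_signatures_off_diagonal_one(self):
        m = pairwise_similarity(self._sigs([list("abc"), list("abc")]), p=0.8)
        assert abs(m.values[0, 1] - 1.0) < 1e-12

    def test_disjoint_signatures_off_diagonal_zero(self):
        m = pairwise_similarity(self._sigs([list("abc"), list("def"), list("ghi")]), p=0.8)
        off = m.values[np.triu_indices(3, k=1)]
        np.testing.assert_array_equal(off, 0.0)

    def test_matches_independent_rbo_calls(self):
        rng = np.random.default_rng(9)
        lists = [random_signature_pair(rng, 12, 50)[0] for _ in range(3)]
        sigs = self._sigs(lists)
        m = pairwise_similarity(sigs, p=0.88)
        for i in range(3):
            for j in range(i + 1, 3):
                assert abs(m.values[i, j] - rbo_ext(lists[i], lists[j], 0.88)) < 1e-12

    def test_matches_brute_force_on_larger_batch(self):
        rng = np.random.default_rng(10)
        lists = [random_signature_pair(rng, 15, 60)[0] for _ in range(12)]
        m = pairwise_similarity(self._sigs(lists), weight=0.8)
        for i in range(12):
            for j in range(i + 1, 12):
                assert abs(m.values[i, j] - rbo_brute_force(lists[i], lists[j], m.p)) < 1e-12

    def test_single_subject_errors(self):
        with pytest.raises(ValueError, match="2 subjects"):
            pairwise_similarity(self._sigs([list("abc")]), p=0.8)

    def test_pluggable_measure(self):
        sigs = self._sigs([list("abc"), list("abc"), list("xyz")])
        m = pairwise_similarity(sigs, measure=spearman_footrule_similarity)
        assert m.values[0, 1] == 1.0
        assert m.values[0, 2] == 0.0


class TestCombineSides:
    def _matrix(self, values, side):
        sigs = [make_signature([f"f{i}", f"g{i}"], subject=f"s{i}", side=side) for i in range(3)]
        m = pairwise_similarity(sigs, p=0.8)
        m.values = values
        return m

    def test_mean_of_equal_inputs_is_identity(self):
        rng = np.random.default_rng(1)
        v = rng.uniform(0, 1, (3, 3))
        v = 0.5 * (v + v.T)
        np.fill_diagonal(v, 1.0)
        top = self._matrix(v, "top")
        bottom = self._matrix(v.copy(), "bottom")
        out = combine_sides(top, bottom)
        np.testing.assert_allclose(out.values, v, atol=1e-15)
        assert out.side == "combined"

    def test_entrywise_mean(self):
        v0 = np.eye(3)
        v1 = np.ones((3, 3))
        out = combine_sides(self._matrix(v0, "top"), self._matrix(v1, "bottom"))
        assert out.values[0, 1] == 0.5

    def test_random_pair_stays_valid(self):
        rng = np.random.default_rng(2)
        mats = []
        for side in ("top", "bottom"):
            v = rng.uniform(0, 1, (3, 3))
            v = 0.5 * (v + v.T)
            np.fill_diagonal(v, 1.0)
            mats.append(self._matrix(v, side))
        out = combine_sides(*mats)
        assert np.allclose(out.values, out.values.T)
        assert out.values.min() >= 0 and out.values.max() <= 1
        np.testing.assert_allclose(np.diag(out.values), 1.0)

    def test_subject_mismatch_errors(self):
        top = self._matrix(np.eye(3), "top")
        bottom = self._matrix(np.eye(3), "bottom")
        bottom.subject_ids = ["x", "y", "z"]
        with pytest.raises(ValueError, match="share subjects"):
            combine_sides(top, bottom)
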