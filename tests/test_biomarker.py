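"""Signature-score normalization, rank-sum fusion and the Wilcoxon filter."""

from itertools import combinations

import numpy as np
import pytest
from scipy.stats import rankdata

from rankfuse.biomarker import (
    candidate_biomarker,
    normalized_signature_scores,
    rank_value_matrix,
    select_cluster_pair,
    wilcoxon_filter,
)
from rankfuse.containers import ClusterAssignment, OmicsMatrix, SurvivalTable

from conftest import make_signature


class TestNormalizedScores:
    def test_length_three_single_subject(self):
        sig = make_signature(["a", "b", "c"])
        assert normalized_signature_scores(sig, 1) == {"a": 1.0, "b": 0.5, "c": 0.0}

    def test_division_by_group_size(self):
        sig = make_signature(["a", "b", "c"])
        scores = normalized_signature_scores(sig, 4)
        assert scores == {"a": 0.25, "b": 0.125, "c": 0.0}

    def test_frequency_normalization_identity(self):
        """Four subjects sharing one signature sum to the 1-subject scores."""
        totals: dict[str, float] = {}
        for i in range(4):
            sig = make_signature(["a", "b", "c"], subject=f"s{i}")
            for f, v in normalized_signature_scores(sig, 4).items():
                totals[f] = totals.get(f, 0.0) + v
        assert totals == pytest.approx({"a": 1.0, "b": 0.5, "c": 0.0})

    def test_single_feature_signature_degenerate(self):
        sig = make_signature(["only"])
        assert normalized_signature_scores(sig, 5) == {"only": pytest.approx(0.2)}


class TestCandidateBiomarker:
    @staticmethod
    def _both_sides(subject, top, bottom):
        return [
            make_signature(top, subject=subject, side="top"),
            make_signature(bottom, subject=subject, side="bottom"),
        ]

    def test_shared_signature_tops_the_list(self):
        sigs = []
        for i in range(3):
            sigs += self._both_sides(f"s{i}", ["a", "b", "c"], ["x", "y", "z"])
        ranked = candidate_biomarker([f"s{i}" for i in range(3)], sigs, top_n=6)
        # both sides score symmetrically: a and x tie at 1.0, ties break by id
        assert [f for f, _ in ranked[:2]] == ["a", "x"]
        assert dict(ranked)["a"] == pytest.approx(1.0)

    def test_half_frequency_scores_half(self):
        sigs = []
        for i in range(4):
            top = ["f_all", "pad1", "pad2"] if i < 2 else ["f_all", "pad3", "pad4"]
            sigs += self._both_sides(f"s{i}", top, [f"bot{i}", f"bot{i}x", f"bot{i}y"])
        # f_half appears at position 1 in half the subjects only
        sigs[0] = make_signature(["f_half", "pad1", "pad2"], subject="s0", side="top")
        sigs[2] = make_signature(["f_half", "pad1", "pad2"], subject="s1", side="top")
        ranked = dict(candidate_biomarker([f"s{i}" for i in range(4)], sigs, top_n=50))
        sigs_all = []
        for i in range(4):
            sigs_all += self._both_sides(
                f"s{i}", ["f_all", "p1", "p2"], [f"b{i}a", f"b{i}b", f"b{i}c"]
            )
        ranked_all = dict(candidate_biomarker([f"s{i}" for i in range(4)], sigs_all, top_n=50))
        assert ranked["f_half"] == pytest.approx(0.5 * ranked_all["f_all"])

    def test_subject_and_signature_order_invariance(self):
        rng = np.random.default_rng(0)
        sigs = []
        for i in range(5):
            feats = [f"f{j}" for j in rng.choice(30, 8, replace=False)]
            sigs += self._both_sides(f"s{i}", feats[:4], feats[4:])
        a = candidate_biomarker([f"s{i}" for i in range(5)], sigs, top_n=10)
        b = candidate_biomarker(
            [f"s{i}" for i in reversed(range(5))], list(reversed(sigs)), top_n=10
        )
        assert a == b

    def test_missing_side_errors(self):
        sigs = [make_signature(["a", "b"], subject="s0", side="top")]
        with pytest.raises(ValueError, match="both signature sides"):
            candidate_biomarker(["s0"], sigs)

    def test_empty_cluster_errors(self):
        with pytest.raises(ValueError, match="empty"):
            candidate_biomarker([], [])

    def test_planted_block_recovered(self):
        """A 10-feature block planted at extreme ranks in a 20-subject group
        lands in the top 15 of the rank-sum list."""
        rng = np.random.default_rng(33)
        n_feat, n_sub = 100, 20
        values = rng.normal(size=(n_feat, n_sub))
        values[:5, :] += 6.0  # planted high block
        values[5:10, :] -= 6.0  # planted low block
        m = OmicsMatrix(
            "L", [f"f{i}" for i in range(n_feat)], [f"s{j}" for j in range(n_sub)], values
        )
        from rankfuse.signatures import extract_signatures, layer_rank_profiles

        sigs = []
        for prof in layer_rank_profiles(m):
            t, b = extract_signatures(prof, 10, 10)
            sigs += [t, b]
        ranked = candidate_biomarker(m.subject_ids, sigs, top_n=100)
        top15 = {f for f, _ in ranked[:15]}
        assert {f"f{i}" for i in range(10)} <= top15


def exact_rank_sum_p(a, b):
    """Exact two-sided rank-sum p by enumerating all C(n+m, n) label splits."""
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n = len(a)
    observed = ranks[:n].sum()
    mean = n * (len(pooled) + 1) / 2
    stats = [ranks[list(idx)].sum() for idx in combinations(range(len(pooled)), n)]
    extreme = sum(abs(s - mean) >= abs(observed - mean) - 1e-12 for s in stats)
    return extreme / len(stats)


class TestWilcoxonFilter:
    def test_identical_distributions_filtered_out(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=10)
        out = wilcoxon_filter([("f", 1.0)], {"f": v}, {"f": v.copy()}, alpha=0.05)
        assert out == []

    def test_complete_separation_matches_exact_enumeration(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([10.0, 11.0, 12.0, 13.0, 14.0])
        out = wilcoxon_filter([("f", 1.0)], {"f": a}, {"f": b}, alpha=1.1)
        assert len(out) == 1
        assert out[0].raw_p == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)
        assert out[0].direction == -1

    def test_exact_oracle_on_random_small_samples(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(size=5)
            b = rng.normal(loc=rng.uniform(0, 2), size=5)
            out = wilcoxon_filter([("f", 1.0)], {"f": a}, {"f": b}, alpha=1.1)
            assert out[0].raw_p == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)

    def test_bonferroni_monotonicity(self):
        rng = np.random.default_rng(2)
        a = {f"f{i}": rng.normal(size=6) for i in range(20)}
        b = {f"f{i}": rng.normal(loc=3, size=6) for i in range(20)}
        few = wilcoxon_filter([(f"f{i}", 1.0) for i in range(5)], a, b, alpha=1.1)
        many = wilcoxon_filter([(f"f{i}", 1.0) for i in range(20)], a, b, alpha=1.1)
        few_p = {f.feature_id: f.adjusted_p for f in few}
        for f in many:
            if f.feature_id in few_p:
                assert f.adjusted_p >= few_p[f.feature_id] - 1e-15

    def test_constant_feature_gets_p_one(self):
        # p = 1 can never beat any alpha <= 1, so the feature is kept out
        out = wilcoxon_filter([("f", 1.0)], {"f": np.ones(4)}, {"f": np.ones(4)}, alpha=1.0)
        assert out == []
        # with the threshold relaxed past 1 the recorded p is exactly 1
        out_loose = wilcoxon_filter([("f", 1.0)], {"f": np.ones(4)}, {"f": np.ones(4)}, alpha=1.5)
        assert len(out_loose) == 1 and out_loose[0].raw_p == 1.0

    def test_power_on_single_shifted_feature(self):
        """One large-effect feature among 100 candidates survives Bonferroni
        in >= 95/100 seeded simulations."""
        survived = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            a = {f"f{i}": rng.normal(size=10) for i in range(100)}
            b = {f"f{i}": rng.normal(size=10) for i in range(100)}
            b["f0"] = rng.normal(loc=4.0, size=10)
            out = wilcoxon_filter([(f"f{i}", 1.0) for i in range(100)], a, b, alpha=0.05)
            survived += any(f.feature_id == "f0" for f in out)
        assert survived >= 95


class TestHelpers:
    def test_rank_value_matrix(self):
        m = OmicsMatrix("L", ["f1", "f2", "f3"], ["a", "b"],
                        np.array([[5.0, 1.0], [1.0, 2.0], [3.0, 3.0]]))
        ranks = rank_value_matrix(m)
        np.testing.assert_array_equal(ranks[:, 0], [1, 3, 2])
        np.testing.assert_array_equal(ranks[:, 1], [3, 2, 1])

    def test_select_cluster_pair(self):
        rng = np.random.default_rng(4)
        time = np.concatenate([rng.exponential(40, 10), rng.exponential(900, 10),
                               rng.exponential(200, 10)]) + 0.5
        surv = SurvivalTable([f"s{i}" for i in range(30)], time, np.ones(30, int))
        a = ClusterAssignment([f"s{i}" for i in range(30)],
                              np.repeat([0, 1, 2], 10), k=3)
        hi, lo = select_cluster_pair(a, surv)
        assert (hi, lo) == (1, 0)
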