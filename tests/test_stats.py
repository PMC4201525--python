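import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from corneamorph import stats as st


class TestNormality:
    def test_gaussian_samples_screen_normal_at_test_level(self):
        # Lilliefors at alpha = 0.05 rejects ~5 % of true-normal samples;
        # allow 3-sigma binomial slack below the nominal 95 % pass rate
        verdicts = [
            st.normality_test(np.random.default_rng(seed).normal(size=500)).normal
            for seed in range(100)
        ]
        assert sum(verdicts) >= 88

    def test_exponential_sample_rejected(self):
        x = np.random.default_rng(0).exponential(size=200)
        assert not st.normality_test(x).normal

    def test_small_sample_errors(self):
        with pytest.raises(st.StatsError, match="n >= 4"):
            st.normality_test([1.0, 2.0, 3.0])

    def test_constant_sample_errors(self):
        with pytest.raises(st.StatsError, match="constant"):
            st.normality_test([2.0] * 10)


class TestCompareGroups:
    def test_exact_mann_whitney_p(self):
        # U = 0 for fully separated triples; 2 of C(6,3) = 20 assignments
        # are as extreme, so the exact two-sided p is 0.10
        gc = st.compare_groups([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert gc.test == "Mann-Whitney"
        assert gc.p == pytest.approx(0.10, abs=1e-12)

    def test_identical_groups_give_p_one(self):
        gc = st.compare_groups([5, 6, 7, 5, 6, 7], [0, 0, 0, 1, 1, 1])
        assert gc.p == pytest.approx(1.0)

    def test_t_test_selected_for_normal_groups(self):
        rng = np.random.default_rng(1)
        v = np.concatenate([rng.normal(0, 1, 40), rng.normal(3, 1, 40)])
        labels = np.repeat([0, 1], 40)
        gc = st.compare_groups(v, labels)
        assert gc.test == "t-test"
        assert gc.normal_a and gc.normal_b
        assert gc.p < 1e-6

    def test_type_i_error_near_alpha(self):
        # equal-mean Gaussian groups: rejection rate at alpha = 0.05 should
        # sit within 3 sigma of 0.05 over 1000 replicates
        hits = 0
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            v = rng.normal(size=60)
            labels = np.repeat([0, 1], 30)
            if st.compare_groups(v, labels).p < 0.05:
                hits += 1
        assert 0.05 - 3 * 0.0069 < hits / 1000 < 0.05 + 3 * 0.0069

    def test_single_group_errors(self):
        with pytest.raises(st.StatsError, match="two groups"):
            st.compare_groups([1, 2, 3], [0, 0, 0])

    def test_mw_z_reported_for_large_samples(self):
        rng = np.random.default_rng(4)
        v = np.concatenate([rng.exponential(1, 50), rng.exponential(2, 50)])
        labels = np.repeat([0, 1], 50)
        gc = st.compare_groups(v, labels)
        assert gc.test == "Mann-Whitney"
        assert gc.z is not None and abs(gc.z) > 2


class TestStagedComparison:
    @pytest.mark.filterwarnings("ignore:stage")
    def test_kruskal_wallis_hand_computed_h(self):
        # mean ranks (1.5, 3.5, 5.5): H = 12/(6*7) * 2*(4 + 0 + 4) = 4.571
        sc = st.staged_comparison(
            [1, 2, 3, 4, 5, 6], ["normal", "normal", "I", "I", "II", "II"]
        )
        assert sc.kw_h == pytest.approx(4.571, abs=1e-3)

    @pytest.mark.filterwarnings("ignore:stage")
    def test_identical_groups_flat(self):
        sc = st.staged_comparison(
            [7, 8, 7, 8, 7, 8], ["normal", "normal", "I", "I", "II", "II"]
        )
        assert sc.kw_h == pytest.approx(0.0, abs=1e-9)
        assert all(p == 1.0 for p in sc.dunn_p_adjusted.values())

    def test_pooled_sd_effect_size_fixture(self):
        a = np.array([9.0, 10.0, 10.0, 11.0])
        b = np.array([12.0, 13.0, 13.0, 14.0])
        assert st.pooled_sd(a, b) == pytest.approx(0.8165, abs=1e-4)
        assert st.effect_size(a, b) == pytest.approx(-3.674, abs=1e-3)

    @pytest.mark.filterwarnings("ignore:stage")
    def test_effect_size_sign_convention(self):
        sc = st.staged_comparison(
            [10, 11, 12, 5, 6, 7], ["normal"] * 3 + ["I"] * 3
        )
        assert sc.effect_sizes["I"] > 0  # normal mean exceeds stage mean

    def test_bonferroni_is_capped_scaling(self):
        rng = np.random.default_rng(2)
        vals = np.concatenate([rng.normal(s, 1, 12) for s in (0, 0.5, 1, 3)])
        stages = np.repeat(["normal", "I", "II", "III-IV"], 12)
        sc = st.staged_comparison(vals, stages)
        n_pairs = len(sc.dunn_z)
        assert n_pairs == 6
        from scipy.stats import norm

        for pair, z in sc.dunn_z.items():
            raw = 2 * norm.sf(abs(z))
            assert sc.dunn_p_adjusted[pair] == pytest.approx(min(1.0, raw * n_pairs))

    def test_empty_stage_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="III-IV"):
            sc = st.staged_comparison([1, 2, 3, 4], ["normal", "normal", "I", "I"])
        assert sc.stages == ["normal", "I"]


class TestRoc:
    def test_perfect_separation(self):
        vals = np.r_[np.zeros(6), np.ones(6)]
        labels = np.r_[np.zeros(6, int), np.ones(6, int)]
        r = st.roc_analysis(vals, labels)
        assert r.auc == 1.0
        assert r.accuracy_ratio == 1.0
        assert r.sensitivity == 1.0 and r.specificity == 1.0

    @pytest.mark.parametrize("auc,ratio", [(0.847, 0.694), (0.891, 0.782)])
    def test_accuracy_ratio_identity(self, auc, ratio):
        assert st.accuracy_ratio(auc) == pytest.approx(ratio, abs=1e-12)

    def test_accuracy_ratio_reported_with_direction_larger(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(1, 1, 60), rng.normal(0, 1, 30)])
        labels = np.r_[np.zeros(60, int), np.ones(30, int)]  # diseased smaller
        r = st.roc_analysis(vals, labels, direction="larger")
        assert r.auc < 0.5
        assert r.accuracy_ratio == pytest.approx(2 * r.auc - 1)
        assert r.accuracy_ratio < 0
        flipped = st.roc_analysis(vals, labels, direction="auto")
        assert flipped.direction == "smaller"
        assert flipped.auc == pytest.approx(1 - r.auc)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(hst.integers(min_value=0, max_value=10_000))
    def test_auc_equals_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 50))
        vals = np.round(rng.normal(size=n), 1)  # coarse values force ties
        labels = np.zeros(n, int)
        labels[rng.choice(n, size=max(1, n // 3), replace=False)] = 1
        if labels.sum() in (0, n):
            return
        pos, neg = vals[labels == 1], vals[labels == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        brute = (wins + 0.5 * ties) / (len(pos) * len(neg))
        assert st.auc_mann_whitney(vals, labels) == pytest.approx(brute, abs=1e-12)

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        r = st.roc_analysis(vals, labels, direction="larger")
        assert abs(r.auc - 0.5) < 0.03
        assert r.p > 0.01

    def test_youden_cutoff_on_known_mixture(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(0, 1, 500), rng.normal(2, 1, 500)])
        labels = np.repeat([0, 1], 500)
        r = st.roc_analysis(vals, labels)
        # optimal cut for equal-variance Gaussians is the midpoint
        assert abs(r.cutoff - 1.0) < 0.35
        assert r.sensitivity + r.specificity - 1 > 0.5

    def test_hanley_mcneil_se_reference_value(self):
        # n_pos = n_neg = 50, AUC 0.8: published formula value
        se = st.hanley_mcneil_se(0.8, 50, 50)
        q1, q2 = 0.8 / 1.2, 2 * 0.64 / 1.8
        expected = np.sqrt((0.16 + 49 * (q1 - 0.64) + 49 * (q2 - 0.64)) / 2500)
        assert se == pytest.approx(expected, abs=1e-12)

    def test_single_class_errors(self):
        with pytest.raises(st.StatsError, match="both classes"):
            st.roc_analysis([1, 2, 3], [1, 1, 1])


class TestCohortReport:
    def test_report_shapes(self):
        import pandas as pd

        rng = np.random.default_rng(9)
        n = 40
        labels = np.repeat([0, 1], n // 2)
        stages = np.where(labels == 0, "normal",
                          np.random.default_rng(1).choice(["I", "II"], n))
        records = pd.DataFrame({
            "volume": rng.normal(26, 1, n) - 2 * labels,
            "area": rng.normal(43, 0.2, n) + 0.4 * labels,
        })
        rep = st.cohort_report(records, labels, stages)
        assert set(rep) == {"group", "roc", "staged"}
        assert list(rep["roc"]["variable"]) == ["volume", "area"]
        aucs = rep["roc"].set_index("variable")["auc"]
        assert aucs["volume"] < 0.5 < aucs["area"]
        ratios = rep["roc"]["accuracy_ratio"]
        np.testing.assert_allclose(ratios, 2 * rep["roc"]["auc"] - 1, atol=1e-12)
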