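import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import lagcast as lc
from lagcast.evaluation import (
    calibration_curve,
    cramers_distance,
    mape,
    max_calibration_deviation,
    pairwise_wilcoxon,
    quantile_score,
    rqs,
    score_backtest,
    summarize,
    wilcoxon_compare,
)
from lagcast.quantiles import LEVELS


def brute_force_quantile_score(y, quantiles):
    """Term-by-term evaluation of the two-sided pinball sum (oracle)."""
    total = 0.0
    for alpha, q in zip(LEVELS, quantiles):
        if y >= q:
            total += 2 * alpha * (y - q)
        else:
            total += 2 * (1 - alpha) * (q - y)
    return total


class TestMape:
    def test_worked_examples(self):
        assert mape([100, 200], [110, 180]) == pytest.approx(0.10)
        assert mape([5.0, 7.0], [5.0, 7.0]) == 0.0

    def test_zero_truth_months_excluded(self):
        value, n_excluded = mape([5, 0, 10], [4, 1, 12], return_detail=True)
        assert value == pytest.approx(0.20)
        assert n_excluded == 1

    def test_all_zero_truth_flagged_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            value, n = mape([0.0, 0.0], [1.0, 2.0], return_detail=True)
        assert np.isnan(value) and n == 2

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mape([1.0], [1.0, 2.0])


class TestQuantileScore:
    def test_perfect_point_mass_scores_zero(self):
        q = np.full(23, 3.7)
        assert quantile_score(3.7, q) == 0.0

    def test_single_level_hand_example(self):
        # at alpha=0.5, y=10 vs q=8 contributes 2*0.5*2 = 2
        assert quantile_score(10.0, np.full(23, 8.0), levels=np.array([0.5] * 23)) == pytest.approx(
            23 * 2.0
        )

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(200):
            q = np.sort(rng.normal(size=23))
            y = rng.normal()
            assert quantile_score(y, q) == pytest.approx(
                brute_force_quantile_score(y, q), abs=1e-12
            )

    def test_vectorized_over_months(self):
        rng = np.random.default_rng(15)
        q = np.sort(rng.normal(size=(4, 23)), axis=1)
        y = rng.normal(size=4)
        out = quantile_score(y, q)
        assert out.shape == (4,)
        for i in range(4):
            assert out[i] == pytest.approx(brute_force_quantile_score(y[i], q[i]), abs=1e-12)

    def test_level_count_enforced(self):
        with pytest.raises(ValueError, match="23"):
            quantile_score(1.0, np.ones(10))


class TestRqs:
    def test_identical_models_score_zero(self):
        assert rqs([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_perfect_model_attains_lower_bound(self):
        assert rqs([0.0, 0.0, 0.0], [0.5, 1.0, 2.0]) == -100.0

    def test_hand_example(self):
        assert rqs([1.0, 1.0], [3.0, 1.0]) == pytest.approx(-25.0)

    def test_both_zero_pairs_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluding 1"):
            value = rqs([0.0, 1.0], [0.0, 3.0])
        assert value == pytest.approx(-50.0)

    def test_all_perfect_pairs_rejected(self):
        with pytest.raises(ValueError, match="perfect everywhere"):
            rqs([0.0], [0.0])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=1, max_size=20),
        st.lists(st.floats(min_value=0.0, max_value=100.0), min_size=1, max_size=20),
    )
    def test_antisymmetry_and_bounds(self, a, b):
        n = min(len(a), len(b))
        a, b = np.asarray(a[:n]) + 1e-9, np.asarray(b[:n]) + 1e-9
        forward = rqs(a, b)
        assert rqs(b, a) == pytest.approx(-forward, abs=1e-9)
        assert -100.0 <= forward <= 100.0


class TestWilcoxon:
    def test_constant_shift_exact_p(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = wilcoxon_compare(a, a + 1.0)
        assert res.n == 5
        assert res.pvalue == pytest.approx(2 / 32)  # sign-flip enumeration

    def test_identical_scores_degenerate(self):
        res = wilcoxon_compare([1.0, 2.0], [1.0, 2.0])
        assert res.degenerate and res.pvalue == 1.0

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(16)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        ours = wilcoxon_compare(a, b)
        ref = stats.wilcoxon(a - b, method="exact")
        assert ours.pvalue == pytest.approx(float(ref.pvalue))

    def test_type_one_error_rate_near_nominal(self):
        """Exchangeable pairs: rejection rate at 0.05 stays within +-0.02."""
        rng = np.random.default_rng(17)
        rejections = 0
        reps = 1000
        for _ in range(reps):
            d = rng.normal(size=30)
            res = wilcoxon_compare(d, np.zeros(30))
            rejections += res.pvalue < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.02)


class TestCalibration:
    def test_total_over_and_under_coverage(self):
        q = np.tile(np.linspace(10, 12, 23), (40, 1))
        truths_below = np.full(40, 5.0)
        truths_above = np.full(40, 20.0)
        assert np.allclose(calibration_curve(q, truths_below), 1.0)
        assert np.allclose(calibration_curve(q, truths_above), 0.0)

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            calibration_curve(np.empty((0, 23)), np.array([]))

    def test_cramers_distance_examples(self):
        assert cramers_distance(LEVELS) == 0.0
        assert cramers_distance(LEVELS + 0.1) == pytest.approx(0.01)
        assert max_calibration_deviation(LEVELS + 0.1) == pytest.approx(0.1)

    def test_consistency_distance_shrinks_with_sample_size(self):
        """A perfectly specified Gaussian forecaster's distance -> 0."""
        rng = np.random.default_rng(18)
        distances = {}
        for n in (500, 2000, 10_000):
            mu = rng.normal(size=n)
            truths = mu + 0.5 * rng.standard_normal(n)
            q = mu[:, None] + 0.5 * stats.norm.ppf(LEVELS)[None, :]
            distances[n] = cramers_distance(calibration_curve(q, truths))
        assert distances[10_000] < distances[500]
        assert distances[10_000] < 1e-3


class TestSummarize:
    def test_singleton_stratum(self, small_backtest, small_panel):
        scores = score_backtest(small_backtest, small_panel)
        one = scores[(scores.family == "auto") & (scores.horizon_kind == "forecast")].iloc[:1]
        out = summarize(one, by="overall")
        assert out["median"].iloc[0] == out["mean"].iloc[0] == one["qs"].iloc[0]

    def test_strata_partition_cells(self, small_backtest, small_panel):
        scores = score_backtest(small_backtest, small_panel)
        fc = scores[scores.horizon_kind == "forecast"]
        by_jur = summarize(fc, by="jurisdiction")
        assert by_jur.groupby("family")["n"].sum().eq(len(fc) / fc.family.nunique()).all()

    def test_unknown_stratum_rejected(self, small_backtest, small_panel):
        scores = score_backtest(small_backtest, small_panel)
        with pytest.raises(ValueError, match="unknown stratum"):
            summarize(scores, by="county")

    def test_reference_rqs_column(self, small_backtest, small_panel):
        scores = score_backtest(small_backtest, small_panel)
        fc = scores[scores.horizon_kind == "forecast"]
        out = summarize(fc, by="overall", reference="baseline")
        assert "rqs_vs_baseline" in out.columns
        assert out.loc[out.family == "baseline", "rqs_vs_baseline"].iloc[0] == 0.0

    def test_pairwise_table_covers_all_pairs(self, small_backtest, small_panel):
        scores = score_backtest(small_backtest, small_panel)
        table = pairwise_wilcoxon(scores)
        assert len(table) == 3  # 3 families -> 3 pairs


def test_score_backtest_shape_and_invariants(small_backtest, small_panel):
    scores = score_backtest(small_backtest, small_panel)
    assert len(scores) == 2 * len(small_backtest)  # hindcast + forecast rows
    assert (scores["qs"].dropna() >= 0).all()
    assert (scores["mape"].dropna() >= 0).all()
    fc = scores[scores.horizon_kind == "forecast"]
    assert (fc["evaluable_horizons"] <= 6).all()
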