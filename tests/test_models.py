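import warnings

import numpy as np
import pandas as pd
import pytest

from lagcast.models import (
    BaselineDrift,
    HarmonicARIMA,
    ModelSpec,
    fit_auto,
    fit_augmented,
    fit_baseline,
    fourier_terms,
    predict_quantiles,
)
from lagcast.quantiles import LEVELS


def _series(values, start=24_000):
    return pd.Series(np.asarray(values, dtype=float), index=np.arange(start, start + len(values)))


class TestBaseline:
    @pytest.mark.parametrize(
        "values,steps,expected",
        [
            ([1, 2, 3, 4, 5], 2, [6.0, 7.0]),
            ([4, 4, 4], 3, [4.0, 4.0, 4.0]),
            ([3, 1, 2], 1, [1.5]),  # drift (2-3)/2 = -0.5 from last value 2
        ],
    )
    def test_closed_form_points(self, values, steps, expected):
        res = fit_baseline(_series(values))
        assert np.allclose(res.point(steps), expected)

    def test_constant_series_is_degenerate_point_mass(self):
        res = fit_baseline(_series([4, 4, 4]))
        assert res.degenerate
        qf = predict_quantiles(res, np.arange(24_003, 24_005), n_paths=200, seed=0)
        assert np.allclose(qf.values, 4.0)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_baseline(_series([1, 2]))

    def test_simulated_median_tracks_closed_form(self):
        rng = np.random.default_rng(0)
        res = fit_baseline(_series(1.0 + 0.01 * np.arange(60) + 0.05 * rng.standard_normal(60)))
        qf = predict_quantiles(res, np.arange(24_060, 24_066), n_paths=4000, seed=1)
        assert np.allclose(qf.point_estimate, res.point(6), atol=0.01)


class TestHarmonicARIMA:
    def test_noiseless_trend_and_season_recovered(self):
        months = np.arange(24_000, 24_120)
        y = 1.2 + 0.005 * np.arange(120) + 0.1 * np.sin(2 * np.pi * months / 12)
        res = fit_auto(_series(y))
        nxt = res.point(np.array([months[-1] + 1]))
        truth = 1.2 + 0.005 * 120 + 0.1 * np.sin(2 * np.pi * (months[-1] + 1) / 12)
        # recovery to optimizer precision (the noiseless likelihood is
        # degenerate, so machine-exact recovery is not attainable)
        assert abs(nxt[0] - truth) < 1e-3

    def test_white_noise_forecasts_stay_near_mean(self):
        """Forecasting pure noise: point forecasts hug the series mean."""
        rng = np.random.default_rng(3)
        errs = []
        for _ in range(10):
            y = 2.0 + 0.1 * rng.standard_normal(120)
            res = fit_auto(_series(y))
            fc = res.point(np.arange(24_120, 24_126))
            errs.append(np.mean(fc) - 2.0)
        # mean forecast error across replicates is near zero relative to noise
        assert abs(np.mean(errs)) < 2 * 0.1 / np.sqrt(10)

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError, match="36"):
            fit_auto(_series(np.ones(30)))

    def test_target_months_must_be_contiguous(self):
        rng = np.random.default_rng(1)
        res = fit_auto(_series(1 + 0.05 * rng.standard_normal(60)))
        with pytest.raises(ValueError, match="contiguous"):
            res.point(np.array([24_062]))


@pytest.fixture(scope="module")
def noisy_series():
    rng = np.random.default_rng(7)
    months = np.arange(24_000, 24_096)
    y = 1.2 + 0.002 * np.arange(96) + 0.1 * np.sin(2 * np.pi * months / 12)
    return _series(y + 0.08 * rng.standard_normal(96))


class TestAugmented:
    def test_constant_exog_dropped_and_equivalent_to_auto(self, noisy_series):
        exog = pd.DataFrame(
            {"log_call_rate": 0.0}, index=np.arange(24_000, 24_110)
        )
        with pytest.warns(UserWarning, match="collinear"):
            aug = fit_augmented(noisy_series, exog, ModelSpec(family="calls"))
        assert aug.model.dropped_exog == ["log_call_rate"]
        auto = fit_auto(noisy_series)
        target = np.arange(24_096, 24_102)
        assert np.allclose(aug.point(target), auto.point(target), atol=1e-2)

    def test_missing_hindcast_exog_months_error(self, noisy_series):
        rng = np.random.default_rng(8)
        exog = pd.DataFrame(
            {"log_call_rate": rng.standard_normal(96)}, index=np.arange(24_000, 24_096)
        )
        aug = fit_augmented(noisy_series, exog, ModelSpec(family="calls"))
        with pytest.raises(ValueError, match="missing target months"):
            aug.point(np.arange(24_096, 24_099))

    def test_exog_shorter_than_training_rejected(self, noisy_series):
        exog = pd.DataFrame({"log_call_rate": np.ones(50)}, index=np.arange(24_000, 24_050))
        with pytest.raises(ValueError, match="missing training months"):
            fit_augmented(noisy_series, exog, ModelSpec(family="calls"))

    def test_family_exog_columns_required(self, noisy_series):
        exog = pd.DataFrame({"wrong": np.ones(96)}, index=np.arange(24_000, 24_096))
        with pytest.raises(ValueError, match="lacks columns"):
            fit_augmented(noisy_series, exog, ModelSpec(family="calls"))


class TestQuantileExtraction:
    def test_n_paths_floor(self):
        res = fit_baseline(_series([1, 2, 3]))
        with pytest.raises(ValueError, match="at least 100"):
            predict_quantiles(res, np.array([24_003]), n_paths=50)

    def test_median_level_is_point_estimate(self):
        rng = np.random.default_rng(2)
        res = fit_auto(_series(1 + 0.1 * rng.standard_normal(60)))
        qf = predict_quantiles(res, np.arange(24_060, 24_063), n_paths=400, seed=3)
        med_idx = int(np.where(LEVELS == 0.5)[0][0])
        assert np.array_equal(qf.point_estimate, qf.values[:, med_idx])

    def test_gaussian_interval_width(self):
        """One-step 95% interval spans ~3.92 innovation SDs."""
        rng = np.random.default_rng(4)
        res = fit_auto(_series(1.5 + 0.1 * rng.standard_normal(150)))
        qf = predict_quantiles(res, np.array([24_150]), n_paths=10_000, seed=5)
        sd = float(np.sqrt(res.sm_results.params[-1]))
        lo = qf.values[0, int(np.where(LEVELS == 0.025)[0][0])]
        hi = qf.values[0, int(np.where(LEVELS == 0.975)[0][0])]
        assert (hi - lo) == pytest.approx(3.92 * sd, rel=0.05)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        res = fit_auto(_series(1 + 0.1 * rng.standard_normal(60)))
        a = predict_quantiles(res, np.arange(24_060, 24_066), n_paths=300, seed=9)
        b = predict_quantiles(res, np.arange(24_060, 24_066), n_paths=300, seed=9)
        assert np.array_equal(a.values, b.values)


def test_coverage_under_correct_specification():
    """95% central intervals cover ~95% when the model matches the process.

    The process is a seasonal random walk with drift (nested in the fitted
    family): y_t = rw_t + Fourier season. Over >= 2000 forecast-truth pairs
    the empirical coverage of the 0.025-0.975 interval must be within +-3%
    of nominal.
    """
    rng = np.random.default_rng(12)
    n_train, horizon = 200, 6
    hits = total = 0
    lo_idx = int(np.where(LEVELS == 0.025)[0][0])
    hi_idx = int(np.where(LEVELS == 0.975)[0][0])
    for rep in range(334):
        months = np.arange(24_000, 24_000 + n_train + horizon)
        rw = np.cumsum(0.002 + 0.05 * rng.standard_normal(len(months)))
        y = 2.0 + rw + 0.1 * np.sin(2 * np.pi * months / 12)
        series = _series(y[:n_train])
        res = fit_auto(series)
        qf = predict_quantiles(
            res, months[n_train:], n_paths=1000, seed=int(rng.integers(2**31))
        )
        truth = y[n_train:]
        hits += int(((truth >= qf.values[:, lo_idx]) & (truth <= qf.values[:, hi_idx])).sum())
        total += horizon
    assert total >= 2000
    assert hits / total == pytest.approx(0.95, abs=0.03)


def test_fourier_terms_shape_and_period():
    months = np.arange(0, 24)
    F = fourier_terms(months, 2)
    assert F.shape == (24, 4)
    assert np.allclose(F[0], F[12])  # period 12
    assert fourier_terms(months, 0).shape == (24, 0)
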