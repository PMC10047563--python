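import numpy as np
import pandas as pd
import pytest

from lagcast.ensemble import (
    EnsembleSpec,
    combine,
    fit_arima_search,
    fit_component,
    fit_ets,
    fit_nnar,
)
from lagcast.evaluation import quantile_score
from lagcast.models import ModelSpec, predict_quantiles
from lagcast.quantiles import LEVELS, QuantileForecast


def _series(values, start=24_000):
    return pd.Series(np.asarray(values, dtype=float), index=np.arange(start, start + len(values)))


def _random_qf(rng, months=(10, 11)):
    values = np.sort(rng.uniform(0, 5, size=(len(months), 23)), axis=1)
    return QuantileForecast(target_months=np.array(months), values=values)


class TestCombine:
    def test_idempotence(self):
        rng = np.random.default_rng(0)
        f = _random_qf(rng)
        out = combine([f, f, f])
        assert np.allclose(out.values, f.values)

    def test_weighted_mean_arithmetic(self):
        a = QuantileForecast.point_mass([2.0], [5])
        b = QuantileForecast.point_mass([4.0], [5])
        out = combine([a, b])
        assert np.allclose(out.values, 3.0)
        out = combine([a, b], weights=[0.25, 0.75])
        assert np.allclose(out.values, 3.5)

    def test_monotone_and_within_envelope(self):
        rng = np.random.default_rng(1)
        comps = [_random_qf(rng) for _ in range(3)]
        out = combine(comps)
        assert np.all(np.diff(out.values, axis=1) >= 0)
        stacked = np.stack([c.values for c in comps])
        assert np.all(out.values >= stacked.min(axis=0) - 1e-12)
        assert np.all(out.values <= stacked.max(axis=0) + 1e-12)

    def test_mismatched_months_rejected(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError, match="mismatched target months"):
            combine([_random_qf(rng, (10, 11)), _random_qf(rng, (11, 12))])

    def test_pinball_convexity_bounds_ensemble_score(self):
        """QS of the quantile average never exceeds the worst component."""
        rng = np.random.default_rng(3)
        for _ in range(200):
            comps = [_random_qf(rng, (7,)) for _ in range(3)]
            y = rng.uniform(0, 5)
            ens = combine(comps)
            scores = [quantile_score(y, c.values[0]) for c in comps]
            assert quantile_score(y, ens.values[0]) <= max(scores) + 1e-9


class TestEnsembleSpec:
    def test_needs_two_components(self):
        with pytest.raises(ValueError, match="at least 2"):
            EnsembleSpec(components=(ModelSpec(family="ets"),))

    def test_weights_must_be_simplex(self):
        comps = tuple(ModelSpec(family=f) for f in ("ets", "arima_search"))
        with pytest.raises(ValueError, match="sum to 1"):
            EnsembleSpec(components=comps, weights=(0.9, 0.9))
        spec = EnsembleSpec(components=comps)
        assert np.allclose(spec.weight_vector(), 0.5)


class TestComponents:
    def test_ets_tracks_noiseless_linear_trend(self):
        y = 1.0 + 0.01 * np.arange(60)
        res = fit_ets(_series(y))
        assert abs(res.point(1)[0] - (1.0 + 0.01 * 60)) < 1e-6

    def test_nnar_requires_hidden_units(self):
        with pytest.raises(ValueError, match="hidden unit"):
            ModelSpec(family="nnar", nnar_hidden=0)

    def test_nnar_fits_and_simulates(self):
        rng = np.random.default_rng(4)
        months = np.arange(24_000, 24_060)
        y = 1.5 + 0.2 * np.sin(2 * np.pi * months / 12) + 0.05 * rng.standard_normal(60)
        res = fit_nnar(_series(y), ModelSpec(family="nnar", nnar_restarts=2), seed=1)
        qf = predict_quantiles(res, np.arange(24_060, 24_063), n_paths=200, seed=2)
        assert qf.values.shape == (3, 23)
        assert np.all(qf.values > 0)

    def test_arima_search_prefers_differencing_for_integrated_series(self):
        """On random-walk-with-drift data the search should pick d=1 and
        never do worse (by AICc) than the fixed default order."""
        rng = np.random.default_rng(5)
        spec = ModelSpec(family="arima_search", search_max_p=2, search_max_q=2)
        d_choices = []
        for rep in range(6):
            y = 2.0 + np.cumsum(0.01 + 0.08 * rng.standard_normal(120))
            res = fit_arima_search(_series(y), spec)
            d_choices.append(res.order[1])
            from statsmodels.tsa.arima.model import ARIMA
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fixed = ARIMA(y, order=(1, 1, 1), trend="t").fit()
            assert res.sm_results.info_criteria("aicc") <= fixed.info_criteria("aicc") + 1e-6
        assert sum(d == 1 for d in d_choices) >= 4

    def test_fit_component_dispatch(self):
        rng = np.random.default_rng(6)
        y = _series(2 + 0.1 * rng.standard_normal(60))
        assert fit_component(y, ModelSpec(family="ets")).point(1).shape == (1,)
        with pytest.raises(ValueError, match="component family"):
            fit_component(y, ModelSpec(family="auto"))
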