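"""Multi-model forecast ensembles.

Three alternative forecasters to the fixed-order dynamic harmonic
regression, combined by quantile averaging (Vincentization):

``ets``
    Additive error/trend/seasonal exponential smoothing.
``arima_search``
    ARIMA with order selected by corrected AIC over a bounded grid
    (p, q in 0..3, d in 0..1, drift optional), refitted at each cycle.
``nnar``
    Feed-forward neural autoregression on the last 12 lags with a single
    hidden layer, trained with multiple seeded restarts; forecast paths are
    generated recursively with bootstrapped residuals.

Quantile averaging keeps the combination closed under the 23-level quantile
representation and preserves monotonicity across levels; ensemble values
always lie within the componentwise min-max envelope, so by convexity of
the pinball loss the ensemble quantile score never exceeds the worst
component's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPRegressor
from statsmodels.tsa.arima.model import ARIMA as _SmARIMA
from statsmodels.tsa.exponential_smoothing.ets import ETSModel

from .models import ModelSpec, predict_quantiles
from .quantiles import LEVELS, QuantileForecast

__all__ = [
    "EnsembleSpec",
    "fit_component",
    "combine",
    "ETSResults",
    "ArimaSearchResults",
    "NNARResults",
]

DEFAULT_COMPONENTS = ("ets", "arima_search", "nnar")


@dataclass(frozen=True)
class EnsembleSpec:
    """Ensemble of alternative forecasters combined by quantile averaging."""

    components: Tuple[ModelSpec, ...] = field(
        default_factory=lambda: tuple(ModelSpec(family=f) for f in DEFAULT_COMPONENTS)
    )
    weights: Optional[Tuple[float, ...]] = None
    family: str = "ensemble"
    n_paths: int = 1000

    def __post_init__(self):
        if len(self.components) < 2:
            raise ValueError("an ensemble needs at least 2 components")
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float)
            if len(w) != len(self.components):
                raise ValueError("weights length must match components")
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("weights must be non-negative and sum to 1")

    @property
    def exog_columns(self) -> tuple:
        return ()

    def weight_vector(self) -> np.ndarray:
        if self.weights is None:
            return np.full(len(self.components), 1.0 / len(self.components))
        return np.asarray(self.weights, dtype=float)


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------


@dataclass
class ETSResults:
    """Fitted additive exponential smoothing model."""

    sm_results: object
    last_month: int

    def simulate_paths(self, target_months, n_paths, rng, exog=None) -> np.ndarray:
        target_months = np.asarray(target_months, dtype=int)
        h = len(target_months)
        # the exponential-smoothing simulator predates numpy Generators
        state = np.random.RandomState(int(rng.integers(2**31)))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = self.sm_results.simulate(
                nsimulations=h, anchor="end", repetitions=n_paths, random_state=state
            )
        return np.asarray(sim).reshape(h, n_paths).T

    def point(self, steps: int) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return np.asarray(self.sm_results.forecast(steps))


def fit_ets(series: pd.Series, seasonal_periods: int = 12) -> ETSResults:
    """Additive error/trend(/seasonal) exponential smoothing.

    The seasonal component is included when the series covers at least two
    full periods; otherwise trend-only smoothing is used.
    """
    series = pd.Series(series).astype(float)
    y = series.reset_index(drop=True)
    seasonal = "add" if len(series) >= 2 * seasonal_periods else None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = ETSModel(
            y,
            error="add",
            trend="add",
            seasonal=seasonal,
            seasonal_periods=seasonal_periods if seasonal else None,
        )
        res = model.fit(disp=False)
    return ETSResults(sm_results=res, last_month=int(series.index[-1]))


@dataclass
class ArimaSearchResults:
    """Best-AICc ARIMA over the bounded search grid."""

    sm_results: object
    order: Tuple[int, int, int]
    trend: str
    last_month: int

    def simulate_paths(self, target_months, n_paths, rng, exog=None) -> np.ndarray:
        target_months = np.asarray(target_months, dtype=int)
        h = len(target_months)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = self.sm_results.simulate(
                nsimulations=h, anchor="end", repetitions=n_paths, random_state=rng
            )
        return np.asarray(sim).reshape(h, n_paths).T


def fit_arima_search(series: pd.Series, spec: ModelSpec = ModelSpec(family="arima_search")):
    """Select (p, d, q) and drift by corrected AIC over a bounded grid.

    Falls back to the ModelSpec's fixed order when no grid point fits, with
    a warning.
    """
    series = pd.Series(series).astype(float)
    y = series.to_numpy()
    best = None
    for d in range(spec.search_max_d + 1):
        trends = ["n", "c"] if d == 0 else ["n", "t"]
        for p in range(spec.search_max_p + 1):
            for q in range(spec.search_max_q + 1):
                if p == q == 0 and d == 0:
                    continue
                for trend in trends:
                    try:
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore")
                            res = _SmARIMA(y, order=(p, d, q), trend=trend).fit(
                                method_kwargs={"maxiter": 100}
                            )
                        aicc = float(res.info_criteria("aicc"))
                    except Exception:
                        continue
                    if np.isfinite(aicc) and (best is None or aicc < best[0]):
                        best = (aicc, res, (p, d, q), trend)
    if best is None:
        warnings.warn("order search exhausted the grid; falling back to the fixed order")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = _SmARIMA(y, order=spec.arima_order, trend="t").fit()
        best = (np.nan, res, spec.arima_order, "t")
    _, res, order, trend = best
    return ArimaSearchResults(
        sm_results=res, order=order, trend=trend, last_month=int(series.index[-1])
    )


@dataclass
class NNARResults:
    """Feed-forward autoregression; simulates via residual bootstrap."""

    network: MLPRegressor
    lags: int
    history: np.ndarray
    residuals: np.ndarray
    y_mean: float
    y_scale: float
    last_month: int

    def _predict_scaled(self, window: np.ndarray) -> np.ndarray:
        return self.network.predict(window)

    def simulate_paths(self, target_months, n_paths, rng, exog=None) -> np.ndarray:
        target_months = np.asarray(target_months, dtype=int)
        h = len(target_months)
        hist = (self.history - self.y_mean) / self.y_scale
        window = np.tile(hist[-self.lags:], (n_paths, 1))
        out = np.empty((n_paths, h))
        for j in range(h):
            mu = self._predict_scaled(window)
            shock = rng.choice(self.residuals, size=n_paths, replace=True)
            step = mu + shock
            out[:, j] = step
            window = np.column_stack([window[:, 1:], step])
        return out * self.y_scale + self.y_mean


def fit_nnar(
    series: pd.Series, spec: ModelSpec = ModelSpec(family="nnar"), seed: int = 0
) -> NNARResults:
    """Neural autoregression on the last ``spec.nnar_lags`` months.

    The network is refit ``spec.nnar_restarts`` times from seeded starts and
    the best in-sample fit kept.
    """
    if spec.nnar_hidden < 1:
        raise ValueError("nnar requires at least one hidden unit")
    series = pd.Series(series).astype(float)
    y = series.to_numpy()
    lags = spec.nnar_lags
    if len(y) < lags + 12:
        raise ValueError(f"nnar needs at least {lags + 12} observations")
    y_mean, y_scale = float(y.mean()), float(y.std() or 1.0)
    ys = (y - y_mean) / y_scale
    X = np.column_stack([ys[i : len(ys) - lags + i] for i in range(lags)])
    target = ys[lags:]
    best = None
    for r in range(spec.nnar_restarts):
        net = MLPRegressor(
            hidden_layer_sizes=(spec.nnar_hidden,),
            activation="tanh",
            solver="lbfgs",
            max_iter=500,
            random_state=int(np.random.SeedSequence(seed, spawn_key=(r,)).generate_state(1)[0] % 2**31),
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            net.fit(X, target)
        mse = float(np.mean((net.predict(X) - target) ** 2))
        if best is None or mse < best[0]:
            best = (mse, net)
    net = best[1]
    resid = target - net.predict(X)
    return NNARResults(
        network=net,
        lags=lags,
        history=y,
        residuals=resid,
        y_mean=y_mean,
        y_scale=y_scale,
        last_month=int(series.index[-1]),
    )


def fit_component(series: pd.Series, spec: ModelSpec, seed: int = 0):
    """Fit one ensemble component (``ets``, ``arima_search`` or ``nnar``)."""
    if spec.family == "ets":
        return fit_ets(series)
    if spec.family == "arima_search":
        return fit_arima_search(series, spec)
    if spec.family == "nnar":
        return fit_nnar(series, spec, seed=seed)
    raise ValueError(f"not an ensemble component family: {spec.family!r}")


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------


def combine(forecasts: Sequence[QuantileForecast], weights=None) -> QuantileForecast:
    """Vincentized combination: weighted mean of quantiles, level by level.

    All components must share target months, level set and horizon kind.
    """
    if len(forecasts) < 1:
        raise ValueError("nothing to combine")
    ref = forecasts[0]
    for f in forecasts[1:]:
        if not np.array_equal(f.target_months, ref.target_months):
            raise ValueError("component forecasts have mismatched target months")
        if f.horizon_kind != ref.horizon_kind:
            raise ValueError("component forecasts have mismatched horizon kinds")
    if weights is None:
        w = np.full(len(forecasts), 1.0 / len(forecasts))
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(forecasts):
            raise ValueError("weights length must match forecasts")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be non-negative and sum to 1")
    stacked = np.stack([f.values for f in forecasts])  # (k, months, levels)
    values = np.tensordot(w, stacked, axes=1)
    return QuantileForecast(
        target_months=ref.target_months, values=values, horizon_kind=ref.horizon_kind
    )
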