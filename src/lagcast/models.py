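"""Per-jurisdiction forecasting models.

Five model families are used throughout the backtest:

``baseline``
    Random walk with drift: persistence plus the series' average change per
    time step, no trend/seasonal structure beyond that.
``auto``
    Dynamic harmonic regression — a fixed-order ARIMA on the rate series
    with drift and Fourier seasonal covariates (period 12).
``calls`` / ``ght`` / ``calls_ght``
    The ``auto`` structure augmented with exogenous proxy covariates:
    the log crisis-call rate, the six logit search proportions, or both.

All models are fitted per jurisdiction on the raw rate scale (rates may be
zero in small jurisdictions, so no log transform of the response is used)
and emit probabilistic estimates by simulating sample paths and taking
empirical quantiles at the 23 standard levels.

Classes follow the statsmodels convention: a model object is constructed
from data, ``fit()`` returns a results object, and prediction/simulation
hang off the results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from statsmodels.tsa.arima.model import ARIMA as _SmARIMA

from .months import format_month
from .panel import PROXY_COLUMNS
from .quantiles import LEVELS, QuantileForecast

__all__ = [
    "ModelSpec",
    "BaselineDrift",
    "BaselineDriftResults",
    "HarmonicARIMA",
    "HarmonicARIMAResults",
    "fit_baseline",
    "fit_auto",
    "fit_augmented",
    "predict_quantiles",
    "FAMILY_EXOG",
    "MODEL_FAMILIES",
]

#: Exogenous proxy columns used by each augmented family.
FAMILY_EXOG = {
    "baseline": (),
    "auto": (),
    "calls": ("log_call_rate",),
    "ght": tuple(c for c in PROXY_COLUMNS if c.startswith("logit_")),
    "calls_ght": tuple(PROXY_COLUMNS),
    # ensemble component families carry no proxy covariates
    "ets": (),
    "arima_search": (),
    "nnar": (),
}

MODEL_FAMILIES = ("baseline", "auto", "calls", "ght", "calls_ght")

#: Fallback ARIMA order used when the default order fails to converge.
FALLBACK_ORDER = (0, 1, 1)


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one model family.

    ``n_paths`` is the number of simulated sample paths used for quantile
    extraction; ``fourier_K`` the number of harmonic pairs at period 12.
    """

    family: str = "auto"
    arima_order: Tuple[int, int, int] = (1, 1, 1)
    fourier_K: int = 2
    n_paths: int = 1000
    include_drift: bool = True
    # ensemble-component knobs (ignored by the core families)
    search_max_p: int = 3
    search_max_q: int = 3
    search_max_d: int = 1
    nnar_hidden: int = 8
    nnar_lags: int = 12
    nnar_restarts: int = 5

    def __post_init__(self):
        if self.family not in FAMILY_EXOG:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.n_paths < 100:
            raise ValueError("n_paths must be at least 100")
        if self.family == "baseline" and self.fourier_K != 0:
            object.__setattr__(self, "fourier_K", 0)
        if self.family != "baseline" and not 0 <= self.fourier_K <= 5:
            raise ValueError("fourier_K must be in 0..5")
        if self.family == "nnar" and self.nnar_hidden < 1:
            raise ValueError("nnar requires at least one hidden unit")

    @property
    def exog_columns(self) -> Tuple[str, ...]:
        return FAMILY_EXOG[self.family]


# ---------------------------------------------------------------------------
# baseline: random walk with drift
# ---------------------------------------------------------------------------


class BaselineDrift:
    """Random walk with drift on an observed rate series.

    The drift is the mean first difference; the j-step-ahead predictive
    distribution is Gaussian around last value + j * drift with variance
    growing linearly in j (innovation variance estimated from the residual
    first differences).
    """

    def __init__(self, series: pd.Series):
        series = pd.Series(series).astype(float)
        if len(series) < 3:
            raise ValueError("baseline model needs at least 3 observations")
        self.series = series

    def fit(self) -> "BaselineDriftResults":
        values = self.series.to_numpy()
        diffs = np.diff(values)
        drift = float(diffs.mean())
        resid = diffs - drift
        sigma = float(np.sqrt((resid**2).mean())) if len(resid) else 0.0
        return BaselineDriftResults(
            drift=drift,
            sigma=sigma,
            last_value=float(values[-1]),
            last_month=int(self.series.index[-1]),
            nobs=len(values),
        )


@dataclass(frozen=True)
class BaselineDriftResults:
    drift: float
    sigma: float
    last_value: float
    last_month: int
    nobs: int

    @property
    def degenerate(self) -> bool:
        """True when the residual variance collapsed (e.g. constant series)."""
        return self.sigma == 0.0

    def point(self, steps: int) -> np.ndarray:
        """Closed-form point forecasts: last value + j * drift, j = 1..steps."""
        j = np.arange(1, steps + 1)
        return self.last_value + j * self.drift

    def simulate_paths(self, steps: int, n_paths: int, rng: np.random.Generator) -> np.ndarray:
        innov = self.drift + self.sigma * rng.standard_normal((n_paths, steps))
        return self.last_value + np.cumsum(innov, axis=1)

    def predict_quantiles(self, target_months, n_paths: int = 1000, seed=None) -> QuantileForecast:
        return predict_quantiles(self, target_months, n_paths=n_paths, seed=seed)

    def summary(self) -> str:
        return (
            "Random walk with drift\n"
            f"  nobs:  {self.nobs}\n"
            f"  drift: {self.drift:.6g} per month\n"
            f"  sigma: {self.sigma:.6g}"
            + ("  [degenerate: zero residual variance]" if self.degenerate else "")
        )


# ---------------------------------------------------------------------------
# auto / augmented: dynamic harmonic regression with ARIMA errors
# ---------------------------------------------------------------------------


def fourier_terms(month_indices: np.ndarray, K: int) -> np.ndarray:
    """Sin/cos pairs at periods 12/k, k = 1..K, on the absolute month index."""
    t = np.asarray(month_indices, dtype=float)
    cols = []
    for k in range(1, K + 1):
        w = 2.0 * np.pi * k * t / 12.0
        cols.extend([np.sin(w), np.cos(w)])
    return np.column_stack(cols) if cols else np.empty((len(t), 0))


def _drop_collinear(X: np.ndarray, names: Sequence[str], n_protected: int):
    """Drop near-constant or linearly dependent trailing columns.

    The first ``n_protected`` columns (the Fourier terms) are kept; proxy
    columns that add no rank are dropped with a warning.
    """
    keep = list(range(n_protected))
    dropped = []
    for i in range(n_protected, X.shape[1]):
        col = X[:, i]
        trial = X[:, keep + [i]]
        if np.ptp(col) < 1e-12 or np.linalg.matrix_rank(
            np.column_stack([trial, np.ones(len(X))])
        ) <= len(keep) + 1:
            dropped.append(names[i])
        else:
            keep.append(i)
    if dropped:
        warnings.warn(f"dropping constant/collinear exogenous columns: {dropped}")
    return X[:, keep], [names[i] for i in keep], dropped


class HarmonicARIMA:
    """Dynamic harmonic regression with ARIMA errors and optional proxies.

    Parameters
    ----------
    series
        Observed mortality-rate series indexed by integer month.
    exog
        Optional DataFrame of transformed proxy covariates indexed by month.
        Must cover every training month, and later every prediction target
        month.
    order, fourier_K, include_drift
        ARIMA(p, d, q) order of the error process, number of Fourier
        harmonic pairs, and whether a drift (linear trend) term is included.
    """

    MIN_OBS = 36  # three seasonal cycles

    def __init__(
        self,
        series: pd.Series,
        exog: Optional[pd.DataFrame] = None,
        order: Tuple[int, int, int] = (1, 1, 1),
        fourier_K: int = 2,
        include_drift: bool = True,
    ):
        series = pd.Series(series).astype(float)
        if len(series) < self.MIN_OBS:
            raise ValueError(
                f"need at least {self.MIN_OBS} observations (three seasonal "
                f"cycles), got {len(series)}"
            )
        if 2 * fourier_K >= len(series) / 4:
            raise ValueError("fourier_K too large for series length")
        self.series = series
        self.order = tuple(order)
        self.fourier_K = int(fourier_K)
        self.include_drift = bool(include_drift)
        self.exog = None
        self.exog_names: list = []
        self.dropped_exog: list = []
        if exog is not None and exog.shape[1] > 0:
            missing = [format_month(m) for m in series.index if m not in exog.index]
            if missing:
                raise ValueError(f"exogenous covariates missing training months: {missing}")
            self.exog = exog.loc[series.index]
            self.exog_names = list(exog.columns)

    def fit(self) -> "HarmonicARIMAResults":
        months = self.series.index.to_numpy()
        F = fourier_terms(months, self.fourier_K)
        names = [f"fourier_{i}" for i in range(F.shape[1])]
        if self.exog is not None:
            X = np.column_stack([F, self.exog.to_numpy(dtype=float)])
            names = names + list(self.exog_names)
            X, kept, dropped = _drop_collinear(X, names, F.shape[1])
            self.dropped_exog = dropped
            kept_exog = [n for n in kept if n in self.exog_names]
        else:
            X = F
            kept_exog = []
        trend = "t" if self.include_drift and self.order[1] >= 1 else ("ct" if self.include_drift else "n")
        res, order_used = self._fit_sm(self.series.to_numpy(), X if X.shape[1] else None, trend)
        return HarmonicARIMAResults(
            model=self,
            sm_results=res,
            order_used=order_used,
            trend=trend,
            kept_exog=kept_exog,
            months=months,
        )

    def _fit_sm(self, y, X, trend):
        def attempt(order):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = _SmARIMA(y, exog=X, order=order, trend=trend)
                return model.fit(method_kwargs={"maxiter": 200})

        try:
            res = attempt(self.order)
            if np.isfinite(res.llf):
                return res, self.order
            raise ValueError("non-finite likelihood")
        except Exception:
            if self.order == FALLBACK_ORDER:
                raise
            warnings.warn(
                f"ARIMA{self.order} fit failed; refitting at fallback order {FALLBACK_ORDER}"
            )
            return attempt(FALLBACK_ORDER), FALLBACK_ORDER


@dataclass
class HarmonicARIMAResults:
    """Fitted dynamic harmonic regression; supports path simulation."""

    model: HarmonicARIMA
    sm_results: object
    order_used: Tuple[int, int, int]
    trend: str
    kept_exog: list
    months: np.ndarray

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.sm_results.params, index=self.sm_results.param_names)

    @property
    def drift(self) -> float:
        """Estimated per-month drift (0 if no trend term was included).

        statsmodels places trend coefficients first in the parameter vector:
        the drift is parameter 0 under trend "t" and parameter 1 under "ct".
        """
        if self.trend == "t":
            return float(self.sm_results.params[0])
        if self.trend == "ct":
            return float(self.sm_results.params[1])
        return 0.0

    def _future_design(self, target_months: np.ndarray, exog: Optional[pd.DataFrame]):
        F = fourier_terms(target_months, self.model.fourier_K)
        if self.kept_exog:
            source = exog if exog is not None else self.model.exog
            if source is None:
                raise ValueError("model was fitted with exogenous covariates; provide exog")
            missing = [format_month(m) for m in target_months if m not in source.index]
            if missing:
                raise ValueError(f"exogenous covariates missing target months: {missing}")
            X = np.column_stack(
                [F, source.loc[target_months, self.kept_exog].to_numpy(dtype=float)]
            )
        else:
            X = F
        return X if X.shape[1] else None

    def point(self, target_months, exog: Optional[pd.DataFrame] = None) -> np.ndarray:
        """Mean forecast for contiguous months immediately after training."""
        target_months = np.asarray(target_months, dtype=int)
        self._check_contiguous(target_months)
        Xf = self._future_design(target_months, exog)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fc = self.sm_results.get_forecast(len(target_months), exog=Xf)
        return np.asarray(fc.predicted_mean)

    def simulate_paths(
        self,
        target_months: np.ndarray,
        n_paths: int,
        rng: np.random.Generator,
        exog: Optional[pd.DataFrame] = None,
    ) -> np.ndarray:
        target_months = np.asarray(target_months, dtype=int)
        self._check_contiguous(target_months)
        Xf = self._future_design(target_months, exog)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sim = self.sm_results.simulate(
                nsimulations=len(target_months),
                anchor="end",
                repetitions=n_paths,
                exog=Xf,
                random_state=rng,
            )
        sim = np.asarray(sim).reshape(len(target_months), n_paths)
        return sim.T  # (n_paths, n_months)

    def _check_contiguous(self, target_months: np.ndarray):
        start = int(self.months[-1]) + 1
        expected = np.arange(start, start + len(target_months))
        if not np.array_equal(target_months, expected):
            raise ValueError(
                f"target months must be contiguous from {format_month(start)}; "
                f"got {[format_month(m) for m in target_months]}"
            )

    def predict_quantiles(
        self, target_months, n_paths: int = 1000, seed=None, exog: Optional[pd.DataFrame] = None,
        horizon_kind: str = "forecast",
    ) -> QuantileForecast:
        return predict_quantiles(
            self, target_months, n_paths=n_paths, seed=seed, exog=exog, horizon_kind=horizon_kind
        )

    def summary(self):
        return self.sm_results.summary()


# ---------------------------------------------------------------------------
# spec-surface constructors and quantile extraction
# ---------------------------------------------------------------------------


def fit_baseline(series: pd.Series) -> BaselineDriftResults:
    """Fit the random-walk-with-drift baseline."""
    return BaselineDrift(series).fit()


def fit_auto(series: pd.Series, spec: ModelSpec = ModelSpec(family="auto")) -> HarmonicARIMAResults:
    """Fit the trend + Fourier-seasonality ARIMA on mortality rates alone."""
    return HarmonicARIMA(
        series,
        order=spec.arima_order,
        fourier_K=spec.fourier_K,
        include_drift=spec.include_drift,
    ).fit()


def fit_augmented(series: pd.Series, exog: pd.DataFrame, spec: ModelSpec) -> HarmonicARIMAResults:
    """Fit the auto structure plus exogenous proxy covariates.

    ``exog`` must cover every training month; prediction additionally
    requires rows for every target month (the observed proxy values over
    the hindcast window).
    """
    cols = [c for c in spec.exog_columns if c in exog.columns]
    missing = set(spec.exog_columns) - set(cols)
    if missing:
        raise ValueError(f"exog lacks columns required by family {spec.family!r}: {sorted(missing)}")
    return HarmonicARIMA(
        series,
        exog=exog[cols],
        order=spec.arima_order,
        fourier_K=spec.fourier_K,
        include_drift=spec.include_drift,
    ).fit()


def predict_quantiles(
    fitted,
    target_months,
    n_paths: int = 1000,
    seed=None,
    exog: Optional[pd.DataFrame] = None,
    horizon_kind: str = "forecast",
) -> QuantileForecast:
    """Simulate sample paths and extract the 23-level quantile set.

    Deterministic given ``seed`` (an int or :class:`numpy.random.SeedSequence`).
    Quantiles are sorted within each month and clipped at zero.
    """
    if n_paths < 100:
        raise ValueError("n_paths must be at least 100")
    target_months = np.asarray(target_months, dtype=int)
    rng = np.random.default_rng(seed)
    if isinstance(fitted, BaselineDriftResults):
        if fitted.degenerate:
            return QuantileForecast.point_mass(
                fitted.point(len(target_months)), target_months, horizon_kind
            )
        paths = fitted.simulate_paths(len(target_months), n_paths, rng)
    else:
        paths = fitted.simulate_paths(target_months, n_paths, rng, exog=exog)
    return QuantileForecast.from_paths(paths, target_months, horizon_kind)
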