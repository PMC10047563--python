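"""Rolling hindcast-then-forecast backtest.

At each generation month m, for each jurisdiction and model family:

1. the hindcast model is fitted on mortality observed through k (the last
   released month) — augmented families additionally condition on proxies
   observed through m — and emits quantile hindcasts for the l + 1 gap
   months m-l .. m;
2. the hindcast point estimates (medians) are appended to the observed
   series ("stitched");
3. a forecast model with the plain trend + Fourier structure (or the
   persistence baseline, for the baseline family) is fitted on the stitched
   series and emits quantile forecasts for m+1 .. m+6.

Cycles advance monthly with an expanding training window, re-masking the
panel at every cycle so the backtest only ever touches data that would have
been available in real time. The whole run is reproducible from
(panel, specs, master_seed): each (jurisdiction, cycle, family) fit draws
from its own seed substream, so re-running any subset reproduces the full
run's values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .availability import AvailabilityView, ReleaseCalendar, mask_panel
from .ensemble import EnsembleSpec, combine, fit_component
from .models import (
    ModelSpec,
    fit_auto,
    fit_augmented,
    fit_baseline,
    predict_quantiles,
)
from .months import as_index, format_month
from .panel import SurveillancePanel
from .quantiles import LEVELS, QuantileForecast

__all__ = [
    "CycleResult",
    "BacktestResult",
    "stitch",
    "run_cycle",
    "run_rolling",
    "audit_leakage",
    "HORIZON",
]

#: Forecast horizon in months (1..6 months ahead of the generation month).
HORIZON = 6

#: Stable family ordering used for seed-substream derivation.
FAMILY_SEED_ORDER = (
    "baseline",
    "auto",
    "calls",
    "ght",
    "calls_ght",
    "ets",
    "arima_search",
    "nnar",
    "ensemble",
)


def stitch(observed: pd.Series, hindcast: QuantileForecast) -> pd.Series:
    """Append hindcast point estimates to the observed series.

    The hindcast target months must exactly fill the gap immediately after
    the last observation: no gaps, no overlap.
    """
    observed = pd.Series(observed).astype(float)
    if len(hindcast) == 0:
        return observed
    start = int(observed.index[-1]) + 1
    expected = np.arange(start, start + len(hindcast))
    if not np.array_equal(hindcast.target_months, expected):
        raise ValueError(
            f"hindcast months {[format_month(m) for m in hindcast.target_months]} do not "
            f"contiguously follow the observations ending {format_month(observed.index[-1])}"
        )
    appended = pd.Series(hindcast.point_estimate, index=expected)
    return pd.concat([observed, appended])


@dataclass(frozen=True)
class CycleResult:
    """All outputs of one (jurisdiction, generation month, family) cycle."""

    jurisdiction: str
    generation_month: int
    family: str
    hindcast: QuantileForecast
    stitched_series: pd.Series
    forecast: QuantileForecast
    last_observed_month: int
    mortality_through: int  # last month of mortality actually used in training
    proxies_through: Optional[int]  # last proxy month used, None for unaugmented

    @property
    def hindcast_span(self) -> int:
        return self.generation_month - self.last_observed_month - 1

    def validate(self, panel_start: int) -> None:
        if len(self.forecast) != HORIZON:
            raise AssertionError("forecast must cover exactly 6 target months")
        if len(self.hindcast) != self.hindcast_span + 1:
            raise AssertionError("hindcast must cover exactly l + 1 target months")
        if len(self.stitched_series) != self.generation_month - panel_start + 1:
            raise AssertionError("stitched series must run from panel start through m")


def _seed_sequence(master_seed: int, jurisdiction_idx: int, m: int, family: str):
    fam_idx = FAMILY_SEED_ORDER.index(family) if family in FAMILY_SEED_ORDER else 99
    return np.random.SeedSequence(master_seed, spawn_key=(jurisdiction_idx, int(m), fam_idx))


def run_cycle(
    panel: SurveillancePanel,
    m,
    jurisdiction: str,
    spec: Union[ModelSpec, EnsembleSpec],
    calendar: ReleaseCalendar = ReleaseCalendar(),
    seed=None,
    jurisdiction_idx: int = 0,
    master_seed: Optional[int] = None,
    propagate_hindcast_uncertainty: bool = True,
) -> CycleResult:
    """Run one generation month for one jurisdiction and one model family.

    ``seed`` may be an int or :class:`numpy.random.SeedSequence`; if omitted
    and ``master_seed`` is given, the cycle's substream is derived from
    (master_seed, jurisdiction_idx, m, family).

    By default, forecast paths carry the hindcast's uncertainty about the
    unobserved current level: each forecast sample path is shifted by the
    terminal deviation of one hindcast sample path. Without this the
    forecast model — fitted on a stitched series whose recent months are
    smooth hindcast medians — treats the level at m as known and its
    intervals undercover badly. Set ``propagate_hindcast_uncertainty=False``
    for the minimal median-append pipeline.
    """
    m = as_index(m)
    view = mask_panel(panel, m, calendar)
    series = view.mortality(jurisdiction)
    k = view.last_observed_month
    hindcast_months = view.hindcast_months
    if seed is None:
        seed = _seed_sequence(master_seed or 0, jurisdiction_idx, m, spec.family)
    elif not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(int(seed))
    seed_h, seed_f = seed.spawn(2)

    family = spec.family
    proxies_through = None
    n_paths = spec.n_paths
    rng_h = np.random.default_rng(seed_h)

    if isinstance(spec, EnsembleSpec):
        hind_res = fit_auto(series, ModelSpec(family="auto", n_paths=n_paths))
        paths_h = hind_res.simulate_paths(hindcast_months, n_paths, rng_h)
    elif family == "baseline":
        hind_res = fit_baseline(series)
        if hind_res.degenerate:
            paths_h = np.tile(hind_res.point(len(hindcast_months)), (n_paths, 1))
        else:
            paths_h = hind_res.simulate_paths(len(hindcast_months), n_paths, rng_h)
    elif family == "auto":
        hind_res = fit_auto(series, spec)
        paths_h = hind_res.simulate_paths(hindcast_months, n_paths, rng_h)
    elif family in ("ets", "arima_search", "nnar"):
        # alternative forecasters share the primary hindcast model
        hind_res = fit_auto(series, ModelSpec(family="auto", n_paths=n_paths))
        paths_h = hind_res.simulate_paths(hindcast_months, n_paths, rng_h)
    else:
        exog = view.proxies(jurisdiction)
        proxies_through = int(exog.index.max())
        missing = [format_month(mm) for mm in hindcast_months if mm not in exog.index]
        if missing:
            raise ValueError(f"proxies missing hindcast target months: {missing}")
        hind_res = fit_augmented(series, exog, spec)
        paths_h = hind_res.simulate_paths(hindcast_months, n_paths, rng_h, exog=exog)
    hindcast = QuantileForecast.from_paths(paths_h, hindcast_months, "hindcast")

    stitched = stitch(series, hindcast)
    forecast_months = np.arange(m + 1, m + 1 + HORIZON)
    # deviation of each hindcast sample path from the median level the
    # forecast model was anchored on; carried into the forecast as a level
    # shift (exactly how anchor uncertainty enters an integrated model)
    if propagate_hindcast_uncertainty and len(hindcast):
        terminal_dev = paths_h[:, -1] - hindcast.point_estimate[-1]
    else:
        terminal_dev = np.zeros(n_paths)

    def finish(paths: np.ndarray) -> QuantileForecast:
        return QuantileForecast.from_paths(paths + terminal_dev[:, None], forecast_months)

    if isinstance(spec, EnsembleSpec):
        comp_seeds = seed_f.spawn(len(spec.components))
        comp_forecasts = []
        for comp, cseed in zip(spec.components, comp_seeds):
            fitted = fit_component(stitched, comp, seed=int(cseed.generate_state(1)[0] % 2**31))
            paths = fitted.simulate_paths(forecast_months, n_paths, np.random.default_rng(cseed))
            comp_forecasts.append(finish(paths))
        forecast = combine(comp_forecasts, spec.weight_vector())
    elif family == "baseline":
        fore_res = fit_baseline(stitched)
        if fore_res.degenerate:
            forecast = QuantileForecast.point_mass(fore_res.point(HORIZON), forecast_months)
        else:
            paths = fore_res.simulate_paths(HORIZON, n_paths, np.random.default_rng(seed_f))
            forecast = finish(paths)
    elif family in ("ets", "arima_search", "nnar"):
        fitted = fit_component(stitched, spec, seed=int(seed_f.generate_state(1)[0] % 2**31))
        paths = fitted.simulate_paths(forecast_months, n_paths, np.random.default_rng(seed_f))
        forecast = finish(paths)
    else:
        # forecast model identical in structure to auto, trained on the
        # stitched series; the proxies inform the forecast only through the
        # hindcast estimates
        fore_spec = ModelSpec(
            family="auto",
            arima_order=getattr(spec, "arima_order", (1, 1, 1)),
            fourier_K=getattr(spec, "fourier_K", 2),
            n_paths=n_paths,
            include_drift=getattr(spec, "include_drift", True),
        )
        fore_res = fit_auto(stitched, fore_spec)
        paths = fore_res.simulate_paths(forecast_months, n_paths, np.random.default_rng(seed_f))
        forecast = finish(paths)

    result = CycleResult(
        jurisdiction=jurisdiction,
        generation_month=m,
        family=family,
        hindcast=hindcast,
        stitched_series=stitched,
        forecast=forecast,
        last_observed_month=k,
        mortality_through=int(series.index.max()),
        proxies_through=proxies_through,
    )
    result.validate(panel.start_month)
    return result


@dataclass
class BacktestResult:
    """Collection of cycle results plus a record of skipped cycles."""

    cycles: List[CycleResult]
    failures: List[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.cycles)

    @property
    def families(self) -> list:
        return sorted({c.family for c in self.cycles})

    def quantile_frame(self, horizon_kind: str = "forecast") -> pd.DataFrame:
        """Long-format quantile table: one row per (cycle, target month, level)."""
        rows = []
        for c in self.cycles:
            qf = c.forecast if horizon_kind == "forecast" else c.hindcast
            for i, tm in enumerate(qf.target_months):
                for j, level in enumerate(LEVELS):
                    rows.append(
                        (
                            c.jurisdiction,
                            format_month(c.generation_month),
                            format_month(tm),
                            c.family,
                            level,
                            qf.values[i, j],
                        )
                    )
        return pd.DataFrame(
            rows,
            columns=["jurisdiction", "generation_month", "target_month", "family", "level", "value"],
        )


def run_rolling(
    panel: SurveillancePanel,
    start_cycle,
    end_cycle,
    specs: Sequence[Union[ModelSpec, EnsembleSpec]],
    calendar: ReleaseCalendar = ReleaseCalendar(),
    master_seed: int = 0,
    jurisdictions: Optional[Sequence[str]] = None,
    propagate_hindcast_uncertainty: bool = True,
) -> BacktestResult:
    """Run rolling monthly cycles over [start_cycle, end_cycle] inclusive.

    One :class:`CycleResult` per (jurisdiction, cycle month, family).
    Individual fit failures are recorded and skipped rather than aborting
    the run.
    """
    start_cycle, end_cycle = as_index(start_cycle), as_index(end_cycle)
    all_jurs = panel.jurisdictions
    jurs = list(jurisdictions) if jurisdictions is not None else all_jurs
    cycles: List[CycleResult] = []
    failures: List[dict] = []
    for m in range(start_cycle, end_cycle + 1):
        for jur in jurs:
            jidx = all_jurs.index(jur)
            for spec in specs:
                try:
                    cycles.append(
                        run_cycle(
                            panel,
                            m,
                            jur,
                            spec,
                            calendar=calendar,
                            jurisdiction_idx=jidx,
                            master_seed=master_seed,
                            propagate_hindcast_uncertainty=propagate_hindcast_uncertainty,
                        )
                    )
                except Exception as exc:  # recorded, not fatal
                    failures.append(
                        {
                            "jurisdiction": jur,
                            "generation_month": format_month(m),
                            "family": spec.family,
                            "error": f"{type(exc).__name__}: {exc}",
                        }
                    )
    return BacktestResult(cycles=cycles, failures=failures)


def audit_leakage(
    result: BacktestResult,
    panel: SurveillancePanel,
    calendar: ReleaseCalendar = ReleaseCalendar(),
) -> pd.DataFrame:
    """Independently recompute availability and audit every cycle for leaks.

    For each cycle, re-derives k from the release calendar and checks that
    (a) training mortality stopped at k, (b) hindcast targets are exactly
    the gap months, (c) the observed segment of the stitched series equals
    the panel truth through k (i.e. no hindcast month was replaced by a
    then-unreleased truth), and (d) proxies were not read beyond
    m - proxy_lag. Returns a per-cycle report; raises if any check fails.
    """
    from .availability import last_available_month

    rows = []
    for c in result.cycles:
        m = c.generation_month
        k_expected = last_available_month(m, calendar)
        checks = {
            "mortality_stops_at_k": c.mortality_through == k_expected,
            "hindcast_targets_fill_gap": np.array_equal(
                c.hindcast.target_months, np.arange(k_expected + 1, m + 1)
            ),
            "forecast_starts_after_m": int(c.forecast.target_months[0]) == m + 1
            and len(c.forecast) == HORIZON,
            "proxies_stop_at_limit": c.proxies_through is None
            or c.proxies_through <= m - calendar.proxy_lag,
        }
        truth = panel.mortality(c.jurisdiction)
        observed_part = c.stitched_series.loc[: k_expected]
        checks["stitched_observed_matches_truth"] = bool(
            np.allclose(observed_part.to_numpy(), truth.loc[: k_expected].to_numpy())
        )
        checks["stitched_gap_is_hindcast"] = bool(
            np.allclose(
                c.stitched_series.loc[k_expected + 1 :].to_numpy(), c.hindcast.point_estimate
            )
        )
        rows.append(
            {
                "jurisdiction": c.jurisdiction,
                "generation_month": format_month(m),
                "family": c.family,
                **checks,
            }
        )
    report = pd.DataFrame(rows)
    check_cols = [col for col in report.columns if col not in ("jurisdiction", "generation_month", "family")]
    bad = report[~report[check_cols].all(axis=1)]
    if len(bad):
        raise AssertionError(f"leakage audit failed for {len(bad)} cycles:\n{bad.head()}")
    return report
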