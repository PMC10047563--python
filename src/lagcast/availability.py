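"""Data-release calendar and real-time masking.

Official mortality data arrive in calendar-year batches: the full year Y is
released in December of Y+1 and becomes usable at the January generation
cycle of Y+2. At a generation month m this leaves a gap of l = m - k - 1
months between the last usable observation month k and the present, with
12 <= l <= 24 over an annual cycle (the realised maximum under the default
calendar is 23). Proxy streams (calls, searches) are assumed available
through the generation month itself, minus an optional fixed lag.

:func:`mask_panel` produces the view of the panel a forecaster would have
had at month m — mortality through k, proxies through m — which is the only
view the backtest pipeline is allowed to touch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .months import as_index, format_month, month_index, year_of
from .panel import SEARCH_COLUMNS, SurveillancePanel


class AvailabilityError(ValueError):
    """Requested month is outside what the calendar/panel can supply."""


@dataclass(frozen=True)
class ReleaseCalendar:
    """Annual-release rule plus optional per-year overrides.

    Parameters
    ----------
    proxy_lag
        Months of delay for call/search streams (0 = available through the
        generation month).
    usable_from
        Optional override mapping data-year -> first generation month
        (ISO or index) at which that year's mortality is usable. Years not
        listed follow the default rule: data-year Y usable from January of
        Y + 2 (released December Y + 1, picked up at the next cycle).
    """

    proxy_lag: int = 0
    usable_from: Optional[Dict[int, object]] = None

    def __post_init__(self):
        if self.proxy_lag < 0:
            raise ValueError("proxy_lag must be non-negative")
        if self.usable_from is not None:
            norm = {int(y): as_index(m) for y, m in self.usable_from.items()}
            for y, m in norm.items():
                if m <= month_index(y, 12):
                    raise ValueError(
                        f"usable_from for data-year {y} must fall after the "
                        f"release month (got {format_month(m)})"
                    )
            object.__setattr__(self, "usable_from", norm)

    def usable_from_month(self, data_year: int) -> int:
        """First generation month at which `data_year`'s mortality is usable."""
        if self.usable_from is not None and data_year in self.usable_from:
            return self.usable_from[data_year]
        return month_index(data_year + 2, 1)

    @classmethod
    def from_csv(cls, path, proxy_lag: int = 0) -> "ReleaseCalendar":
        """Load overrides from a CSV with columns data_year, usable_from_month."""
        df = pd.read_csv(path)
        table = {int(r.data_year): as_index(r.usable_from_month) for r in df.itertuples()}
        return cls(proxy_lag=proxy_lag, usable_from=table)


def last_available_month(m, calendar: ReleaseCalendar = ReleaseCalendar()) -> int:
    """Last usable mortality observation month k at generation month m.

    Under the default calendar, k = December of (year(m) - 2) for every
    generation month m of a calendar year.
    """
    m = as_index(m)
    years = [year_of(m) - 2, year_of(m) - 1, year_of(m)]
    if calendar.usable_from is not None:
        years = sorted(set(years) | set(calendar.usable_from))
    usable = [y for y in years if calendar.usable_from_month(y) <= m]
    if not usable:
        raise AvailabilityError(
            f"no mortality release is usable at generation month {format_month(m)}"
        )
    return month_index(max(usable), 12)


def hindcast_span(m, calendar: ReleaseCalendar = ReleaseCalendar()) -> int:
    """Hindcast span l = m - k - 1; the l + 1 hindcast targets are m-l .. m."""
    m = as_index(m)
    return m - last_available_month(m, calendar) - 1


@dataclass(frozen=True)
class AvailabilityView:
    """The panel as visible at one generation month.

    ``frame`` contains only months <= m; mortality_rate is NaN after k and
    proxy columns are NaN after m - proxy_lag.
    """

    generation_month: int
    last_observed_month: int
    frame: pd.DataFrame

    @property
    def hindcast_span(self) -> int:
        return self.generation_month - self.last_observed_month - 1

    @property
    def hindcast_months(self) -> np.ndarray:
        """Target months m-l .. m of the hindcast (the unobserved gap)."""
        return np.arange(self.last_observed_month + 1, self.generation_month + 1)

    def mortality(self, jurisdiction) -> pd.Series:
        """Observed mortality through k for one jurisdiction (no NaN rows)."""
        df = self.frame[self.frame["jurisdiction"] == jurisdiction]
        s = df.set_index("month")["mortality_rate"].sort_index()
        return s.dropna()

    def proxies(self, jurisdiction) -> pd.DataFrame:
        """Transformed proxies (log calls, logit searches) through m - proxy_lag."""
        from .panel import PROXY_COLUMNS, log_call_rate, logit_search_rate

        df = self.frame[self.frame["jurisdiction"] == jurisdiction].set_index("month").sort_index()
        df = df.dropna(subset=["call_rate"])
        out = pd.DataFrame(index=df.index)
        out["log_call_rate"] = log_call_rate(df["call_rate"].to_numpy())
        for col in SEARCH_COLUMNS:
            out[f"logit_{col}"] = logit_search_rate(df[col].to_numpy())
        return out


def mask_panel(
    panel: SurveillancePanel, m, calendar: ReleaseCalendar = ReleaseCalendar()
) -> AvailabilityView:
    """Restrict a panel to what was available at generation month m.

    Mortality is visible only through k = :func:`last_available_month`;
    proxies through m - proxy_lag; months after m are absent entirely.
    """
    m = as_index(m)
    k = last_available_month(m, calendar)
    if m > panel.end_month:
        missing = [format_month(mm) for mm in range(panel.end_month + 1, m + 1)]
        raise AvailabilityError(f"panel lacks months required at cycle {format_month(m)}: {missing}")
    if k < panel.start_month:
        raise AvailabilityError(
            f"panel starts {format_month(panel.start_month)}, after the last "
            f"usable observation {format_month(k)}"
        )
    df = panel.frame[panel.frame["month"] <= m].copy()
    df.loc[df["month"] > k, "mortality_rate"] = np.nan
    proxy_limit = m - calendar.proxy_lag
    proxy_cols = ["call_rate", *SEARCH_COLUMNS]
    df.loc[df["month"] > proxy_limit, proxy_cols] = np.nan
    return AvailabilityView(generation_month=m, last_observed_month=k, frame=df.reset_index(drop=True))
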