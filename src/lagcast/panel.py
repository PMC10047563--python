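"""Surveillance panel container and variable transforms.

A :class:`SurveillancePanel` is a rectangular (jurisdiction, month) grid of
monthly suicide mortality rates (deaths per 100,000), crisis-hotline call
rates (calls per 100,000) and six search-rate proportions, one per
suicide-related search term category. Mortality rates may legitimately be
zero in small jurisdictions; call rates are strictly positive and search
proportions strictly interior to (0, 1).

Transforms mirror the analysis conventions: call rates are log-transformed
and search proportions logit-transformed before entering any regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logit as _logit

from .months import as_index, format_month, parse_month

SEARCH_CATEGORIES = (
    "suicide_seeking",
    "suicide_prevention",
    "suicide_neutral",
    "mood_anxiety",
    "psychosis",
    "stressor_trauma",
)

SEARCH_COLUMNS = tuple(f"search_{c}" for c in SEARCH_CATEGORIES)

#: Column order of the eight surveillance streams, as used in the pooled
#: rank-correlation matrix.
STREAM_COLUMNS = ("mortality_rate", "call_rate") + SEARCH_COLUMNS

#: Clipping bound applied to externally supplied proportions before logit.
PROPORTION_EPS = 1e-6


def rate_from_counts(deaths, population):
    """Monthly rate per 100,000 population from event counts.

    Population is held constant within a calendar year when applied
    month-wise. Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any population is non-positive or any count negative.
    """
    deaths = np.asarray(deaths, dtype=float)
    population = np.asarray(population, dtype=float)
    if np.any(population <= 0):
        raise ValueError("population must be positive")
    if np.any(deaths < 0):
        raise ValueError("death counts must be non-negative")
    out = deaths / population * 100_000.0
    return float(out) if out.ndim == 0 else out


def log_call_rate(call_rate):
    """Natural log of a call rate per 100,000; the rate must be positive."""
    call_rate = np.asarray(call_rate, dtype=float)
    if np.any(call_rate <= 0):
        raise ValueError("call rate must be strictly positive for log transform")
    out = np.log(call_rate)
    return float(out) if out.ndim == 0 else out


def logit_search_rate(proportion):
    """log(p / (1 - p)) of a search proportion strictly inside (0, 1)."""
    proportion = np.asarray(proportion, dtype=float)
    if np.any(proportion <= 0) or np.any(proportion >= 1):
        raise ValueError("search proportion must lie strictly in (0, 1)")
    out = _logit(proportion)
    return float(out) if out.ndim == 0 else out


def clip_proportion(proportion, eps: float = PROPORTION_EPS):
    """Clip externally supplied proportions to [eps, 1 - eps] before logit.

    Generated panels always have interior proportions; this guards malformed
    external feeds only.
    """
    return np.clip(np.asarray(proportion, dtype=float), eps, 1.0 - eps)


@dataclass(frozen=True)
class SurveillancePanel:
    """Rectangular (jurisdiction, month) grid of surveillance streams.

    Wraps a DataFrame with columns ``jurisdiction``, ``month`` (integer month
    index), ``mortality_rate``, ``call_rate`` and ``search_<category>`` for the
    six term categories.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        self.validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "SurveillancePanel":
        df = frame.copy()
        if df["month"].dtype == object:
            df["month"] = df["month"].map(parse_month)
        df = df.sort_values(["jurisdiction", "month"], kind="stable").reset_index(drop=True)
        return cls(df)

    @classmethod
    def from_csv(cls, path) -> "SurveillancePanel":
        return cls.from_dataframe(pd.read_csv(path, dtype={"jurisdiction": str}))

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["month"] = out["month"].map(format_month)
        out.to_csv(path, index=False)

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        df = self.frame
        required = {"jurisdiction", "month", *STREAM_COLUMNS}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        months = np.sort(df["month"].unique())
        jurisdictions = df["jurisdiction"].unique()
        expected = len(months) * len(jurisdictions)
        if len(df) != expected:
            raise ValueError(
                f"panel is not a complete grid: {len(df)} rows, expected "
                f"{len(jurisdictions)} jurisdictions x {len(months)} months = {expected}"
            )
        if not np.array_equal(months, np.arange(months[0], months[-1] + 1)):
            raise ValueError("panel months are not contiguous")
        if df.duplicated(["jurisdiction", "month"]).any():
            raise ValueError("duplicate (jurisdiction, month) rows")
        if (df["mortality_rate"] < 0).any():
            raise ValueError("mortality_rate must be non-negative")
        if (df["call_rate"] <= 0).any():
            raise ValueError("call_rate must be strictly positive")
        for col in SEARCH_COLUMNS:
            vals = df[col]
            if (vals <= 0).any() or (vals >= 1).any():
                raise ValueError(f"{col} must lie strictly in (0, 1)")

    # -- accessors ------------------------------------------------------

    @property
    def jurisdictions(self) -> list:
        return sorted(self.frame["jurisdiction"].unique())

    @property
    def months(self) -> np.ndarray:
        return np.sort(self.frame["month"].unique())

    @property
    def start_month(self) -> int:
        return int(self.frame["month"].min())

    @property
    def end_month(self) -> int:
        return int(self.frame["month"].max())

    def __len__(self) -> int:
        return len(self.frame)

    def jurisdiction_frame(self, jurisdiction) -> pd.DataFrame:
        df = self.frame[self.frame["jurisdiction"] == jurisdiction]
        if df.empty:
            raise KeyError(f"unknown jurisdiction {jurisdiction!r}")
        return df.set_index("month").sort_index()

    def mortality(self, jurisdiction) -> pd.Series:
        """Observed mortality-rate series for one jurisdiction, indexed by month."""
        return self.jurisdiction_frame(jurisdiction)["mortality_rate"]

    def proxies(self, jurisdiction, transformed: bool = True) -> pd.DataFrame:
        """Proxy streams for one jurisdiction, optionally on the model scale.

        The model scale is log for call rates and logit for search
        proportions.
        """
        df = self.jurisdiction_frame(jurisdiction)[["call_rate", *SEARCH_COLUMNS]]
        if not transformed:
            return df
        out = pd.DataFrame(index=df.index)
        out["log_call_rate"] = log_call_rate(df["call_rate"].to_numpy())
        for col in SEARCH_COLUMNS:
            out[f"logit_{col}"] = logit_search_rate(df[col].to_numpy())
        return out


#: Transformed proxy column names, matching :meth:`SurveillancePanel.proxies`.
PROXY_COLUMNS = ("log_call_rate",) + tuple(f"logit_{c}" for c in SEARCH_COLUMNS)


def spearman_matrix(panel: SurveillancePanel):
    """Pooled pairwise Spearman correlations among the eight streams.

    Pools all (jurisdiction, month) rows, as in a panel-wide association
    summary. Returns ``(rho, pvalues)`` DataFrames indexed by stream column;
    a constant column yields NaN for its pairs (correlation undefined).
    """
    df = panel.frame[list(STREAM_COLUMNS)]
    if len(df) < 3:
        raise ValueError("need at least 3 rows for rank correlations")
    k = len(STREAM_COLUMNS)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    values = df.to_numpy()
    constant = [np.ptp(values[:, i]) == 0 for i in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            if constant[i] or constant[j]:
                rho[i, j] = rho[j, i] = np.nan
                pval[i, j] = pval[j, i] = np.nan
                continue
            r, p = stats.spearmanr(values[:, i], values[:, j])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    cols = list(STREAM_COLUMNS)
    return (
        pd.DataFrame(rho, index=cols, columns=cols),
        pd.DataFrame(pval, index=cols, columns=cols),
    )
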