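"""Scoring, model comparison and calibration assessment.

Point estimates are scored with mean absolute proportionate error (MAPE)
and probabilistic estimates with the quantile score (QS): the sum over the
23 levels of the two-sided pinball penalty

    QS_alpha = 2 alpha (y - q_alpha)          if y >= q_alpha
               2 (1 - alpha) (q_alpha - y)    otherwise.

Both are non-negative penalties: 0 means a perfect estimate. Pairs of
models are compared with the relative quantile score (RQS), the pairwise
normalised QS difference averaged over (jurisdiction, generation-month)
cells and scaled to [-100, 100] (negative = better than the reference), and
with the Wilcoxon signed-rank test. Calibration is assessed by per-level
empirical coverage of the truths against the estimated quantiles and
summarised by a Cramer-type distance (mean squared deviation from the
diagonal).

Score tables are plain DataFrames keyed by (family, jurisdiction,
generation_month, horizon_kind) with columns ``qs``, ``mape``,
``evaluable_horizons`` and ``zero_truth_months``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .months import format_month, parse_month, year_of, month_of
from .panel import SurveillancePanel
from .pipeline import BacktestResult
from .quantiles import LEVELS, QuantileForecast

__all__ = [
    "mape",
    "quantile_score",
    "score_backtest",
    "rqs",
    "wilcoxon_compare",
    "WilcoxonResult",
    "calibration_curve",
    "cramers_distance",
    "max_calibration_deviation",
    "collect_calibration_pairs",
    "summarize",
]


def mape(truth, point, return_detail: bool = False):
    """Mean absolute proportionate error over evaluable horizons.

    Months with zero truth are excluded from the average (the proportionate
    error is undefined there); the exclusion count is available via
    ``return_detail``. All-zero truth yields NaN with a warning.
    """
    truth = np.asarray(truth, dtype=float)
    point = np.asarray(point, dtype=float)
    if truth.shape != point.shape or truth.ndim != 1 or len(truth) < 1:
        raise ValueError("truth and point estimates must be equal-length 1-d arrays")
    nonzero = truth != 0
    n_excluded = int((~nonzero).sum())
    if not nonzero.any():
        warnings.warn("all truth values are zero; MAPE undefined")
        value = np.nan
    else:
        value = float(np.mean(np.abs(truth[nonzero] - point[nonzero]) / truth[nonzero]))
    return (value, n_excluded) if return_detail else value


def quantile_score(truth, quantiles, levels: np.ndarray = LEVELS):
    """Quantile score: sum over levels of the two-sided pinball penalty.

    Parameters
    ----------
    truth
        Scalar truth, or array of shape (n,) for per-month scoring.
    quantiles
        Quantile set of shape (23,), or (n, 23) matching the truths.

    Returns the per-month QS (scalar or array of shape (n,)).
    """
    q = np.asarray(quantiles, dtype=float)
    y = np.asarray(truth, dtype=float)
    if q.shape[-1] != len(levels):
        raise ValueError(f"quantile set must have {len(levels)} levels, got {q.shape[-1]}")
    yb = y[..., None]
    penalty = np.where(
        yb >= q,
        2.0 * levels * (yb - q),
        2.0 * (1.0 - levels) * (q - yb),
    )
    out = penalty.sum(axis=-1)
    return float(out) if out.ndim == 0 else out


def score_backtest(result: BacktestResult, panel: SurveillancePanel) -> pd.DataFrame:
    """Score every cycle of a backtest against the truth panel.

    Returns one row per (family, jurisdiction, generation month, horizon
    kind). Per-cycle QS and MAPE are means over the evaluable target months
    (those whose truth exists in the panel), so cycles truncated at the
    panel edge remain comparable; ``evaluable_horizons`` records how many
    months entered each score.
    """
    rows = []
    truth_cache = {}
    for c in result.cycles:
        if c.jurisdiction not in truth_cache:
            truth_cache[c.jurisdiction] = panel.mortality(c.jurisdiction)
        truth = truth_cache[c.jurisdiction]
        for kind, qf in (("hindcast", c.hindcast), ("forecast", c.forecast)):
            available = np.isin(qf.target_months, truth.index)
            n_eval = int(available.sum())
            if n_eval == 0:
                qs_val, mape_val, n_zero = np.nan, np.nan, 0
            else:
                y = truth.loc[qf.target_months[available]].to_numpy()
                qmat = qf.values[available]
                qs_val = float(np.mean(quantile_score(y, qmat)))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    mape_val, n_zero = mape(y, qf.point_estimate[available], return_detail=True)
            rows.append(
                {
                    "family": c.family,
                    "jurisdiction": c.jurisdiction,
                    "generation_month": c.generation_month,
                    "horizon_kind": kind,
                    "qs": qs_val,
                    "mape": mape_val,
                    "evaluable_horizons": n_eval,
                    "zero_truth_months": n_zero,
                }
            )
    return pd.DataFrame(rows)


def _aligned_scores(scores_a, scores_r) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(scores_a, pd.Series) and isinstance(scores_r, pd.Series):
        if not scores_a.index.equals(scores_r.index):
            if set(scores_a.index) != set(scores_r.index):
                raise ValueError("score tables have mismatched (jurisdiction, month) keys")
            scores_r = scores_r.loc[scores_a.index]
        return scores_a.to_numpy(dtype=float), scores_r.to_numpy(dtype=float)
    a = np.asarray(scores_a, dtype=float)
    r = np.asarray(scores_r, dtype=float)
    if a.shape != r.shape:
        raise ValueError("score arrays must have identical shapes")
    return a, r


def rqs(scores_a, scores_r) -> float:
    """Relative quantile score of model A against reference R.

    100 / N times the sum over (jurisdiction, generation-month) cells of
    (QS_A - QS_R) / (QS_A + QS_R). Bounded in [-100, 100]; negative means A
    improves on the reference. Cells where both models are perfect (both
    scores 0) are excluded from the mean — the ratio is defined only when
    at least one model is not perfect — with a warning recording the count.
    """
    a, r = _aligned_scores(scores_a, scores_r)
    if np.any(a < 0) or np.any(r < 0):
        raise ValueError("quantile scores must be non-negative")
    both_zero = (a == 0) & (r == 0)
    n_excluded = int(both_zero.sum())
    if n_excluded:
        warnings.warn(f"excluding {n_excluded} cells where both models score 0")
    a, r = a[~both_zero], r[~both_zero]
    if len(a) == 0:
        raise ValueError("no scorable cells: both models are perfect everywhere")
    return float(100.0 * np.mean((a - r) / (a + r)))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    pvalue: float
    n: int
    degenerate: bool = False


def _exact_signed_rank_pvalue(d: np.ndarray) -> float:
    """Two-sided exact sign-flip enumeration (handles ties in |d|)."""
    ranks = stats.rankdata(np.abs(d))
    n = len(d)
    w_obs = ranks[d > 0].sum()
    mean_w = ranks.sum() / 2.0
    count = 0
    total = 1 << n
    for mask in range(total):
        w = 0.0
        for i in range(n):
            if mask >> i & 1:
                w += ranks[i]
        if abs(w - mean_w) >= abs(w_obs - mean_w) - 1e-12:
            count += 1
    return count / total


def wilcoxon_compare(scores_a, scores_b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired model scores.

    Zero differences are dropped. Exact enumeration is used for n <= 25
    (falling back to an in-package sign-flip enumeration when ties in |d|
    prevent the standard exact distribution and n is small enough); the
    normal approximation with tie correction is used otherwise. All
    differences zero yields p = 1 with a degenerate flag.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired scores must have identical shapes")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonResult(statistic=0.0, pvalue=1.0, n=0, degenerate=True)
    if n < 5:
        raise ValueError(f"need at least 5 non-zero differences, got {n}")
    has_ties = len(np.unique(np.abs(d))) < n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if n <= 25 and not has_ties:
            res = stats.wilcoxon(d, method="exact", alternative="two-sided")
            return WilcoxonResult(float(res.statistic), float(res.pvalue), n)
        if n <= 16 and has_ties:
            ranks = stats.rankdata(np.abs(d))
            stat = float(ranks[d > 0].sum())
            return WilcoxonResult(stat, _exact_signed_rank_pvalue(d), n)
        res = stats.wilcoxon(d, method="approx", correction=False, alternative="two-sided")
    return WilcoxonResult(float(res.statistic), float(res.pvalue), n)


def calibration_curve(quantile_values, truths) -> np.ndarray:
    """Per-level empirical coverage of truths against quantile estimates.

    Parameters
    ----------
    quantile_values
        Array of shape (n_pairs, 23), one quantile set per truth.
    truths
        Array of shape (n_pairs,).

    Returns the fraction of truths at or below each level's quantile — a
    vector of 23 values in [0, 1] that lies on the diagonal (coverage ==
    level) for a perfectly calibrated forecaster.
    """
    q = np.atleast_2d(np.asarray(quantile_values, dtype=float))
    y = np.asarray(truths, dtype=float)
    if len(y) == 0:
        raise ValueError("empty forecast-truth collection")
    if q.shape != (len(y), len(LEVELS)):
        raise ValueError(f"expected quantile array of shape ({len(y)}, {len(LEVELS)})")
    return (y[:, None] <= q).mean(axis=0)


def cramers_distance(coverage) -> float:
    """Mean squared deviation between empirical coverage and nominal levels.

    Zero iff the coverage curve lies exactly on the diagonal.
    """
    coverage = np.asarray(coverage, dtype=float)
    if coverage.shape != LEVELS.shape:
        raise ValueError(f"coverage must have {len(LEVELS)} levels")
    return float(np.mean((coverage - LEVELS) ** 2))


def max_calibration_deviation(coverage) -> float:
    """Maximum absolute deviation from the diagonal (robust companion)."""
    coverage = np.asarray(coverage, dtype=float)
    return float(np.max(np.abs(coverage - LEVELS)))


def collect_calibration_pairs(
    result: BacktestResult,
    panel: SurveillancePanel,
    family: str,
    horizon_kind: str = "forecast",
) -> Tuple[np.ndarray, np.ndarray]:
    """Gather (quantile set, truth) pairs for one family across a backtest."""
    qrows, truths = [], []
    for c in result.cycles:
        if c.family != family:
            continue
        truth = panel.mortality(c.jurisdiction)
        qf = c.forecast if horizon_kind == "forecast" else c.hindcast
        available = np.isin(qf.target_months, truth.index)
        qrows.append(qf.values[available])
        truths.append(truth.loc[qf.target_months[available]].to_numpy())
    if not qrows:
        raise ValueError(f"no cycles for family {family!r}")
    return np.vstack(qrows), np.concatenate(truths)


def summarize(
    scores: pd.DataFrame,
    by: str = "overall",
    reference: Optional[str] = None,
    metric: str = "qs",
) -> pd.DataFrame:
    """Stratified score summaries, optionally with RQS against a reference.

    Parameters
    ----------
    scores
        A score table from :func:`score_backtest` (one horizon kind at a
        time is conventional; filter beforehand).
    by
        ``"jurisdiction"``, ``"year"``, ``"month"`` (calendar month of the
        generation cycle) or ``"overall"``.
    reference
        Family against which per-stratum RQS is computed for every other
        family (quantile scores only).
    """
    if scores.empty:
        raise ValueError("empty score table")
    df = scores.copy()
    if by == "jurisdiction":
        df["stratum"] = df["jurisdiction"]
    elif by == "year":
        df["stratum"] = df["generation_month"].map(year_of)
    elif by == "month":
        df["stratum"] = df["generation_month"].map(month_of)
    elif by == "overall":
        df["stratum"] = "overall"
    else:
        raise ValueError(f"unknown stratum key {by!r}; use jurisdiction|year|month|overall")

    def agg(group):
        vals = group[metric].dropna()
        q1, q3 = (np.percentile(vals, [25, 75]) if len(vals) else (np.nan, np.nan))
        return pd.Series(
            {
                "median": vals.median() if len(vals) else np.nan,
                "mean": vals.mean() if len(vals) else np.nan,
                "iqr": q3 - q1,
                "n": len(vals),
            }
        )

    out = (
        df.groupby(["family", "stratum"])[[metric]]
        .apply(agg)
        .reset_index()
    )
    if reference is not None:
        ref = df[df["family"] == reference]
        if ref.empty:
            raise ValueError(f"reference family {reference!r} not in score table")
        rqs_rows = []
        keys = ["jurisdiction", "generation_month", "horizon_kind"]
        for (family, stratum), group in df.groupby(["family", "stratum"]):
            if family == reference:
                rqs_rows.append((family, stratum, 0.0))
                continue
            merged = group.merge(ref, on=keys, suffixes=("_a", "_r"))
            merged = merged.dropna(subset=["qs_a", "qs_r"])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                value = rqs(merged["qs_a"].to_numpy(), merged["qs_r"].to_numpy())
            rqs_rows.append((family, stratum, value))
        rqs_df = pd.DataFrame(rqs_rows, columns=["family", "stratum", f"rqs_vs_{reference}"])
        out = out.merge(rqs_df, on=["family", "stratum"])
    return out


def pairwise_wilcoxon(
    scores: pd.DataFrame, metric: str = "qs", horizon_kind: str = "forecast"
) -> pd.DataFrame:
    """Wilcoxon signed-rank comparison for every pair of families."""
    df = scores[scores["horizon_kind"] == horizon_kind]
    keys = ["jurisdiction", "generation_month"]
    wide = df.pivot_table(index=keys, columns="family", values=metric)
    rows = []
    for fam_a, fam_b in combinations(sorted(wide.columns), 2):
        sub = wide[[fam_a, fam_b]].dropna()
        try:
            res = wilcoxon_compare(sub[fam_a].to_numpy(), sub[fam_b].to_numpy())
        except ValueError:  # too few informative pairs for the test
            res = WilcoxonResult(np.nan, np.nan, len(sub), degenerate=True)
        rows.append(
            {
                "family_a": fam_a,
                "family_b": fam_b,
                "statistic": res.statistic,
                "pvalue": res.pvalue,
                "n": res.n,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)
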