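"""Synthetic multi-jurisdiction surveillance panel generator.

Emulates the panel structure the backtest assumes: a rectangular grid of
jurisdictions by months carrying a monthly suicide mortality rate per
100,000, a crisis-call rate per 100,000 and six search-proportion streams,
with configurable trend, annual seasonality, serially correlated noise and a
target pooled Spearman correlation structure across the eight streams.

Rank correlations are induced with a Gaussian copula: the target Spearman
matrix ``rho`` is converted to a latent linear correlation matrix via
``r = 2 sin(pi * rho / 6)``, the mortality series is generated first from its
trend + seasonal + AR(1)-noise mean structure, and the seven proxy latents
are then drawn conditionally on the normal scores of the realised mortality
series. Because every proxy marginal is a monotone map of its latent, the
pooled Spearman correlations match the targets irrespective of the trend and
seasonal settings, and the proxy block keeps its own target correlations by
the conditional-Gaussian identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .months import as_index, month_of, month_range
from .panel import SEARCH_CATEGORIES, STREAM_COLUMNS, SurveillancePanel

__all__ = [
    "GeneratorConfig",
    "generate_panel",
    "default_spearman_targets",
    "spearman_to_pearson",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


def spearman_to_pearson(rho):
    """Latent Gaussian correlation reproducing a Spearman rank correlation.

    For bivariate Gaussian latents with linear correlation r, the Spearman
    correlation of any monotone marginals is (6/pi) * arcsin(r/2); this is
    the inverse map.
    """
    return 2.0 * np.sin(np.pi * np.asarray(rho, dtype=float) / 6.0)


def default_spearman_targets() -> np.ndarray:
    """Default 8x8 pooled Spearman targets among the surveillance streams.

    Mortality correlates weakly (|rho| < 0.15) with every proxy; calls
    correlate strongly with mood/anxiety and prevention searches; search
    categories are moderately inter-correlated, with mood/anxiety the hub.
    Stream order matches :data:`lagcast.panel.STREAM_COLUMNS`.
    """
    m = np.eye(8)

    def set_(i, j, v):
        m[i, j] = m[j, i] = v

    # mortality vs proxies: small positive
    set_(0, 1, 0.10)
    for j, v in zip(range(2, 8), (0.08, 0.06, 0.10, 0.08, 0.05, 0.06)):
        set_(0, j, v)
    # calls vs searches
    set_(1, 2, 0.15)
    set_(1, 3, 0.41)  # prevention
    set_(1, 4, 0.12)
    set_(1, 5, 0.40)  # mood/anxiety
    set_(1, 6, 0.15)
    set_(1, 7, 0.15)
    # search cross-correlations, mood/anxiety (index 5) the hub
    set_(2, 5, 0.23)
    set_(3, 5, 0.45)
    set_(5, 6, 0.30)
    set_(5, 7, 0.20)
    set_(4, 5, 0.15)
    for i, j in ((2, 3), (2, 4), (2, 6), (2, 7), (3, 4), (3, 6), (3, 7), (4, 6), (4, 7), (6, 7)):
        set_(i, j, 0.12)
    return m


#: Default base search proportions per term category (fraction of sessions).
DEFAULT_SEARCH_BASE = {
    "suicide_seeking": 2.0e-4,
    "suicide_prevention": 1.5e-4,
    "suicide_neutral": 3.0e-4,
    "mood_anxiety": 8.0e-4,
    "psychosis": 1.0e-4,
    "stressor_trauma": 2.5e-4,
}


@dataclass
class GeneratorConfig:
    """Study-condition parameters of the synthetic panel.

    Parameters
    ----------
    n_jurisdictions
        Number of jurisdictions (states); default 50.
    start_month, end_month
        Inclusive panel span, ISO strings or month indices. The default
        span Jan 2007 - Dec 2020 gives 168 months.
    base_rate
        Mean monthly mortality rate per 100,000 at the panel start
        (default 1.17, about 14 per 100,000 annually).
    trend_slope
        Per-month change in the mortality rate. A scalar applies to every
        jurisdiction; a (low, high) pair draws one slope per jurisdiction
        uniformly from that range. Default (0.0005, 0.003): a secular rise
        of roughly 5-30% of the base level over the 14-year span.
    seasonal_amplitude
        Peak-to-mean difference of the annual sinusoid (rate units). The
        default 0.12 (about 10% of the base level, comparable to the noise
        scale) makes seasonality a material part of the signal, as in the
        mortality series the backtest emulates.
    seasonal_peak_month
        Calendar month (1-12) of the seasonal peak; default 5 (late spring).
    noise_sd
        Marginal standard deviation of the residual anomaly, rate units.
    noise_ar
        AR(1) coefficient of the anomaly in time; anomalies in suicide
        mortality persist over a few months rather than resetting monthly.
    spearman_targets
        Symmetric 8x8 target rank-correlation matrix over the streams in
        :data:`lagcast.panel.STREAM_COLUMNS` order.
    populations
        Optional per-jurisdiction population counts (held constant over the
        panel); default drawn log-uniformly between 0.5M and 20M.
    count_mode
        If True, realise monthly death counts as Poisson draws with mean
        rate x population / 1e5 and recompute the rate from the counts,
        adding small-population discreteness.
    """

    n_jurisdictions: int = 50
    start_month: Union[int, str] = "2007-01"
    end_month: Union[int, str] = "2020-12"
    base_rate: float = 1.17
    trend_slope: Union[float, Sequence[float]] = (0.0005, 0.003)
    seasonal_amplitude: float = 0.12
    seasonal_peak_month: int = 5
    noise_sd: float = 0.12
    noise_ar: float = 0.5
    spearman_targets: np.ndarray = field(default_factory=default_spearman_targets)
    populations: Optional[Sequence[float]] = None
    count_mode: bool = False
    call_base_rate: float = 20.0
    call_log_sd: float = 0.30
    search_base: dict = field(default_factory=lambda: dict(DEFAULT_SEARCH_BASE))
    search_logit_sd: float = 0.25
    master_seed: int = 0

    def __post_init__(self):
        self.start_month = as_index(self.start_month)
        self.end_month = as_index(self.end_month)
        self.spearman_targets = np.asarray(self.spearman_targets, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.n_jurisdictions < 1:
            raise ConfigError("n_jurisdictions must be positive")
        if self.end_month < self.start_month:
            raise ConfigError("end_month before start_month")
        if self.base_rate <= 0:
            raise ConfigError("base_rate must be positive")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if not -1 < self.noise_ar < 1:
            raise ConfigError("noise_ar must lie in (-1, 1)")
        if not 1 <= self.seasonal_peak_month <= 12:
            raise ConfigError("seasonal_peak_month must be in 1..12")
        s = self.spearman_targets
        if s.shape != (8, 8):
            raise ConfigError("spearman_targets must be 8x8")
        if not np.allclose(s, s.T):
            raise ConfigError("spearman_targets must be symmetric")
        if not np.allclose(np.diag(s), 1.0):
            raise ConfigError("spearman_targets must have unit diagonal")
        off = s[~np.eye(8, dtype=bool)]
        if np.any(np.abs(off) >= 1):
            raise ConfigError("off-diagonal spearman_targets must lie in (-1, 1)")
        self._check_psd(spearman_to_pearson(s))
        if self.populations is not None:
            pops = np.asarray(self.populations, dtype=float)
            if len(pops) != self.n_jurisdictions:
                raise ConfigError("populations length must equal n_jurisdictions")
            if np.any(pops <= 0):
                raise ConfigError("populations must be positive")
        if set(self.search_base) != set(SEARCH_CATEGORIES):
            raise ConfigError("search_base must cover exactly the six term categories")

    @staticmethod
    def _check_psd(r: np.ndarray) -> None:
        eigmin = float(np.linalg.eigvalsh(r).min())
        if eigmin >= -1e-10:
            return
        # name the off-diagonal pair whose removal most restores PSD-ness
        best_pair, best_gain = None, -np.inf
        for i in range(8):
            for j in range(i + 1, 8):
                if r[i, j] == 0:
                    continue
                trial = r.copy()
                trial[i, j] = trial[j, i] = 0.0
                gain = float(np.linalg.eigvalsh(trial).min()) - eigmin
                if gain > best_gain:
                    best_gain, best_pair = gain, (i, j)
        names = STREAM_COLUMNS
        i, j = best_pair
        raise ConfigError(
            f"spearman_targets is not positive semidefinite after latent "
            f"conversion (min eigenvalue {eigmin:.3g}); the "
            f"{names[i]} <-> {names[j]} entry is the most implicated pair"
        )

    @property
    def n_months(self) -> int:
        return self.end_month - self.start_month + 1

    def slope_range(self):
        if np.isscalar(self.trend_slope):
            return float(self.trend_slope), float(self.trend_slope)
        lo, hi = self.trend_slope
        return float(lo), float(hi)


def _jurisdiction_label(j: int, n: int) -> str:
    width = max(2, len(str(n)))
    return f"S{j + 1:0{width}d}"


def _normal_scores(y: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(y, method="average")
    return stats.norm.ppf((ranks - 0.5) / len(y))


def generate_panel(config: GeneratorConfig) -> SurveillancePanel:
    """Generate a synthetic surveillance panel.

    Identical ``config`` (including ``master_seed``) yields a bit-identical
    panel. Each jurisdiction draws from its own seed substream derived from
    ``(master_seed, jurisdiction_index)``, so enlarging ``n_jurisdictions``
    never perturbs already-generated jurisdictions.
    """
    cfg = config
    T = cfg.n_months
    t = np.arange(T, dtype=float)
    cal_month = np.array([month_of(m) for m in month_range(cfg.start_month, cfg.end_month)])
    season = cfg.seasonal_amplitude * np.cos(2 * np.pi * (cal_month - cfg.seasonal_peak_month) / 12.0)

    r_latent = spearman_to_pearson(cfg.spearman_targets)
    r1 = r_latent[0, 1:]
    cond_cov = r_latent[1:, 1:] - np.outer(r1, r1)
    # guard tiny negative eigenvalues from the conversion
    cond_chol = np.linalg.cholesky(cond_cov + 1e-12 * np.eye(7))

    lo, hi = cfg.slope_range()
    cats = list(SEARCH_CATEGORIES)
    base_logits = np.array([logit(cfg.search_base[c]) for c in cats])

    frames = []
    for j in range(cfg.n_jurisdictions):
        rng = np.random.default_rng(np.random.SeedSequence(cfg.master_seed, spawn_key=(j,)))
        slope = rng.uniform(lo, hi)
        if cfg.populations is not None:
            pop = float(np.asarray(cfg.populations, dtype=float)[j])
        else:
            pop = float(np.exp(rng.uniform(np.log(5e5), np.log(2e7))))

        # AR(1) anomaly with unit marginal variance
        eps = rng.standard_normal(T)
        z = np.empty(T)
        z[0] = eps[0]
        phi = cfg.noise_ar
        scale = np.sqrt(1.0 - phi**2)
        for i in range(1, T):
            z[i] = phi * z[i - 1] + scale * eps[i]

        rate = np.clip(cfg.base_rate + slope * t + season + cfg.noise_sd * z, 0.0, None)
        if cfg.count_mode:
            deaths = rng.poisson(rate * pop / 1e5)
            rate = deaths / pop * 1e5

        ns = _normal_scores(rate)
        innov = rng.standard_normal((T, 7))
        latents = ns[:, None] * r1 + innov @ cond_chol.T

        frame = pd.DataFrame(
            {
                "jurisdiction": _jurisdiction_label(j, cfg.n_jurisdictions),
                "month": np.array(month_range(cfg.start_month, cfg.end_month), dtype=int),
                "mortality_rate": rate,
                "call_rate": np.exp(np.log(cfg.call_base_rate) + cfg.call_log_sd * latents[:, 0]),
            }
        )
        for ci, cat in enumerate(cats):
            frame[f"search_{cat}"] = expit(base_logits[ci] + cfg.search_logit_sd * latents[:, 1 + ci])
        frames.append(frame)

    return SurveillancePanel.from_dataframe(pd.concat(frames, ignore_index=True))
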