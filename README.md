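# lagcast

Probabilistic hindcast-then-forecast modelling of monthly jurisdiction-level
suicide mortality rates under realistic reporting delay.

## The problem

Official suicide mortality counts reach public-health analysts in
calendar-year batches, typically released in December of the following year.
At any generation month *m* the last usable observation is therefore 12–24
months old: if the last observed month is *k*, the gap spans
*l = m − k − 1* months. Timelier signals exist — crisis-hotline call volumes
and the frequency of suicide-related search queries are available
essentially in real time — but they are proxies, not measurements.

`lagcast` implements and evaluates a two-step procedure for this setting:

1. **Hindcast** the unreleased gap months *m−l … m* from the observed rate
   series, optionally augmented with transformed proxy covariates
   (log call rates; logit search proportions for six term categories).
2. **Stitch** the hindcast onto the observations and issue 6-month-ahead
   probabilistic **forecasts** from the stitched series.

Because the real surveillance feeds (vital-statistics mortality records,
hotline call logs, search-trends API) are access-restricted, the package
ships a first-class synthetic panel generator that emulates their joint
structure — trend, annual seasonality, serially correlated anomalies, and a
target Spearman correlation matrix across the eight streams — so the whole
pipeline is testable end to end without any restricted data.

## Models and scores

Let Y_k = (y_1, …, y_k) be the observed rate series. Five model families
are backtested:

- **baseline** — random walk with drift: ŷ_{k+j} = y_k + j·c with c the
  mean first difference;
- **auto** — dynamic harmonic regression: ARIMA(1,1,1) errors with drift
  and Fourier seasonal terms (period 12, K = 2 harmonic pairs) on the rate
  series alone;
- **calls**, **ght**, **calls_ght** — the auto structure plus exogenous
  proxy covariates (log call rate, the six logit search proportions, or
  both), with hindcasts conditioning on the proxies observed through *m*.

All estimates are emitted as quantile sets at the 23 levels
α ∈ {0.01, 0.025, 0.05, 0.1, 0.15, …, 0.95, 0.975, 0.99}, extracted from
simulated sample paths; the 0.5 level is the point estimate. Forecast paths
carry the hindcast's uncertainty about the current level (each forecast
path is shifted by the terminal deviation of a paired hindcast path).

Scoring uses the quantile (pinball) score

    QS_α = 2α(y − q_α)·1{y ≥ q_α} + 2(1−α)(q_α − y)·1{y < q_α},
    QS   = Σ_α QS_α,

MAPE for point estimates, the relative quantile score
RQS = (100/|s||m|) Σ_{s,m} (QS_A − QS_R)/(QS_A + QS_R) ∈ [−100, 100]
(negative = better than the reference) for pairwise model comparison,
Wilcoxon signed-rank tests, and per-level empirical coverage curves
summarised by a Cramér-type distance (mean squared deviation from the
diagonal). A multi-model ensemble (additive exponential smoothing,
AICc-searched ARIMA, neural autoregression) is combined by quantile
averaging.

Rolling-origin backtests advance monthly with an expanding training
window, re-masking the panel at every cycle so no model ever sees a value
that had not been released at its generation month; an independent audit
(`lagcast.audit_leakage`) re-derives the release calendar and verifies
this for every cycle.

## Worked example

```python
import numpy as np
import lagcast as lc

panel = lc.generate_panel(lc.GeneratorConfig(n_jurisdictions=2, master_seed=0))
cycle = lc.run_cycle(panel, "2012-01", "S01", lc.ModelSpec(family="calls"), seed=1)

scores = lc.score_backtest(lc.BacktestResult(cycles=[cycle]), panel)
row = scores[scores.horizon_kind == "forecast"].iloc[0]
print(f"QS={row.qs:.3f}  MAPE={row.mape:.3f}")
```

which prints (among other things):

```
last observed month : 2010-12
hindcast span l     : 12
hindcast months     : 2011-01 .. 2012-01
forecast months     : 2012-02 .. 2012-07
forecast median     : [1.396 1.446 1.484 1.49  1.477 1.442]
forecast QS=1.236  MAPE=0.060  evaluable horizons=6
```

Read this as: generating estimates at the end of January 2012, mortality
is observed only through December 2010 (a 13-month gap, *l* = 12), so the
model first hindcasts January 2011 – January 2012 using call rates
observed through January 2012, then forecasts February – July 2012. The
forecast medians are monthly rates per 100,000; the quantile score 1.236
is the pinball penalty summed over the 23 levels and averaged over the six
target months (0 would be a perfect forecast), and the point estimates are
off by 6% on average (MAPE 0.060).

A full run — generate, backtest over validation (2012–2019) and test
(2020) spans, score, summarise — is one call (or `lagcast run-all` from
the shell):

```python
from lagcast.config import RunConfig, run_all
manifest = run_all(RunConfig(out_dir="out", master_seed=0))
```

It writes the panel, per-cycle quantile tables, score tables, stratified
summaries, calibration curves, pairwise Wilcoxon comparisons and a JSON
manifest with the config hash and any skipped cycles.

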