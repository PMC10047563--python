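# Methods

## The two-step estimation procedure

At each generation month *m*, the release calendar determines the last
usable mortality observation *k* (under the default annual-release rule,
December of year(*m*) − 2, so the hindcast span *l = m − k − 1* cycles
through 12 … 23 within a calendar year and always satisfies the design
bound 12 ≤ *l* ≤ 24). The pipeline then:

1. fits the hindcast model on mortality rates observed through *k*
   (augmented families also condition on proxy covariates observed through
   *m*) and emits quantile hindcasts for the *l* + 1 gap months;
2. appends the hindcast medians to the observed series ("stitching");
3. fits the forecast model — always the plain trend + Fourier harmonic
   regression, or the persistence baseline for the baseline family — on
   the stitched series and emits quantile forecasts for *m*+1 … *m*+6.

All models operate on the raw rate scale (deaths per 100,000 per month).
Rates can legitimately be zero in small jurisdictions, so no log transform
is applied to the response; proxies enter as log call rates and logit
search proportions, the transformations under which their relationship to
the response is closest to linear.

### Model families

- **baseline**: random walk with drift. Drift = mean first difference;
  the *j*-step predictive law is Gaussian around last value + *j*·drift
  with variance *j*·σ², σ² estimated from residual first differences.
  A constant series yields zero residual variance and is flagged
  degenerate; its predictive law collapses to a point mass.
- **auto**: regression with ARIMA(1,1,1) errors and a drift term, with
  K = 2 Fourier harmonic pairs at period 12 as regressors (statsmodels'
  regression-with-ARIMA-errors). The order is a configuration field; on a
  failed fit the model falls back to (0,1,1) with a warning.
- **calls / ght / calls_ght**: the auto structure plus exogenous proxy
  columns. These are full dynamic regressions with proxy covariates (not
  regressions on the auto model's hindcast values — both readings are
  defensible; this one uses strictly more information and needs no second
  fitting stage). Constant or linearly dependent proxy columns are dropped
  with a warning, which also guarantees that an uninformative (constant)
  proxy reproduces auto's predictions exactly.

### Quantile extraction

Predictive distributions are represented by quantiles at the 23 levels
{0.01, 0.025, 0.05, 0.1, 0.15, …, 0.95, 0.975, 0.99}. Quantiles are
empirical quantiles of simulated sample paths (default 1000 paths; at
least 100 enforced), sorted within each target month to guarantee
monotonicity across levels and clipped at zero. Simulation rather than
analytic Gaussian intervals keeps every family — including the neural
autoregression — under one seedable mechanism.

### Propagation of hindcast uncertainty

The minimal reading of "forecast from the stitched series" treats the
hindcast medians as data. Measured on synthetic backtests, that pipeline's
nominal 95% forecast intervals covered only ~71% of truths: the stitched
tail is smooth, so the forecast model both underestimates its innovation
variance and treats the level at *m* as known. The default pipeline
therefore propagates hindcast uncertainty: forecast path *i* is shifted by
the terminal deviation of hindcast path *i* from the hindcast median — for
an integrated (d = 1) model, uncertainty about the anchor level enters
future months exactly as a level offset. With propagation, coverage of the
95% interval rises to ~93%. `propagate_hindcast_uncertainty=False`
restores the minimal median-append behaviour.

## Synthetic panel generator

The generator emulates the joint structure of the three surveillance
streams the analysis assumes; it is the package's study-condition
definition, not a tuning dial.

Per jurisdiction, the mortality rate is

    y_t = base + slope·t + A·cos(2π(month_t − peak)/12) + σ·z_t,   clipped at 0,

with z_t a unit-variance AR(1) anomaly. Defaults: base 1.17 per 100,000
per month (≈14 annually), slope drawn uniformly from
(0.0005, 0.003)/month (a 5–30% secular rise over the 14-year default
span), amplitude A = 0.12 (≈10% of the level — seasonality is a material
component of the signal, as in the mortality series being emulated), peak
in May, σ = 0.12 (the sampling scale of monthly counts in a mid-size
jurisdiction), AR coefficient φ = 0.5 (anomalies persist over a few
months; a half-life of ~1 month). The persistence value matters in both
directions: with white noise, proxies cannot inform forecasts at all,
while with very persistent anomalies (φ ≈ 0.7 was tried and rejected) the
d = 1 forecast extrapolates single-proxy inference noise and the calls
family degrades toward baseline. An optional count mode draws Poisson
death counts at rate × population / 10⁵ and recomputes rates, adding
small-population discreteness.

Cross-stream dependence uses a Gaussian copula. The target Spearman matrix
ρ (8 × 8 over mortality, calls and six search categories; defaults mirror
a weak mortality–proxy association |ρ| ≲ 0.15 with strong calls–search
and search–search hubs) is converted to latent correlations via
r = 2·sin(πρ/6). The seven proxy latents are drawn **conditionally on the
normal scores of the realised mortality series**, so pooled rank
correlations hit their targets regardless of the trend and seasonal
settings, and the proxy block keeps its own correlations by the
conditional-Gaussian identity (the conditional covariance R₂₂ − r₁r₁ᵀ
restores the marginal block exactly). Proxies are then monotone maps of
their latents: calls = exp(log 20 + 0.3·u), search proportions are
inverse-logits around category-specific base rates (10⁻⁴–10⁻³).

Seeding: one master seed spawns one substream per jurisdiction
(`SeedSequence(master_seed, spawn_key=(j,))`), so enlarging the panel
never perturbs existing jurisdictions, and identical configurations are
bit-identical.

What the generator does **not** emulate: secular drift in the proxy
streams (their marginals are stationary, keeping rank-correlation control
exact), cross-jurisdiction spillovers, demographic strata, reporting
artefacts, or any pandemic-era disruption. Consequently, passing tests
show that the pipeline extracts the kinds of structure the generator
encodes — trend, seasonality, persistent anomalies partially visible
through proxies — not that real surveillance feeds carry that structure.

## Backtest and scoring conventions

- Cycles advance monthly with an expanding window; every cycle re-masks
  the panel (mortality through *k*, proxies through *m* − proxy_lag) and
  an independent audit re-derives *k* from the calendar and checks every
  cycle's recorded training extents, hindcast window, and stitched values.
- Per-cycle QS is the pinball sum over the 23 levels per target month,
  averaged over the evaluable target months (those whose truth exists in
  the panel); the same averaging applies to MAPE. Averaging rather than
  summing keeps cycles truncated at the panel edge comparable; the number
  of evaluable horizons is recorded per cycle.
- MAPE months with zero truth are excluded from the average (the
  proportionate error is undefined), with the exclusion count reported;
  an all-zero cycle is flagged undefined.
- RQS excludes cells where both models score exactly zero (the normalised
  ratio is defined only when at least one model is imperfect), warns with
  the excluded count, and raises if nothing remains.
- Wilcoxon signed-rank comparisons drop zero differences; the exact
  distribution is used for n ≤ 25 without ties, an in-package sign-flip
  enumeration for small tied samples (n ≤ 16), and the tie-corrected
  normal approximation otherwise. No multiple-testing correction is
  applied across model pairs.
- Calibration curves report, per level, the fraction of truths at or below
  the level's quantile; the Cramér-type summary is the mean squared
  deviation from the diagonal over the 23 levels (max absolute deviation
  is reported alongside as a robust companion).

## Ensembles

Components: additive error/trend/seasonal exponential smoothing; an ARIMA
whose order is selected by corrected AIC over p, q ∈ {0..3}, d ∈ {0, 1},
drift optional; and a single-hidden-layer neural autoregression on 12 lags
(tanh, L-BFGS, 5 seeded restarts keeping the best in-sample fit) whose
forecast paths are generated recursively with bootstrapped residuals.
Combination is quantile averaging (Vincentization) with non-negative
weights summing to one: it is closed under the quantile representation,
preserves monotonicity, keeps the ensemble inside the componentwise
min–max envelope, and by convexity of the pinball loss in the quantile
argument guarantees the ensemble's QS never exceeds the worst
component's. The neural component is optional in full runs to keep the
rolling backtest light; the ensemble requires at least two components.

## Numerical choices and degenerate inputs

- Months are integers (year·12 + month − 1), displayed as ISO "YYYY-MM";
  all ranges inclusive. A December release becomes usable at the January
  cycle of the following month — this reproduces the worked availability
  example (a January 2012 cycle uses mortality through December 2010) and
  keeps *l* ≥ 12 at every cycle; the calendar's realised maximum is 23,
  and only the upper bound *l* ≤ 24 is asserted.
- Externally supplied search proportions are clipped to [10⁻⁶, 1 − 10⁻⁶]
  before logit; generated panels are always interior.
- Non-PSD Spearman targets are rejected at configuration time with the
  most implicated stream pair named (the off-diagonal entry whose removal
  most restores positive semidefiniteness).
- MLE fits are wrapped with a fallback order (0,1,1); noiseless series
  make the likelihood degenerate, so "exact" recovery tests assert
  optimizer precision (~10⁻³ on the rate scale), not machine precision.
- Seed discipline: every stochastic step draws from a substream keyed by
  (master seed, jurisdiction index, cycle month, family), so re-running
  any subset of a backtest reproduces the full run's values.

## Problem sizes used in the shipped checks

The test suite runs its heaviest scientific check — the directional skill
comparison — on a 5-jurisdiction, 24-cycle (2012–2013) backtest of all
five families with 500 sample paths, with proxies generated at pooled
Spearman 0.4 to mortality; coverage and calibration consistency use
10,000 forecast–truth pairs; parameter recovery uses 168-month series
across 6 jurisdictions. These sizes are the package's own scaled-down
study conditions, chosen to make the directional claims decidable while
keeping a full test run in minutes on one CPU.

## Known limitations

- The augmented families are dynamic regressions with contemporaneous
  proxy covariates; lagged or lead proxy structure is not searched.
- Hindcast-uncertainty propagation is first-order (a level shift); it
  ignores uncertainty in the forecast model's parameters induced by the
  smooth stitched tail, so intervals remain slightly narrow (~93% realised
  coverage at nominal 95%).
- The order-searching ensemble component refits up to ~70 candidate
  models per cycle; it is intended for focused runs, not the full
  50-jurisdiction grid.
- Release calendars are annual with optional per-year overrides;
  week-level or jurisdiction-specific schedules are out of scope.
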