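# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of the pipeline.

## The analysis protocol

The pipeline reproduces a standard land-based census analysis chain:

1. **Effort reconstruction.** A CART classifier (Gini impurity, default
   max depth 5, minimum leaf 5, cost-complexity pruning chosen by
   10-fold cross-validated accuracy over a quantile-subsampled pruning
   path) learns P(effort | weather) from the years with recorded effort
   metadata. Predictions are dichotomised at the cutoff maximising
   overall accuracy over candidate thresholds (midpoints of sorted
   unique leaf probabilities, plus 0 and just-above-max; ties resolve to
   the lower threshold, i.e. toward classifying effort). Youden's J is
   available as an alternative criterion. Days with recorded effort
   metadata use the recorded label directly; the classifier only
   resolves the legacy period. A blank-or-zero day classified as
   no-effort is removed; any day with a positive count is kept
   regardless of the prediction, since a sighting implies effort.
   Missing weather values are median-imputed with a warning. A
   rule-based labeller (visibility > 11.2 km, wind ≤ Beaufort 4, swell
   < 3 m) is provided for sanity checks only.

2. **Weekly NB2 trends.** Weeks are consecutive 7-day blocks from day 1
   of the species year; the 1–2 leftover days fold into week 52. Weeks
   with zero retained days are omitted, not zero-filled. Gray whale days
   with morning/evening survey pairs contribute the pair mean.
   Year and month are centred and scaled before polynomial expansion to
   tame the collinearity of raw polynomials; this changes no test
   statistic. The NB2 likelihood is maximised by BFGS with a
   Nelder–Mead fallback; a dispersion estimate at the Poisson boundary
   triggers a Poisson refit with a warning; non-convergence raises.
   Shape selection keeps the highest-order year term with a two-sided
   Wald P < 0.05, lower orders retained. Prediction intervals use the
   delta method on the linear predictor, back-transformed.

3. **Phenology.** Percentile days use the achieved-count rule: the
   smallest day whose cumulative count reaches p% of the annual total,
   with no interpolation. Timing is computed from daily counts (weekly
   aggregation exists for the count models only). The anomaly-year rule
   is a threshold: a species-year is excluded when its total falls below
   5% (configurable) of the cross-year median, generalising the ad hoc
   removal of a single collapsed year.

4. **Attribution.** Univariate screening fits each covariate at orders
   3 → 2 → 1 and forwards the first order whose top term has P < 0.05.
   Backward elimination demotes, per iteration, the covariate whose
   top-order term has the largest non-significant p — dropping one
   polynomial order at a time, so the hierarchy (no x² without x) holds
   at every step; ties break by covariate name. When the forwarded set
   approaches the sample size, it is thinned by screening p-value before
   elimination. After convergence, any design column with VIF ≥ 10
   removes the higher-p member of the offending pair and re-runs
   elimination; VIF is 1/(1−R²) from auxiliary OLS regressions, +∞ on
   perfect collinearity. The final AIC is compared against all
   single-covariate-deletion submodels and a flag records whether a more
   parsimonious model would be preferred. Margins predictions hold
   other covariates at sample means with t-based CIs at residual df.

5. **Forecast and validation.** A covariate is forecast-eligible when
   its raw data window closes before the species' minimum historical
   arrival day (minus a configurable lead, default 0): previous-year
   seasons close before day 1, current seasons at their last calendar
   day, annual and lagged-annual aggregates at day 365. The forecast
   model refits the eligible subset without re-elimination; when nothing
   is dropped it equals the full model (ratio 1). Year-removal
   validation refits the fixed retained-term set once per left-out year;
   the validation R² is the squared Pearson correlation between observed
   and out-of-sample predictions (a 1−SSE/SST "skill" variant is
   exposed, and is the right choice for null-behaviour checks, since
   leave-one-out predictions of pure noise anti-correlate with the
   observations and inflate the correlation-based statistic).

6. **Entanglements.** Monthly counts come from the weekly series by
   day-proportional apportionment of weeks straddling month boundaries.
   The combined model screens counts, arrival and departure through the
   same elimination machinery. Attribution between two retained
   predictors reports t² each and (t²_a/t²_b − 1)×100 rounded to the
   nearest integer; the comparison is scale-invariant. Species with
   fewer than 10 total entanglements (configurable) are not modelled.

## Synthetic study conditions

The generator defaults define the study the tests run:

* 24 years of daily counts for three species. Within-year curves are
  Gaussian intensities on the species-year axis — humpback (mean day
  250, SD 40), blue (230, 45), gray a 0.55/0.45 mixture at adjusted days
  230 and 290 (SDs 22, 18), matching a unimodal summer season for the
  rorquals and the two-pulse gray migration. Annual totals: 150
  (humpback, rising quadratically by ~×1.3 over the series), 141
  (blue), 600 (gray). Daily counts are NB2 via a gamma–Poisson mixture
  (α = 0.4–0.6). Arrival drifts −5 d/yr (humpback) and −4.3 d/yr
  (blue); gray timing is stationary. Gray whales get independent
  morning/evening draws whose mean is the analysis value.
* Monthly SOI/PDO/NPGO are stationary AR(1) with means/SDs matching the
  published long-term summaries of those indices (e.g. SOI −0.20 ± 1.85)
  and persistence φ = 0.6/0.85/0.9. Daily SST is an annual sinusoid
  (mean 12.49 °C, amplitude 1.6, warmest near day 250) plus a
  +0.013 °C/yr trend and AR(1) noise; SSS mirrors it around 33.40 PSU.
* The gridded SST field is monthly (the front index varies on monthly
  scales here; daily fields would multiply data volume for no tested
  behaviour): a planar front of random orientation and |N(0.03, 0.012)|
  °C/km strength plus cell noise on a 4-km grid out to ±20 km.
* Coastal wind is poleward (+2.5 m/s) before a per-year spring reversal
  day (N(100, 8)) and equatorward (−5.5 m/s) after, with 2 m/s noise;
  Ekman transport uses the bulk formula (ρ_air 1.22 kg/m³, C_d 1.3×10⁻³,
  ρ_sw 1025 kg/m³) at 38°N along a north–south coast. The spring
  transition is the day of the cumulative-transport minimum — a standard
  choice where the original buoy-based algorithm is not specified.
* Effort is Bernoulli(logistic(weather)) with steep coefficients, since
  the survey protocol is a hard threshold rule: effort is near-certain
  in good weather, near-impossible in heavy swell or fog, overall rate
  ~75%. Counts are blanked on no-effort days; the trailing 4 years carry
  effort metadata, reproducing the labelled/legacy split.
* Monthly entanglements are a linear-Gaussian function of monthly count
  (+0.03/whale) and arrival day (−0.04/day) with SD-1 noise, rounded and
  floored at 0 — a linear model because observed entanglement residuals
  behave normally, unlike the overdispersed sighting counts.

What the generator does **not** emulate: spatial structure (sighting
geometry, distance effects, gear density), observer heterogeneity,
within-year autocorrelation of counts beyond the seasonal curve, and any
coupling of counts to the environmental series. Passing tests therefore
demonstrate that the estimators recover the temporal structure they
assume, not that the real data meet those assumptions.

## Numerical choices and degenerate inputs

* Percentile rule ties: the smallest qualifying day wins; adding
  zero-count days or rescaling all counts never changes a timing metric.
* A species-year with no sightings yields an excluded timing record, not
  an error; an emptied attribution model is flagged not significant.
* Single-class effort labels yield a degenerate one-leaf tree with a
  warning; a monotone cumulative transport curve yields spring-transition
  day 1 with a warning; |latitude| < 1° is rejected (Coriolis ≈ 0).
* The timing-trend and screening p-values are two-sided t tests at
  residual df; NB trend tests are Wald z.
* Seasonal means error on missing member months, naming them; lags
  propagate missing leading months explicitly.

## Problem sizes

The recovery studies use 100 replicates of the 24-year study for timing
drift and NB trends, 100 six-year seeds for the effort filter and 50
three-year seeds for the spring transition; these sizes give stable
rates (binomial SE ≈ 3% at rate 0.9) while keeping a full run in minutes.

## Known limitations

* The stepwise protocol is reproduced as specified, including its known
  weaknesses (screening multiplicity, post-selection inference); no
  model averaging or shrinkage alternative is offered.
* With ~24 years and >60 candidate covariates, screening at 5% forwards
  noise covariates regularly; the elimination keeps final models
  all-significant but selection noise across replicates is expected and
  visible in the attribution outputs.
* The forecast-eligibility calendar treats availability as a fixed
  day-of-year per temporal scope; per-year data latencies are not
  modelled.
* The NB fitter requires ~10 observations per parameter and will refuse
  smaller problems rather than fit them badly.
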