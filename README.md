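# whaletrends

Effort-corrected sighting trends, migration phenology, environmental
attribution and entanglement-risk models for long-term land-based whale
counts — the kind of daily humpback, blue and gray whale census kept at a
fixed coastal observation point for decades.

The package is aimed at marine-mammal and fisheries-interaction
researchers who need to answer, from such a series: are local sightings
increasing, is the migration shifting, which ocean conditions drive the
shift, and does the shift change entanglement risk in fixed fishing gear?

## What it computes

**Effort reconstruction.** Legacy daily records store a count only when
whales were seen, so a blank day is ambiguous — a true zero or a
no-effort day (weather stopped the survey). Years with recorded effort
metadata train a classification tree (CART, Gini splits) of effort on
in-situ weather; its predicted effort probability, dichotomised at an
accuracy-optimal cutoff, labels the ambiguous days, and blank-or-zero
days classified as no-effort are removed as false zeros.

**Abundance trends.** Filtered daily counts are summed over 7-day blocks
of the species year with the number of on-effort days as exposure, and
weekly counts *y* are modelled as NB2 negative binomial
(Var = μ + αμ²) with log link:

    log μ = β₀ + poly(year) + poly(month) + log(effort days)

The trend shape is the highest-order year term significant at P < 0.05
(L/Q/C with the sign of the top coefficient).

**Phenology.** Arrival, peak and departure are the days of the species
year on which cumulative annual sightings first reach the 10th, 50th and
90th percentile of the annual total; residency = departure − arrival.
Gray whales run on an adjusted year starting June 1 so the southbound
pulse is not split across calendar years; blue whales lose
January–February, the gray-south dataset loses adjusted weeks 1–18, and
anomaly years with collapsed totals are excluded.

**Environmental attribution.** Per species-year covariates — SST, SSS,
an SST-gradient front intensity index at 5/10/15/20 km radii, an Ekman
upwelling index with its spring-transition day, and monthly SOI/PDO/NPGO
with 1–3 month lags — enter annual, seasonal and previous-season means.
Each covariate is screened with linear/quadratic/cubic terms; significant
ones feed a backward stepwise elimination that preserves the polynomial
hierarchy, checks collinearity (VIF < 10) and confirms parsimony by AIC.
The retained model yields margins-style partial predictions, a
forecast variant restricted to covariates observable before migration,
and leave-one-year-out validation.

**Entanglement risk.** Monthly confirmed entanglements are regressed
(OLS) on monthly whale counts and annual arrival/departure days;
predictor contributions are compared by squared t statistics
(variance explained ∝ t²).

A seeded synthetic-data module generates all inputs with known ground
truth — seasonal count curves with configurable timing drift and
abundance trend, NB overdispersion, weather-driven effort censoring,
AR(1) climate indices and count-coupled entanglements — so every stage
is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the pipeline over a synthetic
24-year study (they share a working directory, default
`results/pipeline/`):

```bash
python analysis/01_simulate.py --seed 2
python analysis/02_filter_effort.py --seed 2
python analysis/03_covariates.py --seed 2
python analysis/04_abundance_trends.py --seed 2
python analysis/05_phenology.py --seed 2
python analysis/06_timing_attribution.py --seed 2
python analysis/07_entanglement.py --seed 2
```

Step 02 prints the effort reconstruction quality on the labelled days:

```
optimal cutoff: 0.438
labelled-day accuracy: 0.946 (naive 0.5 threshold: 0.946)
confusion on labelled days: {'fn': 15, 'fp': 64, 'tn': 130, 'tp': 1252}
species-days removed as false zeros: 2608
```

Step 04 recovers the configured trend shapes — the generator gives
humpbacks a quadratic abundance increase and the gray datasets none:

```
blue         year-trend shape Q(+), dispersion alpha=0.56, AIC 3765
gray_north   year-trend shape NA, dispersion alpha=0.10, AIC 1928
gray_south   year-trend shape NA, AIC 8090
humpback     year-trend shape Q(+), dispersion alpha=0.81, AIC 4162
```

Step 05 recovers the configured timing drift (humpback arrival drifts
−5 d/yr in the generator; the fit returns −4.8 d/yr, labelled L(−)):

```
humpback     mean arrival day 141.3, residency 101.5 d; arrival trend L(-) (-4.8 d/yr), departure C(+)
gray_north   mean arrival day 266.9, residency  45.8 d; arrival trend L(+) (+0.2 d/yr), departure NA
```

and step 06 reports, per significant timing model, the full-model R²,
the forecast-to-full R² ratio and the year-removal validation R².

The same stages are available as a CLI (`whaletrends simulate … effort …
all`) with `--config`, `--seed`, `--outdir` and `--species` options.

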