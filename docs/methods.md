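# Methods

This note documents the models implemented in `thermoyield`, the parameter
choices that matter, what the synthetic generator does and does not emulate,
and the numerical decisions a user auditing results should know about.

## Thermal time

Daily growing degree days use max/min air temperature with the minimum
floored at the crop base temperature *before* averaging and the maximum
capped at 30 °C, and negative capped means contribute nothing:

    inc = max(0, (min(Tx, 30) + max(Tn, Tb)) / 2 − Tb)

Base temperatures are 5 °C (winter wheat, winter rapeseed) and 10 °C
(maize). Only `Tx` is capped; a (rare) `Tn` above 30 °C therefore produces
an increment slightly above `30 − Tb`, which the tests acknowledge.

Accumulation starts on 1 January of the harvest year for all crops. For
winter crops an autumn-sowing origin would also be defensible; 1 January is
the simpler, fully reproducible convention, it is configurable
(`GddParams.accumulation_origin`), and since every year is treated
identically the *relative* quantities the pipeline uses (envelopes,
anomalies, year-to-year differences) are unaffected by the choice.
Accumulation refuses to bridge missing days: thermal time across a gap is
undefined, and silently interpolating temperature would bias every
downstream milestone.

Predictors are read at eight milestone levels, 150–1200 °C·day in steps of
150. Observations are resampled to milestones by linear interpolation in
the GDD coordinate between the nearest non-missing observations; there is
no extrapolation — levels outside the observed range, or never attained in
a cold year, are missing. Interpolating in GDD rather than in calendar time
means a cloud gap is bridged along the crop's development axis.

## Condition indices

VCI and TCI scale the current value against the min–max envelope over the
reference years at the same unit and GDD level. Three edge rules:

- envelopes need at least two reference years at a level, otherwise the
  index is missing there (one year gives a zero-width, meaningless range);
- a degenerate envelope (max = min) yields a missing index, never a number;
- current-year values outside the envelope are clamped to [0, 100] — a
  record year is "best/worst observed", keeping Kogan's semantics.

Envelopes are built per unit *after* spatial aggregation (not per pixel).
Per-pixel envelopes before aggregation would be closer to "at a particular
location" but multiply memory by the pixel count for little benefit at the
unit-level modelling scale; the choice is isolated in
`build_predictor_matrix` and could be inverted without touching the index
math. Note the envelope uses the whole reference period even when those
same years are later cross-validated — matching the operational design this
mirrors — so the leakage guarantee of the forecasting loop (below) covers
scaling, pruning, selection, baselines and fitting, not the envelope
denominators.

## Spatial aggregation

Pixels with arable fraction strictly below 0.30 are screened out (exactly
0.30 survives; the rule is "less than 30 %"). Surviving pixels are weighted
by `arable_fraction × coverage_fraction`, normalised per unit. The
multiplicative form is the simplest rule that is monotone in both stated
requirements (more weight for more arable land, more weight for fuller
coverage). Cloud-missing pixels are handled by renormalising weights over
the non-missing subset rather than voiding the unit-day: daily optical gaps
are routine and the surviving pixels remain an unbiased sample under the
independent-cloud assumption the generator also uses. Pixel geometry is
half-open unit squares; coverage fractions are exact polygon–pixel
intersection areas (shapely).

## Crop-mask fusion

Two-orbit disagreements are resolved by: (1) higher classification
probability *and* higher presence prior wins; (2) a higher-probability crop
with the lower presence prior is kept only if `Δp > Δq`, strictly.
Tie conventions not covered by the two criteria (all deterministic):

- equal classification probabilities → the crop with higher presence;
- still tied → the first orbit's label;
- `Δp = Δq` exactly → the strict inequality fails, the second crop wins.

Unsown detection: a segment is reclassified to "no crops" when strictly
more than half of its non-missing images between 16 May and 30 June
(inclusive, configurable) have mean NDVI below 0.4. An exact tie keeps the
crop label (reclassification is the aggressive action; ties stay
conservative). Reclassification only ever moves labels *to* "no crops".

## The forecasting loop

Design matrix: one row per (unit, year); 13 variables × 8 levels + seasonal
maximum NDVI = 105 named columns. Instantaneous weather variables are read
on the day a milestone is first attained; the two accumulation columns sum
daily radiation/precipitation from 1 April to that day.

The target is the yield anomaly: observed yield minus the unit's mean over
the *training* years of the fold ("residuals"); predictions add the
baseline back and are floored at zero. The per-unit training mean is the
simplest baseline that cannot leak the held-out year.

Preprocessing inside every fold, in order: min-max scaling to [0, 1] with
training-rows bounds (held-out values clipped; constant columns dropped);
training-median imputation of missing cells (cold years leave high
milestones unattained — dropping those rows would discard most of an
already tiny sample); greedy correlation pruning at |r| > 0.75 (strictly
above; the most-correlated offending pair is located and its member with
the higher mean absolute correlation is removed — the `findCorrelation`
scheme); recursive feature elimination with gradient boosting.

Boosting hyperparameters are fixed: 100 rounds, depth 3, learning rate 0.1,
`hist` tree method with 64 bins (ample resolution for panels of a few
hundred rows), single thread, seeded. Feature importance for elimination is
**total gain**: average gain over-ranks a feature used once in a lucky
split, which destabilises elimination at these sample sizes. Elimination
removes all zero-gain features at once (they cannot influence the
deterministic fit), then the bottom 10 % of the remaining set per refit,
down to `k = min(5, n_years − 1)` features — aggressive shrinkage is
mandatory with ≤ 5 years of yields.

Cross-validation is leave-one-year-out: all rows of one year are held out
together and every preprocessing step above is recomputed from the rest.
With a single unit this is the classic per-region small-n design; the
default synthetic study pools units within a crop (unit level removed by
the per-unit baselines), because four training rows per fold cannot support
feature selection. An instrumented test asserts that no training-side call
ever sees the held-out year.

R² is reported as the squared Pearson correlation between pooled held-out
predictions and observations; the `1 − SSE/SST` variant is returned
alongside (`r2_sse`) since the two differ for biased predictions. MAPE
excludes zero observations with a warning.

## Anomaly products

Percent yield change is `100·(current/reference − 1)` — −20 % means the
year reached 80 % of the reference. References are the previous year or the
five-year mean (mean over what exists with a warning below five years;
missing below three). GDD differences are taken at fixed cutoff dates
(31 July for winter crops, 30 September for maize, configurable); note that
a leap year in the window shifts the cutoff accumulation by one day's
increment, which is real, not an artefact.

## The synthetic generator

What it emulates, with defaults chosen once as plausible for a continental
east-European grain belt:

- **Geometry**: a rectangular unit tiling with jittered (non-integer)
  boundaries over the pixel grid, so boundary pixels have fractional
  coverage; arable fractions uniform in [0, 1], spanning the 30 % screen.
- **Weather**: sinusoidal annual cycle (mean 9 °C, amplitude 12 °C, warmest
  ~day 201) + unit offset (sd 3 °C, a country-scale north–south spread) +
  year anomaly (sd 0.8 °C) + AR(1) daily noise (ρ 0.6, sd 2 °C); Tx/Tn
  straddle the mean by a random positive half-range, so Tx ≥ Tn always.
  Precipitation is a wet-day Bernoulli × Gamma; soil moisture layers are
  clipped AR(1) processes.
- **Vegetation**: NDVI is a double logistic in cumulative GDD with
  per-year peak amplitude (mean 0.78, sd 0.05) over a 0.15 background,
  plus observation noise sd 0.05 (realistic for daily 300 m optical data);
  LST is air temperature + 8 °C bare-soil offset − 10 °C × NDVI
  (evapotranspirative cooling) + noise. Cloud gaps are independent
  Bernoulli per unit-day, masking NDVI and LST together.
- **Yields**: unit baselines uniform in 30–90 dt/ha; yield = baseline +
  Σ coefficients × globally-scaled predictors + Gaussian noise, floored at
  zero. Default drivers: TCI at 600 °C·day (0.8) and 7–28 cm soil moisture
  at 300 °C·day (0.5) — mid-season thermal stress and early-season deep
  soil moisture, classic drought-limited-yield proxies whose generated
  correlation structure keeps them clear of the |r| > 0.75 pruning
  clusters, so named-driver recovery is a well-posed question.
- **Classification fixture**: two-orbit segment tables engineered to cover
  every branch of the overlap rule (agreement, both criteria in both
  directions, the exact `Δp = Δq` tie, equal-p ties, single orbit) with the
  expected label known by construction, plus configured unsown segments.

One root seed; per-unit sub-streams keep unit series reproducible when the
unit count changes.

What it does **not** emulate — and hence what passing tests do not show
about real data: spatially correlated cloud fields, sensor view-angle and
atmospheric-correction artefacts, mixed pixels at real field scale,
non-linear or threshold yield responses (heat-shock days, frost kill),
trends in management or varieties across years, and spatial correlation of
weather between neighbouring units. The recovery experiments demonstrate
the *pipeline* is unbiased and leakage-free under a known linear model;
they say nothing about how much variance real satellite predictors explain
in real yield statistics.

## Known limitations

- With 5-year panels, per-unit (non-pooled) fitting leaves 4 training rows
  per fold; the library allows it but selection is then essentially noise.
- The condition-index envelope is deliberately outside the leakage
  guarantee (see above).
- `R²` as squared correlation can flatter a biased forecaster; compare with
  `r2_sse` when absolute calibration matters.
- Unsown detection assumes at least one usable image in the late-spring
  window; a fully clouded window raises rather than guesses.
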