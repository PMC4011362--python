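# Methods

## Model and estimation

The package rests on the law of effective temperature: above a
developmental threshold *C*, physiological time accrues linearly with
thermal excess, so a stage completing in *D* days at constant *T* satisfies
D·(T − C) = K. The estimator regresses treatment temperature on mean
developmental rate, T = C + K·V, so the intercept and slope are directly
the threshold and the thermal constant. Two choices here are deliberate:

- **Treatment-mean fits.** The regression uses one point per
  constant-temperature treatment (the reciprocal of the mean duration over
  individuals completing the stage), not per-individual rates. This is the
  classical design in the rearing literature and gives n = number of
  treatments, so standard errors have n − 2 residual degrees of freedom
  (with five chambers, three).
- **Orientation.** Regressing T on V keeps the parameters directly
  interpretable and avoids the intercept bias that arises when noisy rates
  sit on the regressor side of a V-on-T fit and are then inverted.

Rates use the arithmetic mean of durations then reciprocal (not the mean
of reciprocals), consistent with reporting mean stage durations per
treatment. Individuals that died or entered developmental arrest are
excluded from duration means: an arrested larva carries no completion
time. Stages that never complete at a temperature (pupae at 18 °C) simply
drop that treatment from the stage's fit, so pre-pupal/pupal constants
rest on four chambers. Fits with K ≤ 0 are rejected as non-physical, and
with only two treatments the standard errors are reported as NaN rather
than zero.

Standard errors *Sc* and *Sk* are the ordinary OLS intercept/slope
standard errors. A caveat worth knowing: with five treatments the
residual degrees of freedom are three, so an interval of ±3 standard
errors has true coverage near 94% for the slope (the t₃ value), not the
99.7% a normal approximation suggests. The intercept does better in
practice because the rate errors grow with V, which inflates the residual
variance relative to the intercept's leverage. `analysis/02` reports
empirical coverage over 200 simulated replicates.

## Survival curve and optimum

Percent generation survival is fit as a cubic in temperature on the
21–30 °C range where the full life cycle completes; outside that range the
curve is not used. The optimum is the stationary point of the cubic with
negative second derivative strictly inside the range, solved from the
derivative quadratic in closed form. A cubic whose leading coefficient is
positive with the remaining coefficients of this curve's magnitudes has no
real stationary point at all; the dome-shaped convention (negative leading
coefficient) is therefore required of any curve passed to the
optimum-finder, and curves without an interior maximum raise an error
rather than returning an extrapolated value. Presentation rounding is
half-up to two decimals; all internal computation is full precision.

## Life table and trend index

Life tables start at 100 live eggs and propagate the cohort through the
ordered stage survival fractions (egg → larva → pre-pupa → pupa → adult
emergence). The index of population trend is the product of those
fractions times the female fraction times eggs per female — the per-egg
replacement rate, which the brute-force cohort walk reproduces to
floating-point accuracy (a tested invariant). Interpretive choices:

- Low-temperature developmental arrest (mature larvae failing to pupate)
  is mortality at the larva→pre-pupa transition for trend-index purposes;
  the arrested share can be carried as a separate reported column.
- Adult "survival" means emergence success from the pupa; adult longevity
  does not enter I.
- The default sex ratio is 0.5 (no temperature effect on sex ratio was
  detected in the rearing data the calibration mirrors).

## Phenology

Degree-days above a threshold are accumulated with cold days floored at
zero (no thermal debt). Monthly series contribute max(0, mean − C) times
the Gregorian month length (leap years respected) — plain sums of monthly
means would be ~30-fold too small to represent a year's heat budget.
Daily series yield a running trajectory; a stage transition is assigned to
the first day whose cumulative excess reaches the stage's K, with no
within-day interpolation, daily means being the finest input used. On a
constant series this makes the transition day exactly ⌈K/(T − C)⌉, a
tested oracle.

Forecasts enter the year at the pupal stage — spring adults emerge from
overwintered pupae — then cycle pupa → pre-oviposition adult → egg →
larva → pre-pupa per generation. Pupal completions are the per-generation
adult emergence peaks. If the series ends mid-cycle the forecast is
returned flagged incomplete rather than raising. Generations per year are
reported unfloored to two decimals; an integer floor is available
separately.

## Synthetic data

The generator emulates the rearing design: chambers at 18/21/24/27/30 °C,
90 individuals per treatment, stage durations K/(T − C) under
multiplicative lognormal noise (default CV 5%, mean exactly 1), stage-wise
Bernoulli survival, Bernoulli pre-pupal arrest of surviving mature larvae
(0.95 at 18 °C, 0.70 at 21 °C), and recording on a 1/3-day grid — three
development checks per day — rounded **up**, because a molt seen at a
check happened at some earlier unobserved instant. Setting
`observation_interval=None` disables the grid; the estimator-property
experiments (exact round-trip recovery, bias/coverage replicates) use the
continuous durations, since the recording grid is an observation-layer
effect distinct from the biological noise those experiments probe.

Calibrated truth values are the reference constants for this species: thresholds
11.03/9.04/15.08/11.79/11.63 °C and thermal constants
63.51/339.42/30.04/118.41/35.06 DD for egg/larva/pre-pupa/pupa/
pre-oviposition, and 10.84 °C / 574.08 DD for the whole generation.
Whole-generation durations are drawn from their own (C, K) law rather than
summed across stages: independently fitted generation constants are not
the sum of stage constants (the stage K's total 586.44 DD), and the
round-trip property requires recovering all six pairs exactly. Survival
probabilities anchor to the reported first-instar percentages
(20.56/50.48/62.49% at 18/21/30 °C, >95% at 24/27 °C) and the reported
fecundity pattern (345.15 eggs per female at 27 °C, ~17% lower at
21/24 °C, 12.5% lower at 30 °C, none at 18 °C where pupae fail); the
remaining per-stage values are calibration choices that reproduce the
qualitative pattern — 27 °C optimal, 18 °C non-replacing. Instar count
(5 vs 6) is temperature-dependent in the real insect but affects only
labels here, not total larval duration.

Synthetic weather is a sinusoid bottoming mid-January and peaking
mid-July plus Gaussian daily noise. The defaults (annual mean 13.5 °C,
amplitude 14.5 °C) give ≈ 2.2 × 10³ degree-days above 10.84 °C — a
warm-temperate North China Plain regime supporting close to four
generations. What the generator does **not** emulate: within-day
temperature cycles, autocorrelated weather, fluctuating-temperature
acceleration of development, photoperiod-driven diapause, food effects.
Passing tests therefore demonstrate the estimators and forecasters are
correct under the model's own assumptions, not that constant-temperature
constants transfer perfectly to field microclimates.

## Problem sizes and numerics

The test suite and drivers run the simulation at the rearing design's own scale
(5 × 90 individuals) and use 200 replicates for bias/coverage experiments,
100 random draws for the oracle-equivalence checks, and a 10⁻⁴ °C grid for
the optimum cross-check. Seeds are fixed throughout; the same seed
reproduces byte-identical simulated CSVs. Ceiling quantization is applied
with a 10⁻⁹ tolerance so durations already on the grid are not bumped a
step. Ties in trend-index ranking break toward the lower temperature.

## Known limitations

- Thresholds and constants come from constant-temperature rearing;
  field development under fluctuating temperatures is typically somewhat
  faster, so forecast peaks can run late (the overwintered-generation
  peak especially, as warm spells trigger early pupation).
- The linear rate law is only valid mid-range: it ignores the high-
  temperature falloff (this species suffers above ~33 °C), so
  extrapolation beyond the fitted 18–30 °C window is refused rather than
  modelled (no Briere/Lactin-type nonlinear alternatives).
- The cubic survival curve is an empirical smoother, not a mechanism; its
  optimum is only meaningful inside the fitted range.
- The trend index ignores adult longevity, density dependence and
  age-structured fecundity schedules (no lx·mx table, no intrinsic rate
  of increase).
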