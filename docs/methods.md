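# Methods

This note documents the models implemented in `odee`, the synthetic data
that stands in for the field inputs, the numerical choices made where the
design was genuinely open, and what the test suite does and does not
establish about real collar and isotope data.

## ODBA from raw counts

The two-second ODBA operator takes, per channel, the absolute difference
between the window mean and the window *midpoint*, scaled by the ADC
basis (2^14 counts per *g*), and sums over the three channels. "Midpoint"
admits two readings and both are implemented:

* `midpoint_mode="range"` (default): the midpoint of the sample range,
  (max + min)/2, computed within each window. This makes the statistic
  invariant to any per-channel constant offset — collar orientation and
  sensor bias drop out — which matches the metric's purpose of isolating
  dynamic acceleration.
* `midpoint_mode="fixed"`: a fixed sensor midpoint (default 0 for signed
  counts), for pipelines that calibrate the static component separately.

Windows are anchored at the first sample, non-overlapping, with the
trailing partial window dropped. Daily aggregation groups windows by
local calendar day by default; a noon-to-noon mode exists because the
animals are nocturnal and a midnight boundary splits every active night
across two "days" (for per-day *means* this matters little, which is why
midnight is an acceptable default). The first and last calendar days are
always discarded — release-day activity is depressed and the final day is
partly spent in a trap — and the deployment statistic ODBA_i is the
unweighted mean of the retained daily means. At least one retained day is
required, so deployments must span more than two calendar days.

Units are *g* throughout; no conversion to m s⁻².

## Doubly-labelled water

The single-pool model is used, appropriate for animals near or below
10 kg:

    rCO2 = (N / 2.078)(k_o − k_d) − 0.0062 k_d N.

`N` is taken as the **oxygen** dilution space N_o (the single-pool
convention); the deuterium space N_d enters only the quality-control
ratio N_d/N_o. Elimination rates come from two-point log-linear washout
between the plateau sample (3–3.5 h after dosing) and the recapture
sample; dilution spaces from the plateau method with per-isotope molar
masses of labelled water (20.015 g/mol for H₂¹⁸O, 19.017 for ²H-water).

Energy conversion defaults to 22.414 L/mol and 24.03 kJ/L CO₂ (an assumed
respiratory quotient of 0.8). The field study this design follows does
not print its conversion, so both constants are explicit configuration,
echoed into every run manifest.

Quality control mirrors field practice: a dosing is excluded when

* either isotope's final excess over background falls below a margin
  (default 2 ppm, twice the assumed analytical sd) — `below_background`;
* the dilution-space ratio N_d/N_o leaves [1.00, 1.10], or k_o ≤ k_d —
  `dosing_discrepancy` (the operationalisation of "improper dosing";
  the exact field rule is not published, so the window is configurable);
* N_o implies body water outside 40–80 % of body weight —
  `body_water_implausible`;
* recapture falls outside the 6–10-day validity window —
  `window_invalid`.

Exclusion is a data outcome, never an exception; excluded records carry
reason codes into the attrition report.

## Body condition

BCI = ln W / ln BL with W in kg and BL in **millimetres** (the recorded
precision; the unit is configuration because the log-ratio's absolute
value shifts with it, while residual-based conclusions do not). The
adjustment model is an additive smooth regression of BCI on s(age),
s(day-of-year) and sex, fitted with penalized cubic B-splines (basis size
10 per smooth) via statsmodels' generalized additive models. The penalty
weight is either fixed in configuration (the pipeline default, 50, keeps
runs fast and reproducible) or chosen by generalized cross-validation.
Season follows the trapping calendar — May = spring, September = summer,
November = autumn; other months map to the nearest trapping month with a
warning — and "next season" advances spring → summer → autumn →
next-year spring (there is no winter trapping). Individuals without a
next-season recapture yield missing values, not errors.

## Energetics models

Allometric scaling is fitted as ln(metric) ~ ln W × season — free
exponent *and* intercept per season — alongside the pooled single-exponent
fit. Per-season exponents and their standard errors are linear contrasts
of the interaction fit, so "per-season subsets vs interaction contrasts"
are numerically labelled: the contrast version is reported, and the
seasonal subsets are recoverable from the stored model objects.

Driver models regress a metric on covariate × season + sex where the
covariate is body weight **or** age, never both (they are collinear
within season). Selection is bidirectional stepwise AIC from the full
model, respecting marginality, with a post-hoc audit asserting that no
retained term's removal lowers AIC. Note the statistical character of
AIC selection: a truly null 1-df term is retained with probability
P(χ²₁ > 2) ≈ 16 % (somewhat more along a stepwise path), so "null terms
are dropped" holds at that rate, not near-certainly.

OD = ODBA_i / DEE_i, present only where both metrics exist, in g per
kJ/day (≈10⁻⁵ for these data; outputs that print OD rescale by 10⁴ for
readability, documented where they do). Group contrasts use Student's
t for means and a two-sided variance-ratio F test; fold-ranges (max/min)
describe spread. Repeated measures per individual are not modelled as
random effects (matching the plain-regression design this emulates); a
cluster-bootstrap SE helper is deliberately out of scope for the default
path.

## Survival surface

Annual survival is logistic in age, BCI_res, their interaction,
reproductive-female status and its interaction with BCI_res, plus
per-season intercept offsets when the records carry a season of
assessment. **The coefficients of the published long-term survival model
for this population are not available; this surface is a synthetic
stand-in** whose defaults (intercept 1.8, age −0.18, BCI_res 10,
age×BCI_res 2.5, repro +0.8, repro×BCI_res −5, autumn offset +0.3)
reproduce the qualitative structure the literature describes: survival
is much more condition-dependent in old animals, and reproductive
females' survival depends less on condition and sits higher at equal
condition. With the generator's condition scale (BCI_res sd 0.015) these
defaults place the survival cost of the observed OD range at roughly
5–10 percentage points for two-year-olds and 20–45 for nine-year-olds —
the order of magnitude reported for this system — but no claim of
coefficient-level fidelity is made.

`survival_delta` returns the probability difference between the high and
low predicted condition with a delta-method standard error on the
probability scale (gradient p(1−p)x per endpoint); season-offset
uncertainty is not propagated. `od_to_survival_cost` maps the min/max
*observed* OD through the fitted OD→BCI_res trendline — the trendline,
not individual points, so outliers are not projected — and tabulates
deltas per age, season and status, plus the reproductive-female "arrow"
(the survival lift relative to a non-reproductive animal at the same age
and condition).

## Synthetic data

The generator's role is to provide every input with known truth; its
defaults are the study conditions, chosen once:

* **Population**: ~200 individuals tracked 29 years; ages 0–14 with a
  geometric entry distribution; asymptotic growth plus mild senescent
  decline in weight; a two-harmonic annual weight cycle with its trough
  at the September trapping session and peak in November (animals are
  lightest in summer, heaviest in autumn); weights recorded to 0.1 kg and
  lengths to 5 mm. The individual-year condition residual z ~ N(0, 0.015)
  enters weight as W ∝ exp(z·ln BL), so the fitted BCI_res recovers z up
  to rounding noise. Annual survival is drawn from the truth surface at
  (age, z, reproductive status); ~35 % of adult females reproduce in a
  given year.
* **Traces**: exactly deployment_days × 86 400 × 25 samples per channel;
  per-deployment integer channel offsets (orientation); ±2-count uniform
  jitter; nocturnal activity bouts (10 per night of 1200 s between 21:00
  and 05:00) of rectified-sinusoid bursts aligned to the 2-s window grid.
  The rectified sinusoid is deliberate: a zero-mean sinusoid has window
  mean ≈ midpoint and thus ODBA ≈ 0 under this operator, while |sin| has
  the closed-form per-window value 3·a·(mean−midrange of the discrete
  template), exactly linear in amplitude a — so the generator can return
  the expected ODBA of the oscillatory component analytically. Integer
  rounding and jitter perturb the realised ODBA by well under 1 %.
* **Dosings**: k_d fixed at the configured water turnover (0.12/day) and
  k_o set by algebraic inversion of the single-pool equation, so the
  estimator recovers the generating rCO2 *exactly* when analytical noise
  is off; plateau enrichments follow from the dose and dilution spaces,
  final enrichments decay exponentially toward background; Gaussian
  analytical noise (default 1 ppm) on all four measured enrichments. The
  printed field dose-mass rule (0.65·W·DIE/IE) is implemented as its own
  operation; the simulator sizes doses from the exact plateau relation
  instead, because the rule of thumb is not an identity consistent with
  the plateau equation.
* **Energetics records**: DEE = α_s·W^β_s (defaults β = −0.14 / 0.90 /
  0.65 and α chosen so seasonal means sit near 3000–3500 kJ/day) with
  lognormal sd 0.12, plus a +350 kJ/day spring offset for reproductive
  females. The OD ratio is the latent trait — baseline 10⁻⁵, a summer
  age slope, a ×1.3 spring multiplier for reproductive females, lognormal
  sd 0.08 — and ODBA = OD × DEE. This makes activity and total
  expenditure share the DEE noise component: the reproductive-female OD
  contrast then has the small within-group spread that the reported
  spring variance decomposition implies. The trade-off is a positive
  ODBA–DEE correlation in the generated records, unlike the null
  covariation reported from the field; the covariation test's null
  calibration is therefore checked against an explicitly independent
  generator in the tests. Next-season BCI_res responds linearly to OD
  (slope −10⁴ per unit OD, noise sd 0.010, centred on the sample mean),
  giving an OD–condition R² near 0.5–0.7 at study scale.

What passing tests show — and do not. Recovery tests establish that the
estimators invert the generating processes at the stated tolerances and
sample sizes. They do not establish robustness to features the generator
omits: collar clock drift and dropped samples, behavioural (non-sinusoidal)
acceleration waveforms, isotope fractionation and two-pool physiology,
non-stationary weight cycles, density- or weather-dependent survival, or
capture heterogeneity.

## Problem sizes and tolerances

* Oracle equivalence uses 3-day deployments (the minimum retaining one
  day after edge trimming) so the deliberately naive per-window loop
  finishes quickly; equality is exact (no tolerance).
* Noise-free DLW round-trips assert relative error < 1e-9; noisy DLW
  bias < 1 % over 1000 replicates.
* Allometric CI calibration: 200 replicates at 40 records/season,
  coverage required in [90 %, 98 %]; noise-free recovery to 1e-10.
* Survival recovery: 100 replicates of 5000 badger-years; each
  coefficient's 2-SE interval must cover truth in ≥ 90 % of replicates
  (a per-coefficient calibration statement; joint coverage of six
  coefficients is necessarily lower).
* Closed-form compositions (survival deltas, cost tables on truth
  parameters) assert 1e-6. Fitted-versus-truth cost comparisons use a
  Monte-Carlo tolerance of four delta-method SEs plus a 0.02 allowance
  for trendline sampling error.
* Pipeline determinism: identical seeds must produce byte-identical
  manifests (file hashes included), modulo the output directory path.

## Known limitations

* The survival surface is a parametric stand-in, not a fitted published
  model; absolute survival costs depend on its configured coefficients.
* The GAM's smoothing penalty is fixed by default; GCV selection is
  available but slower and can choose different penalties across runs on
  different data.
* Elimination rates use two samples (dose-plateau and recapture); no
  multi-sample regression of washout curves.
* The day-boundary choice interacts with nocturnal activity when days
  are incomplete; only whole-day deployments are generated, so the
  default midnight boundary is unbiased here.
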