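# odee

Energy-budget analysis for bio-logged wild mammals: mechanical energy
expenditure from tri-axial accelerometry (**ODBA**), total daily energy
expenditure from doubly-labelled water (**DEE**), the activity-budget
ratio **OD = ODBA / DEE**, and the survival-probability cost of
high-activity energy budgets on an age × condition × reproductive-status
surface.

The package targets the study design used for European badgers
(*Meles meles*): collar deployments of 6–9 days with 25-Hz tri-axial
accelerometers, concurrent doubly-labelled-water dosings with a 6–10-day
recapture window, three trapping seasons per year (spring/May,
summer/September, autumn/November), and a multi-decade capture archive
that calibrates body condition and survival. Because no field accession
is available, a first-class synthetic-data module generates every input
with known ground truth, so each stage of the analysis has a
recovery-based test surface.

## The quantities

**ODBA** (in *g*). Per two-second window of a three-channel raw count
trace,

```
ODBA_2s = |A_x| + |A_y| + |A_z|,   A_c = (mean_c − midpoint_c) / 2^14,
```

with 2^14 counts per *g*. Two-second values are averaged per calendar day
(ODBA_d); the first and last deployment days are discarded; the retained
daily means average into the deployment statistic ODBA_i.

**DEE** (kJ/day). From the divergence of the 18O and 2H washout rates
`k = [ln(E0 − E_bg) − ln(Ef − E_bg)] / t` and the plateau dilution space
`N = dose_moles (IE − E0)/(E0 − E_bg)`, the single-pool model gives

```
rCO2 = (N / 2.078)(k_o − k_d) − 0.0062 k_d N      [mol/day]
DEE  = rCO2 × 22.414 L/mol × 24.03 kJ/L           (RQ 0.8, configurable)
```

Dosings are excluded when the final enrichment sits too close to
background, when the dilution-space ratio N_d/N_o leaves [1.00, 1.10]
(improper dosing), or when recapture falls outside the 6–10-day window.

**Condition and survival.** Body condition index BCI = ln W / ln BL is
adjusted against the long-term archive with an additive smooth model
`BCI ~ s(age) + s(day of year) + sex`; the residual BCI_res is regressed
on OD, and the fitted OD→BCI_res trendline is composed with a logistic
annual-survival surface
`logit P = b0 + b_a·age + (b_z + b_az·age)·BCI_res + repro terms` to
express the observed OD range as a survival-probability difference per
age and reproductive status.

## Worked example

```python
from odee import accelerometry, dlw, models
from odee.synthetic import (SimConfig, simulate_accel_trace,
                            simulate_dlw_experiment,
                            simulate_energetics_records)
from odee.survival import od_to_survival_cost

cfg = SimConfig(seed=42)

dep, truth = simulate_accel_trace(cfg, deployment_days=6)
series = accelerometry.compute_odba(dep)
# ODBA_i = 0.0286 g over 5 retained days (analytic truth 0.0286)

dosing, _ = simulate_dlw_experiment(5.6, 380.0, 8.0, cfg, noise_sd=0.0)
res = dlw.estimate_dee(dosing)
# k_o = 0.1522, k_d = 0.1200 /day, N_o = 380.0 mol, ratio 1.030
# rCO2 = 5.600 mol/day  ->  DEE = 3016 kJ/day (exactly the generating value)

rec, _ = simulate_energetics_records(cfg, n_per_season=5)   # 30 records
nxt = models.regress_od_on_next_bci(rec)
# OD -> next-season BCI_res: slope -7161, p = 0.0075, R² = 0.23, n = 30

table = od_to_survival_cost(
    (nxt.fits["od"].params[0], nxt.fits["od"].params[1]),
    cfg.survival_coefficients.surface(),
    (rec["od"].min(), rec["od"].max()),
    ages=[2.0, 9.0], seasons=["summer", "autumn"], statuses=[False],
)
# survival-probability cost of the observed OD range (percentage points):
#   summer age 2:  5.1     summer age 9: 17.8
#   autumn age 2:  4.2     autumn age 9: 16.7
```

The interpretation: a two-year-old badger at the condition predicted by
the highest observed OD ratio pays a few percentage points of annual
survival relative to the lowest; for a nine-year-old the same spread in
activity budgeting costs several times more, because survival becomes
more condition-dependent with age. Reproductive females sit above the
corresponding curve of a non-reproductive badger of equal age and
condition (the `repro_arrow` column).

## Command line

```
odee simulate  --seed 1 --out inputs/          # write synthetic input tables
odee odba      --in trace.csv --midpoint range --day-boundary midnight
odee dee       --in dosings.csv --energy-equiv 24.03
odee condition --captures captures.csv
odee fit-scaling --records records.csv --metric dee
odee od-analysis --records records.csv
odee survival-cost --annual annual.csv --od-fit odfit.json --ages 2,9
odee run-all   --seed 1 --out run/             # full orchestrated pipeline
```

`run-all` executes simulate → ODBA → DEE → condition → models →
survival-cost, writes every intermediate table, and emits a
`manifest.json` with input hashes, the config snapshot, and a per-stage
attrition report (deployed / recovered / retained with reason codes). The
pipeline is a pure function of (config, seed): identical manifests on
re-runs.

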