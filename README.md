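# u5logquad

Log-quadratic modelling of under-five age- and cause-specific mortality
(U5ACSM).

Global estimates of child mortality are usually reported for broad age
bands (neonatal, 1–59 months), yet causes of death such as pneumonia or
injury are sharply concentrated in particular parts of the first five
years of life. This package implements a model-life-table approach that
predicts the full fine-age schedule of cumulative death probabilities —
at 7 days, 28 days, and 6, 12, 24 and 60 months — from a single summary
input, the under-five mortality level, for all-cause as well as
cause-specific mortality. It is aimed at demographers and burden-of-
disease analysts who must disaggregate mortality by age when only
aggregate levels (and perhaps neonatal mortality) are observed.

## The model

For age cut point *x* and cause *c*, with ₓq₀ the cumulative probability
of dying from birth to age *x* and ₅q₀ the under-five mortality:

    ln(ₓq₀,c) = aₓ,c + bₓ,c · ln(₅q₀,c) + cₓ,c · ln(₅q₀,c)² + vₓ,c · k

* (aₓ, bₓ, cₓ) are fitted per age group by OLS across a reference
  collection of life tables (a log-linear variant drops the quadratic
  term);
* vₓ is the **age deviation vector** — the leading right singular vector
  of the matrix of log-scale residuals (unit Euclidean norm, youngest
  entry non-negative), describing how schedules at the same mortality
  level differ in age pattern;
* *k* is a per-life-table **shape parameter**: 0 gives the average
  pattern, and it can be calibrated in closed form so the predicted
  schedule matches an observed anchor age exactly (by default neonatal
  mortality, 0–27 days).

Predicted schedules are repaired to be non-decreasing in age (cumulative
probabilities cannot fall) and the 60-month entry is pinned to the input
₅q₀. The package also implements the conventional fallback used when no
age detail is available — a constant mortality hazard within 0–27 days
and within 1–59 months ("standard approach") — as the comparison
baseline, and validates the model by leave-one-stratum-out
cross-validation and a fully reproducible Monte-Carlo simulation study.
A synthetic surveillance-like data generator (six geography×urbanicity
strata × 20 years, three causes, known ground truth) makes every piece
testable without any external download.

## Worked example

```python
import warnings
from u5logquad import (default_truth, make_mchss_like, validate_set,
                       loso_crossval, fit_logquad, calibrate_k, predict_pattern)

lts, truth = make_mchss_like(default_truth(), seed=7)   # 360 records, 3 causes
print(len(lts), lts.causes)                             # 360 ['all', 'injury', 'pneumonia']
print(validate_set(lts).ok)                             # True

with warnings.catch_warnings():
    warnings.simplefilter("ignore")                     # zero-anchor fallbacks
    cv = loso_crossval(lts, cause="pneumonia", anchor_label="0-27d", degree=2)
for lab in lts.grid.labels:
    print(lab,
          round(100 * cv.pooled.mean_rel_error(lab, "logquad_k0"), 1),
          round(100 * cv.pooled.mean_rel_error(lab, "logquad_anchored"), 1),
          round(100 * cv.pooled.mean_rel_error(lab, "standard"), 1))
```

which prints the pooled mean relative cross-validation error (%) per age
group for the average-pattern (k = 0), anchored-k, and constant-hazard
methods:

```
   age     k0 % anchored % standard %
  0-6d     75.5       16.1      100.6
 0-27d     54.1        0.0        0.0
  0-5m     26.2        9.3       59.8
 0-11m     14.9        7.2       62.6
 0-23m      6.9        3.8       50.4
 0-59m      0.0        0.0        0.0
```

Reading the table: anchoring the shape parameter to each held-out
table's observed neonatal value reproduces 0–27 days exactly (0.0 by
construction, as is 0–59 months for every method, since the terminal
entry is pinned to the input ₅q₀), and cuts the error at the other ages
well below both the average pattern and the constant-hazard baseline —
e.g. 9.3% vs 59.8% at 0–5 months.

Predicting a single schedule at ₅q₀ = 3 per 1000 with the shape
calibrated to a neonatal value of 0.4 per 1000:

```python
fit = fit_logquad(lts, cause="pneumonia")
k = calibrate_k(fit, q5=0.003, anchor_label="0-27d", q_anchor=0.0004)
sched = predict_pattern(fit, 0.003, k=k)        # k = 0.697
# per 1000: {0-6d: 0.075, 0-27d: 0.4, 0-5m: 1.55, 0-11m: 2.359, 0-23m: 2.83, 0-59m: 3.0}
```

The same workflows are available from the shell:

```sh
u5logquad synth --seed 7 --out data.csv --truth-out truth.csv
u5logquad fit --input data.csv --cause pneumonia --out fit.json
u5logquad predict --fit fit.json --q5 3 --anchor-q 0.4 --units per1000 --out sched.csv
u5logquad crossval --input data.csv --cause pneumonia --out cv.csv
u5logquad simulate --fit fit.json --reps 100 --noise-scale 2 --seed 1 --out sim
```

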