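# Methods

## Model

The package models the cumulative probability of dying from birth to a
set of under-five age cut points (7 d, 28 d, 6 mo, 12 mo, 24 mo, 60 mo;
upper bounds are completed days/months) as a function of the under-five
mortality level. For age *x* and cause *c*,

    ln(ₓq₀,c) = aₓ,c + bₓ,c ln(₅q₀,c) + cₓ,c ln(₅q₀,c)² + vₓ,c k,

with a per-life-table shape scalar *k*. Working with cumulative
probabilities (rather than interval probabilities or rates) makes the
monotonicity constraint explicit and keeps the terminal entry identical
to the conditioning variable ₅q₀. Natural logarithms are used
throughout; the model is invariant to the base up to coefficient
rescaling. Each cause is treated as its own single-decrement schedule;
no competing-risk correction or reconciliation of cause-specific totals
to all-cause mortality is attempted.

## Estimation

1. **Per-age OLS.** For each age label, ln qₓ is regressed on
   {1, ln q₅} (degree 1) or {1, ln q₅, (ln q₅)²} (degree 2) over records
   with qₓ > 0 and q₅ > 0, via `numpy.linalg.lstsq` with a rank check.
   Zero cells are excluded rather than floored: ln 0 is undefined and
   any imputation floor would inject an arbitrary level into the age
   pattern.
2. **Age deviation vector.** The residual matrix (one row per
   complete-case record — all ages positive — one column per age) is
   decomposed by SVD; v is the first right singular vector, normalized
   to unit Euclidean norm with a non-negative entry at the youngest age
   carrying signal. The singular value is absorbed into k, so k values
   are comparable across fits. If the residual matrix is numerically
   zero (largest singular value ≤ 1e-10) or has fewer than two rows,
   v is the zero vector and shape calibration refuses explicitly.
3. **Per-record shape.** `training_k` is the projection of each
   complete-case residual row onto v (the inner product, for unit-norm
   v). `sigma` is the per-age SD of residuals net of the rank-1 v·k
   component (ddof = 1), the noise scale of the simulation study's
   error term.

Two estimator properties worth knowing:

* Over a realistic mortality range, ln q₅ and (ln q₅)² are strongly
  collinear and the intercept extrapolates to ln q₅ = 0, so individual
  coefficients have large sampling variance even when predictions
  inside the observed range are accurate. Coefficient-level claims
  should be read with this in mind.
* Because the rank-1 term is estimated, its removal also absorbs the
  component of independent noise lying along v; the reported `sigma` is
  therefore a *net* residual scale, mildly below the total noise at
  ages where v is concentrated. This is inherent to the two-stage
  estimator, not a defect of the implementation.

## Prediction, calibration, and repair

`predict_pattern` evaluates the model at a given (q₅, k), clips any
pathological value above 1 with a warning, repairs monotonicity, and
pins the terminal entry to q₅ exactly (q₅ is the model's own
conditioning variable). Repair is a right-to-left cumulative minimum:
each younger entry is capped at its elder neighbour's value, ties
allowed; it is idempotent and never increases an entry. Modified labels
are recorded on the schedule.

`calibrate_k` inverts the model at an anchor age (default 0–27 days):
k = (ln q_anchor − a − b ln q₅ − c (ln q₅)²) / v at the anchor. The
anchored prediction reproduces q_anchor exactly unless repair touches
the anchor label. A zero anchor deviation (v = 0) raises a calibration
error; a non-positive observed anchor (zero recorded neonatal deaths)
warns and falls back to the average pattern k = 0.

## Constant-hazard baseline

The comparison method assumes a constant daily hazard within 0–27 days
and a constant monthly hazard within 1–59 months, calibrated to the
observed neonatal and under-five probabilities; the 28-day boundary is
spliced as exactly one month. The monthly hazard is solved with
denominator (T − 1) months where T is the terminal cut point expressed
in months via the configured month length (30.4375 d/mo by default,
T ≈ 59.96 mo), so that q(60 mo) = q₅ holds as an exact identity rather
than only approximately; q(28 d) = q_neonatal is likewise pinned
against float residue. A linear-in-q interpolation variant is available
for sensitivity; at realistic magnitudes the two differ below reporting
precision. Hazard interpolation was chosen as the primary form because
"constant mortality rate" is a statement about hazards.

## Cross-validation

`loso_crossval` holds out one stratum at a time, fits on the rest, and
predicts every held-out record three ways: average pattern (k = 0),
anchored k (using the held-out record's own observed q₅ and anchor
probability — the intended use case where level and neonatal mortality
are known but age detail is not), and the constant-hazard baseline.
Errors are |q̂ − q| (absolute, reported ×1000 as deaths per 1000
livebirths) and |q̂ − q| / q (relative, reported as %), accumulated per
(age, method) cell. Observed-zero cells are excluded from the relative
metric and counted. Fold tables carry running sums, so the pooled table
is the cell-count-weighted aggregate exactly, and per-fold tables are
retained so an equal-fold-weight average can be recomputed. Two error
cells are structurally zero: the anchored method at the anchor age, and
every method at the terminal age.

## Simulation study

`simulate_dataset` draws q₅ ~ Uniform(2, 40 per 1000) and
k ~ Normal(0, 1) per table (or resamples the reference fit's training_k),
adds per-age Gaussian log-scale noise Normal(0, sigma × noise_scale),
exponentiates, repairs monotonicity, and pins the terminal entry.
`run_sim_study` refits each replicate and predicts hypothetical life
tables at scenario levels 1, 2 and 3 per 1000 with low/middle/high
shape (quartiles ±0.6745, 0 of the generating shape distribution),
anchoring k to the true neonatal value; per-age prediction errors and
coefficient errors |â−a|, |b̂−b|, |ĉ−c| plus the angular error of v̂
are aggregated over replicates. Noise scales 1× and 2× the reference
sigma probe the effect of measurement error. Scenario levels below the
simulated range are flagged as extrapolated; there, monotone repair can
occasionally cap the anchored prediction, so anchor exactness is only
guaranteed inside the range. RNG streams derive from
SeedSequence(root_seed, replicate_index), making every replicate
independently reproducible.

Study sizes used by the packaged checks: parameter recovery at 50
replicates and 60/120/480 tables; noise-dominance comparison at 100
paired replicates; both complete in seconds on a single core. Larger
runs (e.g. 1000 replicates, the config default) are a CLI flag away.

## Synthetic data generator

`synthdata` emulates the *shape* of a six-stratum (geography ×
urbanicity), twenty-year child-mortality surveillance collection — 120
strata-years per cause — for all-cause, a pneumonia-like and an
injury-like cause; it makes no attempt to match any real country's
levels or trends. Each cause's (a, b, c) are constructed as the parabola
through two anchor schedules (age-specific fractions of q₅ at a low and
a high mortality level) with a chosen log-scale midpoint bulge setting
the curvature; the terminal age is the identity (0, 1, 0) with
v = sigma = 0. Levels follow a declining geometric trend with stratum
multipliers and lognormal jitter; shape spread k_sd is per cause
(all-cause 0.3 — all-cause age patterns are comparatively stable;
pneumonia-like 1.0, matching the simulation's standard-normal shape
draw; injury-like 0.7). Zero-inflation masks a *prefix* of ages (a zero
cumulative probability at some age forces zeros at all younger ages),
emulating observed 0.0 cells in rare-cause data while keeping records
monotone. The generator returns the latent truth (per-record k, noise
draws, mask flags) alongside the observable collection, so recovery is
testable end to end.

The pneumonia-like curvature is deliberately pronounced: a design-stage
variance analysis of the per-age OLS (with the v·k term as effective
noise) shows that near-log-linear truths leave (a, b, c) individually
unidentifiable at a few hundred tables, while the chosen magnitudes make
coefficient-recovery error at 480 tables small relative to every
coefficient. The curvature is capped by pairwise monotonicity
constraints so the implied schedule is non-decreasing in age for every
q₅ in [0.001, 0.040].

What passing tests on these fixtures do **not** show: robustness to age
heaping, cause-of-death misclassification (verbal-autopsy error),
denominator drift between live births and true population at risk, or
non-stationary age patterns — all present in real surveillance data and
outside the generating mechanism.

## Numerical choices and degenerate inputs

* Probabilities are proportions internally; per-1000 is an I/O
  convention declared at read time (never sniffed).
* The redundant q5 column is cross-checked against the terminal age
  column at 1e-9 (float round-off scale for 6-significant-digit data).
* CSV reads use round-trip float parsing; write→read→write is
  bit-identical.
* Month length 30.4375 d/mo, configurable on the age grid.
* SVD zero threshold 1e-10 on the largest singular value; net-residual
  SDs at or below 1e-12 are clamped to 0 so exact constructions report
  sigma = 0.
* Degenerate cases are explicit: v = 0 fits refuse calibration, zero
  anchors fall back to k = 0 with a warning, all-zero sigma with
  positive noise scale warns, fewer than two complete-case records skip
  the SVD with v = 0.

## Limitations

Point predictions only — no uncertainty intervals. No joint constraint
tying cause-specific schedules to the all-cause total. Mortality rates
(ₓm₀) and interval probabilities are out of scope by design. The
stratum hold-out is the only cross-validation scheme implemented.
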