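# Methods

## Designs and coding

Factors are defined by (low, center, high) in actual units; coded levels
−1/0/+1 map exactly to those settings. Coding is **piecewise-affine** on
[low, center] and [center, high]: the center of a factor range need not be
the arithmetic midpoint, and the contract must not assume it. Decoding is
the exact inverse on [−1, 1]; values outside the range raise.

The Plackett–Burman generator returns the standard 12-run base built from
the cyclic first row `+ + − + + + − − − + −` plus a final all-minus run.
Real factors occupy the first k ≤ 11 columns; the remaining columns are
kept as **dummy columns** whose (null) effects estimate experimental
error. Optional center runs are appended and flagged; they are excluded
from effect estimation.

The Box–Behnken generator is fixed at 3 factors (the supported use case):
the 12 edge midpoints (±1, ±1 on each factor pair, third factor at 0)
plus n center replicates, default 5, giving the 17-run design whose
center replication supplies pure error.

## Screening effects and significance

Main effects use E(Xᵢ) = 2(ΣMᵢ₊ − ΣMᵢ₋)/N over non-center runs, which on
a balanced column equals the difference of level means and exactly twice
the OLS coefficient of the coded column (property-tested). Three error
estimates are offered for the Pareto ranking, none asserted as canonical:

- **Lenth** (default): s₀ = 1.5·median|effect| over all m contrast
  columns, PSE = 1.5·median of the |effects| below 2.5·s₀, reference t
  distribution with m/3 degrees of freedom. Chosen as default because it
  needs no replicates and is standard for saturated screening designs.
- **dummy-variance**: SE = √(mean of squared dummy effects), df = number
  of dummies.
- **center-replicates**: Var(effect) = 4s²/N from center-point pure
  variance s², df = n_center − 1.

When the error estimate is exactly zero, nonzero effects get the smallest
positive float as p-value rather than zero.

## Second-order surface

The model matrix is [1, xᵢ, xᵢ², xᵢxⱼ] (10 parameters at k = 3), fitted
by ordinary least squares (`numpy.linalg.lstsq`); a rank-deficient matrix
raises. ANOVA decomposes the residual into lack-of-fit and pure error
pooled over replicated design points; with five center replicates
df_pure = 4. Identical replicates give zero pure error and an explicitly
flagged undefined F rather than a division by zero. The lack-of-fit
p-value was cross-checked against numerical integration of the F density.

Canonical analysis solves ∇Y = 0 as the k×k system H x = −g with
H = 2·diag(bᵢᵢ) + off-diagonal bᵢⱼ, classifying the point by the Hessian
eigenvalue signs. "Inside region" uses |coordinate| ≤ 1 + 1e−9.

Because the stationary point of a quadratic fitted over a screening-scale
region frequently lies outside the coded cube (and here is a saddle), the
reported operating optimum is always the **constrained maximum over
[−1, 1]^k**, computed exactly: for every subset of coordinates fixed at
±1, the reduced stationary system on the free coordinates is solved and
interior solutions kept; all candidates (including the 2^k vertices) are
compared. This is exact for quadratics, needs no iteration, and agrees
with a 0.01-step grid oracle on random surfaces (tested). Both the
unconstrained stationary point (with its classification) and the
constrained optimum are reported.

`results_from_coefficients` analyses a published coefficient set without
raw data by generating noise-free responses on the design and refitting —
OLS interpolates exactly, so the refitted object carries the given
coefficients while supporting the full ANOVA/canonical machinery.

## Calibration and limits

Calibration is unweighted OLS of area on concentration (no weighting in
the method being emulated); 1/x and 1/x² weights exist as hooks but are
off by default. Reported: slope and intercept with t-based confidence
half-widths t₍α/2,n−2₎·SE, Pearson r, residual sd s_yx with df = n − 2,
and a replicate lack-of-fit F test. An intercept interval containing zero
sets a "crosses through the origin" flag.

Detection limits follow L = k·s_yx/b with k = 3 (LOD) and k = 10 (LOQ),
so LOQ/LOD = 10/3 identically and both are invariant to rescaling all
areas. On-column masses use conc (ng/mL) × injection volume (µL) = pg;
the assay's injection volume is 2 µL.

## Precision, accuracy, recovery, matrix effect

QC batches are day × replicate matrices. Intra-day statistics use one
day's replicates (n = 9 in the emulated protocol); inter-day pools all
days (n = 27, pooled mean rather than mean-of-day-means — the latter is
not distinguishable from the printed tables). RSD = 100·sd/mean with the
n−1 sd; accuracy = 100·mean/nominal.

Recovery and matrix effect come from three replicate peak-area sets per
QC level: R1 pure standard, R2 spiked post-extraction, R3 spiked before
extraction. Recovery = 100·R̄3/R̄2; matrix effect = 100·R̄2/R̄1;
classification is suppression below 85%, enhancement above 115%. The
per-analyte overall figure is the arithmetic mean ± sample sd (n−1) of
the three per-level percentages. Report tables round percentages
half-away-from-zero to the printed precision (integer for the recovery
table, two decimals for the QC table); unrounded values are always
retained.

## Noncompartmental analysis

- **Assembly.** Destructive sampling yields one group of animals per
  timepoint. Pseudo-subject assembly (default) stitches the i-th animal
  of every timepoint into the i-th profile — with n = 3 per timepoint
  this produces the n = 3 per-arm summaries of the emulated study design;
  it requires equal n at every time. Mean-profile assembly averages per
  timepoint and keeps the sd.
- **Cmax/Tmax** are the observed maximum and its earliest time.
- **λz** is the negative slope of log-concentration vs. time over the
  contiguous tail (≥ 3 positive points strictly after Tmax) with the
  largest adjusted R², ties going to the longer tail — the common
  "best fit" automatic rule; manual index selection is available. A
  non-declining tail raises.
- **AUC/AUMC** use the linear trapezoid on [0, 24 h] (log-down optional,
  applied only on strictly declining positive segments). A (0, 0) anchor
  is prepended when the first sample is after t = 0, as appropriate for
  oral dosing; profiles not reaching t_end raise — extrapolation to
  infinity is out of scope.
- **CL/F = dose_mg / AUC₀₋₂₄** and **V/F = CL/F / λz**, keeping the
  report-table unit convention (mg)/(ng/mL)/h and (mg)/(ng/mL) verbatim
  (dimensionally 10⁶ mL but kept as printed). Dose in mg is
  mg/kg × body weight, defaulting to 0.225 kg (midpoint of the 200–250 g
  animals); absolute CL/V therefore depend on an assumed weight and are
  not treated as reproducible quantities.
- **BLQ**: optionally, values below the LOQ are set to 0 before Tmax and
  dropped after Tmax.
- **Arm comparison** is a two-sided t-test, Welch by default (the
  emulated analysis names only "a t-test"), pooled optional, accepting
  raw values or (mean, sd, n) summaries so printed tables can be
  compared. Degenerate equal groups return t = 0, p = 1.

## Synthetic data

The generators emulate the study's data-generating processes with known
truth, all bit-reproducible for a fixed seed (`numpy.random.default_rng`):

- **Surfaces**: quadratic polynomial at the coded design points plus
  additive N(0, σ) noise — peak-area noise at fixed settings is
  approximately additive over a narrow response range.
- **Assay areas**: intercept + slope·level with either constant-sd or
  proportional-CV Gaussian noise; R1/R2/R3 expectations scale by the
  matrix factor µ and recovery ρ (E[R2] = µE[R1], E[R3] = ρµE[R1]).
- **PK**: one-compartment first-order absorption (Bateman),
  C(t) = D·ka/(V/F·(ka−ke))·(e^(−ke·t) − e^(−ka·t)), sampled at the
  17-point grid (5 min – 24 h) with 3 animals per timepoint (51 records);
  per-animal multiplicative error exp(η), η ~ N(0, log(1+CV²)), because
  concentrations are positive and bioanalytical CVs are roughly constant.
  ka = ke is rejected rather than implementing the degenerate t·e^(−kt)
  limit. Defaults (ka = 1.5/h, ke = ln2/3 /h, V/F = 0.3 (mg)/(ng/mL),
  dose 15.525 mg = 69 mg/kg × 0.225 kg, CV 10%) echo the order of
  magnitude of the emulated hesperidin arm; they are modeling choices,
  not assertions about the real animals.

What passing tests show — and do not. The generators capture design
geometry, noise scale and the destructive-sampling structure; they do not
model absorption-phase nonlinearity, enterohepatic recirculation,
correlated within-animal error (each pseudo-subject is an artificial
stitch of unrelated animals), or chromatographic drift. Recovery of truth
here validates the estimators' arithmetic and selection rules, not the
biological fidelity of a one-compartment model.

## Problem sizes in the test suite

Monte-Carlo checks use 200–500 seeded replicates (coverage of calibration
CIs, screening power, coefficient recovery, end-to-end PK recovery) and
100 random surfaces against the 0.01-grid optimum oracle; these sizes
give stable pass/fail margins for the asserted rates while keeping the
whole suite fast on a single CPU.

## Known limitations

- Raw instrument responses and individual-animal concentrations of the
  emulated study are not published, so its fitted coefficients, R²adj,
  calibration table and absolute PK values cannot be re-derived from
  data; the package instead verifies those pipelines on synthetic truth
  and reproduces the derived, printed quantities.
- The Box–Behnken generator is fixed at 3 factors; central-composite and
  D-optimal designs, multi-response desirability optimization, AUC
  extrapolation to infinity and compartmental fitting are out of scope.
- A Welch or pooled t-test on the printed AUC₀₋₂₄ summaries (n = 3) does
  not reach p < 0.05 for hesperidin despite the emulated study's
  significance claim; the comparison functions are provided, but that
  claim is not asserted anywhere in the tests.
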