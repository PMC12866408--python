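# Methods

This note documents the models, numerical choices and known limitations of
`petquant`, in the spirit of a model-documentation page for a simulation or
statistics package. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Acquisition model

All analyses operate on frame-averaged regional concentrations over an
ordered, contiguous schedule of half-open frames `[start, start+Δt)` in
minutes. The standard schedule (`make_standard_frame_schedule`) is the
120-min dynamic mouse acquisition with 45 frames of increasing duration
(12×10 s, 3×20 s, 3×30 s, 3×60 s, 3×150 s, 21×300 s). Frame midpoints serve
as the Logan abscissa; model curves are always averaged over the full frame
interval, not sampled at midpoints.

Activities are decay-corrected to injection time, the standard convention
for reconstructed PET frames; the ¹⁸F half-life (109.8 min) is stored as a
constant (`core.F18_HALF_LIFE_MIN`) but enters no default computation.

## Input function

The synthetic whole-blood curve is a delayed tri-exponential bolus
(`InputModelParams`): a linear-rise peak term `A1 t' e^(−λ1 t')` plus two
washout exponentials, continuous at the bolus-arrival delay and closed-form
integrable. Defaults (delay 0.25 min; A1 = 60 min⁻¹, A2 = 1.2, A3 = 0.35;
λ = 3.5, 0.35, 0.012 min⁻¹ on a normalized SUV-like concentration scale)
give a peak within the first minute and a terminal blood clearance
half-life of ~58 min, typical of a small-molecule CNS radioligand in mice.
The terminal rate matters: Logan behaviour under truncation depends on the
relation between input clearance and the slowest tissue eigenvalue, so it
is a study condition, not a free dial.

Metabolite correction is multiplicative and pointwise:
`C_p,parent = C_wb · (r0 + r1 t) · f(t)`. The plasma-to-whole-blood ratio is
an OLS line through measured ratios (default r0 = 1.10, r1 = 0.0015/min);
the intact-parent fraction is a biexponential, by default constrained to
f(0) = 1 because the injectate is radiochemically pure parent, and
calibrated so that f(90 min) = 0.799. Parent-fraction fits use uniform
weights unless inverse-variance weights are supplied; an optional
extraction-efficiency pre-division of measured fractions is available but
off by default. Whole-blood curves sampled at frame resolution are resampled
onto the uniform analysis grid by piecewise-linear interpolation anchored at
(0, 0) — at a 0.05-min grid step, higher-order schemes change nothing
downstream.

Blood-sample fitting pools all animals into one parent-fraction and one
ratio model (per-group fitting is available by refitting on a subset table);
the biexponential optimization runs from a small deterministic grid of rate
starting pairs to dodge the local minima typical of sums of exponentials,
with components stored in canonical order μ1 ≤ μ2.

## Two-tissue compartment model

Tissue concentration is the convolution of the plasma-parent input with the
2TCM impulse response

    h(t) = K1/(α2−α1) · [(k3+k4−α1) e^(−α1 t) + (α2−k3−k4) e^(−α2 t)],
    α1,2 = ½[(k2+k3+k4) ∓ √((k2+k3+k4)² − 4 k2 k4)],

plus a fractional blood-volume term: `C_model = (1−vB) C_T + vB C_wb`. The
macro-parameter is `V_T = (K1/k2)(1+k3/k4) = ∫h`.

Numerics: each exponential convolution is evaluated *exactly* for a
piecewise-linear input on the uniform grid (default 0.05 min) via a
first-order IIR recursion (`scipy.signal.lfilter`), which is stable for any
α·Δt and has an explicit α→0 limit that reduces to trapezoid accumulation.
Degenerate repeated eigenvalues (α1 = α2, possible only on the k3 = 0
boundary with k2 = k4) are separated by 1e-10 min⁻¹; the discriminant is
clamped at zero against rounding. Frame averages come from the interpolated
cumulative trapezoid integral of the model curve.

Fitting minimizes `Σ w_i (C_obs,i − C_model,i)²` with `w_i = Δt_i` by
default (longer frames carry more counts); inverse-variance or custom
weights are accepted. Rates are optimized in log10 space within bounds
K1 ∈ [1e-4, 2] mL·cm⁻³·min⁻¹ and k2, k3, k4 ∈ [1e-5, 1] min⁻¹; vB is fitted
linearly in [0, 0.2] unless fixed. Ten starts are used: one mid-range
heuristic plus nine log-uniform draws from a seeded generator, making the
fit deterministic under a fixed seed. A fitted K1 at its lower bound is
flagged as unidentifiable rather than rejected.

## Logan graphical analysis

For frames with midpoint ≥ t*, `∫₀ᵀ C_obs/C_obs(T)` is regressed on
`∫₀ᵀ C_p/C_obs(T)`; the slope estimates V_T. The tissue integral uses the
trapezoid rule over (midpoint, frame value) pairs anchored at the origin;
the plasma integral is accumulated on the fine grid and interpolated. The
two quadratures differ at O(Δt²), so even exactly proportional curves
recover a proportionality constant only to ~0.2%, not to machine precision.

t* defaults to 30 min. With `t_star="auto"` the smallest frame start whose
linear segment has maximum relative residual ≤ 10% is chosen; if no
candidate qualifies, the candidate minimizing that residual is used and
flagged. Two documented biases are asserted as properties rather than
corrected: additive frame noise enters the Logan denominator and produces a
nonpositive median bias in the slope, and slow washout (small k4 relative
to the input clearance) delays the linear regime so that truncated scans
underestimate V_T — the basis of the time-stability table, which reports
`100 · V_T(duration)/V_T(full)` at fixed t*.

## SUV

`SUV = C̄ / (dose/weight)` with `C̄` the duration-weighted mean over frames
*fully inside* the window (no partial-frame weighting); the default window
100–120 min contains exactly four 5-min frames of the standard schedule.
Units: kBq/mL ÷ (MBq·1000/g) → g/mL.

## Synthetic study generator

The generator is the package's ground-truth engine, emulating a
two-genotype (WT/HET), two-session mouse study. Genotype affects only the
binding-associated rate k3 (WT 0.012, HET 0.075 min⁻¹, with K1 = 0.3,
k2 = 0.15, k4 = 0.03, vB = 0.03 shared), i.e. the aggregate-binding
interpretation of the phenotype; this puts WT V_T at 2.8 and HET at 7.0
mL/cm³, a HET excess of ~150%. Biological variability is lognormal on k3:
an animal-level factor (SD 0.15 on the log scale) shared across sessions
and regions scaled per region, plus a session-level factor (SD 0.06) that
generates genuine test–retest variability. Doses are drawn near 4.1 MBq,
weights near 28 g, injected masses uniform in 0.2–0.9 µg/kg.

Frame noise is zero-mean Gaussian with SD = scale·√(C_model/Δt), the
standard count-statistics heuristic for reconstructed TACs (default scale
0.05). Simulated concentrations live on an SUV-like normalized scale of
order 0.1–10, where that law yields a few-percent CV on late 5-min frames;
the study writer multiplies by each subject's dose/weight to store kBq/mL
files. V_T is invariant to this common rescaling and SUV recovers the
normalized values, so the scale choice is cosmetic for all endpoints.

What the generator does *not* emulate: voxel-level images and partial-volume
effects, reconstruction physics and correlated frame noise, IDIF
delay/dispersion relative to tissue (the synthetic input is taken as the
true plasma curve), anesthesia or perfusion drift between sessions, and any
age dependence. Passing recovery tests therefore demonstrates correctness
of the estimators under the stated generative model, not robustness to
those real-data effects.

## Reliability battery

rTRV = 100·(test − retest)/mean(test, retest); aTRV = |rTRV|. Bland–Altman
uses the per-animal rTRV values as differences, bias = mean, limits =
bias ± 1.96·SD with the n−1 sample SD.

The ICC model has fixed effects genotype + session + genotype×session
(aliased columns dropped automatically, e.g. one-genotype cohorts), a
random animal intercept, and a residual. It is fitted by profiled REML: for
each variance ratio λ = σ²_a/σ²_e the fixed effects and σ²_e have closed
GLS forms via the blockwise inverse, and λ solves the analytic REML score
equation by bracketed root-finding to machine precision. On balanced
two-session data with an intercept-only mean model this reproduces the
one-way ANOVA method-of-moments components exactly (an algebraic identity,
asserted at 1e-8); statsmodels' MixedLM serves as an independent
cross-check in the tests rather than the solver, because its generic
optimizer does not reliably reach that precision. Negative component
estimates are truncated at zero and excluded from the ICC denominator.
Animal×genotype and animal×session random terms can be requested
(statsmodels backend): with one observation per animal and session the
first is confounded with the animal intercept and the second with the
residual, so they collapse toward zero and leave the ICC unchanged — the
flag exists to document exactly that. ICC is computed per region per
metric, pooling genotypes.

## Group statistics and power

Cohen's d uses the pooled-SD convention; the genotype percent difference is
defined relative to the WT mean (so values above 100% mean the HET mean
exceeds twice the WT mean) — stated prominently because the convention is
often left implicit. Power for the equal-n two-sample t-test is exact via
the noncentral-t distribution (df = 2n−2, δ = d√(n/2)); the returned n is
the smallest ≥ 2 meeting the target (α = 0.05, power 0.80, one-tailed by
default), verified minimal against a Monte-Carlo oracle in the tests.
`d_for_relative_difference` converts a planned relative group difference
into d as (rel·mean_ref)/SD_pooled — one explicit convention among several
possible. Group inference is per-region Welch comparisons with Bonferroni
scaling; a full two-way ANOVA is deliberately out of scope as routine.
The 4PL mass–dose curve is fitted on x = log10(mass) with a descending
slope; `mass_at_drop(q)` inverts it for the mass at a fractional drop q
from the upper asymptote and returns `None` on degenerate flat fits.

## Problem sizes

Test and acceptance runs use deliberately modest sizes chosen to exercise
the estimators well inside their asymptotic regimes: a 27-point (K1, k2,
k3) grid for recovery, 100 noisy replicates for the Monte-Carlo V_T error,
cohorts of 200 animals (21 replicates) for ICC recovery, 500 animals for
Bland–Altman coverage, 1e5 replicates for the Monte-Carlo power oracle, and
2–4 animals per genotype with two regions for the end-to-end pipeline runs.

## Known limitations

* No reference-region or irreversible (Patlak) models; the target has no
  reference region.
* No voxelwise parametric maps; all quantification is regional.
* Logan bias is documented, not corrected (no multilinear variants).
* ICC confidence intervals are not computed.
* The unbalanced-design ICC path falls back to available-case fitting with
  a warning rather than implementing a dedicated unbalanced estimator.
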