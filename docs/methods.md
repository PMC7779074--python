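# Methods

This note documents the models and numerical choices behind cortflow:
what the synthetic cohort generator emulates, how each analysis stage is
defined, and which design decisions were genuinely open.

## Synthetic cohort generator

The generator exists so that every downstream stage has a recoverable
ground truth. It emulates, at the parcel level, the statistical
structure the analyses are designed to detect; it does not attempt
voxelwise realism, physiological noise spectra, or motion artifact
structure.

**Geometry.** Parcels are uniform random points on the unit sphere;
distances are great-circle arc lengths (radians). The sphere stands in
for a cortical hemisphere's surface geometry: it provides the distance
structure that spatial smoothness and the surrogate machinery need,
nothing more.

**Planted maps.** Four spatially smooth Gaussian fields (white noise
smoothed with a Gaussian distance kernel, length scale 0.7 rad) are
orthogonalized and mixed through a factor of a target correlation
matrix over (hierarchy, τ, myelin, activation amplitude); monotone
transforms then map the latents to physical scales. Because Spearman
correlations of smooth fields scatter widely around their planted
Pearson value (the effective sample size is the number of independent
spatial patches, not the parcel count), the generator redraws fields —
deterministically, from the seeded stream — until the achieved Spearman
structure is within ±0.075 of target, which guarantees the ±0.1
contract. Default targets: hierarchy–τ +0.6, hierarchy–myelin −0.6,
hierarchy–amplitude −0.6, with direct cross-couplings τ–amplitude
−0.55, τ–myelin −0.45, myelin–amplitude +0.45 (signs and rough
magnitudes as observed empirically in task fMRI). The implied Pearson
matrix is checked for positive semidefiniteness; infeasible targets are
rejected.

**Physical scales.** τ ∈ [0.8, 2.5] s (a ~1 s unimodal-to-transmodal
spread at TR = 0.72 s — narrow enough that the block-peak statistics
below are not dominated by per-parcel effective-sample differences);
myelin proxy ∈ [1, 2] (T1w/T2w-like ratio); local evoked amplitude up
to ~1 in units of the unit-variance background (a strong but plausible
block-design effect size). None of these are claimed to match any real
dataset's effect sizes; they are fixed study conditions.

**Rest dynamics.** Each parcel is a discretized Ornstein–Uhlenbeck /
AR(1) process, φᵢ = exp(−TR/τᵢ), driven by innovations that mix K = 10
shared standard-normal drivers (non-negative loadings, so background
coupling is predominantly positive, as cortical FC is) with independent
noise; coupling strength w = 0.6 puts mean background FC near 0.15.
Because the innovations are temporally white, the lag-k autocorrelation
is exactly φᵢᵏ whatever the coupling — the timescale fit is therefore a
clean parameter-recovery oracle. Runs are z-scored per parcel.

**Task dynamics.** Evoked responses are per-block boxcars convolved
with the canonical HRF and scaled by amplitude[parcel, condition].
Amplitudes decompose into a *local* part — monotone in the planted
amplitude latent, with idiosyncratic condition-to-condition jitter
(sd 0.6) that no other parcel shares — and a *distributed* part (scale
0.35) lying in the span of the driver loadings, which is exactly the
component activity flow mapping can reconstruct. Two suppression
mechanisms plant the task-state FC reduction: background coupling is
multiplied by a per-parcel scale s ∈ (0.2, 1], decreasing in activation
rank (max suppression 0.8), and block-to-block evoked gains (sd 0.45)
fluctuate with the same — equally suppressed — driver structure,
emulating trial-to-trial response variability whose inter-region
covariance weakens where activation is strong. The second mechanism is
what the block-peak FC measures most directly.

**Confounds.** Six slow AR(1) motion traces and two compartments (white
matter, ventricles) of 10 signals sharing two latent physiological
components each. Confounds are statistically independent of the neural
signal; the nuisance stage is exercised as machinery, not as a
denoising benchmark.

**What passing tests do and do not show.** The cohort is well-specified
for the pipeline by construction (shared canonical HRF, exactly
block-locked mean responses, Gaussian innovations). Passing tests
demonstrate correctness of the estimators and recoverability of the
planted structure — not robustness to hemodynamic mismatch, motion
artifact, or non-stationarity in real data. A mismatched-HRF stress
mode (`simulate_task_timeseries(..., hrf=...)`) exists for sensitivity
checks but is off by default.

## Preprocessing

First five frames dropped; linear demean/detrend per parcel. Nuisance
design: 6 motion parameters, their backward differences (first row 0),
and the squares of those 12 (24 columns); 5 principal-component time
series from each compartment (unit-norm, sign fixed by the first
nonzero loading), their differences, and the squares of those 20 (40
columns); 64 total. "Quadratics of all regressors" is read as
elementwise squares of the expanded parameter+derivative set — the only
reading consistent with the 24/40 block counts. Residuals come from OLS
on [intercept | design]; the parcel-mean (global) signal is never
constructed as a regressor. Demeaning/detrending operates
post-parcellation only.

## Task GLM and FIR

The canonical HRF is the SPM-style double gamma (peak 6 s, undershoot
16 s, unit dispersions, 6:1 peak:undershoot), sampled at the TR and
scaled to peak 1. Activation betas are OLS per parcel on [intercept |
HRF-convolved condition boxcars | nuisance columns]; no prewhitening or
temporal filtering is applied (the generator's errors are AR(1), but
group-level random-effects t-statistics absorb within-subject
autocorrelation). The group magnitude map is the mean over conditions
of |one-sample t across subjects|, with 0/0 defined as t = 0 and
sd = 0 with nonzero mean flagged.

FIR regression uses, per condition, one indicator per peri-onset lag
from block onset through offset + 25 TRs, pooled across that
condition's blocks; all-zero and duplicate columns are dropped with a
warning, and rank deficiency falls back to the least-norm solution
(residuals are unique regardless). When data have already been
residualized against a nuisance design, those columns are carried into
the FIR model (`extra_regressors`): sequential regression is not
projection onto the joint span, and the earlier fit re-introduces
evoked variance into the residual — empirically enough to invert
activation/ΔFC associations. Joint modeling keeps residuals orthogonal
to both sets (Frisch–Waugh).

## Connectivity

Task FC: Pearson correlation of the FIR residual over the concatenated
in-block TRs, treated as one series (no per-block correlation
averaging). Matched rest FC: the same FIR design (and the same carried
nuisance columns) regressed from the resting run truncated to the task
run's length, then correlation over the identical intervals. Weighted
degree = mean off-diagonal row entry; an optional positive-only variant
zeroes negative edges first (denominator unchanged). ΔGBC ≡ task −
rest throughout, so FC reductions are negative; no Fisher-z transform
is applied before degree averaging. Zero-variance parcels get FC 0 and
a flag rather than NaNs.

## Block-peak approach

After baselining each parcel to its mean over all inter-block rest TRs
(no post-block washout exclusion by default), each block contributes
the in-block sample of maximal absolute value, sign retained (a
magnitude-only mode exists behind a flag; retaining sign keeps
deactivations informative and the block-to-block correlation
well-defined). Ties go to the earliest TR. Activation is the mean of
peaks across blocks; FC is the Pearson correlation of peak vectors
across all blocks pooled; rest uses pseudo-blocks from the same design.
This path deliberately imports nothing from the GLM/FIR module — no
task regression occurs anywhere on it.

## Intrinsic timescale

The sample ACF uses the biased estimator with a single global mean
(statsmodels `acf`, FFT). The offset exponential is fitted over lags
1..K (lag 0 is 1 by construction and would over-weight A(1+B) = 1),
K = 100 by default (40/50 reproduce the same ranking), with bounded
trust-region least squares: A ∈ [0, ∞), τ ∈ [0, ∞), B free. Multi-start
τ₀ ∈ {0.5, 2, 10} s with A₀ = r(1) and B₀ = mean of the last 10 lags;
lowest-RSS convergent solution wins; non-convergent parcels are
excluded from group maps (not clipped). Per-subject fitting with
across-subject averaging of τ maps (rather than fitting the group-mean
ACF) follows the per-subject definition of the estimator.

## Activity flow

Multiple-regression FC solves, for each target, OLS of its rest series
on all other parcels plus an intercept. With T > P and a
well-conditioned covariance this is computed through one precision
matrix (βⱼₙ = −Θⱼₙ/Θⱼⱼ), which is algebraically identical to the
per-target solve; collinear inputs fall back to explicit per-target
least squares, and T ≤ P falls back (only when explicitly enabled) to
per-target ridge with leave-one-out GCV over a log-spaced penalty grid,
flagged on the result. Predictions use no intercept (the stored β₀ is
unused), and the zero diagonal enforces leave-target-out structurally.
Per-subject MAE maps are averaged across subjects.

## Surrogate statistics

Surrogate maps: permute the map's values, smooth with a row-stochastic
Gaussian distance kernel, optionally mix back a fraction of the
unsmoothed permutation (nugget), and rank-remap onto the source map's
exact value multiset. Because rank-remapping restores the marginal
exactly, any affine rescaling is absorbed; variogram matching is
achieved by selecting the kernel width (grid over distance quantiles
0.01–0.25) and nugget (0–0.5) that minimize the mean L1 variogram
mismatch of ten trial surrogates, evaluated over the nearest quartile
of pair distances (a single smooth realization often carries a global
trend whose long-range semivariance no stationary surrogate can match,
and it is short-range autocorrelation that shapes the null). Variograms
use 25 equal-width distance bins of ½(xᵢ−xⱼ)²; empty bins are dropped.
On smooth synthetic maps (n = 100) the median per-surrogate short-range
relative variogram error is ~0.15–0.25 — preserving the exact value
multiset via rank-remapping costs ~0.1 of fidelity over the raw
smoothing-family fit — and the test's empirical type-I error at
α = 0.05 is ~0.04–0.06 against independent smooth maps where plain
value permutation rejects at ~0.55.

P-values are two-tailed with the +1 correction in numerator and
denominator, so the minimum attainable p is 1/(n_surrogates + 1).
Partition contrasts are paired across subjects (per-subject transmodal
− unimodal means, one-sample t, df = n − 1). The partition comes from a
median split of the hierarchy score. FDR is Benjamini–Hochberg step-up
at q = 0.01 by default.

## Pipeline defaults and problem sizes

Default cohort: 20 subjects, 360 parcels, 24 conditions across 7
task-like groupings, 3 blocks per condition of 15 s separated by 15 s
rest at TR = 0.72 s (~3000 task TRs), rest runs of 3200 TRs (rest must
cover the task design for interval matching). Group association tests
operate on group-mean maps; per-subject variants sit behind the
subject-level contrast machinery. All randomness flows from one seed
through derived substreams; rerunning a config bit-reproduces every
output. Output directories carry the resolved config, the seed, and
SHA-256 hashes of every written file.

## Known limitations

- The generator shares the analysis HRF by default; hemodynamic
  mismatch is a stress mode, not a tested default.
- The block-peak rest comparison inherits extreme-value statistics
  whose correlation attenuation depends on each parcel's timescale;
  with very wide τ ranges this can mask planted FC-change gradients.
- Ridge-based multiple-regression FC (T ≤ P) is a flagged deviation
  from the OLS definition and is not used by any default path.
- Surrogate-map calibration is approximate (≈0.06 at nominal 0.05);
  the test is far closer to nominal than naive permutation but not
  exact.
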