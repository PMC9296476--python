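# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind `hdacscope`, in the order the pipeline runs them.

## SRTM kinetics

**Model.** The simplified reference tissue model describes a target tissue
curve relative to a reference region assumed free of specific binding:

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·∫ C_R(u)·e^(−k2a(t−u)) du,
    k2a = k2/(1+BP).

Assumptions: one effective tissue compartment in both target and reference,
a common arterial input, and a reference region with negligible specific
binding.  R1 (unitless) is the headline output as a relative-perfusion
surrogate; k2 is quoted per minute; BP is unitless.

**Fitting.** For fixed `k2a` the model is linear in `(R1, φ)` with
`φ = k2 − R1·k2a`, so the solver sweeps a grid of `k2a` candidates
(default: 64 log-spaced in [0.006, 0.6] min⁻¹, a range bracketing plausible
tracer kinetics), solves a 2-parameter weighted least squares per candidate
and keeps the minimum.  Three rounds of local re-gridding between the
winning candidate's neighbours shrink the `k2a` bracket by ~1.076^(1/64),
which is what lets a noiseless round trip recover BP to well under 1%
(the acceptance tolerance) rather than the ~4% a 64-point grid alone
would leave.  Weights default to frame durations, the standard surrogate
for count statistics; the weighting scheme is configurable because
acquisition-software defaults vary.

**Discretisation.** The convolution runs on a uniform 1 s internal grid.
The reference curve is interpolated piecewise-linearly through its frame
means (anchored at zero activity at scan start), the exponential
convolution uses the exact closed-form update for piecewise-linear input,
and frame values are trapezoidal averages.  The `R1·C_R` term uses the
reference frame values directly, so `R1 = 1, BP = 0` reproduces the
reference exactly and forward-simulation followed by fitting is a
fixed point of the discretisation.

**Degeneracy.** When the fitted `φ` is numerically zero (|φ| < 1e-6·k2a)
the target is proportional to the reference and `k2a` is unidentifiable;
the fit is flagged and reported as BP = 0 with `k2 = R1·k2a`.  Negative BP
estimates are retained and flagged rather than clipped — clipping would
bias region means.

**Frame schedule.** The built-in 26-frame binning (6×10 s, 6×20 s, 2×30 s,
1×60 s, 5×300 s, 6×600 s; 5400 s total) is asserted on construction.
Re-binning uses duration-weighted means, conserving the activity–time
integral.

## Static quantification

**SUVR.** Duration-weighted mean over the tracer's uptake window divided by
the scalar reference-region mean, so the reference mean is exactly 1.
Built-in protocols: HDAC tracer (white-matter reference, 60–90 min), tau
tracer (cerebellar grey, 90–110 min), amyloid tracer (cerebellar grey,
40–70 min).  Supplied frames must lie inside the window; no implicit frame
selection happens.

**Smoothing.** Gaussian, with applied FWHM = √(target² − intrinsic²)
(variance additivity), truncated at 6σ, zero-padded.  Zero padding
conserves the total image sum; the sequential-smoothing identity
(f1 then f2 ≡ one pass at √(f1²+f2²)) holds to <1e-6 RMS away from the
volume boundary, where cropping the intermediate image discards kernel
tails.

**GTM/RBV partial-volume correction.** The geometric transfer matrix
`W[i,j]` is the mean over region i of the PSF-blurred indicator of region
j; solving `W·m = o` recovers regional true means, and RBV rescales voxels
by `s/(s⊗PSF)` with `s` the piecewise-constant image of those means.  Two
deliberate choices:

* *Boundary normalisation.*  The blurred indicators and the RBV denominator
  are divided by the blurred all-ones volume.  Without this, zero padding
  leaks kernel mass off the grid, `W` rows would sum below 1 even for
  volume-tiling label maps, and a uniform image on a tiling map would not
  be a fixed point of the correction.
* *Guard rails.*  A near-singular `W` (regions indistinguishable at the
  PSF) raises with the condition number (default limit 1e8); the RBV
  denominator is floored at 1e-6·max(s) and floored voxels are counted in
  the result.

The PSF defaults to the 8 mm final resolution of the smoothing step but is
configurable, since correction methods state the scheme more often than
the width.  GTM assumes zero activity outside labelled regions; analyses
that need a modelled background should include it as an explicit region.

## Voxel statistics

Voxel-wise OLS is solved in closed form per voxel; the contrast t-test uses
df = n − rank.  Exact fits (zero residual) report p at a documented machine
floor (1e-300) with a count, never silently as 0.  FDR is Benjamini–
Hochberg step-up over in-mask voxels only, returning the adaptive p
threshold (0 when nothing is rejected).  The ROC map is the Mann–Whitney
AUC with ties counted ½, oriented as P(control > patient) so that reduced
uptake in patients yields AUC > 0.5 — fixed here because a silently flipped
AUC map is a classic bug.  ANOVA uses Tukey HSD via the studentized-range
distribution with the Tukey–Kramer rule for unequal group sizes; the HSD
table can be skipped (`pairwise=False`) when only the omnibus test is
needed, as in calibration loops.  Longitudinal models are complete-case OLS
with an intercept; collinear predictor sets raise with the offending
columns named.

## Structural-equation engine

**Model class.** Observed-variable linear path models: directed acyclic
structural edges (free or fixed), free variances everywhere, free
covariances among exogenous variables by default, endogenous residual
covariances fixed at zero unless declared.  Parameters use lavaan-style
names (`y~x`, `a~~b`).  Implied covariance
`Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ`; df = p(p+1)/2 − q.

**Estimation.** ML discrepancy
`F = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p` minimised by L-BFGS-B with the analytic
gradient (`dF = tr[Σ⁻¹(Σ−S)Σ⁻¹ dΣ]`), variance parameters bounded below.
Starting values are the equation-wise least-squares solutions computed from
S — for recursive models with uncorrelated disturbances these are already
the MLE, so the optimizer typically verifies a stationary point in a few
iterations, and for constrained or fixed-parameter models they are a
robust warm start.  Standard errors come from the inverse numerical
Hessian of ((n−1)/2)·F (central differences of the analytic gradient).
Non-convergence is flagged on the result, never silent.

**Conventions** (published programs differ; these are pinned):
S uses the n−1 divisor; χ² = (n−1)·F_min; the log-likelihood entering
AIC/BIC uses the Wishart (n−1) convention, so −2lnL = χ² + a data-only
constant and information-criterion differences between nested models equal
χ² differences minus penalty differences *exactly* (asserted in tests);
RMSEA = √(max(χ²−df,0)/(df(n−1))) with a 90% CI from inverting the
noncentral-χ² CDF at the 5%/95% bounds; CFI against the independence
baseline (closed form: F_b = Σln s_ii − ln|S|); SRMR includes the diagonal
and standardises residuals in the correlation metric; df = 0 truncates to
RMSEA = 0, CFI = 1.  A fit is classified "good" when RMSEA < 0.05,
CFI > 0.97 and SRMR < 0.05.  Standardized estimates are computed post hoc
from model-implied SDs.  Missing data are handled listwise.

**Mediation.** The total effect matrix is (I−B)⁻¹ − I.  The indirect
effect through a mediator is the total effect minus the total effect with
the mediator's outgoing edges severed — for a single-mediator triangle this
reduces to the product of coefficients a·b, and it correctly sums multiple
routes crossing the mediator.  Two proportions are reported because
published analyses are ambiguous when several mediated routes exist:
indirect/(indirect+direct) with the direct edge only, and indirect/total
with all routes.  Opposite-signed indirect and direct effects make the
first undefined; it is returned as NaN with a flag, components intact.

**Bootstrap.** Row resampling with replacement, percentile 95% CIs
(the simplest defensible scheme; BCa adds complexity without changing the
qualitative conclusions the CIs support here), two-sided p from the
doubled smaller tail around zero.  Non-converged replicates are excluded
and counted; >20% failures flags the result.

**Power.** Monte-Carlo: simulate from Σ(θ), refit, count Wald-z rejections
per free parameter.  With a zero coefficient this estimates the test's
size, which calibrates within α ± 0.02 at 1000 simulations.

**The five constructs.** The bundled model suite orders amyloid, tau, HDAC,
atrophy and cognition five ways.  The mediation hypothesis is the full
recursive ordering (10 biomarker paths) with all three covariates pointing
at both outcomes and a saturated exogenous block: 36 moments − 30 free
parameters = 6 df.  The alternatives are deliberately *restrictive* — HDAC
downstream of atrophy only, HDAC exogenous acting only through the
pathologies, HDAC strictly between amyloid and tau, and a classical cascade
with HDAC disconnected — because complete orderings of the same variables
would be Markov equivalent and fit identically; the restrictions are what
make the comparison informative, mirroring how competing causal hypotheses
are specified in practice.

## Synthetic data

**Phantoms** are box regions with unique positive labels on a regular grid;
overlaps raise with the colliding labels named.

**Dynamic PET.** The reference curve is a bi-exponential
A1(e^(−λ1·t) − e^(−λ2·t)) whose frame values are exact analytic means, so
no quadrature error enters simulations.  Target regions follow the SRTM
forward model; reference regions are pinned to (R1 = 1, BP = 0) so the
simulation is self-consistent.  Noise is i.i.d. Gaussian per voxel and
frame with SD = noise_sd/√(frame duration), the standard counting-
statistics surrogate; the level is a free parameter (defaults exercise the
fitters at realistic contrast) since real acquisitions vary widely.  Not
emulated: scanner physics (scatter, randoms, reconstruction correlations),
motion, and anatomical texture — passing tests therefore demonstrate
correctness of the estimators under the stated noise model, not robustness
to acquisition artefacts.

**Cohorts.** Subjects are drawn from the linear-Gaussian structural model
amyloid → tau → HDAC → {atrophy, cognition} with age/sex/education
covariates.  All continuous variables are generated z-scaled; the amyloid
exogenous variable receives group-mean offsets (−0.8, −0.3, +0.7, +1.3 for
young controls, elderly controls, MCI, AD), giving the group separation a
four-group clinical sample shows.  Default group sizes are 25/28/15/26.
Path-coefficient defaults are standardized-scale with HDAC effects
positive (atrophy is stored as grey-matter density and cognition as an
MMSE-like score, lower = worse): the tau→HDAC and HDAC→outcome paths are
±0.5 and the tau direct effects are solved so the tau-route proportion
mediated is exactly 57% (atrophy) and 51% (cognition).  Diagnosis labels
are the generating groups; amyloid/tau positivity columns record explicit
cut points (0.5 z) because clinical criteria are not computable.  Regional
HDAC-tracer SUVR columns couple a plausible group mean (≈1.16 young
controls down to ≈0.94 AD in the vulnerable cortices, SD 0.06) to the
subject's HDAC latent, emulating reduced uptake in posterior cingulate,
precuneus, inferior parietal and lateral temporal regions.  The group
mixture makes amyloid non-Gaussian; path recovery is unaffected because
the structural equations hold conditionally on the exogenous draw.

## Problem sizes used in the checks

The test suite and acceptance checks run at sizes chosen to make the
Monte-Carlo error a small fraction of each tolerance: 6³-voxel regions on
24³–32³ grids for imaging round trips, 500 FDR replicates of 1000 voxels,
100 cohort replicates of n = 500 for mediation recovery and model ranking,
600 replicates for the χ²-mean invariant, and 1000 simulations for power
calibration.  All randomness flows through explicit seeds; every generator
is bit-reproducible given (spec, seed).

## Known limitations

No arterial-input models, SRTM2/k2′ coupling or motion correction; no
spatial registration or resampling (inputs must share a grid exactly); no
Meltzer/Müller-Gärtner PVC variants; no latent-variable measurement
models, ordinal estimators or multi-group SEM; no random-field or
permutation cluster inference.  The SEM engine targets the small observed-
variable models used here (p ≤ ~20); it favours clarity over scale.
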