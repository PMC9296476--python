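# hdacscope

Quantification and causal-path statistics for molecular PET imaging of
class-I histone deacetylase (HDAC I) availability in neurodegeneration.

Dementia imaging studies increasingly combine several tracers — amyloid-β,
tau, and epigenetic targets such as HDAC I — with structural MRI and
cognitive testing.  `hdacscope` implements the complete computational chain
such a study needs, end to end and testable without any patient data:

1. **Kinetic quantification** (`hdacscope.kinetics`).  The simplified
   reference tissue model (SRTM) expresses a target time–activity curve as

   `C_T(t) = R1·C_R(t) + (k2 − R1·k2a)·[C_R ⊗ e^(−k2a·t)](t)`,  `k2a = k2/(1+BP)`

   where `R1` is the target/reference ratio of the delivery constant K1 (a
   perfusion surrogate), `k2` the efflux rate and `BP` the binding
   potential.  Fitting is by basis functions: for each candidate `k2a` the
   model is linear in `(R1, φ)`, solved by duration-weighted least squares,
   with local refinement of the winning candidate.  A 26-frame binning of a
   0–90 min acquisition (6×10 s, 6×20 s, 2×30 s, 1×60 s, 5×300 s, 6×600 s)
   is built in, and `make_r1_map` produces voxel-wise R1 parametric images.

2. **Static quantification** (`hdacscope.pet_quant`).  SUVR with
   tracer-specific uptake windows and reference regions (white matter
   60–90 min for the HDAC tracer; cerebellar grey 90–110 min and 40–70 min
   for the tau and amyloid tracers), Gaussian smoothing to a target
   resolution, geometric-transfer-matrix (GTM) / region-based voxel-wise
   (RBV) partial-volume correction, ROI extraction and normative z-score
   maps.

3. **Voxel statistics** (`hdacscope.voxel_stats`).  Voxel-wise GLM t/p maps
   with Benjamini–Hochberg FDR at q = 0.05 inside the analysis mask,
   voxel-wise ROC-AUC (Mann–Whitney, oriented so that *reduced* uptake in
   patients gives AUC > 0.5), one-way ANOVA with Tukey HSD, Pearson/Spearman
   correlations, and longitudinal regressions of change scores on baseline
   biomarkers.

4. **Structural-equation mediation** (`hdacscope.sem_mediation`).  A
   from-scratch linear SEM engine: ML fitting of `Σ(θ) = (I−B)⁻¹Ψ(I−B)⁻ᵀ`
   to a sample covariance (χ² = (n−1)·F_min), fit indices (RMSEA with 90%
   CI, SRMR, CFI, AIC, BIC), per-equation R², mediation decomposition with
   proportion mediated, percentile bootstrap (default 1000 replicates),
   multi-model comparison, and Monte-Carlo power.  Five competing causal
   orderings of amyloid → tau → HDAC → {atrophy, cognition} are bundled,
   including the mediation hypothesis (6 df) and a classical no-HDAC
   cascade.

5. **Synthetic data** (`hdacscope.synthetic_data`).  Box phantoms, dynamic
   PET whose regional curves follow the SRTM forward model around a
   bi-exponential reference, and multivariate cohorts drawn from the
   linear-Gaussian causal structure with age/sex/education covariates.
   Every generator is a pure function of (spec, seed).

A `hdacscope` CLI (`simulate`, `suvr`, `r1`, `pvc`, `glm`, `roc`, `anova`,
`sem fit|compare|mediate|power`, `run`) wraps the library; `hdacscope run`
chains everything into a manifest-checked, seed-reproducible run directory.

## Worked example

Simulate a 94-subject cohort (25 young controls, 28 elderly controls, 15
MCI, 26 AD-like) and compare the five causal constructs:

```python
from hdacscope.synthetic_data import CohortSpec, simulate_cohort
from hdacscope.sem_mediation import (
    five_model_suite, compare_models, mediation_effects,
)

cohort = simulate_cohort(CohortSpec(seed=7))
table, best, fits = compare_models(five_model_suite(), cohort)
fit = fits["hdac_mediation"]
print(f"n = {fit.n}, chi2 = {fit.chi2:.3f}, df = {fit.df}, p = {fit.p_value:.3f}")
for outcome in ("atrophy", "cognition"):
    med = mediation_effects(fit, "tau", "hdac", outcome)
    print(f"tau -> {outcome}: indirect {med.indirect:+.3f}, direct {med.direct:+.3f}, "
          f"proportion mediated {med.proportion_mediated:.0f}%")
print(table.round(3).to_string())
```

prints

```
n = 94, chi2 = 5.674, df = 6, p = 0.461
tau -> atrophy: indirect -0.262, direct -0.289, proportion mediated 48%
tau -> cognition: indirect -0.223, direct -0.417, proportion mediated 35%
       hdac_mediation  hdac_after_atrophy  hdac_first  hdac_between  classical_cascade
RMSEA           0.000               0.230       0.245         0.280              0.345
SRMR            0.041               0.085       0.054         0.074              0.090
CFI             1.000               0.892       0.877         0.819              0.816
AIC          1745.447            1782.966    1788.332      1808.172           1812.269
BIC          1821.746            1854.178    1859.544      1876.841           1888.567
```

The mediation construct fits the data it generated (χ² ≈ df, RMSEA 0,
CFI 1) while every restrictive alternative ordering fails the conventional
good-fit thresholds (RMSEA < 0.05, CFI > 0.97, SRMR < 0.05) and loses on
AIC/BIC.  The mediation decomposition reads: of tau's total effect on
atrophy, the share routed through HDAC availability is the indirect part
(−0.262) of indirect + direct; at this small n the estimate (48%) scatters
around the generating value of 57%.  The cohort generator's defaults place
the true tau-route proportion at 57% (atrophy) and 51% (cognition).

The full imaging pipeline runs from a config:

```sh
hdacscope run --config examples/demo_config.yaml
```

producing SUVR/R1/PVC maps, t/p/AUC maps with FDR summaries, ROI and
cohort tables, the five-model comparison and a SHA-256 manifest — rerun
with the same seed, the manifest checksums are identical.

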