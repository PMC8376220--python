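# Methods

## Model

Individual-level data are assumed to follow the linear structural system

    X_i = Σ_j β_XGj G_ij + e_Xi
    Y_i = β X_i + Σ_j α_j G_ij + e_Yi

with independent bi-allelic dosages G_ij ~ Binomial(2, maf), causal effect
β, direct (horizontally pleiotropic) SNP effects α_j, and a bivariate
Gaussian residual pair (e_X, e_Y) with standard deviations (σ_X, σ_Y) and
correlation ρ. Any scalar-confounder formulation (loadings β_UX, β_UY on a
shared U plus independent noise) maps onto (σ_X, σ_Y, ρ); the package
parameterizes the residual moments directly because only they are
identified by the procedure, and provides
`residual_moments_from_confounder` for the mapping. The reduced-form
SNP–outcome association is β_YGj = α_j + β β_XGj.

Conditioning the outcome regression on the observed exposure (step 1)
biases the coefficient on X to β* = β + ρ σ_Y / σ_X in the large-n limit,
and links the collider-biased SNP coefficients to the first stage through
α*_j = α_j + (β − β*) β_XGj. The collider-correction slope β − β* is
estimated from the summary pairs (β̂_XGj, α̂*_j) by weighted least squares
through the origin (IVW), with a free intercept (MR-Egger), by weighted
least absolute deviations through the origin (LAD), or by profile
estimation with exact first-stage weighting (LIML at z = 0, a RAPS-style
Tukey-penalized fit at z = 1). The causal effect is β̂ = β̂* + (β − β*)̂.

Homogeneity (a constant individual-level causal effect) is assumed
throughout; outcomes and exposures are continuous and Gaussian-residual.
Binary exposures for user data would enter through a logistic first stage;
the simulator never generates that case.

## Key parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| k, maf | 50, 0.3 | independent bi-allelic SNPs, no LD |
| h2x | 0.015 | variance of X explained jointly by SNPs |
| β | 0.5 | causal effect (outcome units per exposure unit) |
| σ_X, σ_Y, ρ | 1, 0.69, 0.9 | main-condition residuals; give β* ≈ 1.121 and slope ≈ −0.621 |
| β_XG mean, sd | 0.026, 0.007 | chosen jointly with h2x so that I²GX runs from ≈0.1 (n = 5000) to ≈0.5 (n = 50000) |
| pleiotropy sd | 0.004 | ≈2× the SE of α̂* at n = 50000, so overdispersion (φ > 1) is exercised |
| pleiotropy mean | 0.01 (egger/lad) | directional pleiotropy scenarios |
| inside_corr | 0.5 (lad), 0.45 (toy) | α–β_XG correlation on the InSIDE-violating subset |
| SIMEX λ grid, B | (0, .5, 1, 1.5, 2), 100 | conventional grid; quadratic extrapolant |
| Tukey constant | 4.685 | conventional 95%-efficiency biweight tuning |

Effect vectors are redrawn independently for every replicate and rescaled
so that Σ β²_XGj · 2 maf (1 − maf) equals h2x/(1 − h2x) · σ_X² exactly;
this pins the population variance explained at h2x while preserving the
relative between-SNP spread. A flag-free alternative (fixing effects
across replicates) was considered and rejected: independent replicate
datasets match the Monte-Carlo design the experiment harness reports.

The `fig3_toy` condition (residual correlation 0.5, α correlated with
β_XG across *all* SNPs at 0.45) demonstrates that the collider-corrected
residuals are independent of the first-stage errors even when InSIDE fails
globally. It uses a null causal effect: the across-SNP correlation between
first-stage errors and *standard* SNP–outcome errors equals
(β σ_X + ρ σ_Y)/sd(β e_X + e_Y), which reduces to ρ exactly when β = 0 —
the only calibration consistent with both that correlation and the
residual correlation being ~0.5.

## Estimation details and numerical choices

* **IVW / MR-Egger.** Weighted least squares with weights 1/σ²_α*j.
  Multiplicative random effects: the SE is scaled by √φ with
  φ = max(1, RSS_w/df); the raw φ is kept in `extras`. The Egger fit goes
  through statsmodels WLS; the IVW fit is the closed-form normal equation.
* **LAD.** The weighted L1 objective through the origin is piecewise
  linear and convex, so the exact minimizer is a weighted median of the
  data ratios α̂*_j/β̂_XGj; ties on flat segments break toward the
  smallest |slope|. SE by nonparametric bootstrap over SNPs (default
  B = 1000, seeded).
* **LIML (z = 0).** Minimizes Q(s) = Σ (α̂*_j − s β̂_XGj)² / (s² σ²_XGj +
  σ²_α*j) by multistart bounded search on IVW ± 10 SE; the curvature of Q
  (treated as a −2 log-likelihood profile) gives the SE. The minimized
  objective *is* the exact Q statistic — one shared code path, asserted in
  tests.
* **RAPS-style (z = 1).** Tukey-biweight estimating equations with a
  profiled pleiotropy variance τ²: τ² solves mean[ψ(r) r] = E[ψ(Z) Z]
  (Z standard normal; floored at 0), and the slope is a root of the robust
  profile score. The score is scanned across IVW ± 10 SE; every root is
  reported (tagged stable/unstable by the crossing direction) and the
  stable root nearest the IVW anchor is returned. Sandwich-type SE. A
  direct minimization of the bounded loss with profiled τ² is *not* used:
  bounded losses reward inflating τ², which is the mechanism behind the
  instability this estimator is known for; unstable fits are surfaced via
  `converged=False` and the candidate list rather than hidden.
* **TSLS.** statsmodels' IV2SLS; asymptotically equal to the
  collider-corrected IVW causal estimate for independent SNPs (asserted to
  within 0.01 at n = 50000 in the acceptance suite).
* **SIMEX.** Pseudo first-stage associations β̂_XGj + √λ σ_XGj Z, noise
  independent across SNPs; λ = 0 uses the observed summary unresampled so
  the curve is anchored; quadratic (default) or linear extrapolation to
  λ = −1. Variance by the Stefanski–Cook difference method — extrapolating
  mean(se²(λ)) − Var_B(slope(λ)) — falling back to the unadjusted SE if
  the extrapolated variance is non-positive or per-pseudo SEs are
  unavailable (LAD runs without its inner bootstrap inside SIMEX). SIMEX
  is intentionally *not* offered for LIML/RAPS, whose weighting handles
  first-stage error internally.
* **Step-1/2 regressions.** Joint fits (all SNPs simultaneously), which is
  what makes collider-corrected IVW equivalent to TSLS. Homoskedastic OLS
  SEs by default, sandwich SEs by flag. The non-robust path solves the
  normal equations by Cholesky (the Monte-Carlo hot loop); it is asserted
  against statsmodels to 1e-10 in the tests. Missing values raise unless
  complete-case analysis is explicitly requested; exactly duplicated SNP
  columns raise a singular-design error naming the columns.
* **F̄.** Implemented as the *mean* per-SNP F statistic, which is the
  quantity the dilution factor (F̄ − 1)/F̄ requires; the bare sum is
  exposed as `sum_f`.
* **Final SE.** β̂* and the slope are combined as independent
  (√(se² + se²)); a paired bootstrap over individuals is available for an
  exact treatment of their covariance.
* **p-values.** Two-sided normal by default; t reference by option.

## What the simulator does and does not emulate

It reproduces the stated generating conditions: independent SNPs at a
common MAF, a linear homogeneous causal effect, Gaussian residuals with a
single shared confounder, and the three pleiotropy regimes (balanced
InSIDE-satisfied; directional InSIDE-satisfied; InSIDE-violated on a
subset). It does **not** emulate linkage disequilibrium, allele-frequency
spectra, binary or non-linear exposures/outcomes, population
stratification, relatedness, selection or winner's curse. Passing tests
therefore certify the estimators under the model's assumptions, not
robustness to these real-data features.

## Problem sizes

The Monte-Carlo checks use 200 replicates per condition at the stated
sample sizes (n = 10000 for the toy and calibration conditions, n = 5000
to 50000 for the estimator conditions), with SIMEX B = 50 inside replicate
loops and B = 100 for single-dataset analyses; these sizes give
Monte-Carlo standard errors comfortably inside the asserted tolerances.
All randomness flows from one root seed through `numpy` `SeedSequence`
spawning, so any replicate is reproducible in isolation and identical
seeds give byte-identical datasets and output files.

## Known limitations

* The pleiotropy moments and the β_XG distribution of the published
  simulation studies are reconstructions calibrated to the printed
  summaries (β* ≈ 1.12, slope ≈ −0.62, I²GX 0.1→0.5, h2x = 1.5%); the
  magnitudes of scenario-specific bias curves depend on them.
* The RAPS-style fit follows the exact-weighting model with Tukey
  penalization; it is not guaranteed to match any particular external
  implementation's tuning choices.
* SEs for SIMEX-adjusted LAD reuse the unadjusted bootstrap SE.
* Covariates are passed through both regressions identically; there is no
  mixed-model or stratification correction beyond that.
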