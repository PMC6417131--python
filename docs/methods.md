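# Methods

This note documents the statistical model, the numerical choices, and the
limits of what the test suite demonstrates.

## Model and assumptions

For SNP j, let γⱼ be its true association with the exposure (per effect
allele, exposure in % of total fatty acids) and Γⱼ its true association with
the outcome (log-odds for case-control outcomes). Under the instrumental-
variable assumptions — relevance, no confounding of the SNP–outcome
relation, and exclusion (no pathway to the outcome other than the exposure) —
Γⱼ = θγⱼ, and θ is the causal effect. Direct (pleiotropic) effects αⱼ break
exclusion: Γⱼ = θγⱼ + αⱼ. The estimators differ in what they assume about α:

* **IVW** assumes all αⱼ = 0 (or balanced with mean zero under random
  effects).
* **Weighted median** is consistent when instruments carrying > 50% of the
  inverse-variance weight are valid.
* **MR-Egger** allows systematic directional pleiotropy provided InSIDE
  holds (αⱼ independent of γⱼ); its intercept estimates the average direct
  effect and its slope the causal effect.
* **PCA-IVW** addresses a different failure mode — correlated instruments —
  by generalized least squares on the top principal components of the
  weighted instrument system, avoiding the unstable inversion of a full,
  near-singular LD correlation matrix.

Two-sample structure: exposure- and outcome-side estimates come from
disjoint samples, so their sampling errors are independent. Wald-ratio SEs
use the first-order delta method ignoring exposure-side error (NOME), the
standard choice when every instrument passes F > 10; a second-order variant
(`wald_ratio_second_order`) is available.

## Estimator details and numerical choices

* CI bounds are β ∓ 1.959964·SE throughout; p-values use the two-sided
  normal reference, except the Egger intercept, which uses the t reference
  with J−2 df — honest at the small J (3–50) typical of these analyses.
* Heterogeneity: Cochran's Q on the Wald ratios with J−1 df. The IVW point
  estimate is identical under fixed and multiplicative random effects; the
  random-effects SE multiplies the fixed SE by max(1, √(Q/(J−1))) and is
  used when the Q test's p < 0.05. The same inflation (residual scale
  floored at 1) applies to MR-Egger's SEs. Egger's WLS is solved through
  explicit normal equations so the noiseless (zero-residual) case yields the
  unscaled fixed SEs rather than 0/0; a test cross-checks the fit against
  statsmodels WLS.
* Weighted median: ratios sorted stably by (ratio, snp id); with
  standardized weights sⱼ the breakpoints are pⱼ = Σ_{i<j}sᵢ + sⱼ/2 and the
  estimate interpolates the ordered ratios at p = 0.5. SE: parametric
  bootstrap (default 1000 replicates, seeded) drawing rⱼ* ~ N(rⱼ, seⱼ).
* PCA-IVW: Ψ_kl = γ̂ₖγ̂ₗρ_kl/(σ_yk σ_yl) is eigendecomposed; the smallest m
  leading components reaching a cumulative eigenvalue share of
  `pca_variance_kept` (default 0.99) are retained; GLS on the projected
  system gives β̂ = (γ̃ᵀΣ̃⁻¹γ̃)⁻¹γ̃ᵀΣ̃⁻¹Γ̃ with variance (γ̃ᵀΣ̃⁻¹γ̃)⁻¹.
  With identity LD and all components retained this reduces exactly to
  fixed-effect IVW; perfectly duplicated instruments collapse to a single
  component and reproduce the single-SNP Wald estimate.
* LD matrices: symmetrized when asymmetry ≤ 1e−6 (error beyond), unit
  diagonal enforced to 1e−6, and eigenvalue-clipped to the nearest PSD
  correlation matrix (with a logged warning) when the smallest eigenvalue is
  below −1e−8 — published, rounded r matrices frequently fail strict PSD.
* LD sign convention: the input r matrix is signed with respect to the
  outcome table's allele coding; harmonization applies D r D over flipped
  SNPs. Under this convention every estimate is exactly invariant to
  re-coding any SNP's alleles consistently across the three input files
  (verified to 1e−12 in the suite). r²-based operations (uncorrelated
  selection, proxy thresholds) are coding-free.

## Harmonization

Palindromic SNPs are oriented by frequency only when both EAFs lie outside
0.5 ± `palindromic_eaf_window` (default 0.08, i.e. drop within [0.42,
0.58]); setting the window to 0.5 forces dropping all palindromes. Proxies
(r² ≥ 0.8) keep their own alleles and are oriented by frequency agreement
with the index SNP; an unorientable proxy is dropped, never guessed.
Harmonization is idempotent, and every drop carries a reason code
(`ambiguous_palindrome`, `allele_mismatch`, `missing_in_outcome`,
`duplicate`, `proxy_unorientable`) into the run log.

## Screens

Significance is strict (p < threshold, default 5×10⁻⁸). Instrument strength
uses F ≈ (β/SE)², the standard summary-data approximation (the
R²(n−2)/(1−R²) form is provided as an option); the cutoff of 10 is the usual
weak-instrument rule of thumb. "Uncorrelated" in top-k selection means
pairwise r² ≤ 0.1 by default — a choice, since no numeric convention is
universal — with greedy acceptance in p-value order and lexicographic tie
breaks, making the selection invariant to input row order. The confounder
screen uses the most conservative Bonferroni denominator, SNPs ×
confounders. Exclusion lists support a pass-through mode (`exclude=false`)
for outcomes where the flagged variants may lie on the causal pathway and
removing them would condition away real effect.

## Power approximation

For a case-control outcome (N total, case fraction K) and instruments
explaining R² of the exposure, the detectable OR per unit exposure is first
attenuated onto the observed 0/1 scale, b = K(OR/(1 + K(OR−1)) − 1), and
power = Φ(|b|√(N·R²)/√(K(1−K)) − z₁₋α/₂). The simpler
Φ(|ln OR|·√(N·K(1−K)·R²) − z) variant is provided (`method="log_or"`); at
the study scale (76,014/264,785, R² 0.15, OR 0.96) both give ≈ 0.97 ≥ 0.8.
The approximation is asymptotic and two-sided; it does not model instrument
weakness or pleiotropy.

## Synthetic data: what it emulates and what it does not

The generator works directly on the summary scale: γ̂ⱼ ~ N(γⱼ, σ_xj),
Γ̂ⱼ ~ N(θγⱼ + sign(γⱼ)αⱼ, σ_yj), with noise correlated across SNPs through
the Cholesky factor of an AR(1) LD matrix and independent between the two
samples (zero sample overlap). Per-SNP SEs follow the standard GWAS forms:
σ² = 1/(n·2f(1−f)) for unit-variance continuous traits and
1/(N·K(1−K)·2f(1−f)) on the log-odds scale for case-control outcomes, with
MAF f ~ U(0.05, 0.5). Exposure effects share the target R² equally
(γⱼ² · 2f(1−f) = R²/J) with random signs; pleiotropic effects αⱼ are defined
relative to the exposure-raising allele, since "directional" pleiotropy is
only meaningful in a fixed orientation. Default scenario parameters are the
study scale the estimators target: exposure GWAS n = 8631 with R² = 0.15,
47 correlated instruments (AR(1) ρ = 0.5), outcome sample 340,799 with case
fraction 76,014/340,799, θ = ln 0.97.

Deliberately **not** modeled: individual-level genotypes (summary-scale
simulation has the same asymptotic structure at a fraction of the cost),
winner's-curse selection of instruments, population stratification,
sample overlap, and confounder tables beyond uniform-null p-values. Passing
recovery tests therefore demonstrates estimator correctness under the
two-sample summary model's own assumptions — not robustness to the
selection and stratification artifacts of real GWAS pipelines.

The bundled instrument catalog (`make_instrument_catalog`) is a synthetic
stand-in reproducing only the accounting structure of a published
instrument list (173 genome-wide significant SNPs, 47 in the functional
genes FADS1/FADS2/NTAN1, plus sub-threshold rows); its ids and effect sizes
are generated, not published values.

## Breakdown sweep

`breakdown_sweep` locates the weighted median's invalid-weight breakdown
point. Because the breakdown point is an asymptotic (noise-free) property,
the sweep uses constant-strength instruments (per-allele effect 2.0 at MAF
0.25), which (i) makes all inverse-variance weights equal, so the invalid
*weight* share equals the invalid count share exactly, and (ii) keeps
outcome sampling noise at the scenario's sample size (500,000) an order of
magnitude below the bias tolerance, isolating pleiotropy-induced bias. With
directional pleiotropy of mean 0.05 on invalid SNPs, θ = 0.1, J = 100, and
a 5%·|θ| tolerance over 200 seeds, the largest passing fraction is 0.49 —
i.e. the estimator holds up to, and fails just past, half the weight.

## Problem sizes used in validation

Monte-Carlo calibration runs 500 seeds with J = 50 independent instruments
at large samples (exposure 500,000 — at the 8631 exposure scale,
regression-dilution from exposure-side noise is ≈ 1/F ≈ 4% and would
dominate the estimator's own bias; outcome 300,000): IVW mean bias is below
2% of θ = 0.1, 95% CI coverage within [92%, 98%], and type-I error at θ = 0
within [3%, 7%]. The recovery suite's weighted-median bootstrap is reduced
to 200 replicates; the point estimate is unaffected. The whole suite runs
in well under a minute on one CPU.

## Known limitations

* No MR-PRESSO, mode-based, multivariable, nonlinear, sex-specific, or
  bidirectional MR.
* Proxy LD uses the index SNP's row of the supplied matrix (adequate at
  r² ≥ 0.8, but an approximation).
* The exact component-retention rule for PCA-IVW is a convention
  (cumulative eigenvalue share ≥ 0.99); results at full retention equal
  direct GLS, and the retained count is always reported.
* The power formula's "attenuated" and "log_or" variants can differ for
  large effects; both are exposed.
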