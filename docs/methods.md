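# Methods note

This note records the statistical model, the default parameters (with
units and rationale), and the numerical decisions baked into the
implementation. It is written from the package's own point of view; the
code is the authority on exact behaviour.

## 1. The score

For a gene with m QC-passed SNPs carrying harmonized external effects
β ∈ ℝᵐ, let G be the n×m matrix of target-cohort allele counts (0/1/2,
missing entries mean-imputed per SNP) and R the Pearson correlation of
its columns, with spectral decomposition R = Q Λ Qᵀ. The LD-adjusted
weights are

    w = Q (Λ + kI)⁻¹ Qᵀ β,

and individual i's gene score is Σⱼ (gᵢⱼ − ḡⱼ) wⱼ.

Choices and their reasons:

- **Correlation, not covariance.** External betas are per-allele effects;
  R on the allele-count scale matches how marginal effects were
  estimated. The score multiplies *centered but unstandardized*
  genotypes by w — standardizing the genotypes would silently rescale
  each beta by the target cohort's SD.
- **Centering.** Makes the score location-free (a gene's score has mean
  exactly 0), so intercepts absorb nothing gene-specific, and a
  mean-imputed missing genotype contributes exactly 0.
- **Ridge k (default 1, dimensionless).** Dense imputed panels routinely
  contain perfectly collinear SNPs (λ = 0), where the k = 0 joint
  solution does not exist. Regularization acts *only* through k —
  eigenvalues are never truncated — so the map β → w is linear and
  transparent. Requesting k = 0 on a gene whose smallest eigenvalue is
  below 1e-8 is an error that names the gene and suggests a positive k,
  rather than a silent pseudo-inverse.
- **Reduction identities.** R = I, k = 0 gives w = β and the score equals
  the classical centered PRS exactly. This is the content of the "no-LD
  reduction": with finite samples the *estimated* R of uncorrelated SNPs
  is close to but not exactly I, so the exact identity is checked on
  1-SNP genes (where estimated R is exactly the 1×1 identity) plus the
  algebraic m > 1 reduction.

## 2. Association model

Per gene: `logit P(case) = b₀ + b₁·score + covariates`, fitted by
Newton/IRLS (statsmodels, tol 1e-8, ≤ 100 iterations); Wald p-value for
b₁ against the standard normal. Defaults: covariates age (years), sex
(0/1), PC1–PC3 (standardized genotype principal components);
gene-wide α = 2.5×10⁻⁶ (strict `<`; Bonferroni at ~20,000 genes).

Failure handling is deliberate:

- perfect/quasi separation → the fit is flagged `converged = False` with
  NaN beta/SE/p; finite numbers are never fabricated;
- a rank-deficient design raises an error naming the collinear columns
  (found by QR with column pivoting); inside a scan this downgrades to a
  per-gene non-converged flag so one degenerate gene cannot kill a run;
- a single-class outcome is a hard error.

The conditional scan adds the condition genes' scores as covariates and
excludes them from the scanned set; results tables carry one
`*_cond_<genes>` block per conditioning set, with NA in a condition
gene's own row.

## 3. Upstream pipeline defaults

| stage | parameter | default | rationale |
|---|---|---|---|
| hard-call | max genotype probability | ≥ 0.9 (inclusive) | conventional certainty cut; below it the call is missing |
| QC | INFO | keep ≥ 0.4 | standard post-imputation floor; exactly 0.4 kept |
| QC | MAF | keep ≥ 0.01 | rare variants make R unstable; exactly 0.01 kept |
| QC | missingness | remove ≥ 0.05 | exactly 0.05 removed |
| QC | HWE exact p | remove < 1e-6, controls only | cases may deviate through real association; exact test, no mid-p |
| harmonize | ambiguity | A/T and C/G SNPs always dropped | strand unresolvable from labels, even when they agree |
| harmonize | strand rescue | on | complement-and-match before declaring mismatch; flips invert the beta sign |
| windows | upstream/downstream | 35 kb / 10 kb, strand-aware | captures proximal regulation; minus-strand windows mirrored |
| genes | filter | KNOWN + protein_coding (case-insensitive) | well-annotated genes only |
| scan | α | 2.5e-6 | ~20,000-gene Bonferroni |

Filter attribution uses the fixed order info → maf → missingness → hwe;
the kept set is an AND of all four verdicts and does not depend on the
order. All intervals are 1-based and closed; window starts clamp at 1.

## 4. Synthetic study generator

The generator is the package's laboratory: two independent cohorts
(discovery → summary statistics via per-SNP logistic scans; target →
individual genotypes), sharing one population.

- **LD**: per block, each haplotype's latent Gaussian vector is AR(1)
  with parameter rho (default 20 blocks × 10 SNPs, rho 0.7); the
  haplotype carries the counted allele where the latent value falls below
  Φ⁻¹(MAF). Thresholding attenuates the latent rho; the expected allele
  correlation is the exact bivariate-normal orthant probability, which
  the tests verify.
- **Population structure**: two equal subpopulations with Balding-Nichols
  frequency divergence (fst default 0.01) and a PC1 contribution to
  liability (default 0.5), so principal-component covariates matter.
- **Phenotype**: liability threshold — liability = Σ β·g + structure +
  N(0,1), cases above the empirical (1 − case fraction) quantile
  (default case fraction 0.3).
- **Imputation noise**: genotype-probability triples
  (1 − η)·onehot(g) + η·Dirichlet(10·uniform), η default 0.1. The INFO
  score is Var(expected dosage) / (Var(expected dosage) + mean
  per-sample dosage variance) — the law-of-total-variance decomposition
  of the true-dosage variance — which is exactly 1 at η = 0 and decays
  monotonically with η.
- **Reproducibility**: all randomness flows from one master seed through
  named substreams (`default_rng([stream_id, seed])`), so cohorts are
  independent but individually reproducible, and any stage can be
  regenerated without the others.

Acceptance studies use these deliberately simplified settings: the fully
null calibration study switches structure and noise off (fst = 0, PC
liability 0, η = 0) so p-values should be exactly uniform; the power
study plants one causal gene (3 SNPs, per-allele liability effect 0.3,
n_target = 4000) among 19 null genes; the conditional study widens SNP
spacing to 20 kb so an overlapping gene's window captures a proper subset
of the causal block (correlated but not collinear scores).

## 5. Numerical details worth knowing

- The HWE exact test uses the het-count recurrence conditioned on allele
  counts, with periodic rescaling (threshold 1e250) so extreme counts
  (e.g. 500/0/500) neither overflow nor lose the tail; agreement with a
  log-gamma enumeration oracle is ~1e-14 absolute over all triples n ≤ 50.
- Hard-calling at exactly the 0.9 boundary keeps the call (tolerance
  1e-12); argmax ties resolve to the lower genotype.
- The PLINK 1 .bed codec (SNP-major, 2-bit) is implemented directly with
  a 256×4 lookup table; read/write round-trips are tested for
  non-multiple-of-4 sample counts and missing calls.
- The correlation matrix is symmetrized, its diagonal pinned to 1, and
  eigenvalues within 1e-8 below zero clipped to 0; anything lower raises.
- Score/weight computations are exact linear algebra — the dense oracle
  comparison agrees to ~1e-16, far inside the 1e-8 acceptance tolerance.
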