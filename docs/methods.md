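# Methods

## Model and scope

The package treats a quantitative trait under the standard multi-variant
linear model y = Xβ + e and computes LASSO solutions
min (1/2)‖y − Xβ‖² + λ‖β‖₁ for the full range of the tuning parameter λ,
using only (i) per-variant GWAS summary statistics and (ii) an
individual-level reference panel for LD. Two approximations connect the
summary statistics to the quantities the path algorithm needs:

1. **Variant–trait covariance.** From the marginal (univariate) fit of
   each variant, b̂ⱼ ≈ Cov(Xⱼ,y)/Var(Xⱼ) and se²ⱼ ≈ σ²ᵣ/(nⱼ·Var(Xⱼ)).
   When single-variant effects are small, the univariate residual
   variance σ²ᵣ is close to the phenotypic variance σ², giving
   Cov(Xⱼ,y) ≈ b̂ⱼσ²/(se²ⱼnⱼ) with every term except σ² published. The
   per-variant nⱼ makes heterogeneous sample sizes (imputation failures
   across contributing cohorts) harmless, because each covariance is
   reconstructed separately.
2. **LD.** Var(X) is estimated by the reference panel's empirical dosage
   covariance; the path uses the correlation matrix B and the diagonal
   variances D_W (standardized scale). Coefficients are mapped back to
   per-allele units by D_W^(−1/2).

σ² enters only as a global scale: every λ and every coefficient is
proportional to it, so σ² = 1 is the default and exact-scale coefficients
require only the validation/reference phenotypic variance.

The method is intended for *regional* analysis (windows around known
loci). Genome-wide paths are out of scope: LASSO is more sensitive to LD
estimation error than single-step conditional methods, and accumulated
error grows with the number of active variants.

## Path algorithm and numerical choices

The homotopy algorithm alternates hitting times (variant enters) and
crossing times (active coefficient reaches zero), both closed-form in
(C, B); the next breakpoint is the largest candidate below the current λ
("max+"), ties between a hit and a cross resolving to the hit.

* **max+ guard.** Candidates must be below λₖ by a relative 1e-12. A
  candidate exactly *at* λₖ is admitted unless it belongs to the variant
  of the event just processed: this one-variant exclusion prevents
  replaying the previous event (the purpose of strictness) while letting
  exactly tied covariances — e.g. duplicated columns of a test design —
  enter on consecutive events at equal λ instead of being dropped
  forever. With ties, λ is therefore non-increasing rather than strictly
  decreasing.
* **Active-set solves.** Each event re-solves B_A x = r by Cholesky
  factorization, retrying once with 1e-8 diagonal jitter, and raising a
  numerical error naming the active ids if that fails. At regional scale
  (tens to a few hundred variants after pruning) re-factorizing per event
  is cheap and avoids the bookkeeping of incremental up/down-dating; the
  r² > 0.9 pruning step is the primary guard against near-singular B_A
  as λ → 0.
* **Degenerate directions.** Hitting/crossing denominators below 1e-10
  in absolute value are skipped: they correspond to directions already
  spanned by the active set.
* **Entering coefficients.** At its own breakpoint an entering variant's
  coefficient is analytically zero and is stored as exact zero; the KKT
  audit treats coefficients within its tolerance of zero under the
  inactive condition, the weaker (always valid) form at a boundary.
* **Termination.** At λ = 0 (where the active-set solution is the
  unpenalized joint fit), at a caller-supplied λ_min or active-set cap,
  after 20p events, or when no admissible candidate remains. The cap
  defaults to min(p, n_ref − 1) so the final model stays identifiable
  with respect to the panel.

## Per-locus selection pipeline

For a locus: take a closed 1 Mb window (1-based positions) centered on
the top variant; intersect summary and panel variants; prune pairs with
r² > 0.9 keeping the smaller GWAS p value (greedy in ascending p, which
reproduces the pairwise keep-the-more-significant rule deterministically);
run the path; score each breakpoint's active set in a validation cohort;
report the breakpoint maximizing validation R², taking the earliest
(sparsest) breakpoint under exact ties.

Validation R² is the squared Pearson correlation between the polygenic
score (dosages × penalized effects) and the phenotype — invariant to
affine rescaling of the score, so shrunken effects measure the same
predictable variance as refit ones. Variants missing from the validation
cohort are dropped from scoring, not imputed, with a logged count. When
no independent validation sample exists, the reference panel (with its
phenotype) can serve as the validation cohort: it contributes little to
meta-analysis effect estimates, so the tuning choice remains essentially
out of sample. Across loci, `aggregate_loci` reports both the sum of
regional R² (valid for nearly independent scores) and the joint multiple
regression R² (robust to score collinearity).

Panels below 5,000 individuals trigger a warning, not an error: small
public panels are usable regionally, at the cost of noisier LD.

## Generalized degrees of freedom

For y = μ + ε, Cov(ε) = σ²I and a fitting procedure f, the GDF is
df(f) = Σᵢ Cov(fᵢ(y), yᵢ)/σ². The estimator draws independent replicate
responses around a known μ (the natural choice in a synthetic setting;
on real data, where μ is unknown, a data-perturbation estimator would be
required instead), computes per-coordinate sample covariances across
replicates, and attaches a leave-one-replicate-out jackknife standard
error. σ² is an input, never estimated internally.

Three fitter families are built in:

* **Fixed-column OLS** — a projection, df = rank, used as the analytic
  calibration case.
* **LASSO at k selected** — the fit at a *fixed* λₖ, calibrated once
  from pilot replicates so the average active-set size equals k (ties in
  the calibration grid resolve to the plateau midpoint). The fixed-λ
  construction matters: the number of active LASSO coefficients at fixed
  λ is an unbiased estimate of the fit's degrees of freedom, so this
  selector costs ≈ k GDF. Truncating each replicate's path at its own
  k-th entry is a different procedure — its fitted values depend on the
  response only through breakpoint differences and cost well under k —
  and is not what "a k-variant LASSO model" means here.
* **Stepwise at k selected** — forward selection of k variants by
  residual correlation with an unpenalized OLS refit; the selection
  search is what pushes its GDF above k on correlated designs.

## Synthetic data

`simulate_genotypes` produces biallelic dosages whose *population*
correlation is exactly ρ^|i−j|: a latent Gaussian with tetrachorically
pre-inflated correlations (sin(πr/2) at allele frequency 0.5, numeric
inversion of the bivariate-normal orthant probability otherwise) is
dichotomized at the frequency quantile per haplotype and two haplotypes
are summed. Without the inversion, dichotomization would attenuate an
AR(1) latent correlation of 0.8 to ≈ 0.59 between adjacent dosages.

The two-causal benchmark trait is y = β₁X_c1 + β₂X_c2 + e with demeaned
causal columns and e ~ N(0, σ²); defaults β₁ = 5, β₂ = ±1, σ² = 50,
p = 20, ρ = 0.8, allele frequencies 0.5, 200 datasets per scenario, and
causal lags 1/3/7 realizing causal-pair LD of 0.8/0.512/0.21. The default
cohort size is n = 10,000 per dataset — a deliberate reduction from the
hundreds of thousands typical of meta-analyses, keeping a full benchmark
in minutes on one core; n is a scenario knob.

`summary_from_cohort` fits each variant by exact univariate OLS
(`se_method="ols"`), with a `"large-sample"` option that uses
se² = σ²/(n·Var(Xⱼ)) — the approximation under which the covariance
reconstruction, and hence the whole summary-level path, is *exactly*
equal to the individual-level LASSO. With exact OLS standard errors the
reconstruction carries a relative error of order r²ⱼ (the σ²ᵣ ≈ σ²
approximation), which at n = 2,000 puts summary and individual
coefficients within ~1e-3 rather than machine precision; both regimes
are covered by tests. Per-variant subsampling emulates meta-analyses
with unequal sample sizes.

What the generator does **not** emulate: minor-allele-frequency spectra,
genotyping/imputation error, population structure and relatedness,
strand ambiguity, multi-allelic sites, non-Gaussian traits, and LD
beyond the stationary ρ^|i−j| block. Passing tests therefore certify the
algebra and the selection behavior under idealized LD, not robustness to
real-data artifacts such as mismatched reference populations.

## Benchmark design and scoring

Both selectors see the same inputs per replicate: summary statistics
computed from the simulated cohort with the whole cohort as reference
panel. ROC curves are threshold-free: a variant's score is the most
permissive threshold at which its method would select it —

* summary LASSO: the λ at which the variant first enters the path;
* stepwise: the smallest p-value gate admitting it, which is the
  *running maximum* of conditional entry p values up to its entry (a
  gate t stops the forward search at the first step whose best candidate
  p ≥ t, so a sharp signal unmasked late is still gated by the weakest
  earlier step).

Scores are pooled over replicates with the two causal variants as
positives; AUC is the trapezoidal area. The stepwise comparator is the
minimal summary-level conditional-and-joint selector (greedy forward
addition by conditional p, backward removal of jointly non-significant
variants, r² > 0.9 collinearity guard matching the pruning applied on
the LASSO side); it does not reproduce every implementation detail of
existing conditional-analysis software. Superiority of the LASSO
selector is the expected outcome in most LD configurations, with a known
exception when β₁β₂·r_LD < 0 and r_LD is large. The benchmark's ranking
in the high-LD *same-sign* configuration is sensitive to cohort size: at
the package's reduced default scale the conditional signal of the
secondary variant is an order of magnitude weaker than at meta-analysis
scale, and the shipped benchmark shows the stepwise selector ahead in
that one scenario while the LASSO leads in the others.

## Other design choices

* Column dialect: COJO `.ma` (`SNP A1 A2 freq b se p N`), optional
  `CHR`/`BP`, arbitrary headers via a column map. Missing coordinates
  fall back to file order so coordinate-free tables remain usable.
* Invalid summary rows are dropped and counted per reason rather than
  raising; meta-analysis exports routinely contain a few malformed rows.
* Allele alignment matches by allele pair only; no strand complementing
  or frequency-based resolution is attempted. Dropping strand-ambiguous
  A/T–C/G variants is opt-in.
* The sample-size filter (keep N ≥ 2/3 of the input maximum) and MAF
  filter are each idempotent; they commute whenever the maximum-N record
  survives the MAF filter, which the MAF-first pipeline order guarantees
  (the order-dependence is inherent to defining the threshold relative
  to the input table).
* All simulation entry points accept a seed or Generator; CLI runs write
  a JSON manifest with version, configuration and seed.

## Limitations

* LD pruning at r² > 0.9 means one of two near-duplicate signals is
  reported; the selected variant tags, rather than identifies, its
  pruned partner.
* The equivalence to individual-level LASSO is exact only under the
  large-sample standard-error convention; with exact OLS standard errors
  the approximation error scales with per-variant explained variance.
* Tuning by a single validation sample is noisier than cross-validation
  (impossible without individual-level discovery data); resampling-based
  stabilization is not implemented.
* Biallelic SNPs only; no liftover, INDEL normalization, or multi-allelic
  handling.
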