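# sojo — summary-statistics LASSO for multi-variant locus analysis

Genome-wide association studies (GWAS) publish per-variant *summary
statistics* — marginal effect sizes, standard errors, allele frequencies,
p values and sample sizes — while the individual-level genotypes stay
behind access barriers. Yet many trait-associated loci harbor more than
one causal variant (allelic heterogeneity), and identifying those extra
signals requires a *joint* multi-variant model. The standard tool for
this, forward stepwise conditional selection (GCTA-COJO style), is greedy:
it tends to discard informative variants that are correlated with ones
already selected.

`sojo` implements the alternative: the full LASSO solution path computed
**directly from summary statistics** plus a linkage-disequilibrium (LD)
reference panel, so penalized multi-variant selection and shrinkage
estimation are available without any individual-level discovery data.

## The method

For a centered trait y and genotypes X, the LASSO solves

    min_b  (1/2) ||y − X b||² + λ ||b||₁ ,        λ ≥ 0.

The solution path β̂(λ) is piecewise linear, and in the large-sample limit
the path algorithm depends on the data only through

* **C** — standardized variant–trait covariances, reconstructed per
  variant from summary statistics as
  `Cov(Xj, y) = b̂j σ² / (se_j² N_j)` (each variant with its own N, so
  heterogeneous per-variant sample sizes are handled), scaled by the
  reference-panel dosage standard deviation;
* **B** — the LD correlation matrix estimated from a reference panel
  (a subcohort of the meta-analysis, or an external panel).

Starting at λ₀ = ∞ with an empty active set A, the path alternates

* **hitting events** — variant j enters A with sign s at
  `λ = (Cj − B_{jA} B_A⁻¹ C_A) / (s − B_{jA} B_A⁻¹ s_A)`
  (from the empty set: λ₁ = max_j |Cj|);
* **crossing events** — active variant j leaves A when its coefficient
  crosses zero at `λ = [B_A⁻¹ C_A]_j / [B_A⁻¹ s_A]_j`
  (at the first step the crossing time is 0 by definition);

taking at each step the largest admissible candidate below the current λ
and solving `β̂_A(λ) = B_A⁻¹ (C_A − λ s_A)` on each segment. With the whole
cohort as its own reference the result is identical to the
individual-level LASSO — the package's test suite verifies this against a
coordinate-descent solver to < 1e-4 at every breakpoint.

On top of the path, the package provides:

* a **per-locus pipeline**: 1 Mb windows around top GWAS hits,
  r² > 0.9 LD pruning (keeping the more significant variant), path
  computation, and tuning-parameter choice by out-of-sample polygenic-score
  R² in a validation cohort, with cumulative/joint aggregation across loci;
* a **generalized-degrees-of-freedom (GDF)** estimator
  `df(f) = Σᵢ Cov(fᵢ(y), yᵢ)/σ²` by Monte Carlo, quantifying the effective
  model complexity of whole select-and-fit procedures — the LASSO spends
  ~1 GDF per selected variant, stepwise selection on correlated designs
  spends more;
* a **simulation benchmark**: two correlated causal variants in an AR(1)
  LD block (`cor(Xi, Xj) = ρ^|i−j|`), comparing the summary LASSO against
  a summary-level stepwise conditional selector by ROC/AUC over replicate
  datasets.

## Worked example

```python
import numpy as np
import sojo

rng = np.random.default_rng(11)
n_disc, n_val, p = 20_000, 5_000, 12
X = sojo.simulate_genotypes(n_disc + n_val, p, rho=0.8, maf=0.3, rng=rng)
beta = np.zeros(p)
beta[[3, 7]] = 0.08, 0.06            # two causal variants in LD
y = (X - X.mean(0)) @ beta + rng.normal(0, 1, len(X))
Xd, yd = X[:n_disc], y[:n_disc]      # "published" GWAS cohort
Xv, yv = X[n_disc:], y[n_disc:]      # independent validation cohort

table = sojo.summary_from_cohort(Xd, yd, rng=rng)  # GWAS summary statistics
panel = sojo.panel_from_matrix(Xd)                 # LD reference panel
path = sojo.run_path(sojo.build_inputs(table, panel))
print(f"{path.n_events} breakpoints; first four events:")
for ev in path.events[:4]:
    print(f"  step {ev.k}: lambda={ev.lam:.5f}  {ev.kind} {ev.variant}")

top = table.records.loc[table.records["pvalue"].idxmin(), "id"]
validation = sojo.ValidationCohort(Xv, yv, panel.ids)
res = sojo.run_locus(table, panel, validation, sojo.LocusSpec(top, "1", 0, 10**6))
print(f"selected {res.n_selected} variants, validation R2={res.best_r2:.4f}")
print(f"top-variant-only validation R2="
      f"{sojo.validation_r2(validation, [top], [1.0]):.4f}")
```

prints

```
13 breakpoints; first four events:
  step 1: lambda=0.06049  hit v4
  step 2: lambda=0.05790  hit v8
  step 3: lambda=0.03058  hit v7
  step 4: lambda=0.00696  hit v9
selected 7 variants, validation R2=0.0029
top-variant-only validation R2=0.0012
```

The two causal variants (`v4` and `v8`, 0-based columns 3 and 7) enter
the path first and carry the largest penalized effects; choosing the
tuning parameter by validation R² more than doubles the phenotypic
variance explained relative to reporting the top variant alone — the
practical payoff of modeling allelic heterogeneity.

A command-line interface mirrors the library:

```bash
sojo simulate --n 20000 --p 12 --seed 11 --out cohort/
sojo path   --summary cohort/summary.ma --panel-genotypes cohort/genotypes.tsv \
            --panel-meta cohort/variants.tsv --out path/
sojo locus  --summary cohort/summary.ma ... --top-snp v4 --out locus/
sojo gdf    --design cohort/genotypes.tsv --selector lasso --k-grid 1:10 --out gdf.tsv
sojo bench  --scenario scenario.yaml --out bench/
```

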