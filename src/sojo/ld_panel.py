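"""Reference genotype panels and LD (linkage disequilibrium) structure.

The regularization path needs two summary-level inputs: the standardized
variant-trait covariances ``C`` and the LD correlation matrix ``B``.  LD is
estimated from a reference cohort genotyped at the individual level — a
subcohort of the meta-analysis, or an external panel such as 1000 Genomes —
as the empirical correlation matrix of allele dosages.  ``D_W`` holds the
panel's per-variant dosage variances, which map coefficients between the
standardized and the per-allele (original) scale.

Dosage variances are the panel's empirical variances, not 2f(1-f) under
Hardy-Weinberg equilibrium, so imputed (fractional) dosages are handled
unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .summary_io import SummaryInputError, SummaryTable, marginal_covariances

__all__ = [
    "ReferencePanel",
    "StandardizedInputs",
    "load_panel",
    "ld_structure",
    "build_inputs",
    "cohort_inputs",
    "prune_r2",
]

#: panels smaller than this draw an accuracy warning (LD from a few hundred
#: samples is usable regionally but noisier)
MIN_RECOMMENDED_PANEL = 5000


class PanelLookupError(KeyError):
    """A requested variant id is absent from the panel."""


@dataclass
class ReferencePanel:
    """An ``n_W x p`` dosage matrix with per-variant metadata.

    ``variant_meta`` columns: ``id chrom pos counted_allele other_allele``,
    one row per genotype column, ids unique.  Dosages count copies of the
    counted allele in [0, 2] (fractional for imputed data).  Monomorphic
    columns are rejected at construction; missing dosages must already be
    imputed (see :func:`load_panel`).
    """

    genotypes: np.ndarray
    variant_meta: pd.DataFrame
    report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D matrix")
        if self.genotypes.shape[0] < 2:
            raise ValueError("a reference panel needs at least 2 individuals")
        if self.genotypes.shape[1] != len(self.variant_meta):
            raise ValueError("variant_meta rows must match genotype columns")
        if self.variant_meta["id"].duplicated().any():
            raise ValueError("panel variant ids must be unique")
        if np.any(np.var(self.genotypes, axis=0) == 0):
            raise ValueError("monomorphic columns must be removed before construction")
        self.variant_meta = self.variant_meta.reset_index(drop=True)
        if self.n_individuals < MIN_RECOMMENDED_PANEL:
            warnings.warn(
                f"reference panel has {self.n_individuals} individuals; "
                f"LD estimates are more accurate with >= {MIN_RECOMMENDED_PANEL} "
                "(small panels remain usable for regional analysis)",
                stacklevel=2,
            )

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    @property
    def ids(self) -> np.ndarray:
        return self.variant_meta["id"].to_numpy()

    def column_indices(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([lookup[v] for v in ids], dtype=int)
        except KeyError as exc:
            raise PanelLookupError(f"variant {exc.args[0]!r} not in panel") from exc

    def phenotypic_variance_of(self, y) -> float:
        return float(np.var(np.asarray(y, float), ddof=1))


def load_panel(genotypes=None, variant_meta=None, genotype_path=None, meta_path=None) -> ReferencePanel:
    """Build a :class:`ReferencePanel` from arrays or delimited text files.

    ``genotype_path`` is a whitespace/tab-delimited individuals x variants
    dosage matrix (header row of variant ids, ``NA``/empty for missing);
    ``meta_path`` a sidecar table with columns
    ``id chrom pos counted_allele other_allele``.  Missing dosages are
    mean-imputed per column before any variance computation; monomorphic
    columns are removed and counted in the report.
    """
    if genotype_path is not None:
        geno_df = pd.read_csv(genotype_path, sep=r"\s+")
        meta = pd.read_csv(meta_path, sep=r"\s+", dtype={"id": str, "chrom": str})
        meta = meta.set_index("id").loc[list(geno_df.columns)].reset_index()
        genotypes = geno_df.to_numpy(dtype=float)
        variant_meta = meta
    genotypes = np.asarray(genotypes, dtype=float)
    variant_meta = variant_meta.reset_index(drop=True).copy()
    variant_meta["id"] = variant_meta["id"].astype(str)

    report: dict[str, int] = {}
    # mean imputation of missing dosages, per column
    n_missing = int(np.isnan(genotypes).sum())
    if n_missing:
        col_means = np.nanmean(genotypes, axis=0)
        idx = np.where(np.isnan(genotypes))
        genotypes = genotypes.copy()
        genotypes[idx] = np.take(col_means, idx[1])
        report["imputed_dosages"] = n_missing

    variances = np.var(genotypes, axis=0)
    poly = variances > 0
    if not poly.any():
        raise SummaryInputError("all panel columns are monomorphic")
    if not poly.all():
        report["monomorphic_removed"] = int((~poly).sum())
        genotypes = genotypes[:, poly]
        variant_meta = variant_meta[poly].reset_index(drop=True)
    return ReferencePanel(genotypes, variant_meta, report)


@dataclass
class StandardizedInputs:
    """Summary-level inputs to the path algorithm on the standardized scale.

    ``C[j]`` is the covariance between the standardized dosage of variant j
    and the trait; ``B`` the LD correlation matrix (symmetric, unit
    diagonal); ``d_w`` the reference dosage variances mapping back to the
    per-allele scale; ``sigma2`` the phenotypic variance convention the C
    entries were computed under; ``n_ref`` the reference panel size (used
    only to cap the maximum active-set size).
    """

    C: np.ndarray
    B: np.ndarray
    d_w: np.ndarray
    sigma2: float
    ids: np.ndarray
    n_ref: int | None = None

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        self.d_w = np.asarray(self.d_w, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        p = len(self.C)
        if self.B.shape != (p, p) or len(self.d_w) != p or len(self.ids) != p:
            raise ValueError("inconsistent input dimensions")
        if not np.allclose(np.diag(self.B), 1.0, atol=1e-10):
            raise ValueError("B must have a unit diagonal")
        if np.any(self.d_w <= 0):
            raise ValueError("d_w must be strictly positive")

    @property
    def p(self) -> int:
        return len(self.C)

    def index_of(self, ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        return np.array([lookup[v] for v in ids], dtype=int)

    def subset(self, indices) -> "StandardizedInputs":
        idx = np.asarray(indices, dtype=int)
        return replace(
            self,
            C=self.C[idx],
            B=self.B[np.ix_(idx, idx)],
            d_w=self.d_w[idx],
            ids=self.ids[idx],
        )


def _condition_correlation(B: np.ndarray) -> np.ndarray:
    """Exact symmetrization and [-1, 1] clipping of a sample correlation."""
    B = np.asarray(B, dtype=float)
    B = (B + B.T) / 2.0
    B = np.clip(B, -1.0, 1.0)
    np.fill_diagonal(B, 1.0)
    return B


def ld_structure(panel: ReferencePanel, ids) -> tuple[np.ndarray, np.ndarray]:
    """LD correlation matrix and dosage variances for the requested ids.

    ``d_w[j]`` is the sample variance (ddof=1) of the dosage column; ``B``
    the sample correlation matrix, symmetrized and clipped to [-1, 1].
    """
    idx = panel.column_indices(ids)
    G = panel.genotypes[:, idx]
    d_w = np.var(G, axis=0, ddof=1)
    if len(idx) == 1:
        B = np.ones((1, 1))
    else:
        B = _condition_correlation(np.corrcoef(G, rowvar=False))
    return B, d_w


def build_inputs(
    table: SummaryTable, panel: ReferencePanel, sigma2: float | None = None
) -> StandardizedInputs:
    """Assemble ``(C, B, d_w)`` from an allele-aligned table and a panel.

    ``C[j]`` composes the marginal-covariance reconstruction with the
    standardization by the reference dosage standard deviation.  ``sigma2``
    defaults to the table's ``trait_sigma2``, else 1.0.
    """
    shared = [v for v in table.ids if v in set(panel.ids)]
    if not shared:
        raise SummaryInputError("summary table and panel share no variants")
    table = table.subset(shared)
    if sigma2 is None:
        sigma2 = table.trait_sigma2 if table.trait_sigma2 is not None else 1.0
    B, d_w = ld_structure(panel, table.ids)
    cov = marginal_covariances(table, sigma2)
    C = cov / np.sqrt(d_w)
    return StandardizedInputs(
        C=C, B=B, d_w=d_w, sigma2=float(sigma2), ids=table.ids, n_ref=panel.n_individuals
    )


def cohort_inputs(X, y, ids=None) -> StandardizedInputs:
    """Exact standardized inputs from individual-level data.

    Uses the cohort itself as its own reference: ``C`` is the empirical
    covariance between each standardized genotype column and the trait and
    ``B`` the genotype correlation matrix (both ddof=1).  With these inputs
    the summary-level path is algebraically identical to the
    individual-level LASSO on standardized genotypes — useful for oracles
    and for the degrees-of-freedom machinery, where the full cohort is
    available by construction.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if ids is None:
        ids = np.array([f"v{j + 1}" for j in range(p)], dtype=object)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    d_w = (Xc**2).sum(axis=0) / (n - 1)
    C = (Xc.T @ yc) / (n - 1) / np.sqrt(d_w)
    B = _condition_correlation(np.corrcoef(Xc, rowvar=False)) if p > 1 else np.ones((1, 1))
    sigma2 = float(np.var(y, ddof=1))
    return StandardizedInputs(C=C, B=B, d_w=d_w, sigma2=sigma2, ids=ids, n_ref=n)


def prune_r2(
    inputs: StandardizedInputs, pvalues, r2_max: float = 0.9
) -> StandardizedInputs:
    """Greedy LD pruning: keep the more significant variant of each r²-tied pair.

    Variants are visited in ascending (pvalue, id) order; one is kept iff
    its squared correlation with every already-kept variant is <= ``r2_max``.
    Besides limiting redundancy, this guards the active-set solves against
    near-singular LD as the tuning parameter approaches zero.
    """
    pvalues = np.asarray(pvalues, dtype=float)
    if len(pvalues) != inputs.p:
        raise ValueError("pvalues must align with inputs.ids")
    order = np.lexsort((inputs.ids.astype(str), pvalues))
    r2 = inputs.B**2
    kept: list[int] = []
    for j in order:
        if all(r2[j, k] <= r2_max for k in kept):
            kept.append(j)
    kept_idx = np.sort(np.array(kept, dtype=int))
    return inputs.subset(kept_idx)
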