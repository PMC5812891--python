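"""Per-locus selection pipeline and polygenic-score aggregation.

For each established locus (a 1 Mb window centered on the most significant
GWAS variant, by default), the pipeline: (1) intersects the summary table
with the reference panel within the window, (2) estimates LD from the
panel, (3) prunes one of each variant pair with r² > 0.9 (keeping the more
significant), (4) runs the summary-level LASSO path, (5) computes the
out-of-sample R² of the active-set polygenic score at every breakpoint in
a validation cohort, and (6) reports the breakpoint that maximizes the
validation R² together with the selected variants and their penalized
per-allele effects.

When no independent validation cohort exists, the reference panel can
double as the validation sample: it contributes only marginally to the
meta-analysis effect estimates, so the tuning-parameter choice remains
essentially out-of-sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld_panel import ReferencePanel, build_inputs, prune_r2
from .lasso_path import LassoPath, run_path
from .summary_io import SummaryTable

__all__ = [
    "LocusSpec",
    "ValidationCohort",
    "LocusResult",
    "define_locus",
    "run_locus",
    "validation_r2",
    "aggregate_loci",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusSpec:
    """A genomic window centered on a locus's most significant variant."""

    top_variant: str
    chrom: str
    center_pos: int
    window_bp: int = 1_000_000

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")

    @property
    def start(self) -> int:
        # windows are closed 1-based intervals, truncated at position 1
        return max(1, self.center_pos - self.window_bp // 2)

    @property
    def end(self) -> int:
        return self.center_pos + self.window_bp // 2


@dataclass
class ValidationCohort:
    """Individual-level dosages and a pre-adjusted, standardized phenotype."""

    genotypes: np.ndarray
    phenotype: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        self.ids = np.asarray(self.ids, dtype=object)
        if self.genotypes.shape[0] != len(self.phenotype):
            raise ValueError("genotype rows must match phenotype length")
        if self.genotypes.shape[1] != len(self.ids):
            raise ValueError("genotype columns must match ids")
        if np.var(self.phenotype) <= 0:
            raise ValueError("phenotype variance must be positive")


@dataclass
class LocusResult:
    """Selected variants and the validation-R² profile along the path."""

    selected_ids: np.ndarray
    penalized_effects: np.ndarray  # original (per-allele) scale
    r2_profile: np.ndarray  # one entry per path event
    best_event: int  # first maximum of r2_profile
    n_selected: int
    best_lambda: float | None = None
    path: LassoPath | None = None
    report: dict = field(default_factory=dict)

    @property
    def best_r2(self) -> float:
        return float(self.r2_profile[self.best_event]) if len(self.r2_profile) else 0.0

    def selected_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"id": self.selected_ids, "penalized_effect": self.penalized_effects}
        )


def _empty_result(report=None) -> LocusResult:
    return LocusResult(
        selected_ids=np.array([], dtype=object),
        penalized_effects=np.array([]),
        r2_profile=np.array([0.0]),
        best_event=0,
        n_selected=0,
        report=report or {},
    )


def define_locus(
    table: SummaryTable, top_variant: str, window_bp: int = 1_000_000
) -> tuple[LocusSpec, list]:
    """Window the table around ``top_variant`` and list the member variants."""
    df = table.records
    row = df[df["id"] == top_variant]
    if row.empty:
        raise KeyError(f"top variant {top_variant!r} not in summary table")
    chrom = str(row["chrom"].iloc[0])
    center = int(row["pos"].iloc[0])
    spec = LocusSpec(top_variant=top_variant, chrom=chrom, center_pos=center, window_bp=window_bp)
    member = df[
        (df["chrom"] == chrom) & (df["pos"] >= spec.start) & (df["pos"] <= spec.end)
    ]
    return spec, member["id"].tolist()


def validation_r2(validation: ValidationCohort, ids, effects) -> float:
    """Squared Pearson correlation between a polygenic score and the phenotype.

    The score is ``dosages @ effects`` over the supplied variants; the
    squared correlation is invariant to any affine rescaling of the score,
    so penalized (shrunken) effects measure the same predictable variance
    as their refit counterparts.  Returns 0.0 for a constant score.
    """
    ids = np.asarray(ids, dtype=object)
    effects = np.asarray(effects, dtype=float)
    if len(ids) == 0:
        return 0.0
    lookup = {v: i for i, v in enumerate(validation.ids)}
    idx = np.array([lookup[v] for v in ids], dtype=int)
    score = validation.genotypes[:, idx] @ effects
    if np.var(score) == 0:
        return 0.0
    r = np.corrcoef(score, validation.phenotype)[0, 1]
    return float(r**2)


def run_locus(
    table: SummaryTable,
    panel: ReferencePanel,
    validation: ValidationCohort | None,
    spec: LocusSpec,
    r2_prune: float = 0.9,
    sigma2: float | None = None,
    lambda_min: float = 0.0,
    max_active: int | None = None,
    max_steps: int | None = None,
) -> LocusResult:
    """Execute the per-locus selection procedure (steps 1-6 above).

    Tuning requires phenotypes, so a :class:`ValidationCohort` is always
    needed; when no independent sample exists, build one from the reference
    panel's genotypes and its phenotype (the panel-as-validation setting).
    Variants absent from the validation cohort are dropped from scoring
    (not imputed) and counted in the result's report.
    """
    report: dict = {}
    spec2, member_ids = define_locus(table, spec.top_variant, spec.window_bp)
    locus_table = table.subset(member_ids)
    shared = [v for v in locus_table.ids if v in set(panel.ids)]
    report["n_window"] = len(member_ids)
    report["n_intersect"] = len(shared)
    if not shared:
        return _empty_result(report)
    locus_table = locus_table.subset(shared)

    inputs = build_inputs(locus_table, panel, sigma2=sigma2)
    pvals = locus_table.records.set_index("id").loc[inputs.ids, "pvalue"].to_numpy()
    inputs = prune_r2(inputs, pvals, r2_max=r2_prune)
    report["n_after_prune"] = inputs.p
    if inputs.p == 0:
        return _empty_result(report)

    path = run_path(inputs, lambda_min=lambda_min, max_active=max_active, max_steps=max_steps)
    if path.n_events == 0:
        return _empty_result(report)

    if validation is None:
        raise ValueError(
            "a validation cohort is required; build one from the reference "
            "panel genotypes if no independent sample is available"
        )
    val_id_set = set(validation.ids)
    missing = [v for v in inputs.ids if v not in val_id_set]
    if missing:
        report["missing_in_validation"] = len(missing)
        logger.info("%d locus variants absent from validation cohort", len(missing))

    r2_profile = np.empty(path.n_events)
    for i in range(path.n_events):
        act = path.active_sets[i]
        scored = [v for v in act if v in val_id_set]
        if scored:
            jdx = path.inputs.index_of(scored)
            r2_profile[i] = validation_r2(validation, scored, path.beta_orig[i, jdx])
        else:
            r2_profile[i] = 0.0

    best = int(np.argmax(r2_profile))  # first maximum: the sparsest best model
    selected = path.active_sets[best]
    jdx = path.inputs.index_of(selected)
    return LocusResult(
        selected_ids=np.array(selected, dtype=object),
        penalized_effects=path.beta_orig[best, jdx],
        r2_profile=r2_profile,
        best_event=best,
        n_selected=len(selected),
        best_lambda=float(path.events[best].lam),
        path=path,
        report=report,
    )


def aggregate_loci(results: list[LocusResult], validation: ValidationCohort) -> dict:
    """Combine per-locus polygenic scores across loci.

    ``cumulative_r2`` sums the regional proportions of explained variance
    (valid when regional scores are nearly independent, as for distant
    loci); ``joint_r2`` is the coefficient of determination of the multiple
    regression of the phenotype on all regional scores jointly, which
    accounts for any collinearity between scores.
    """
    if not results:
        raise ValueError("results must be non-empty")
    cumulative = float(sum(r.best_r2 for r in results))
    lookup = {v: i for i, v in enumerate(validation.ids)}
    scores = []
    for r in results:
        if r.n_selected == 0:
            continue
        keep = [(v, e) for v, e in zip(r.selected_ids, r.penalized_effects) if v in lookup]
        if not keep:
            continue
        idx = np.array([lookup[v] for v, _ in keep], dtype=int)
        eff = np.array([e for _, e in keep])
        scores.append(validation.genotypes[:, idx] @ eff)
    if not scores:
        return {"cumulative_r2": cumulative, "joint_r2": 0.0}
    S = np.column_stack(scores)
    X = np.column_stack([np.ones(len(S)), S])
    y = validation.phenotype
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(np.sum((y - y.mean()) ** 2))
    joint = 1.0 - float(np.sum(resid**2)) / tss if tss > 0 else 0.0
    return {"cumulative_r2": cumulative, "joint_r2": joint}
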