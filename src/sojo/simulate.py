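"""Synthetic cohorts, the stepwise comparator, and the two-causal ROC benchmark.

The benchmark emulates allelic heterogeneity at a single locus: a cohort
of ``n`` individuals is genotyped at ``p`` variants whose latent
correlation decays as ``rho**|i-j|`` (an AR(1) LD block), and the trait is
driven by exactly two causal variants,

    y = beta1 * X_c1 + beta2 * X_c2 + e,    e ~ Normal(0, sigma2),

with genotype columns demeaned.  Defaults follow the two-causal design:
``beta1 = 5``, ``beta2 = +/-1``, ``sigma2 = 50``, ``p = 20``, ``rho = 0.8``,
allele frequencies 0.5, 200 datasets per scenario, at a desk-runnable
cohort size of ``n = 10,000``.

Genotypes are produced by dichotomizing a latent Gaussian AR(1) process at
the allele-frequency quantile per haplotype and summing two haplotypes, so
dosages take values {0, 1, 2}.  Dichotomization attenuates the latent
correlation (for maf 0.5 the dosage correlation is ``(2/pi) arcsin(rho)``),
so realized dosage correlations are reported and benchmark scenarios are
labelled by their realized causal-pair LD ``r_LD``.

Both selectors are scored threshold-free for the ROC: a variant's score is
the most permissive threshold at which it would be selected — the entry
value of the tuning parameter for the summary LASSO, and the conditional
p value at entry for stepwise forward selection run with an open gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso
from sklearn.metrics import auc as _trapz_auc
from sklearn.metrics import roc_curve

from .ld_panel import ReferencePanel, StandardizedInputs, build_inputs
from .lasso_path import run_path
from .summary_io import SummaryTable

__all__ = [
    "SimulationScenario",
    "RocResult",
    "simulate_genotypes",
    "simulate_trait",
    "summary_from_cohort",
    "panel_from_matrix",
    "stepwise_conditional",
    "individual_lasso",
    "roc_benchmark",
    "paired_bootstrap_auc",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Configuration of one two-causal-variant benchmark scenario."""

    n: int = 10_000
    p: int = 20
    rho: float = 0.8
    maf: float = 0.5
    causal_idx: tuple[int, int] = (9, 10)  # 0-based column indices
    beta1: float = 5.0
    beta2: float = 1.0
    sigma2: float = 50.0
    n_datasets: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        c1, c2 = self.causal_idx
        if c1 == c2 or not (0 <= c1 < self.p and 0 <= c2 < self.p):
            raise ValueError("causal indices must be distinct and within range")
        if not 0 < self.rho < 1:
            raise ValueError("rho must be in (0, 1)")


@dataclass
class RocResult:
    """A pooled ROC curve with its trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    method: str

    @property
    def sensitivity(self) -> np.ndarray:
        return self.tpr

    @property
    def specificity(self) -> np.ndarray:
        return 1.0 - self.fpr


def _tetrachoric_latent(r_target: float, maf: float) -> float:
    """Latent Gaussian correlation giving indicator correlation ``r_target``.

    Dichotomizing a standard bivariate Gaussian at the ``maf`` quantile
    attenuates correlation; this inverts the attenuation so dosages hit the
    target.  At maf = 0.5 the inverse is the arcsine law
    ``sin(pi/2 * r)``; otherwise it is found numerically from the
    bivariate normal orthant probability.
    """
    if r_target == 0.0:
        return 0.0
    if r_target >= 1.0 - 1e-9:
        return 1.0
    if abs(maf - 0.5) < 1e-12:
        return float(np.sin(np.pi / 2.0 * r_target))
    from scipy.optimize import brentq
    from scipy.stats import multivariate_normal

    t = stats.norm.ppf(maf)
    denom = maf * (1.0 - maf)

    def indicator_corr(rho_lat: float) -> float:
        joint = multivariate_normal(
            mean=[0.0, 0.0], cov=[[1.0, rho_lat], [rho_lat, 1.0]]
        ).cdf([t, t])
        return (joint - maf**2) / denom

    return float(brentq(lambda r: indicator_corr(r) - r_target, -0.999999, 0.999999, xtol=1e-10))


from functools import lru_cache


@lru_cache(maxsize=64)
def _latent_cholesky(p: int, rho: float, maf: float) -> np.ndarray:
    """Cholesky factor of the latent correlation matrix for AR(1) dosages."""
    lags = np.arange(p)
    latent_by_lag = np.array([_tetrachoric_latent(rho**lag, maf) for lag in lags])
    R = latent_by_lag[np.abs(lags[:, None] - lags[None, :])]
    # guard against roundoff in the elementwise-transformed Toeplitz matrix
    w, V = np.linalg.eigh(R)
    if w.min() < 1e-10:
        w = np.clip(w, 1e-10, None)
        R = V @ np.diag(w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    return np.linalg.cholesky(R)


def simulate_genotypes(n: int, p: int, rho: float, maf: float = 0.5, seed=None, rng=None) -> np.ndarray:
    """Biallelic dosages with population correlation ``rho**|i-j|``.

    Each of two haplotypes per individual carries the counted allele when a
    latent Gaussian (with tetrachorically pre-inflated correlations, so the
    *dosage* correlation decays exactly as ``rho**|i-j|``) falls below the
    ``maf`` quantile; dosages are the haplotype sums, values {0, 1, 2}.
    """
    if not 0 < rho < 1:
        raise ValueError("rho must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    thresh = stats.norm.ppf(maf)
    L = _latent_cholesky(p, rho, maf)
    z = rng.standard_normal((n, 2, p)) @ L.T
    return (z < thresh).sum(axis=1).astype(float)


def simulate_trait(X: np.ndarray, scenario: SimulationScenario, rng=None) -> np.ndarray:
    """Two-causal-variant trait on demeaned causal genotype columns."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    c1, c2 = scenario.causal_idx
    x1 = X[:, c1] - X[:, c1].mean()
    x2 = X[:, c2] - X[:, c2].mean()
    e = rng.normal(0.0, np.sqrt(scenario.sigma2), size=X.shape[0])
    return scenario.beta1 * x1 + scenario.beta2 * x2 + e


def summary_from_cohort(
    X: np.ndarray,
    y: np.ndarray,
    ids=None,
    chrom: str = "1",
    positions=None,
    se_method: str = "ols",
    subsample_range: tuple[int, int] | None = None,
    rng=None,
) -> SummaryTable:
    """Per-variant univariate GWAS of a cohort, as a :class:`SummaryTable`.

    Each variant is fitted by simple linear regression of ``y`` on its
    dosage.  ``se_method="ols"`` uses the exact residual-variance standard
    error; ``"large-sample"`` uses ``se**2 = Var(y) / (n * Var(Xj))``, the
    approximation under which summary-level and individual-level LASSO
    coincide exactly.  ``subsample_range=(lo, hi)`` fits each variant on a
    random subset of individuals of uniform size in [lo, hi], emulating
    meta-analyses with per-variant sample sizes (imputation failures).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if ids is None:
        ids = [f"v{j + 1}" for j in range(p)]
    if positions is None:
        positions = np.arange(1, p + 1) * 1000
    if rng is None:
        rng = np.random.default_rng()

    def _marginal(xj, yj):
        m = len(yj)
        xc = xj - xj.mean()
        yc = yj - yj.mean()
        sxx = float(xc @ xc)
        sxy = float(xc @ yc)
        syy = float(yc @ yc)
        b = sxy / sxx
        if se_method == "ols":
            dof = m - 2
            sr2 = max(syy - b * sxy, 0.0) / dof
            se = np.sqrt(sr2 / sxx)
        elif se_method == "large-sample":
            se = np.sqrt((syy / (m - 1)) / (m * sxx / (m - 1)))
        else:
            raise ValueError(f"unknown se_method {se_method!r}")
        t = b / se if se > 0 else np.inf
        pval = 2.0 * stats.t.sf(abs(t), m - 2)
        return b, se, max(pval, 1e-300), m

    rows = []
    for j in range(p):
        if subsample_range is not None:
            lo, hi = subsample_range
            m = int(rng.integers(lo, hi + 1))
            idx = rng.choice(n, size=m, replace=False)
            b, se, pv, m = _marginal(X[idx, j], y[idx])
        else:
            b, se, pv, m = _marginal(X[:, j], y)
        freq = float(np.clip(X[:, j].mean() / 2.0, 1e-9, 1 - 1e-9))
        rows.append(
            {
                "id": ids[j],
                "chrom": chrom,
                "pos": int(positions[j]),
                "effect_allele": "A",
                "other_allele": "G",
                "freq": freq,
                "beta": b,
                "se": se,
                "n": float(m),
                "pvalue": pv,
            }
        )
    df = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    return SummaryTable(df, trait_sigma2=float(np.var(y, ddof=1)))


def panel_from_matrix(X: np.ndarray, ids=None, chrom: str = "1", positions=None) -> ReferencePanel:
    """Wrap a dosage matrix as a reference panel (counted allele "A")."""
    import warnings

    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if ids is None:
        ids = [f"v{j + 1}" for j in range(p)]
    if positions is None:
        positions = np.arange(1, p + 1) * 1000
    meta = pd.DataFrame(
        {
            "id": ids,
            "chrom": chrom,
            "pos": positions,
            "counted_allele": "A",
            "other_allele": "G",
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small simulated panels are expected
        return ReferencePanel(X, meta)


def stepwise_conditional(
    inputs: StandardizedInputs,
    n_eff: float,
    p_enter: float = 5e-8,
    r2_guard: float = 0.9,
    max_select: int | None = None,
    return_trace: bool = False,
):
    """Forward stepwise conditional selection from summary-level inputs.

    Mirrors conditional-and-joint selection: at each step the candidate
    with the smallest conditional p value (from the joint model on the
    current set plus the candidate, with residual variance
    ``sigma2 - C_A' B_A^{-1} C_A`` and coefficient variances
    ``sigma_r^2 [B_A^{-1}]_{jj} / n_eff``) is added while its p value is
    below ``p_enter``; after each addition every selected variant's joint
    p value is re-checked and any above ``p_enter`` is dropped.  Candidates
    with r² above ``r2_guard`` to a selected variant are skipped, so the
    method faces the same effective candidate pool as the pruned LASSO.

    Returns ``(ids, joint_effects_orig)``; with ``return_trace=True`` also
    a list of ``(id, conditional_p_at_entry)`` in entry order.
    """
    if not 0 < p_enter <= 1:
        raise ValueError("p_enter must be in (0, 1]")
    C, B, sigma2 = inputs.C, inputs.B, inputs.sigma2
    p = inputs.p
    if max_select is None:
        max_select = p
    selected: list[int] = []
    trace: list[tuple[object, float]] = []

    def joint_stats(idx_set):
        idx = np.array(idx_set, dtype=int)
        B_A = B[np.ix_(idx, idx)]
        try:
            Binv = np.linalg.inv(B_A)
        except np.linalg.LinAlgError:
            return None
        beta = Binv @ C[idx]
        explained = float(C[idx] @ beta)
        sr2 = max(sigma2 - explained, 1e-12 * sigma2)
        var = sr2 * np.diag(Binv) / n_eff
        z = beta / np.sqrt(var)
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        return beta, np.maximum(pvals, 1e-300)

    while len(selected) < max_select:
        best = None
        for j in range(p):
            if j in selected:
                continue
            if selected and np.max(B[j, selected] ** 2) > r2_guard:
                continue  # collinearity guard
            st = joint_stats(selected + [j])
            if st is None:
                continue
            pj = st[1][-1]
            if best is None or pj < best[1]:
                best = (j, pj)
        if best is None or best[1] >= p_enter:
            break
        selected.append(best[0])
        trace.append((inputs.ids[best[0]], float(best[1])))
        # backward pass: drop any variant no longer jointly significant
        while len(selected) > 1:
            st = joint_stats(selected)
            if st is None:
                break
            worst = int(np.argmax(st[1]))
            if st[1][worst] > p_enter:
                dropped = selected.pop(worst)
                trace = [t for t in trace if t[0] != inputs.ids[dropped]]
            else:
                break

    if selected:
        beta_std = joint_stats(selected)[0]
        effects = beta_std / np.sqrt(inputs.d_w[selected])
    else:
        effects = np.array([])
    ids = inputs.ids[selected] if selected else np.array([], dtype=object)
    if return_trace:
        return ids, effects, trace
    return ids, effects


def individual_lasso(X: np.ndarray, y: np.ndarray, lambda_grid) -> np.ndarray:
    """Individual-level LASSO by cyclic coordinate descent.

    Solves ``min (1/2)||y - X b||^2 + lam ||b||_1`` for each ``lam`` in
    ``lambda_grid`` (no intercept; pass centered data), returning a
    ``len(grid) x p`` coefficient matrix.  This is the oracle the
    summary-level path is checked against.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    grid = np.asarray(lambda_grid, dtype=float)
    out = np.empty((len(grid), X.shape[1]))
    model = Lasso(alpha=1.0, fit_intercept=False, max_iter=200_000, tol=1e-12, warm_start=True)
    order = np.argsort(-grid)  # warm-start from most penalized
    for i in order:
        lam = grid[i]
        if lam <= 0:
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            out[i] = coef
            continue
        model.set_params(alpha=lam / n)
        model.fit(X, y)
        if model.n_iter_ >= model.max_iter:
            raise RuntimeError(f"coordinate descent did not converge at lambda={lam}")
        out[i] = model.coef_
    return out


def _sojo_entry_scores(inputs: StandardizedInputs) -> np.ndarray:
    """Per-variant entry lambda along the path (0 = never selected)."""
    path = run_path(inputs)
    scores = np.zeros(inputs.p)
    lookup = {v: i for i, v in enumerate(inputs.ids)}
    for ev in path.events:
        if ev.kind == "hit":
            j = lookup[ev.variant]
            if scores[j] == 0.0:
                scores[j] = ev.lam
    return scores


def _stepwise_entry_scores(inputs: StandardizedInputs, n_eff: float, r2_guard: float) -> np.ndarray:
    """Per-variant -log10 of the smallest p threshold admitting the variant.

    Forward selection with gate ``t`` stops at the first step whose best
    conditional p value is >= ``t``, so a variant entering at step s is
    selected iff ``t`` exceeds every entry p value up to step s — its
    admitting threshold is the running maximum of entry p values, not its
    own (a sharp conditional signal unmasked late is still gated by the
    weakest earlier step).
    """
    _, _, trace = stepwise_conditional(
        inputs, n_eff=n_eff, p_enter=1.0, r2_guard=r2_guard, return_trace=True
    )
    scores = np.zeros(inputs.p)
    lookup = {v: i for i, v in enumerate(inputs.ids)}
    running_max = 0.0
    for vid, pval in trace:
        running_max = max(running_max, pval)
        scores[lookup[vid]] = -np.log10(running_max)
    return scores


@dataclass
class RocBenchmarkResult:
    """Pooled ROC curves plus per-replicate scores for bootstrap resampling."""

    scenario: SimulationScenario
    roc: dict  # method -> RocResult
    scores: dict  # method -> (n_datasets, p) score matrix
    labels: np.ndarray  # length-p 0/1 causal labels
    realized_r_ld: float  # mean realized causal-pair dosage correlation

    def auc(self, method: str) -> float:
        return self.roc[method].auc


def _pooled_roc(scores: np.ndarray, labels: np.ndarray, method: str) -> RocResult:
    y_true = np.tile(labels, scores.shape[0])
    y_score = scores.ravel()
    fpr, tpr, thr = roc_curve(y_true, y_score)
    return RocResult(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(_trapz_auc(fpr, tpr)), method=method)


def roc_benchmark(scenario: SimulationScenario, r2_guard: float = 0.9) -> RocBenchmarkResult:
    """Run the two-causal ROC comparison of the summary LASSO vs stepwise.

    For each of ``scenario.n_datasets`` replicates a cohort is simulated,
    GWAS summary statistics are computed from it, the whole sample is taken
    as the reference panel, and both selectors are run across their full
    threshold ranges.  The two causal variants are the positive labels;
    scores pooled over replicates give each method's ROC curve and
    trapezoidal AUC.
    """
    rng = np.random.default_rng(scenario.seed)
    labels = np.zeros(scenario.p, dtype=int)
    labels[list(scenario.causal_idx)] = 1
    sojo_scores = np.zeros((scenario.n_datasets, scenario.p))
    step_scores = np.zeros((scenario.n_datasets, scenario.p))
    r_lds = np.empty(scenario.n_datasets)
    c1, c2 = scenario.causal_idx
    for t in range(scenario.n_datasets):
        X = simulate_genotypes(scenario.n, scenario.p, scenario.rho, scenario.maf, rng=rng)
        y = simulate_trait(X, scenario, rng=rng)
        r_lds[t] = np.corrcoef(X[:, c1], X[:, c2])[0, 1]
        table = summary_from_cohort(X, y, rng=rng)
        panel = panel_from_matrix(X)
        inputs = build_inputs(table, panel)
        sojo_scores[t] = _sojo_entry_scores(inputs)
        step_scores[t] = _stepwise_entry_scores(inputs, n_eff=scenario.n, r2_guard=r2_guard)
    roc = {
        "sojo": _pooled_roc(sojo_scores, labels, "sojo"),
        "stepwise": _pooled_roc(step_scores, labels, "stepwise"),
    }
    return RocBenchmarkResult(
        scenario=scenario,
        roc=roc,
        scores={"sojo": sojo_scores, "stepwise": step_scores},
        labels=labels,
        realized_r_ld=float(r_lds.mean()),
    )


def paired_bootstrap_auc(
    result: RocBenchmarkResult,
    method_a: str = "sojo",
    method_b: str = "stepwise",
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Paired bootstrap over replicates for the AUC difference a - b."""
    rng = np.random.default_rng(seed)
    sa, sb = result.scores[method_a], result.scores[method_b]
    labels = result.labels
    n_rep = sa.shape[0]
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n_rep, size=n_rep)
        diffs[b] = (
            _pooled_roc(sa[idx], labels, method_a).auc
            - _pooled_roc(sb[idx], labels, method_b).auc
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    point = result.auc(method_a) - result.auc(method_b)
    return {"diff": point, "ci_low": float(lo), "ci_high": float(hi), "level": level}
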