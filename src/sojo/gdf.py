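"""Generalized degrees of freedom (GDF) by Monte Carlo.

A fair comparison between selection procedures must hold model complexity
fixed, and for procedures that *search* (stepwise selection) or *shrink*
(the LASSO) the effective number of parameters is not the number of
selected variables.  For observations y = mu + eps with Cov(eps) =
sigma2 * I and a fitting procedure f: R^n -> R^n, the generalized degrees
of freedom is

    df(f) = (1 / sigma2) * sum_i Cov(f_i(y), y_i),

the covariance penalty of the whole select-and-fit pipeline.  Here the
covariances are estimated directly across independent Monte Carlo
replicates of y around a known mu — the natural estimator in a synthetic
setting, where mu is available by construction (a data-perturbation
estimator would be needed on real data, where it is not).

The LASSO spends one GDF per selected variant (shrinkage exactly offsets
the selection cost), whereas forward stepwise selection on correlated
designs usually spends more than one per variant — the empirical basis for
comparing the two methods at matched complexity rather than matched count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ld_panel import cohort_inputs
from .lasso_path import coefficients_at, run_path

__all__ = [
    "GdfEstimate",
    "estimate_gdf",
    "gdf_curve",
    "ols_projection_fitter",
    "lasso_k_fitter",
    "stepwise_k_fitter",
]


@dataclass
class GdfEstimate:
    """A piecewise map from number of selected variants k to estimated GDF."""

    k_values: np.ndarray
    df_values: np.ndarray
    se_values: np.ndarray
    n_reps: int
    sigma2: float

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=int)
        self.df_values = np.asarray(self.df_values, dtype=float)
        self.se_values = np.asarray(self.se_values, dtype=float)
        if not (len(self.k_values) == len(self.df_values) == len(self.se_values)):
            raise ValueError("k/df/se lengths must agree")


def estimate_gdf(fitter, mu, sigma2: float, n_reps: int, seed: int) -> tuple[float, float]:
    """Monte Carlo GDF of ``fitter`` with a jackknife standard error.

    Draws ``n_reps`` responses ``y = mu + Normal(0, sigma2 I)``, applies
    ``fitter`` (a callable mapping a response vector to fitted values) to
    each, and sums the per-coordinate sample covariances between fitted and
    observed values.  Deterministic given ``seed``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    mu = np.asarray(mu, dtype=float)
    n = len(mu)
    rng = np.random.default_rng(seed)
    Y = mu + rng.normal(0.0, np.sqrt(sigma2), size=(n_reps, n))
    F = np.empty_like(Y)
    for t in range(n_reps):
        try:
            F[t] = np.asarray(fitter(Y[t]), dtype=float)
        except Exception as exc:  # noqa: BLE001 - annotate with replicate index
            raise RuntimeError(f"fitter failed on replicate {t}") from exc

    R = n_reps
    s_f = F.sum(axis=0)
    s_y = Y.sum(axis=0)
    s_fy = (F * Y).sum(axis=0)
    cov = (s_fy - s_f * s_y / R) / (R - 1)
    df = float(cov.sum() / sigma2)

    # leave-one-replicate-out estimates, vectorized over replicates
    lf = s_f - F
    ly = s_y - Y
    lfy = s_fy - F * Y
    cov_loo = (lfy - lf * ly / (R - 1)) / (R - 2)
    df_loo = cov_loo.sum(axis=1) / sigma2
    se = float(np.sqrt((R - 1) / R * np.sum((df_loo - df_loo.mean()) ** 2)))
    return df, se


def gdf_curve(
    selector_family, mu, sigma2: float, k_grid, n_reps: int, seed: int
) -> GdfEstimate:
    """Estimate GDF as a function of the number of selected variants.

    ``selector_family(y, k)`` must return the fitted values of the
    procedure configured to select ``k`` variants, or ``None`` when ``k``
    is unreachable for that response (e.g. the path ends earlier); a ``k``
    unreachable on any replicate is recorded as NaN rather than raising.
    """
    k_grid = list(k_grid)
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    dfs, ses = [], []
    for i, k in enumerate(k_grid):
        unreachable = []

        def fitter(y, _k=k):
            f = selector_family(y, _k)
            if f is None:
                unreachable.append(True)
                return np.full(len(y), np.nan)
            return f

        df, se = estimate_gdf(fitter, mu, sigma2, n_reps, seed + i)
        if unreachable or np.isnan(df):
            dfs.append(np.nan)
            ses.append(np.nan)
        else:
            dfs.append(df)
            ses.append(se)
    return GdfEstimate(
        k_values=np.array(k_grid), df_values=np.array(dfs), se_values=np.array(ses),
        n_reps=n_reps, sigma2=sigma2,
    )


# --- built-in fitter families ----------------------------------------------


def ols_projection_fitter(X_cols: np.ndarray):
    """Least-squares projection onto fixed columns: df = rank(X_cols)."""
    X = np.asarray(X_cols, dtype=float)
    Q, _ = np.linalg.qr(X)

    def fitter(y):
        return Q @ (Q.T @ y)

    return fitter


def lasso_k_fitter(X: np.ndarray, mu=None, sigma2: float = 1.0, n_pilot: int = 200, seed: int = 0):
    """Penalized LASSO fit at a fixed tuning parameter selecting ~k variants.

    The number of active LASSO coefficients at a *fixed* lambda is an
    unbiased estimate of the fit's degrees of freedom, so "the k-variant
    LASSO" is realized as the fit at a fixed lambda_k calibrated (once,
    from ``n_pilot`` pilot responses drawn around ``mu``) so that the
    average active-set size is k.  Calibrating per response — truncating
    each path at its own k-th entry — would instead make the coefficients
    depend on y only through breakpoint differences and cost well under k
    GDF, which is a different procedure from the fixed-penalty selector
    whose complexity is being measured.  Fitted values use the penalized
    (shrunken) coefficients; no intercept, columns centered internally.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    mu = np.zeros(X.shape[0]) if mu is None else np.asarray(mu, dtype=float)
    lambda_for_k: dict[int, float | None] = {}
    pilot_steps: list[tuple[np.ndarray, np.ndarray]] = []  # (event lambdas, sizes after)

    def _pilot() -> None:
        rng = np.random.default_rng(seed)
        for _ in range(n_pilot):
            y = mu + rng.normal(0.0, np.sqrt(sigma2), size=len(mu))
            path = run_path(cohort_inputs(Xc, y))
            sizes = np.array([len(a) for a in path.active_sets])
            pilot_steps.append((path.lambdas, sizes))

    def _mean_active(lam: float) -> float:
        total = 0.0
        for lambdas, sizes in pilot_steps:
            i = np.searchsorted(-lambdas, -lam, side="right") - 1
            total += sizes[i] if i >= 0 else 0
        return total / len(pilot_steps)

    def _lambda_for(k: int) -> float | None:
        # fixed lambda_k at which the pilot-average active-set size is k
        if k not in lambda_for_k:
            if not pilot_steps:
                _pilot()
            grid = np.unique(np.concatenate([lam for lam, _ in pilot_steps]))
            if len(grid) == 0:
                lambda_for_k[k] = None
                return None
            # evaluate just below each breakpoint, where each size is in force
            probes = np.concatenate([grid * (1 - 1e-9), [0.0]])
            means = np.array([_mean_active(lam) for lam in probes])
            if means.max() < k:
                lambda_for_k[k] = None
            else:
                gap = np.abs(means - k)
                ties = np.where(gap == gap.min())[0]
                # middle of the plateau where the pilot mean sits at k
                lambda_for_k[k] = float(probes[ties[len(ties) // 2]])
        return lambda_for_k[k]

    def family(y, k: int):
        if k == 0:
            return np.zeros(len(y))
        lam = _lambda_for(k)
        if lam is None:
            return None  # no pilot path ever held k variants active
        inputs = cohort_inputs(Xc, y)
        path = run_path(inputs)
        beta_std, _ = coefficients_at(path, lam)
        Xs = Xc / np.sqrt(inputs.d_w)
        return Xs @ beta_std

    return family


def stepwise_k_fitter(X: np.ndarray):
    """Forward selection of k variants with an unpenalized least-squares refit.

    At each step the variant most correlated with the current residual
    (equivalently, with the smallest conditional p value) is added; after k
    steps the fitted values come from the joint OLS refit on the selected
    columns.  The selection search is what inflates the GDF beyond k on
    correlated designs.
    """
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    norms = np.sqrt((Xc**2).sum(axis=0))

    def family(y, k: int):
        if k == 0:
            return np.zeros(len(y))
        if k > Xc.shape[1]:
            return None
        selected: list[int] = []
        resid = y.astype(float)
        fitted = np.zeros(len(y))
        for _ in range(k):
            score = np.abs(Xc.T @ resid) / norms
            score[selected] = -np.inf
            j = int(np.argmax(score))
            selected.append(j)
            Xa = Xc[:, selected]
            coef, *_ = np.linalg.lstsq(Xa, y, rcond=None)
            fitted = Xa @ coef
            resid = y - fitted
        return fitted

    return family
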