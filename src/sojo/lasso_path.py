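"""LASSO regularization path from summary-level inputs.

The LASSO objective  min_beta (1/2)||y - X beta||^2 + lambda ||beta||_1
has a piecewise-linear solution path in the tuning parameter lambda.  In
the large-sample limit the homotopy (LARS-style) path algorithm depends on
the data only through the variant-trait covariances ``C`` and the LD
correlation matrix ``B``, so the whole path can be computed from GWAS
summary statistics plus a reference panel.

Starting from lambda_0 = infinity and an empty active set A, the path
alternates two event types as lambda decreases:

* a *hitting* event — an inactive variant's correlation with the current
  residual reaches lambda and the variant enters A with sign s; the
  candidate hitting time for variant j with sign s is
  ``(C_j - B_{jA} B_A^{-1} C_A) / (s - B_{jA} B_A^{-1} s_A)``,
  and from the empty set it reduces to ``lambda_1 = max_j |C_j|``;
* a *crossing* event — an active coefficient shrinks through zero at
  ``[B_A^{-1} C_A]_j / [B_A^{-1} s_A]_j`` and the variant leaves A; the
  crossing time at the first step is 0 by definition.

Either way the next breakpoint is the largest candidate strictly below the
current lambda ("max+"), and between breakpoints the active coefficients
are the affine function ``beta_A(lambda) = B_A^{-1}(C_A - lambda s_A)``.
Coefficients on the original per-allele scale are recovered by dividing by
the reference dosage standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .ld_panel import StandardizedInputs

__all__ = [
    "PathEvent",
    "LassoPath",
    "hitting_time",
    "crossing_time",
    "run_path",
    "coefficients_at",
    "kkt_check",
]

#: strict "max+" guard: a candidate must be below lambda_k by at least this
#: to count as a new event (avoids re-selecting the current event in
#: floating point)
MAXPLUS_EPS = 1e-12

#: denominators smaller than this correspond to directions the active set
#: already spans; such candidates are skipped
DEGENERATE_DEN = 1e-10

#: diagonal jitter added once if an active-set Cholesky fails
SOLVE_JITTER = 1e-8


class PathNumericalError(np.linalg.LinAlgError):
    """An active-set system stayed singular after jitter."""


@dataclass(frozen=True)
class PathEvent:
    """One breakpoint of the path: variant ``variant`` hits or crosses at ``lam``."""

    k: int
    lam: float
    kind: str  # "hit" | "cross" | "end"
    variant: object | None
    sign: int


@dataclass
class LassoPath:
    """An ordered sequence of breakpoints with coefficients on both scales.

    ``beta_std[i]`` / ``beta_orig[i]`` are the full-length coefficient
    vectors at event i (zeros off the active set); ``active_sets[i]`` and
    ``active_signs[i]`` describe the active set *after* event i, which is
    the set in force on the segment down to event i+1.
    """

    events: list[PathEvent]
    active_sets: list[np.ndarray]
    active_signs: list[np.ndarray]
    beta_std: np.ndarray
    beta_orig: np.ndarray
    inputs: StandardizedInputs
    truncated: bool = False

    @property
    def ids(self) -> np.ndarray:
        return self.inputs.ids

    @property
    def lambdas(self) -> np.ndarray:
        return np.array([e.lam for e in self.events])

    @property
    def n_events(self) -> int:
        return len(self.events)

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: one row per (event, variant in active set)."""
        rows = []
        idx = {v: i for i, v in enumerate(self.inputs.ids)}
        for i, ev in enumerate(self.events):
            for v in self.active_sets[i]:
                j = idx[v]
                rows.append(
                    {
                        "step": ev.k,
                        "lambda": ev.lam,
                        "event": ev.kind,
                        "event_variant": ev.variant,
                        "variant": v,
                        "beta_std": self.beta_std[i, j],
                        "beta_orig": self.beta_orig[i, j],
                    }
                )
            if len(self.active_sets[i]) == 0:
                rows.append(
                    {
                        "step": ev.k,
                        "lambda": ev.lam,
                        "event": ev.kind,
                        "event_variant": ev.variant,
                        "variant": None,
                        "beta_std": 0.0,
                        "beta_orig": 0.0,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "n_events": self.n_events,
            "n_variants": int(self.inputs.p),
            "lambda_first": float(self.events[0].lam) if self.events else None,
            "lambda_last": float(self.events[-1].lam) if self.events else None,
            "final_active_size": int(len(self.active_sets[-1])) if self.events else 0,
            "truncated": self.truncated,
        }


def _solve_active(B_A: np.ndarray, rhs: np.ndarray, ids_A) -> np.ndarray:
    """Solve B_A x = rhs via Cholesky, retrying once with diagonal jitter."""
    try:
        return cho_solve(cho_factor(B_A), rhs)
    except LinAlgError:
        try:
            return cho_solve(cho_factor(B_A + SOLVE_JITTER * np.eye(len(B_A))), rhs)
        except LinAlgError as exc:
            raise PathNumericalError(
                f"active-set LD submatrix is singular for variants {list(ids_A)}"
            ) from exc


def _valid_maxplus(cand: np.ndarray, cand_ids, lambda_k: float, exclude) -> np.ndarray:
    """Candidates admissible under max+: positive and below ``lambda_k``.

    Strictly below by ``MAXPLUS_EPS`` in general; a candidate exactly *at*
    ``lambda_k`` (an exact tie, e.g. duplicated covariances) is admitted
    unless it belongs to the variant of the previous event — re-admitting
    that one would replay the event just processed and cycle.
    """
    tol = MAXPLUS_EPS * max(1.0, abs(lambda_k) if np.isfinite(lambda_k) else 1.0)
    below = cand < lambda_k - tol
    tied = np.abs(cand - lambda_k) <= tol
    not_prev = np.array([v != exclude for v in cand_ids])
    return (cand > 0) & (below | (tied & not_prev))


def hitting_time(
    inputs: StandardizedInputs, active, signs, lambda_k: float, exclude=None
) -> tuple[float, object, int] | None:
    """Next hitting event below ``lambda_k``: ``(lambda_hit, variant, sign)``.

    Evaluates the candidate time for every inactive variant and both signs
    and returns the largest candidate that is positive and below
    ``lambda_k`` (max+); ``None`` when no such candidate exists.  From the
    empty active set this is ``max_j |C_j|`` with the sign of the winning
    C.  ``exclude`` names the previous event's variant, which is never
    re-admitted at an exact tie with ``lambda_k``.
    """
    C, B, ids = inputs.C, inputs.B, inputs.ids
    active = list(active)
    idx_A = inputs.index_of(active)
    mask = np.ones(inputs.p, dtype=bool)
    mask[idx_A] = False
    if not mask.any():
        return None

    if len(idx_A) == 0:
        num = C[mask]
        cand = np.abs(num)
        cand_signs = np.where(num >= 0, 1, -1)
        valid = _valid_maxplus(cand, ids[mask], lambda_k, exclude)
        if not valid.any():
            return None
        j = int(np.argmax(np.where(valid, cand, -np.inf)))
        return float(cand[j]), ids[mask][j], int(cand_signs[j])

    s_A = np.asarray(signs, dtype=float)
    x = _solve_active(B[np.ix_(idx_A, idx_A)], C[idx_A], active)
    w = _solve_active(B[np.ix_(idx_A, idx_A)], s_A, active)
    B_jA = B[np.ix_(np.where(mask)[0], idx_A)]
    num = C[mask] - B_jA @ x
    proj = B_jA @ w

    best = None
    ids_out = ids[mask]
    for s in (1.0, -1.0):
        den = s - proj
        ok = np.abs(den) > DEGENERATE_DEN
        cand = np.full(num.shape, -np.inf)
        cand[ok] = num[ok] / den[ok]
        valid = _valid_maxplus(cand, ids_out, lambda_k, exclude)
        if valid.any():
            j = int(np.argmax(np.where(valid, cand, -np.inf)))
            if best is None or cand[j] > best[0]:
                best = (float(cand[j]), ids_out[j], int(s))
    return best


def crossing_time(
    inputs: StandardizedInputs, active, signs, lambda_k: float, exclude=None
) -> tuple[float, object | None] | None:
    """Next crossing event below ``lambda_k``: ``(lambda_cross, variant)``.

    An active coefficient crosses zero at ``[B_A^{-1}C_A]_j / [B_A^{-1}s_A]_j``;
    the largest positive candidate strictly below ``lambda_k`` wins.  With
    an empty active set (the first step) the crossing time is 0 by
    definition, returned as ``(0.0, None)``.  ``None`` means no active
    variant can leave before the path ends.
    """
    active = list(active)
    if len(active) == 0:
        return 0.0, None
    idx_A = inputs.index_of(active)
    B_A = inputs.B[np.ix_(idx_A, idx_A)]
    x = _solve_active(B_A, inputs.C[idx_A], active)
    w = _solve_active(B_A, np.asarray(signs, dtype=float), active)
    ok = np.abs(w) > DEGENERATE_DEN
    cand = np.full(x.shape, -np.inf)
    cand[ok] = x[ok] / w[ok]
    valid = _valid_maxplus(cand, active, lambda_k, exclude)
    if not valid.any():
        return None
    j = int(np.argmax(np.where(valid, cand, -np.inf)))
    return float(cand[j]), active[j]


def run_path(
    inputs: StandardizedInputs,
    lambda_min: float = 0.0,
    max_active: int | None = None,
    max_steps: int | None = None,
) -> LassoPath:
    """Compute the full regularization path by alternating hit/cross events.

    At each step the next breakpoint is the larger of the hitting and
    crossing times; a hit adds the entering variant (ties favor the hit),
    a cross removes the leaving one.  The recorded coefficients at each
    breakpoint solve ``B_A beta_A = C_A - lambda s_A`` on the updated
    active set (the entering/leaving coefficient is exactly zero there).
    The path terminates at ``lambda_min`` (default 0, where the active-set
    solution is the unpenalized joint fit), when ``max_active`` variants
    are active, after ``max_steps`` events, or when no event remains; a
    final "end" breakpoint at ``lambda_min`` closes any untruncated path.
    """
    p = inputs.p
    if max_active is None:
        max_active = p if inputs.n_ref is None else min(p, inputs.n_ref - 1)
    if max_steps is None:
        max_steps = 20 * max(p, 1)
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    if lambda_min < 0:
        raise ValueError("lambda_min must be >= 0")

    events: list[PathEvent] = []
    active: list = []
    signs: list[int] = []
    betas_std: list[np.ndarray] = []
    lam = np.inf
    truncated = False
    active_sets: list[np.ndarray] = []
    active_signs: list[np.ndarray] = []

    def record(k: int, lam_k: float, kind: str, variant, sign: int) -> None:
        beta = np.zeros(p)
        if active:
            idx_A = inputs.index_of(active)
            beta[idx_A] = _solve_active(
                inputs.B[np.ix_(idx_A, idx_A)],
                inputs.C[idx_A] - lam_k * np.asarray(signs, dtype=float),
                active,
            )
        if kind == "hit" and variant is not None:
            # the entering coefficient is analytically zero at its breakpoint
            beta[inputs.index_of([variant])[0]] = 0.0
        events.append(PathEvent(k, lam_k, kind, variant, sign))
        active_sets.append(np.array(active, dtype=object))
        active_signs.append(np.array(signs, dtype=int))
        betas_std.append(beta)

    k = 0
    while True:
        k += 1
        if k > max_steps:
            truncated = True
            break
        prev = events[-1].variant if events else None
        hit = (
            hitting_time(inputs, active, signs, lam, exclude=prev)
            if len(active) < max_active
            else None
        )
        cross = crossing_time(inputs, active, signs, lam, exclude=prev)

        lam_hit = hit[0] if hit is not None else -np.inf
        # the defined first-step crossing time 0 never beats a positive hit
        # and never fires an event by itself
        lam_cross = cross[0] if cross is not None and cross[1] is not None else -np.inf

        if lam_hit == -np.inf and lam_cross == -np.inf:
            break  # no event remains: close the path at lambda_min
        lam_next = max(lam_hit, lam_cross)
        if lam_next <= lambda_min:
            break
        if lam_hit >= lam_cross:
            _, var, s = hit
            active.append(var)
            signs.append(s)
            record(k, lam_next, "hit", var, s)
        else:
            _, var = cross
            j = active.index(var)
            s = signs[j]
            del active[j]
            del signs[j]
            record(k, lam_next, "cross", var, s)
        lam = lam_next
        if len(active) >= max_active and max_active < p:
            truncated = True  # user/panel cap below p: path genuinely cut short
            break

    if not truncated and (not events or events[-1].lam > lambda_min):
        record(k, lambda_min, "end", None, 0)

    beta_std = np.vstack(betas_std) if betas_std else np.zeros((0, p))
    beta_orig = beta_std / np.sqrt(inputs.d_w)
    return LassoPath(
        events=events,
        active_sets=active_sets,
        active_signs=active_signs,
        beta_std=beta_std,
        beta_orig=beta_orig,
        inputs=inputs,
        truncated=truncated,
    )


def coefficients_at(path: LassoPath, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Coefficients at an arbitrary ``lam`` on both scales.

    Exact at breakpoints; between adjacent breakpoints the active set is
    constant and the solution is re-evaluated from the segment's affine
    form.  Above the first breakpoint everything is zero; below the final
    recorded lambda of a truncated path the solution is undefined and a
    ``ValueError`` is raised.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    inputs = path.inputs
    p = inputs.p
    if path.n_events == 0 or lam >= path.events[0].lam:
        z = np.zeros(p)
        return z, z / np.sqrt(inputs.d_w)
    lambdas = path.lambdas
    last = lambdas[-1]
    if lam < last - 1e-12:
        raise ValueError(
            f"lambda={lam} is below the final recorded breakpoint {last} "
            "of a truncated path"
        )
    lam_eval = max(lam, last)
    # segment index: the last event with lambda >= lam governs the segment
    seg = int(np.searchsorted(-lambdas, -lam_eval, side="right")) - 1
    active = path.active_sets[seg]
    signs = path.active_signs[seg]
    beta = np.zeros(p)
    if len(active):
        idx_A = inputs.index_of(active)
        beta[idx_A] = _solve_active(
            inputs.B[np.ix_(idx_A, idx_A)],
            inputs.C[idx_A] - lam_eval * signs.astype(float),
            active,
        )
    return beta, beta / np.sqrt(inputs.d_w)


def kkt_check(
    inputs: StandardizedInputs,
    lam: float,
    beta_std: np.ndarray,
    tol: float = 1e-8,
    zero_tol: float | None = None,
) -> dict:
    """Audit the Karush-Kuhn-Tucker stationarity conditions of a solution.

    For the summary-level objective the conditions read, with residual
    correlation ``r = C - B beta``:
    ``r_j = lam * sign(beta_j)`` for active j, and ``|r_j| <= lam`` for
    inactive j, each within ``tol``.  Coefficients within ``zero_tol``
    (default ``tol``) of zero are audited under the inactive condition,
    which is the weaker and always-valid form at a boundary.  Returns
    per-variant pass flags, the worst violation, and an overall verdict.
    """
    if zero_tol is None:
        zero_tol = tol
    beta_std = np.asarray(beta_std, dtype=float)
    r = inputs.C - inputs.B @ beta_std
    activ = np.abs(beta_std) > zero_tol
    viol = np.where(activ, np.abs(r - lam * np.sign(beta_std)), np.maximum(np.abs(r) - lam, 0.0))
    ok = viol <= tol
    return {
        "ok": bool(ok.all()),
        "per_variant": dict(zip(inputs.ids, ok.tolist())),
        "max_violation": float(viol.max()) if len(viol) else 0.0,
        "tol": tol,
    }
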