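import numpy as np
import pytest

import sojo
from sojo.lasso_path import MAXPLUS_EPS

from conftest import random_pd_inputs


def _admissible(cand, vid, lam_k, exclude):
    tol = MAXPLUS_EPS * max(1.0, abs(lam_k))
    if cand <= 0:
        return False
    if cand < lam_k - tol:
        return True
    return abs(cand - lam_k) <= tol and vid != exclude


def brute_force_hit(inputs, active, signs, lam_k, exclude=None):
    """Exhaustive scan of all (j, s) hitting candidates via explicit inverses."""
    idx = {v: i for i, v in enumerate(inputs.ids)}
    A = [idx[v] for v in active]
    best = None
    for j in range(inputs.p):
        if j in A:
            continue
        for s in (1.0, -1.0):
            if A:
                Binv = np.linalg.inv(inputs.B[np.ix_(A, A)])
                num = inputs.C[j] - inputs.B[j, A] @ Binv @ inputs.C[A]
                den = s - inputs.B[j, A] @ Binv @ np.asarray(signs, float)
            else:
                num, den = inputs.C[j], s
            if abs(den) < 1e-10:
                continue
            cand = num / den
            if _admissible(cand, inputs.ids[j], lam_k, exclude) and (
                best is None or cand > best[0]
            ):
                best = (cand, inputs.ids[j], int(s))
    return best


def brute_force_cross(inputs, active, signs, lam_k, exclude=None):
    idx = {v: i for i, v in enumerate(inputs.ids)}
    A = [idx[v] for v in active]
    Binv = np.linalg.inv(inputs.B[np.ix_(A, A)])
    x = Binv @ inputs.C[A]
    w = Binv @ np.asarray(signs, float)
    best = None
    for pos, j in enumerate(A):
        if abs(w[pos]) < 1e-10:
            continue
        cand = x[pos] / w[pos]
        if _admissible(cand, inputs.ids[j], lam_k, exclude) and (
            best is None or cand > best[0]
        ):
            best = (cand, inputs.ids[j])
    return best


class TestHittingTime:
    def test_empty_active_set_is_max_abs_c(self):
        inputs = sojo.StandardizedInputs(
            C=np.array([0.3, -0.5, 0.1]), B=np.eye(3), d_w=np.ones(3),
            sigma2=1.0, ids=np.array(["a", "b", "c"], dtype=object),
        )
        lam, var, sign = sojo.hitting_time(inputs, [], [], np.inf)
        assert (lam, var, sign) == (0.5, "b", -1)

    def test_exhausted_candidates_return_none(self):
        inputs = sojo.StandardizedInputs(
            C=np.array([0.4]), B=np.eye(1), d_w=np.ones(1),
            sigma2=1.0, ids=np.array(["a"], dtype=object),
        )
        assert sojo.hitting_time(inputs, ["a"], [1], 0.4) is None

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        inputs = random_pd_inputs(rng, p=8)
        # walk a couple of events to get a non-trivial active set
        path = sojo.run_path(inputs, max_active=3)
        active = list(path.active_sets[-1])
        signs = list(path.active_signs[-1])
        lam_k = path.events[-1].lam
        prev = path.events[-1].variant
        got = sojo.hitting_time(inputs, active, signs, lam_k, exclude=prev)
        want = brute_force_hit(inputs, active, signs, lam_k, exclude=prev)
        if want is None:
            assert got is None
        else:
            assert got[0] == pytest.approx(want[0], abs=1e-10)
            assert got[1:] == want[1:]


class TestCrossingTime:
    def test_first_step_crossing_is_zero(self):
        rng = np.random.default_rng(1)
        inputs = random_pd_inputs(rng, p=10)
        lam, var = sojo.crossing_time(inputs, [], [], np.inf)
        assert lam == 0.0 and var is None

    def test_lone_active_variant_never_leaves(self):
        inputs = sojo.StandardizedInputs(
            C=np.array([0.4, 0.1]), B=np.eye(2), d_w=np.ones(2),
            sigma2=1.0, ids=np.array(["a", "b"], dtype=object),
        )
        # candidate equals the entry lambda of the variant just added,
        # which max+ never re-admits
        assert sojo.crossing_time(inputs, ["a"], [1], 0.4, exclude="a") is None

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(100 + seed)
        inputs = random_pd_inputs(rng, p=8)
        path = sojo.run_path(inputs, max_active=3)
        active = list(path.active_sets[-1])
        signs = list(path.active_signs[-1])
        lam_k = path.events[-1].lam
        prev = path.events[-1].variant
        got = sojo.crossing_time(inputs, active, signs, lam_k, exclude=prev)
        want = brute_force_cross(inputs, active, signs, lam_k, exclude=prev)
        if want is None:
            assert got is None
        else:
            assert got[0] == pytest.approx(want[0], abs=1e-10)
            assert got[1] == want[1]


class TestRunPath:
    def test_orthogonal_design_is_soft_thresholding(self):
        inputs = sojo.StandardizedInputs(
            C=np.array([0.5, 0.3]), B=np.eye(2), d_w=np.ones(2),
            sigma2=1.0, ids=np.array(["a", "b"], dtype=object),
        )
        path = sojo.run_path(inputs)
        assert [e.lam for e in path.events[:2]] == pytest.approx([0.5, 0.3])
        beta, _ = sojo.coefficients_at(path, 0.3)
        np.testing.assert_allclose(beta, [0.2, 0.0], atol=1e-10)
        for lam in [0.45, 0.2, 0.0]:
            beta, _ = sojo.coefficients_at(path, lam)
            np.testing.assert_allclose(
                beta, np.sign(inputs.C) * np.maximum(np.abs(inputs.C) - lam, 0), atol=1e-10
            )

    def test_single_variant_path(self):
        inputs = sojo.StandardizedInputs(
            C=np.array([-0.7]), B=np.eye(1), d_w=np.array([4.0]),
            sigma2=1.0, ids=np.array(["a"], dtype=object),
        )
        path = sojo.run_path(inputs)
        assert path.events[0].lam == pytest.approx(0.7)
        assert path.events[-1].lam == 0.0
        assert path.beta_std[-1, 0] == pytest.approx(-0.7)
        assert path.beta_orig[-1, 0] == pytest.approx(-0.35)  # divided by sqrt(d_w)

    @pytest.mark.parametrize("seed", range(5))
    def test_structural_invariants(self, seed):
        rng = np.random.default_rng(200 + seed)
        inputs = random_pd_inputs(rng, p=10)
        path = sojo.run_path(inputs)
        lams = path.lambdas
        assert np.all(np.diff(lams) < 1e-12)
        sizes = [len(a) for a in path.active_sets]
        for i, ev in enumerate(path.events):
            prev = sizes[i - 1] if i else 0
            if ev.kind == "hit":
                assert sizes[i] == prev + 1
            elif ev.kind == "cross":
                assert sizes[i] == prev - 1
            else:
                assert sizes[i] == prev
            rep = sojo.kkt_check(inputs, ev.lam, path.beta_std[i], tol=1e-8)
            assert rep["ok"], rep["max_violation"]
            # active coefficient signs agree with the recorded sign vector
            for v, s in zip(path.active_sets[i], path.active_signs[i]):
                bj = path.beta_std[i, list(inputs.ids).index(v)]
                assert bj == 0 or np.sign(bj) == s

    def test_piecewise_linearity_within_segment(self):
        rng = np.random.default_rng(42)
        inputs = random_pd_inputs(rng, p=9)
        path = sojo.run_path(inputs)
        lams = path.lambdas
        i = len(lams) // 2
        la, lb = lams[i], lams[i + 1]
        for alpha in (0.25, 0.5, 0.75):
            lam = alpha * la + (1 - alpha) * lb
            beta, _ = sojo.coefficients_at(path, lam)
            ba, _ = sojo.coefficients_at(path, la)
            bb, _ = sojo.coefficients_at(path, lb)
            np.testing.assert_allclose(beta, alpha * ba + (1 - alpha) * bb, atol=1e-10)

    def test_max_active_one_stops_at_top_variant(self):
        rng = np.random.default_rng(3)
        inputs = random_pd_inputs(rng, p=6)
        path = sojo.run_path(inputs, max_active=1)
        assert len(path.active_sets[-1]) == 1
        assert path.truncated

    def test_sigma2_scales_lambdas_and_coefficients(self, small_cohort):
        """The whole path is proportional to the assumed phenotypic variance."""
        X, y = small_cohort
        rng = np.random.default_rng(0)
        table = sojo.summary_from_cohort(X, y, rng=rng)
        panel = sojo.panel_from_matrix(X)
        p1 = sojo.run_path(sojo.build_inputs(table, panel, sigma2=1.0))
        p3 = sojo.run_path(sojo.build_inputs(table, panel, sigma2=3.0))
        assert p1.n_events == p3.n_events
        np.testing.assert_allclose(3.0 * p1.lambdas, p3.lambdas, rtol=1e-10)
        np.testing.assert_allclose(3.0 * p1.beta_std, p3.beta_std, rtol=1e-9, atol=1e-12)

    def test_matches_individual_level_solver_breakpoints(self, small_cohort):
        X, y = small_cohort
        n = len(y)
        inputs = sojo.cohort_inputs(X, y)
        path = sojo.run_path(inputs)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        yc = y - y.mean()
        lams = path.lambdas
        coefs = sojo.individual_lasso(Xs, yc, lams * (n - 1))
        np.testing.assert_allclose(coefs, path.beta_std, atol=1e-6)


class TestCoefficientsAt:
    def test_above_first_breakpoint_all_zero(self):
        rng = np.random.default_rng(5)
        inputs = random_pd_inputs(rng, p=5)
        path = sojo.run_path(inputs)
        beta, _ = sojo.coefficients_at(path, path.events[0].lam * 2)
        assert np.all(beta == 0)

    def test_exact_at_stored_breakpoints(self):
        rng = np.random.default_rng(6)
        inputs = random_pd_inputs(rng, p=7)
        path = sojo.run_path(inputs)
        for i, ev in enumerate(path.events):
            beta, borig = sojo.coefficients_at(path, ev.lam)
            np.testing.assert_allclose(beta, path.beta_std[i], atol=1e-9)
            np.testing.assert_allclose(borig, path.beta_orig[i], atol=1e-9)

    def test_below_truncated_path_raises(self):
        rng = np.random.default_rng(7)
        inputs = random_pd_inputs(rng, p=6)
        path = sojo.run_path(inputs, max_active=2)
        with pytest.raises(ValueError, match="truncated"):
            sojo.coefficients_at(path, path.events[-1].lam / 2)


class TestKktCheck:
    def test_all_zero_at_lambda_max_passes(self):
        rng = np.random.default_rng(8)
        inputs = random_pd_inputs(rng, p=6)
        lam_max = np.abs(inputs.C).max()
        assert sojo.kkt_check(inputs, lam_max, np.zeros(6), tol=1e-10)["ok"]

    def test_perturbed_solution_flagged_at_the_right_variant(self):
        rng = np.random.default_rng(9)
        inputs = random_pd_inputs(rng, p=8)
        path = sojo.run_path(inputs)
        i = path.n_events // 2
        beta = path.beta_std[i].copy()
        j = int(np.flatnonzero(beta)[0])
        beta[j] += 0.1
        rep = sojo.kkt_check(inputs, path.events[i].lam, beta, tol=1e-8)
        assert not rep["ok"]
        assert not rep["per_variant"][inputs.ids[j]]
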