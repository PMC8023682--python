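"""GPLEMMA: objective identities, Jacobians, LM behavior, ES extraction."""

import numpy as np
import pytest

from gxeherit import rand_kernels as rk
from gxeherit.gplemma import (
    DenseObjective,
    HutchinsonObjective,
    extract_es_and_pve,
    fit,
    initial_weights,
    lm_minimize,
)

from conftest import dense_W, make_dense_problem


@pytest.fixture(scope="module")
def problem():
    """N=30, M=40, L=2 fixture with the exact dense backend."""
    X, E, C, y, truth = make_dense_problem(n=30, m=40, l=2, n_covar=2, seed=41)
    dense = DenseObjective(X, E, C, y)
    return X, E, C, y, dense


class LinearObjective:
    """f(theta) = A theta: Gauss-Newton is exact, for LM behavior tests."""

    def __init__(self, A, y):
        self.A, self.y = A, y
        self.n_env = A.shape[1] - 2

    def squared_error(self, theta):
        r = self.y - self.A @ theta
        return float(r @ r)

    def jtj_jte(self, theta):
        r = self.y - self.A @ theta
        return self.A.T @ self.A, self.A.T @ r


class _ArraySource:
    """Minimal block-source over an already-standardized matrix."""

    def __init__(self, X):
        self._X = np.asarray(X, dtype=float)
        self.n_samples, self.n_snps = self._X.shape

    def blocks(self, block_size=1024):
        for j0 in range(0, self.n_snps, block_size):
            j1 = min(j0 + block_size, self.n_snps)
            yield j0, j1, self._X[:, j0:j1]


def _hutch_from_arrays(X, E, C, y, n_probes=60, seed=0):
    """HutchinsonObjective over the same (X, E, C, y) a DenseObjective sees."""
    from gxeherit.genio import EnvCovDesign

    design = EnvCovDesign(
        E=np.asarray(E, float), C=np.asarray(C, float),
        env_names=[f"env_{l+1}" for l in range(E.shape[1])],
        covar_names=[f"c{i}" for i in range(C.shape[1])],
        sample_ids=np.array([f"s{i}" for i in range(len(y))], dtype=object),
    )
    probes = rk.draw_probes(X.shape[0], n_probes, seed=seed)
    pre = rk.stream_precomputes(_ArraySource(X), design, y, probes)
    return HutchinsonObjective(pre, design), design, probes


class TestSquaredError:
    def test_all_zero_params_leave_only_data_term(self, problem):
        X, E, C, y, dense = problem
        theta = np.zeros(2 + E.shape[1])
        W = dense_W(C)
        wy = W @ y
        assert abs(dense.squared_error(theta) - (wy @ wy) ** 2) < 1e-8
        obj, _, _ = _hutch_from_arrays(X, E, C, y)
        assert abs(obj.squared_error(theta) - (wy @ wy) ** 2) < 1e-6

    def test_weight_sign_flip_invariance(self, problem):
        X, E, C, y, dense = problem
        theta = np.array([0.3, 0.4, -0.2, 0.5])
        flipped = theta.copy()
        flipped[1:-1] *= -1
        assert dense.squared_error(theta) == pytest.approx(dense.squared_error(flipped), rel=1e-12)

    def test_dense_matches_frobenius_definition(self, problem):
        X, E, C, y, dense = problem
        theta = np.array([0.25, 0.3, 0.1, 0.6])
        W = dense_W(C)
        K = X @ X.T / X.shape[1]
        eta = E @ theta[1:-1]
        A = theta[0] * W @ K @ W + W @ (eta[:, None] * K * eta[None, :]) @ W + theta[-1] * W
        R = np.outer(W @ y, W @ y) - A
        assert dense.squared_error(theta) == pytest.approx(np.sum(R * R), rel=1e-12)

    def test_hutchinson_matches_dense_within_mc_error(self, problem):
        X, E, C, y, dense = problem
        theta = np.array([0.25, 0.3, 0.1, 0.6])
        truth = dense.squared_error(theta)
        draws = [
            _hutch_from_arrays(X, E, C, y, n_probes=40, seed=200 + r)[0].squared_error(theta)
            for r in range(20)
        ]
        se = np.std(draws, ddof=1) / np.sqrt(len(draws))
        assert abs(np.mean(draws) - truth) < 3.5 * se


class TestJacobian:
    @staticmethod
    def _fd_oracle(dense, theta, h=1e-5):
        k = len(theta)
        A0 = dense.model_matrix(theta)
        J = np.empty((A0.size, k))
        for i in range(k):
            tp, tm = theta.copy(), theta.copy()
            tp[i] += h
            tm[i] -= h
            J[:, i] = (dense.model_matrix(tp) - dense.model_matrix(tm)).ravel() / (2 * h)
        R = (dense.Yp - A0).ravel()
        return J.T @ J, J.T @ R

    def test_dense_matches_finite_differences(self, problem):
        X, E, C, y, dense = problem
        theta = np.array([0.3, 0.5, -0.25, 0.7])
        JtJ, Jte = dense.jtj_jte(theta)
        JtJ_fd, Jte_fd = self._fd_oracle(dense, theta)
        assert np.abs(JtJ - JtJ_fd).max() / np.abs(JtJ_fd).max() < 1e-4
        assert np.abs(Jte - Jte_fd).max() / np.abs(Jte_fd).max() < 1e-4

    def test_jtj_symmetric_with_exact_residual_diagonal(self, problem):
        X, E, C, y, dense = problem
        obj, design, _ = _hutch_from_arrays(X, E, C, y)
        theta = np.array([0.2, 0.1, 0.3, 0.5])
        JtJ, _ = obj.jtj_jte(theta)
        np.testing.assert_allclose(JtJ, JtJ.T, atol=1e-10 * np.abs(JtJ).max())
        assert JtJ[-1, -1] == design.projector.trace

    def test_hutchinson_jtj_matches_dense_within_mc_error(self, problem):
        X, E, C, y, dense = problem
        theta = np.array([0.3, 0.5, -0.25, 0.7])
        JtJ_d, Jte_d = dense.jtj_jte(theta)
        reps_J, reps_g = [], []
        n_reps = 40
        for r in range(n_reps):
            obj, _, _ = _hutch_from_arrays(X, E, C, y, n_probes=50, seed=300 + r)
            J, g = obj.jtj_jte(theta)
            reps_J.append(J)
            reps_g.append(g)
        reps_J, reps_g = np.array(reps_J), np.array(reps_g)
        # ~20 simultaneous comparisons: bound the worst standardized deviation
        se_J = reps_J.std(axis=0, ddof=1) / np.sqrt(n_reps)
        se_g = reps_g.std(axis=0, ddof=1) / np.sqrt(n_reps)
        z_J = np.abs(reps_J.mean(0) - JtJ_d) / (se_J + 1e-12)
        z_J[-1, -1] = 0.0  # exact tr(W) by construction
        z_g = np.abs(reps_g.mean(0) - Jte_d) / (se_g + 1e-12)
        assert z_J.max() < 4.0, f"max |z| for J^TJ entries: {z_J.max():.2f}"
        assert z_g.max() < 4.0, f"max |z| for J^T eps entries: {z_g.max():.2f}"


class TestLevenbergMarquardt:
    def test_linear_model_one_accepted_step(self):
        rng = np.random.default_rng(50)
        A = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        obj = LinearObjective(A, y)
        theta_ls, *_ = np.linalg.lstsq(A, y, rcond=None)
        res = lm_minimize(obj, np.zeros(4), mu0=1e-12, max_iter=5)
        np.testing.assert_allclose(res.theta, theta_ls, rtol=1e-6)
        assert res.n_accepted >= 1
        # essentially converged after the first accepted step
        assert res.S_path[1] == pytest.approx(res.S, rel=1e-10)

    def test_large_damping_gives_steepest_descent_direction(self):
        rng = np.random.default_rng(51)
        A = rng.standard_normal((30, 4))
        y = rng.standard_normal(30)
        obj = LinearObjective(A, y)
        theta0 = np.zeros(4)
        JtJ, Jte = obj.jtj_jte(theta0)
        mu = 1e9
        delta = np.linalg.solve(JtJ + mu * np.eye(4), Jte)
        cos = delta @ Jte / (np.linalg.norm(delta) * np.linalg.norm(Jte))
        assert cos > 1 - 1e-6

    def test_monotone_descent_on_fixture(self, problem):
        X, E, C, y, dense = problem
        w0 = initial_weights(E.shape[1], 0, base_seed=1)
        res = lm_minimize(dense, dense.init_params(w0))
        s = np.array(res.S_path)
        assert np.all(np.diff(s) < 0)

    def test_rejected_steps_increase_damping_until_stall(self):
        # a pathological objective that never improves: LM must stop cleanly
        class Stuck:
            n_env = 0

            def squared_error(self, theta):
                return 1.0 + float(theta @ theta)

            def jtj_jte(self, theta):
                return np.eye(len(theta)), np.ones(len(theta))

        res = lm_minimize(Stuck(), np.zeros(2), max_iter=10)
        assert res.converged and "no improving step" in res.reason


class TestFit:
    def test_restart_initialization_distribution(self):
        L = 4
        draws = np.array([initial_weights(L, r, base_seed=0) for r in range(4000)])
        assert np.abs(draws.mean(axis=0) - 1 / L).max() < 4 * (np.sqrt(2) / L) / np.sqrt(4000)
        assert np.abs(draws.std(axis=0) - np.sqrt(2) / L).max() < 0.01

    def test_restart_reproducibility(self):
        a = initial_weights(5, 3, base_seed=9)
        b = initial_weights(5, 3, base_seed=9)
        c = initial_weights(5, 4, base_seed=9)
        np.testing.assert_array_equal(a, b)
        assert not np.allclose(a, c)

    def test_single_restart_equals_lm_from_first_init(self, problem):
        X, E, C, y, dense = problem
        res_fit = fit(dense, n_restarts=1, base_seed=2)
        w0 = initial_weights(E.shape[1], 0, base_seed=2)
        res_lm = lm_minimize(dense, dense.init_params(w0))
        np.testing.assert_allclose(res_fit.theta, res_lm.theta, rtol=1e-12)

    def test_best_restart_has_minimum_s(self, problem):
        X, E, C, y, dense = problem
        res = fit(dense, n_restarts=4, base_seed=3)
        assert res.S == min(r.S for r in res.restarts)

    def test_dense_fixed_point_matches_scipy_least_squares(self, problem):
        from scipy.optimize import least_squares

        X, E, C, y, dense = problem
        res = fit(dense, n_restarts=3, base_seed=4, tol=1e-12, max_iter=500)

        def resid(theta):
            return (dense.Yp - dense.model_matrix(theta)).ravel()

        sol = least_squares(resid, res.theta, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        assert np.linalg.norm(sol.x - res.theta) / np.linalg.norm(res.theta) < 1e-4


class TestExtraction:
    def test_pve_sums_to_one_and_sign_canonical(self, problem):
        X, E, C, y, dense = problem
        res = fit(dense, n_restarts=3, base_seed=5)
        rep = extract_es_and_pve(res, dense)
        assert rep["h2_main"] + rep["h2_gxe"] + rep["residual"] == pytest.approx(1.0, rel=1e-12)
        es = np.array(list(rep["es_weights"].values()))
        assert es[np.argmax(np.abs(es))] > 0
        assert np.linalg.norm(es) == pytest.approx(1.0, rel=1e-12)

    def test_weight_sign_flip_leaves_pve_unchanged(self, problem):
        X, E, C, y, dense = problem
        theta = np.array([0.3, 0.5, -0.25, 0.7])
        flipped = theta.copy()
        flipped[1:-1] *= -1
        assert dense.pve_components(theta) == pytest.approx(dense.pve_components(flipped))

    def test_environment_sign_flip_leaves_pve_unchanged(self, problem):
        # multiplying every column of E by -1 flips the fitted weights but
        # not the variance partition
        X, E, C, y, dense = problem
        res = fit(dense, n_restarts=2, base_seed=6, tol=1e-10)
        rep = extract_es_and_pve(res, dense)
        C_flip = C.copy()
        C_flip[:, -E.shape[1]:] *= -1
        dense_f = DenseObjective(X, -E, C_flip, y)
        res_f = fit(dense_f, n_restarts=2, base_seed=6, tol=1e-10)
        rep_f = extract_es_and_pve(res_f, dense_f)
        assert rep_f["h2_gxe"] == pytest.approx(rep["h2_gxe"], rel=1e-4, abs=1e-6)
        assert rep_f["h2_main"] == pytest.approx(rep["h2_main"], rel=1e-4, abs=1e-6)

    def test_recovers_planted_es_direction(self):
        # moderate-size recovery check through the randomized pipeline
        from gxeherit import simdata
        from gxeherit.genio import assemble_design as asm

        cfg = simdata.SimConfig(n_samples=600, n_snps=800, n_env=3, n_active_env=2,
                                n_causal_main=80, n_causal_gxe=40, h2_main=0.25,
                                h2_gxe=0.2, covar_frac=0.01, seed=61)
        data = simdata.simulate_dataset(cfg)
        design = asm(data.E, covar=data.C)
        y = data.y - data.y.mean()
        probes, pre = rk.prepare(data.source, design, y, n_probes=60, seed=62)
        obj = HutchinsonObjective(pre, design)
        res = fit(obj, n_restarts=5, base_seed=62)
        rep = extract_es_and_pve(res, obj, env_names=design.env_names)
        corr = abs(np.corrcoef(rep["eta_hat"], data.truth.eta_true)[0, 1])
        assert corr > 0.8
        assert abs(rep["h2_gxe"] - 0.2) < 0.1

    def test_null_initialization_collapses_interaction_scale(self):
        # on data with no GxE the 3-component init solve returns a
        # floored interaction variance, so scaled init weights are tiny
        from gxeherit import simdata
        from gxeherit.genio import assemble_design as asm

        cfg = simdata.SimConfig(n_samples=500, n_snps=700, n_env=3, n_active_env=2,
                                n_causal_main=70, n_causal_gxe=35, h2_main=0.3,
                                h2_gxe=0.0, covar_frac=0.01, seed=63)
        data = simdata.simulate_dataset(cfg)
        design = asm(data.E, covar=data.C)
        y = data.y - data.y.mean()
        _, pre = rk.prepare(data.source, design, y, n_probes=60, seed=64)
        obj = HutchinsonObjective(pre, design)
        w0 = initial_weights(3, 0, base_seed=65)
        theta0 = obj.init_params(w0)
        # interaction block far smaller than the main/residual variances
        assert np.abs(theta0[1:-1]).max() < 0.2 * max(theta0[0], theta0[-1])
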