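"""Shared fixtures and independent dense oracles for the test suite.

The oracle helpers here deliberately use plain dense numpy linear algebra
(explicit N x N matrices, np.trace) so they share no code path with the
streaming / randomized implementations they validate.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("suite")


def standardize(A):
    A = np.asarray(A, dtype=float)
    return (A - A.mean(axis=0)) / A.std(axis=0)


def dense_W(C):
    C = np.atleast_2d(np.asarray(C, float))
    if C.shape[0] < C.shape[1]:
        C = C.T
    return np.eye(C.shape[0]) - C @ np.linalg.inv(C.T @ C) @ C.T


def dense_kernels(X, E):
    """[K, per-environment GxE kernels, I] with K = X X^T / M."""
    N, M = X.shape
    K = X @ X.T / M
    out = [K]
    for l in range(E.shape[1]):
        F = E[:, [l]] * X
        out.append(F @ F.T / M)
    out.append(np.eye(N))
    return out


def make_dense_problem(n=40, m=50, l=2, n_covar=1, seed=0, h2_main=0.3, h2_gxe=0.2):
    """Small dense fixture with a planted single-ES GxE signal.

    Returns (X standardized, E, C, y, truth dict).  Built with raw numpy so
    it is independent of the package's simulator.
    """
    rng = np.random.default_rng(seed)
    X = standardize(rng.binomial(2, rng.uniform(0.1, 0.5, size=m), size=(n, m)))
    E = standardize(rng.standard_normal((n, l)))
    user = rng.standard_normal((n, n_covar - 1)) if n_covar > 1 else None
    cols = [np.ones(n)]
    if user is not None:
        cols.append(standardize(user))
    C = np.column_stack(cols + [E])
    w = rng.standard_normal(l)
    w /= np.linalg.norm(w)
    eta = E @ w
    beta = rng.standard_normal(m)
    gamma = rng.standard_normal(m)
    g_main = X @ beta
    g_gxe = eta * (X @ gamma)
    eps = rng.standard_normal(n)
    y = (
        np.sqrt(h2_main) * g_main / g_main.std()
        + np.sqrt(h2_gxe) * g_gxe / g_gxe.std()
        + np.sqrt(1 - h2_main - h2_gxe) * eps / eps.std()
    )
    y = y - y.mean()
    return X, E, C, y, {"w": w, "eta": eta}


@pytest.fixture
def dense_problem():
    return make_dense_problem()


@pytest.fixture
def small_sim():
    """A small simulated dataset bundle reused across estimator tests."""
    from gxeherit import simdata

    cfg = simdata.SimConfig(
        n_samples=400, n_snps=500, n_env=3, n_active_env=2,
        n_causal_main=50, n_causal_gxe=25, h2_main=0.3, h2_gxe=0.15,
        covar_frac=0.01, seed=7,
    )
    return simdata.simulate_dataset(cfg)
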