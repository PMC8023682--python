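"""MEMMA: multi-component randomized Haseman-Elston regression.

Each environmental variable is given its own interaction variance component:

    y ~ N(C alpha, sum_k theta_k K_k),
    K_1 = X X^T / M,   K_{l+1} = F_l F_l^T / M with F_l = E_l ⊙ X,
    K_{L+2} = I,

and the method-of-moments normal equations ``T theta = c`` are solved with
``T_kl = tr(W K_k W K_l W)`` and ``c_k = y^T W K_k W y``.  The T entries are
Hutchinson estimates built from the shared probe set by operator composition
(a Gram matrix of ``W K_k W z_b`` vectors), the c entries are exact data
quadratic forms, and the residual diagonal uses the exact tr(W) = N - D.

Variance components are converted to per-component heritability via
``h^2_k = theta_k tr(W K_k W) / sum_j theta_j tr(W K_j W)``.  Raw MoM
estimates can be negative; both the raw and a zero-truncated copy are
reported and PVE uses the truncated one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .genio import EnvCovDesign
from .rand_kernels import StreamedPrecomputes, prepare

__all__ = [
    "MomentSystem",
    "ComponentEstimates",
    "build_system",
    "build_system_dense",
    "solve_system",
    "memma_pve",
    "run_memma",
]


@dataclass
class MomentSystem:
    """The (L+2)-component HE normal equations T theta = c."""

    T: np.ndarray
    b: np.ndarray          # component traces tr(W K_k W)
    c: np.ndarray
    labels: list
    n_samples: int
    n_env: int
    dof: float             # tr(W) = N - D

    @property
    def n_components(self) -> int:
        return len(self.c)


@dataclass
class ComponentEstimates:
    theta: np.ndarray          # raw MoM solution (may contain negatives)
    theta_trunc: np.ndarray    # zero-truncated copy
    pve: np.ndarray            # from the truncated components; sums to 1
    pve_raw: np.ndarray        # signed, from the raw components
    b: np.ndarray
    labels: list
    se: Optional[np.ndarray] = None


def _labels(env_names) -> list:
    return ["main"] + [f"gxe:{n}" for n in env_names] + ["residual"]


def build_system(pre: StreamedPrecomputes, design: EnvCovDesign) -> MomentSystem:
    """Assemble T, b, c from the streamed precomputes and shared probes.

    With ``a_b^k = K_k W z_b`` (available from the precomputes: u_b/M for the
    main kernel, E_l ⊙ v_{b,l}/M per environment, W z_b for the residual),
    ``T_kl = (1/B) sum_b (W a_b^k)^T (W a_b^l)``, which is symmetric PSD by
    construction.  c is exact: (q_main/M, H_ll/M, y^T W y).
    """
    E = design.E
    N, L = E.shape
    B, M = pre.n_probes, pre.n_snps
    K = L + 2
    proj = design.projector

    A = np.empty((N, K, B))
    A[:, 0, :] = pre.U / M
    A[:, 1 : L + 1, :] = E[:, :, None] * pre.V / M
    A[:, L + 1, :] = pre.WZ
    WA = proj.apply(A.reshape(N, K * B)).reshape(N, K, B)
    T = np.einsum("nkb,nlb->kl", WA, WA, optimize=True) / B
    T = 0.5 * (T + T.T)
    T[-1, -1] = proj.trace

    b = T[:, -1].copy()
    b[-1] = proj.trace
    c = np.concatenate([[pre.q_main / M], pre.q_env / M, [pre.y_wy]])
    return MomentSystem(T=T, b=b, c=c, labels=_labels(design.env_names),
                        n_samples=N, n_env=L, dof=proj.trace)


def build_system_dense(X: np.ndarray, E: np.ndarray, C: np.ndarray, y: np.ndarray,
                       env_names=None) -> MomentSystem:
    """Exact moment system via dense kernels (small problems / oracle checks)."""
    X = np.asarray(X, dtype=np.float64)
    E = np.asarray(E, dtype=np.float64)
    C = np.atleast_2d(np.asarray(C, dtype=np.float64))
    if C.shape[0] != X.shape[0]:
        C = C.T
    y = np.asarray(y, dtype=np.float64)
    N, M = X.shape
    L = E.shape[1]
    Q, _ = np.linalg.qr(C)
    W = np.eye(N) - Q @ Q.T
    kernels = [X @ X.T / M]
    for l in range(L):
        F = E[:, [l]] * X
        kernels.append(F @ F.T / M)
    kernels.append(np.eye(N))
    K = L + 2
    T = np.empty((K, K))
    b = np.empty(K)
    c = np.empty(K)
    Wy = W @ y
    WKW = [W @ Kk @ W for Kk in kernels]
    for k in range(K):
        b[k] = np.trace(WKW[k])
        c[k] = float(y @ WKW[k] @ y)
        for l in range(k + 1):
            T[k, l] = T[l, k] = float(np.sum(WKW[k] * WKW[l].T))  # tr(W K_k W K_l W)
    names = env_names if env_names is not None else [f"env_{l+1}" for l in range(L)]
    return MomentSystem(T=T, b=b, c=c, labels=_labels(names), n_samples=N, n_env=L,
                        dof=float(N - C.shape[1]))


def solve_system(system: MomentSystem) -> ComponentEstimates:
    """Solve T theta = c analytically; least-squares fallback if ill-conditioned."""
    T, c, b = system.T, system.c, system.b
    use_lstsq = False
    try:
        if np.linalg.cond(T) > 1e12:
            use_lstsq = True
        else:
            theta = np.linalg.solve(T, c)
    except np.linalg.LinAlgError:
        use_lstsq = True
    if use_lstsq:
        warnings.warn("moment matrix T is numerically singular; using least-squares solve")
        theta, *_ = np.linalg.lstsq(T, c, rcond=None)

    theta_trunc = np.clip(theta, 0.0, None)
    denom = float(theta_trunc @ b)
    pve = theta_trunc * b / denom if denom > 0 else np.zeros_like(theta)
    denom_raw = float(theta @ b)
    pve_raw = theta * b / denom_raw if denom_raw != 0 else np.zeros_like(theta)
    return ComponentEstimates(theta=theta, theta_trunc=theta_trunc, pve=pve,
                              pve_raw=pve_raw, b=b.copy(), labels=list(system.labels))


def memma_pve(estimates: ComponentEstimates) -> dict:
    """Per-component heritability report (PVE entries sum to 1)."""
    labels = estimates.labels
    pve, pve_raw = estimates.pve, estimates.pve_raw
    per_env = {lab.split(":", 1)[1]: float(p) for lab, p in zip(labels[1:-1], pve[1:-1])}
    return {
        "h2_main": float(pve[0]),
        "per_env": per_env,
        "h2_gxe_total": float(pve[1:-1].sum()),
        "residual": float(pve[-1]),
        "h2_main_raw": float(pve_raw[0]),
        "h2_gxe_total_raw": float(pve_raw[1:-1].sum()),
        "theta_raw": estimates.theta.tolist(),
        "theta_trunc": estimates.theta_trunc.tolist(),
        "labels": list(labels),
    }


def run_memma(source, design: EnvCovDesign, y, n_probes: int = 100, seed: int = 0,
              block_size: int = 1024, precomputes: StreamedPrecomputes | None = None):
    """End-to-end MEMMA: probes, streaming pass, solve, heritability report.

    Returns (report dict, ComponentEstimates, MomentSystem).  Pass
    ``precomputes`` to reuse a streaming pass shared with GPLEMMA.
    """
    y = np.asarray(y, dtype=np.float64)
    y = y - y.mean()
    if precomputes is None:
        _, precomputes = prepare(source, design, y, n_probes=n_probes, seed=seed, block_size=block_size)
    system = build_system(precomputes, design)
    estimates = solve_system(system)
    report = memma_pve(estimates)
    report["meta"] = {
        "n_samples": source.n_samples,
        "n_snps": precomputes.n_snps,
        "n_env": design.n_env,
        "n_covar": design.n_covar,
        "n_probes": precomputes.n_probes,
        "seed": seed,
    }
    return report, estimates, system
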