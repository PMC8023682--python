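"""GPLEMMA: joint non-linear estimation of an environmental score and its
GxE heritability.

The model places Gaussian priors on per-SNP main and interaction effects and
integrates them out, leaving

    y ~ N(C alpha, sigma_b^2 K + K2(w~) + sigma_e^2 I),
    K2(w~) = diag(E w~) K diag(E w~),

where the interaction-scale parameter has been absorbed into the weight
vector (w~ = sigma_gamma * w).  The parameters theta = (sigma_b^2, w~,
sigma_e^2) minimize the squared Frobenius distance between the observed and
model covariance of the projected data,

    S(theta) = || W(y y^T - Cov(y))W ||_F^2,

a non-linear least-squares problem solved by Levenberg-Marquardt with an
adaptive damping parameter and multistart initialization.

Two interchangeable objective backends implement S, J^T J and J^T eps:

* :class:`HutchinsonObjective` — randomized traces assembled from the
  streamed precomputes as Gram matrices over a shared probe set; the
  production path, O(N L^2 B) per LM iteration.
* :class:`DenseObjective` — exact dense-matrix evaluation for small
  problems; the oracle used in validation.

The Jacobian carries the analytic factor 2 from differentiating the
quadratic form in w~ (so J^T eps matches finite differences of the dense
model), and the residual-variance diagonal of J^T J is the exact
tr(W) = N - D.  The overall sign of w~ is unidentifiable (K2(w) = K2(-w));
reports canonicalize it so the largest-magnitude weight is positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genio import EnvCovDesign
from .rand_kernels import StreamedPrecomputes, prepare

__all__ = [
    "HutchinsonObjective",
    "DenseObjective",
    "LMResult",
    "GplemmaFit",
    "lm_minimize",
    "initial_weights",
    "fit",
    "extract_es_and_pve",
    "run_gplemma",
]

INIT_VAR_FLOOR = 1e-6


def _split(theta: np.ndarray):
    return float(theta[0]), np.asarray(theta[1:-1], dtype=np.float64), float(theta[-1])


class HutchinsonObjective:
    """Randomized-trace objective built on streamed precomputes.

    All traces are Gram products of operator words applied to the shared
    probes, e.g. tr(W K2(w) W K2(w) W) = (1/B) sum_b ||W K2(w) W z_b||^2 with
    W K2(w) W z_b = W(eta ⊙ v_b(w))/M and v_b(w) = sum_l w_l v_{b,l}.
    Data-side quadratic forms (q_main, H, y^T W y) are exact.
    """

    def __init__(self, pre: StreamedPrecomputes, design: EnvCovDesign):
        self.pre = pre
        self.design = design
        self.E = design.E
        self.proj = design.projector
        self.n_env = pre.n_env
        self.n_probes = pre.n_probes
        self.n_snps = pre.n_snps
        self.dof = self.proj.trace
        M = self.n_snps
        self.WU = self.proj.apply(pre.U) / M          # W K W z_b stack
        self.WZ = pre.WZ
        self.H = pre.H
        self.d_main = pre.q_main / M                  # y^T W K W y
        self.d_resid = pre.y_wy                       # y^T W y
        self.tyy = pre.y_wy**2                        # tr((Wy y^T W)^2)
        self.tr_wkw = float(np.einsum("nb,nb->", self.WZ, self.WU)) / self.n_probes

    # -- helpers ---------------------------------------------------------
    def _vw_eta(self, w: np.ndarray):
        Vw = np.tensordot(self.pre.V, w, axes=([1], [0]))  # (N, B), = X X^T (eta ⊙ W z_b)
        eta = self.E @ w
        return Vw, eta

    def _gxe_probe(self, w: np.ndarray, Vw=None, eta=None) -> np.ndarray:
        """W K2(w) W z_b for all probes, as an (N, B) stack."""
        if Vw is None:
            Vw, eta = self._vw_eta(w)
        return self.proj.apply(eta[:, None] * Vw) / self.n_snps

    def _model_probe(self, theta: np.ndarray, gxe_stack=None) -> np.ndarray:
        """A(theta) z_b stack with A = sigma_b^2 WKW + W K2 W + sigma_e^2 W."""
        sb2, w, se2 = _split(theta)
        if gxe_stack is None:
            gxe_stack = self._gxe_probe(w)
        return sb2 * self.WU + gxe_stack + se2 * self.WZ

    # -- objective interface ---------------------------------------------
    def squared_error(self, theta: np.ndarray) -> float:
        sb2, w, se2 = _split(theta)
        Az = self._model_probe(theta)
        data = sb2 * self.d_main + float(w @ self.H @ w) / self.n_snps + se2 * self.d_resid
        tr_aa = float(np.einsum("nb,nb->", Az, Az)) / self.n_probes
        S = self.tyy - 2.0 * data + tr_aa
        if not np.isfinite(S):
            raise FloatingPointError("non-finite squared error (data term or tr(A^2) overflowed)")
        return S

    def jtj_jte(self, theta: np.ndarray):
        sb2, w, se2 = _split(theta)
        N, L, B, M = self.WZ.shape[0], self.n_env, self.n_probes, self.n_snps
        Vw, eta = self._vw_eta(w)
        # dA/dw_l applied to probes: W(E_l ⊙ v_b(w) + eta ⊙ v_{b,l}) / M
        Tw = self.E[:, :, None] * Vw[:, None, :] + eta[:, None, None] * self.pre.V
        Pw = self.proj.apply(Tw.reshape(N, L * B)).reshape(N, L, B) / M
        P = np.empty((N, L + 2, B))
        P[:, 0, :] = self.WU
        P[:, 1 : L + 1, :] = Pw
        P[:, L + 1, :] = self.WZ
        JtJ = np.einsum("nib,njb->ij", P, P, optimize=True) / B
        JtJ = 0.5 * (JtJ + JtJ.T)
        JtJ[-1, -1] = self.dof

        gxe_stack = self.proj.apply(eta[:, None] * Vw) / M
        Az = sb2 * self.WU + gxe_stack + se2 * self.WZ
        data_grad = np.concatenate([[self.d_main], 2.0 * (self.H @ w) / M, [self.d_resid]])
        Jte = data_grad - np.einsum("nib,nb->i", P, Az, optimize=True) / B
        return JtJ, Jte

    def init_params(self, w0: np.ndarray) -> np.ndarray:
        """Solve the 3-component linear moment system at fixed weights w0.

        Kernels {K, K2(w0), I}; the fitted sigma_gamma^2 is folded into the
        weights as sqrt(sigma_gamma^2) * w0 (negative moment solutions are
        floored at a small positive value so LM has a finite start).
        """
        gxe_stack = self._gxe_probe(w0)
        comps = np.stack([self.WU, gxe_stack, self.WZ], axis=1)  # (N, 3, B)
        T3 = np.einsum("nib,njb->ij", comps, comps, optimize=True) / self.n_probes
        T3 = 0.5 * (T3 + T3.T)
        T3[2, 2] = self.dof
        c3 = np.array([self.d_main, float(w0 @ self.H @ w0) / self.n_snps, self.d_resid])
        try:
            sol = np.linalg.solve(T3, c3)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(T3, c3, rcond=None)
        sb2, sg2, se2 = (max(float(v), INIT_VAR_FLOOR) for v in sol)
        return np.concatenate([[sb2], np.sqrt(sg2) * w0, [se2]])

    def pve_components(self, theta: np.ndarray):
        """(main, GxE, residual) variance attributions at theta."""
        sb2, w, se2 = _split(theta)
        tr_k2 = float(np.einsum("nb,nb->", self.WZ, self._gxe_probe(w))) / self.n_probes
        return sb2 * self.tr_wkw, tr_k2, se2 * self.dof


class DenseObjective:
    """Exact dense-matrix objective for small problems (validation oracle).

    Same interface as :class:`HutchinsonObjective` but every trace is
    computed from explicit N x N matrices; no probes are involved.
    """

    def __init__(self, X: np.ndarray, E: np.ndarray, C: np.ndarray, y: np.ndarray):
        X = np.asarray(X, dtype=np.float64)
        self.E = np.asarray(E, dtype=np.float64)
        C = np.atleast_2d(np.asarray(C, dtype=np.float64))
        if C.shape[0] != X.shape[0]:
            C = C.T
        y = np.asarray(y, dtype=np.float64)
        N, M = X.shape
        self.n_env = self.E.shape[1]
        self.n_snps = M
        Q, _ = np.linalg.qr(C)
        self.W = np.eye(N) - Q @ Q.T
        self.dof = float(N - C.shape[1])
        self.K = X @ X.T / M
        self.WKW = self.W @ self.K @ self.W
        Wy = self.W @ y
        self.Yp = np.outer(Wy, Wy)
        self.Wy = Wy
        self.tr_wkw = float(np.trace(self.WKW))

    def _K2(self, w: np.ndarray) -> np.ndarray:
        eta = self.E @ w
        return eta[:, None] * self.K * eta[None, :]

    def _A(self, theta: np.ndarray) -> np.ndarray:
        sb2, w, se2 = _split(theta)
        return sb2 * self.WKW + self.W @ self._K2(w) @ self.W + se2 * self.W

    def model_matrix(self, theta: np.ndarray) -> np.ndarray:
        return self._A(theta)

    def squared_error(self, theta: np.ndarray) -> float:
        R = self.Yp - self._A(theta)
        return float(np.sum(R * R))

    def _jac_mats(self, theta: np.ndarray):
        _, w, _ = _split(theta)
        eta = self.E @ w
        mats = [self.WKW]
        for l in range(self.n_env):
            Bl = (self.E[:, l, None] * self.K) * eta[None, :]
            mats.append(self.W @ (Bl + Bl.T) @ self.W)
        mats.append(self.W)
        return mats

    def jtj_jte(self, theta: np.ndarray):
        mats = self._jac_mats(theta)
        k = len(mats)
        JtJ = np.empty((k, k))
        for i in range(k):
            for j in range(i + 1):
                JtJ[i, j] = JtJ[j, i] = float(np.sum(mats[i] * mats[j]))
        R = self.Yp - self._A(theta)
        Jte = np.array([float(np.sum(m * R)) for m in mats])
        return JtJ, Jte

    def init_params(self, w0: np.ndarray) -> np.ndarray:
        comps = [self.WKW, self.W @ self._K2(w0) @ self.W, self.W]
        T3 = np.array([[float(np.sum(a * b)) for b in comps] for a in comps])
        c3 = np.array([float(self.Wy @ c @ self.Wy) / 1.0 for c in [self.K, self._K2(w0), np.eye(len(self.Wy))]])
        try:
            sol = np.linalg.solve(T3, c3)
        except np.linalg.LinAlgError:
            sol, *_ = np.linalg.lstsq(T3, c3, rcond=None)
        sb2, sg2, se2 = (max(float(v), INIT_VAR_FLOOR) for v in sol)
        return np.concatenate([[sb2], np.sqrt(sg2) * w0, [se2]])

    def pve_components(self, theta: np.ndarray):
        sb2, w, se2 = _split(theta)
        tr_k2 = float(np.trace(self.W @ self._K2(w) @ self.W))
        return sb2 * self.tr_wkw, tr_k2, se2 * self.dof


# ---------------------------------------------------------------------------
# Levenberg-Marquardt
# ---------------------------------------------------------------------------

@dataclass
class LMResult:
    theta: np.ndarray
    S: float
    n_iter: int
    n_accepted: int
    converged: bool
    reason: str
    S_path: list = field(default_factory=list)
    mu: float = np.nan


def lm_minimize(objective, theta0: np.ndarray, mu0: Optional[float] = None,
                nu_up: float = 2.0, nu_down: float = 3.0, tol: float = 1e-6,
                patience: int = 3, max_iter: int = 200, max_inner: int = 60) -> LMResult:
    """Damped Gauss-Newton (Levenberg-Marquardt) descent on S(theta).

    Solves ``(J^T J + mu I) delta = J^T eps`` each step; accepted steps
    (S decreases) divide mu by ``nu_down``, rejected ones multiply it by
    ``nu_up`` and retry.  Converged when the relative S decrease stays below
    ``tol`` for ``patience`` consecutive accepted steps.  The objective only
    needs ``squared_error`` and ``jtj_jte``.
    """
    theta = np.array(theta0, dtype=np.float64)
    S = objective.squared_error(theta)
    if not np.isfinite(S):
        return LMResult(theta, S, 0, 0, False, "non-finite initial S", [S])
    JtJ, Jte = objective.jtj_jte(theta)
    k = len(theta)
    mu = mu0 if mu0 is not None else 1e-3 * float(np.mean(np.diag(JtJ)))
    mu = max(mu, np.finfo(float).tiny)
    path = [S]
    n_accepted = 0
    stall = 0
    reason = "max_iter reached"
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        accepted = False
        for _ in range(max_inner):
            try:
                delta = np.linalg.solve(JtJ + mu * np.eye(k), Jte)
            except np.linalg.LinAlgError:
                mu *= nu_up
                continue
            theta_new = theta + delta
            try:
                S_new = objective.squared_error(theta_new)
            except FloatingPointError:
                S_new = np.inf
            if np.isfinite(S_new) and S_new < S:
                rel = (S - S_new) / max(S, np.finfo(float).tiny)
                theta, S = theta_new, S_new
                mu /= nu_down
                accepted = True
                break
            mu *= nu_up
        if not accepted:
            converged = True
            reason = "no improving step (damping exhausted)"
            break
        path.append(S)
        n_accepted += 1
        if rel < tol:
            stall += 1
            if stall >= patience:
                converged = True
                reason = f"relative S decrease < {tol} for {patience} steps"
                break
        else:
            stall = 0
        JtJ, Jte = objective.jtj_jte(theta)
    return LMResult(theta=theta, S=S, n_iter=it, n_accepted=n_accepted,
                    converged=converged, reason=reason, S_path=path, mu=mu)


def initial_weights(n_env: int, restart_index: int, base_seed: int = 0) -> np.ndarray:
    """Restart initialization w~ = (1/L) 1 + N(0, (2/L^2) I)."""
    rng = np.random.default_rng([int(base_seed), int(restart_index)])
    return 1.0 / n_env + rng.standard_normal(n_env) * np.sqrt(2.0) / n_env


@dataclass
class GplemmaFit:
    theta: np.ndarray
    sigma_b2: float
    w_tilde: np.ndarray
    sigma_e2: float
    S: float
    es_weights: np.ndarray     # unit norm, canonical sign
    es_scale: float            # ||w~|| (implied sigma_gamma)
    restarts: list             # per-restart LMResult
    best_restart: int

    @property
    def restart_S(self) -> list:
        return [r.S for r in self.restarts]


def fit(objective, n_restarts: int = 10, base_seed: int = 0, tol: float = 1e-6,
        max_iter: int = 200, patience: int = 3, mu0: Optional[float] = None) -> GplemmaFit:
    """Multistart LM fit; keeps the solution with the lowest squared error."""
    L = objective.n_env
    results = []
    for r in range(n_restarts):
        w0 = initial_weights(L, r, base_seed)
        theta0 = objective.init_params(w0)
        results.append(lm_minimize(objective, theta0, mu0=mu0, tol=tol,
                                   max_iter=max_iter, patience=patience))
    finite = [i for i, res in enumerate(results) if np.isfinite(res.S)]
    if not finite:
        raise RuntimeError(
            "all LM restarts diverged; per-restart reasons: "
            + "; ".join(f"[{i}] {res.reason}" for i, res in enumerate(results))
        )
    best = min(finite, key=lambda i: results[i].S)
    theta = results[best].theta
    sb2, w, se2 = _split(theta)
    norm = float(np.linalg.norm(w))
    if norm > 0:
        es = w / norm
        if es[np.argmax(np.abs(es))] < 0:
            es = -es
    else:
        es = np.zeros_like(w)
    return GplemmaFit(theta=theta, sigma_b2=sb2, w_tilde=w, sigma_e2=se2,
                      S=results[best].S, es_weights=es, es_scale=norm,
                      restarts=results, best_restart=best)


def extract_es_and_pve(fit_result: GplemmaFit, objective, env_names=None) -> dict:
    """Heritability partition and environmental-score report for a fit.

    PVE is each fitted component's variance attribution over their sum
    (sums to 1); the ES is the unit-norm weight vector with canonical sign
    and eta_hat = E @ es_weights.
    """
    v_main, v_gxe, v_resid = objective.pve_components(fit_result.theta)
    total = v_main + v_gxe + v_resid
    eta_hat = objective.E @ fit_result.es_weights
    names = env_names if env_names is not None else [f"env_{l+1}" for l in range(objective.n_env)]
    return {
        "h2_main": float(v_main / total),
        "h2_gxe": float(v_gxe / total),
        "residual": float(v_resid / total),
        "sigma_b2": fit_result.sigma_b2,
        "sigma_e2": fit_result.sigma_e2,
        "es_scale": fit_result.es_scale,
        "es_weights": dict(zip(names, (float(v) for v in fit_result.es_weights))),
        "eta_hat": eta_hat,
        "S": fit_result.S,
        "restart_S": fit_result.restart_S,
        "best_restart": fit_result.best_restart,
        "converged": [r.converged for r in fit_result.restarts],
    }


def run_gplemma(source, design: EnvCovDesign, y, n_probes: int = 100, seed: int = 0,
                n_restarts: int = 10, tol: float = 1e-6, max_iter: int = 200,
                block_size: int = 1024, precomputes: StreamedPrecomputes | None = None):
    """End-to-end GPLEMMA: probes, streaming pass, multistart LM, ES report.

    Returns (report dict, GplemmaFit, HutchinsonObjective).  Restart
    initializations derive from ``seed`` (restart r uses child seed (seed, r)).
    """
    y = np.asarray(y, dtype=np.float64)
    y = y - y.mean()
    if precomputes is None:
        _, precomputes = prepare(source, design, y, n_probes=n_probes, seed=seed, block_size=block_size)
    objective = HutchinsonObjective(precomputes, design)
    fit_result = fit(objective, n_restarts=n_restarts, base_seed=seed, tol=tol, max_iter=max_iter)
    report = extract_es_and_pve(fit_result, objective, env_names=design.env_names)
    report["meta"] = {
        "n_samples": source.n_samples,
        "n_snps": precomputes.n_snps,
        "n_env": design.n_env,
        "n_covar": design.n_covar,
        "n_probes": precomputes.n_probes,
        "seed": seed,
        "n_restarts": n_restarts,
        "tol": tol,
        "max_iter": max_iter,
    }
    return report, fit_result, objective
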