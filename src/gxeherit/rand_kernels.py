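"""Randomized linear algebra for variance-component moment systems.

This module holds the machinery shared by the MEMMA and GPLEMMA estimators:

* Gaussian probe vectors for Hutchinson trace estimation,
  ``tr(A) = E[z^T A z]`` for ``z ~ N(0, I)``;
* the covariate projector ``W = I - C (C^T C)^{-1} C^T`` applied implicitly
  through a thin QR factorization of ``C`` (the N x N matrix is never formed);
* a single streaming pass over genotype blocks that accumulates every
  probe/data summary the estimators need:

  - ``u_b   = X X^T W z_b``                                  (main-effect kernel)
  - ``v_bl  = X X^T (E_l ⊙ W z_b)``                          (per-environment GxE kernel)
  - ``H_lm  = E_l^T diag(Wy) X X^T diag(Wy) E_m``            (data quadratic forms)
  - ``q_main = y^T W X X^T W y``,  ``yWy = (Wy)^T (Wy)``

* generic operator-composition products and trace estimates used by tests
  and small-problem oracles.

All trace estimates downstream are assembled as Gram matrices of operator
words applied to a *shared* probe set, which keeps the estimated moment
matrices symmetric positive semi-definite by construction and positively
correlates the Monte-Carlo errors of their entries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ProbeSet",
    "Projector",
    "StreamedPrecomputes",
    "draw_probes",
    "stream_precomputes",
    "apply_operator",
    "estimate_trace",
    "prepare",
]

DEFAULT_N_PROBES = 100


@dataclass(frozen=True)
class ProbeSet:
    """A fixed matrix of i.i.d. standard Gaussian probe vectors."""

    Z: np.ndarray  # (N, B)
    seed: int

    @property
    def n_samples(self) -> int:
        return self.Z.shape[0]

    @property
    def n_probes(self) -> int:
        return self.Z.shape[1]


def draw_probes(n_samples: int, n_probes: int = DEFAULT_N_PROBES, seed: int = 0) -> ProbeSet:
    """Draw ``n_probes`` Gaussian probe vectors z_b ~ N(0, I_N).

    The same probe set must be reused for every trace term within one
    analysis; reproducible given ``seed``.
    """
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_samples, n_probes))
    return ProbeSet(Z=Z, seed=seed)


class Projector:
    """Residual-forming projector onto the orthogonal complement of span(C).

    Applies ``W v = v - C (C^T C)^{-1} C^T v`` via a thin QR factorization.
    ``C`` must have full column rank (design assembly guarantees this).
    """

    def __init__(self, C: np.ndarray):
        C = np.atleast_2d(np.asarray(C, dtype=np.float64))
        if C.shape[0] < C.shape[1]:
            raise ValueError("C must be tall (N > D)")
        self.C = C
        self.Q, R = np.linalg.qr(C)
        diag = np.abs(np.diag(R))
        if diag.min() <= 1e-10 * max(diag.max(), 1.0):
            raise np.linalg.LinAlgError("C is numerically rank deficient")
        self.n_samples = C.shape[0]
        self.n_covar = C.shape[1]

    @property
    def trace(self) -> float:
        """tr(W) = N - D, exact."""
        return float(self.n_samples - self.n_covar)

    def apply(self, V: np.ndarray) -> np.ndarray:
        """Return W @ V for a vector or matrix V (never forms W)."""
        V = np.asarray(V, dtype=np.float64)
        return V - self.Q @ (self.Q.T @ V)


@dataclass
class StreamedPrecomputes:
    """One-pass streamed summaries reused by every downstream estimator.

    ``V`` is stored as an (N, L, B) array with ``V[:, l, b] = v_{b,l}``.
    ``q_env[l] == H[l, l]`` by construction (same quadratic form).
    """

    U: np.ndarray        # (N, B)      u_b = X X^T W z_b
    V: np.ndarray        # (N, L, B)   v_{b,l} = X X^T (E_l * W z_b)
    H: np.ndarray        # (L, L)
    q_main: float        # y^T W X X^T W y
    q_env: np.ndarray    # (L,) = diag(H)
    y_wy: float          # (Wy)^T (Wy)
    Wy: np.ndarray       # (N,)
    WZ: np.ndarray       # (N, B)
    n_snps: int
    n_probes: int
    n_env: int

    @property
    def n_samples(self) -> int:
        return self.U.shape[0]


def stream_precomputes(source, design, y, probes: ProbeSet, block_size: int = 1024) -> StreamedPrecomputes:
    """Accumulate U, V, H and the data quadratic forms in one genotype pass.

    ``E_l W z_b`` is read as the element-wise product ``E_l ⊙ (W z_b)``
    (E_l acts as diag(E_l)).  Cost O(N·M·L·B) time, O(N·L·B) memory.
    """
    E = np.asarray(design.E, dtype=np.float64)
    N, L = E.shape
    B = probes.n_probes
    M = source.n_snps
    proj = design.projector

    y = np.asarray(y, dtype=np.float64)
    if y.shape != (N,):
        raise ValueError("y must be an N-vector aligned with the design")
    Wy = proj.apply(y)
    WZ = proj.apply(probes.Z)

    # right-hand sides for X^T products: [WZ | E_l*WZ ... | Wy | E*Wy]
    n_uv = B + L * B
    rhs = np.empty((N, n_uv + 1 + L), dtype=np.float64)
    rhs[:, :B] = WZ
    for l in range(L):
        rhs[:, B + l * B : B + (l + 1) * B] = E[:, [l]] * WZ
    rhs[:, n_uv] = Wy
    rhs[:, n_uv + 1 :] = E * Wy[:, None]

    UV = np.zeros((N, n_uv), dtype=np.float64)
    H = np.zeros((L, L), dtype=np.float64)
    q_main = 0.0
    for _, _, Xb in source.blocks(block_size):
        G = Xb.T @ rhs
        UV += Xb @ G[:, :n_uv]
        gy = G[:, n_uv]
        q_main += float(gy @ gy)
        Genv = G[:, n_uv + 1 :]
        H += Genv.T @ Genv
    H = 0.5 * (H + H.T)
    if not (np.all(np.isfinite(UV)) and np.all(np.isfinite(H))):
        raise FloatingPointError("non-finite accumulation while streaming genotype blocks")

    return StreamedPrecomputes(
        U=UV[:, :B],
        V=UV[:, B:].reshape(N, L, B),
        H=H,
        q_main=q_main,
        q_env=np.diag(H).copy(),
        y_wy=float(Wy @ Wy),
        Wy=Wy,
        WZ=WZ,
        n_snps=M,
        n_probes=B,
        n_env=L,
    )


def apply_operator(word, v, source=None, design=None, wy=None, block_size: int = 1024):
    """Apply a composition of primitive operators to a vector, right-to-left.

    ``word`` is a sequence of tokens over the primitives

    - ``"I"``          identity
    - ``"K"``          GRM product, (X X^T / M) v, streamed over blocks
    - ``"W"``          covariate projector
    - ``("E", l)``     diag(E_l) v
    - ``"Dwy"``        diag(Wy) v (``wy`` must be supplied)

    Evaluation is exact (no randomization); only K touches the genotypes.
    """
    out = np.asarray(v, dtype=np.float64)
    for tok in reversed(list(word)):
        if tok == "I":
            continue
        elif tok == "W":
            if design is None:
                raise ValueError("'W' token requires a design")
            out = design.projector.apply(out)
        elif tok == "K":
            if source is None:
                raise ValueError("'K' token requires a genotype source")
            acc = np.zeros_like(out)
            for _, _, Xb in source.blocks(block_size):
                acc += Xb @ (Xb.T @ out)
            out = acc / source.n_snps
        elif tok == "Dwy":
            if wy is None:
                raise ValueError("'Dwy' token requires wy")
            out = np.asarray(wy, dtype=np.float64) * out
        elif isinstance(tok, tuple) and len(tok) == 2 and tok[0] == "E":
            if design is None:
                raise ValueError("('E', l) token requires a design")
            out = np.asarray(design.E, dtype=np.float64)[:, tok[1]] * out
        else:
            raise ValueError(f"malformed operator token: {tok!r}")
    return out


def estimate_trace(word, probes: ProbeSet, source=None, design=None, wy=None, block_size: int = 1024) -> float:
    """Hutchinson estimate ``(1/B) sum_b z_b^T (A z_b)`` of tr(A).

    ``A`` is the composed operator named by ``word``.  The trace of the bare
    projector is returned analytically (tr(W) = N - D, no probes used).
    """
    word = list(word)
    if word == ["W"]:
        if design is None:
            raise ValueError("'W' trace requires a design")
        return design.projector.trace
    total = 0.0
    for b in range(probes.n_probes):
        z = probes.Z[:, b]
        total += float(z @ apply_operator(word, z, source=source, design=design, wy=wy, block_size=block_size))
    return total / probes.n_probes


def prepare(source, design, y, n_probes: int = DEFAULT_N_PROBES, seed: int = 0, block_size: int = 1024):
    """Draw probes and run the streaming pass; returns (probes, precomputes)."""
    probes = draw_probes(source.n_samples, n_probes=n_probes, seed=seed)
    pre = stream_precomputes(source, design, y, probes, block_size=block_size)
    return probes, pre
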