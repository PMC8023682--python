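"""Synthetic genotype / environment / phenotype generation with known truth.

The generator emulates the study design the estimators are built for:
independent binomial SNPs standing in for genotype data, Gaussian or
binomial-ordinal environmental variables, and phenotypes of the form

    y = C alpha + X beta + (eta ⊙ X) gamma + eps,      eta = E w,

with spike-and-slab SNP effects (``M_G`` non-zero main effects, ``M_GxE``
non-zero interaction effects) and an interaction-weight vector holding
``L_active`` entries from an alternating, decreasing sequence.  Three
phenotype classes are provided: the baseline single-ES model above, a
generalization with three pairwise-orthogonal environmental scores, and a
misspecified phenotype with a squared dependence on a heritable environment.

Every simulated component is rescaled *in-sample* so its realized variance
fraction of var(y) equals the configured target exactly (the noise vector is
residualized against the fixed components so the budget closes with
var(y) = 1); this makes parameter-recovery tests sharp.  All outputs are
bit-reproducible given ``SimConfig.seed``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .genio import GenotypeSource

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimData",
    "simulate_genotypes",
    "simulate_environments",
    "make_interaction_weights",
    "simulate_baseline",
    "simulate_multi_es",
    "simulate_misspecified",
    "simulate_dataset",
    "leading_pc",
]

# Causal-SNP counts in the configuration below are defined at this reference
# panel size and scale pro rata for other M (constant polygenicity fraction).
REFERENCE_M = 100_000


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults are the generator's reference design: N=25K samples, M=100K
    SNPs, L=30 environments of which 6 carry interaction weight, 2500 causal
    main-effect SNPs, 1250 interaction SNPs, 20% main-effect heritability,
    5% GxE heritability, and covariates explaining 1% of trait variance.
    """

    n_samples: int = 25_000
    n_snps: int = 100_000
    n_env: int = 30
    n_active_env: int = 6
    n_causal_main: int = 2_500
    n_causal_gxe: int = 1_250
    h2_main: float = 0.20
    h2_gxe: float = 0.05
    covar_frac: float = 0.01
    seed: int = 0
    env_kind: str = "continuous"
    maf_low: float = 0.05
    maf_high: float = 0.5
    weight_form: str = "linear"

    def __post_init__(self):
        if not (1 <= self.n_active_env <= self.n_env):
            raise ValueError("need 1 <= n_active_env <= n_env")
        if not (0 < self.n_causal_main <= self.n_snps and 0 < self.n_causal_gxe <= self.n_snps):
            raise ValueError("causal counts must lie in [1, n_snps]")
        for name in ("h2_main", "h2_gxe", "covar_frac"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.h2_main + self.h2_gxe + self.covar_frac >= 1:
            raise ValueError("variance fractions must sum to < 1")
        if self.env_kind not in ("continuous", "ordinal"):
            raise ValueError("env_kind must be 'continuous' or 'ordinal'")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
        if self.weight_form not in ("linear", "sqrt"):
            raise ValueError("weight_form must be 'linear' or 'sqrt'")


@dataclass
class SimTruth:
    """Ground truth of one simulated phenotype.

    ``fractions`` records the realized variance decomposition of y; the
    entries for covariate / main / gxe are exact by construction and the
    four component fractions plus the recorded in-sample cross term sum
    to 1.
    """

    beta: np.ndarray
    gamma: np.ndarray                    # (M,) or (M, K)
    w_true: np.ndarray                   # (L,) or (L, K)
    eta_true: np.ndarray                 # (N,) or (N, K)
    alpha: np.ndarray
    fractions: dict
    per_es_scale: Optional[np.ndarray] = None
    per_es_h2: Optional[np.ndarray] = None


@dataclass
class SimData:
    """A full simulated dataset bundle (inputs plus ground truth)."""

    config: SimConfig
    source: GenotypeSource
    E: np.ndarray
    C: np.ndarray                        # covariate supplied to estimators (leading genetic PC)
    y: np.ndarray
    truth: SimTruth
    allele_freqs: np.ndarray
    S: Optional[np.ndarray] = None       # heritable environment of the misspecified design
    kind: str = "baseline"


def simulate_genotypes(n_samples: int, n_snps: int, maf_low: float = 0.05, maf_high: float = 0.5, seed: int = 0):
    """Draw a raw 0/1/2 genotype matrix with per-SNP Binomial(2, p) dosages.

    Allele frequencies are uniform on [maf_low, maf_high]; columns whose
    realized variance is zero are resampled so no monomorphic SNP survives.
    Returns (raw int8 matrix, allele frequency vector).
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(maf_low, maf_high, size=n_snps)
    raw = rng.binomial(2, freqs[None, :], size=(n_samples, n_snps)).astype(np.int8)
    while True:
        var = raw.var(axis=0)
        bad = np.flatnonzero(var == 0)
        if bad.size == 0:
            break
        freqs[bad] = rng.uniform(maf_low, maf_high, size=bad.size)
        raw[:, bad] = rng.binomial(2, freqs[None, bad], size=(n_samples, bad.size)).astype(np.int8)
    return raw, freqs


def simulate_environments(n_samples: int, n_env: int, kind: str = "continuous", seed: int = 0) -> np.ndarray:
    """Simulate an N x L standardized environment matrix.

    ``continuous`` draws standard Gaussians; ``ordinal`` draws each column
    from Binomial(n, p) with n in {3, 4, 5} levels and p ~ U(0, 0.5),
    redrawing any degenerate (single-level) column.  Columns are standardized
    to mean 0, variance 1 afterwards.
    """
    if n_env < 1:
        raise ValueError("n_env must be >= 1")
    rng = np.random.default_rng(seed)
    if kind == "continuous":
        E = rng.standard_normal((n_samples, n_env))
    elif kind == "ordinal":
        cols = []
        while len(cols) < n_env:
            n_levels = rng.choice([3, 4, 5])
            p = rng.uniform(0.0, 0.5)
            col = rng.binomial(n_levels, p, size=n_samples)
            if np.unique(col).size < 2:
                continue
            cols.append(col.astype(np.float64))
        E = np.column_stack(cols)
    else:
        raise ValueError("kind must be 'continuous' or 'ordinal'")
    return (E - E.mean(axis=0)) / E.std(axis=0)


def make_interaction_weights(n_env: int, n_active: int, form: str = "linear") -> np.ndarray:
    """Alternating decreasing interaction-weight sequence with L_active non-zeros.

    For 1-based i <= n_active:  w_i = (-1)^i * (1 - i / (2 * n_active))
    (``form='sqrt'`` uses the square-root of the decreasing factor instead);
    all later entries are zero.  Magnitudes are strictly decreasing over the
    active range.
    """
    if not (1 <= n_active <= n_env):
        raise ValueError("need 1 <= n_active <= n_env")
    w = np.zeros(n_env)
    i = np.arange(1, n_active + 1)
    mag = 1.0 - i / (2.0 * n_active)
    if form == "sqrt":
        mag = np.sqrt(mag)
    elif form != "linear":
        raise ValueError("form must be 'linear' or 'sqrt'")
    w[:n_active] = (-1.0) ** i * mag
    return w


def _center(v: np.ndarray) -> np.ndarray:
    return v - v.mean()


def _exact_mix(components, targets, noise, rng_unused=None):
    """Scale components to exact in-sample variance fractions with var(y)=1.

    ``components`` are N-vectors, ``targets`` their variance fractions.
    The noise vector is residualized against the non-null components, then
    scaled so total variance is exactly 1.  Returns (y, scales, fractions)
    where fractions records the realized decomposition including the
    residual cross-covariance among the fixed components.
    """
    comps = [_center(np.asarray(c, dtype=np.float64)) for c in components]
    targets = np.asarray(targets, dtype=np.float64)
    if targets.sum() >= 1.0:
        raise ValueError("variance fractions must sum to < 1")
    scales = np.zeros(len(comps))
    scaled = []
    for i, (c, f) in enumerate(zip(comps, targets)):
        if f > 0:
            sd = c.std()
            if sd == 0:
                raise ValueError(f"component {i} is degenerate but has a positive target fraction")
            scales[i] = np.sqrt(f) / sd
        scaled.append(scales[i] * c)
    fixed = np.sum(scaled, axis=0)
    var_fixed = fixed.var()

    eps = _center(np.asarray(noise, dtype=np.float64))
    active = [s for s, f in zip(scaled, targets) if f > 0]
    if active:
        A = np.column_stack(active)
        coef, *_ = np.linalg.lstsq(A, eps, rcond=None)
        eps = eps - A @ coef
    if var_fixed >= 1.0:
        raise ValueError("fixed components already exceed total variance; lower the fractions")
    s_eps = np.sqrt(1.0 - var_fixed) / eps.std()
    y = fixed + s_eps * eps

    cross = var_fixed - targets.sum()
    fractions = {"noise": 1.0 - var_fixed, "cross": cross}
    return y, scales, s_eps, fractions


def leading_pc(source: GenotypeSource, n_iter: int = 15, seed: int = 0) -> np.ndarray:
    """Leading left singular vector of the standardized genotype matrix.

    Plain power iteration on X X^T; accuracy needs are mild because the
    vector only serves as a covariate.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal(source.n_samples)
    for _ in range(n_iter):
        v = source.kernel_dot(v)
        v /= np.linalg.norm(v)
    return v


def scaled_causal_count(ref_count: int, n_snps: int) -> int:
    """Causal-SNP count defined at the reference panel size, scaled pro rata.

    Keeps the polygenicity fraction constant when simulating fewer SNPs than
    the reference M (at least one causal SNP is always returned).
    """
    return max(1, round(ref_count * n_snps / REFERENCE_M))


def _spike_slab(rng, n_snps: int, n_causal: int):
    idx = rng.choice(n_snps, size=n_causal, replace=False)
    vec = np.zeros(n_snps)
    vec[idx] = rng.standard_normal(n_causal)
    return vec, idx


def simulate_baseline(config: SimConfig, source: GenotypeSource, E: np.ndarray, C=None, seed=None):
    """Simulate the baseline single-ES phenotype; returns (y, SimTruth).

    ``C`` is the covariate vector/matrix carrying ``covar_frac`` of the trait
    variance (the leading genetic PC when not supplied).  beta has
    ``n_causal_main`` non-zeros and gamma ``n_causal_gxe``, at positions
    chosen uniformly at random; the realized fractions of var(y) hit the
    configured targets exactly.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    N, M, L = source.n_samples, source.n_snps, E.shape[1]
    if E.shape[0] != N:
        raise ValueError("E and genotypes disagree on N")
    if C is None:
        C = leading_pc(source, seed=rng.integers(2**31))
    C = np.asarray(C, dtype=np.float64)
    c_vec = C[:, 0] if C.ndim == 2 else C

    w = make_interaction_weights(L, config.n_active_env, form=config.weight_form)
    eta = E @ w
    beta, _ = _spike_slab(rng, M, config.n_causal_main)
    main = source.dot(beta)
    if config.h2_gxe > 0:
        gamma, _ = _spike_slab(rng, M, config.n_causal_gxe)
        gxe = eta * source.dot(gamma)
    else:
        gamma = np.zeros(M)
        gxe = np.zeros(N)
    noise = rng.standard_normal(N)

    y, scales, s_eps, fr = _exact_mix(
        [c_vec, main, gxe],
        [config.covar_frac, config.h2_main, config.h2_gxe],
        noise,
    )
    truth = SimTruth(
        beta=scales[1] * beta,
        gamma=scales[2] * gamma,
        w_true=w,
        eta_true=eta,
        alpha=np.array([scales[0]]),
        fractions={
            "covariates": config.covar_frac if scales[0] > 0 else 0.0,
            "main": config.h2_main,
            "gxe": config.h2_gxe,
            **fr,
        },
    )
    return y, truth


def simulate_multi_es(config: SimConfig, source: GenotypeSource, E: np.ndarray, C=None,
                      singular_values=(80.0, 60.0, 40.0), seed=None):
    """Phenotype with K orthogonal environmental scores and disjoint GxE SNP sets.

    The weight matrix W (L x K) has ``n_active_env`` non-zero rows with
    orthonormal columns; each gamma_k has ``n_causal_gxe`` non-zeros, supports
    pairwise disjoint, scaled so the singular values of Lambda = W Gamma^T
    are proportional to ``singular_values`` (the total GxE fraction of
    var(y) is still ``h2_gxe``).  Returns (y, SimTruth).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    N, M, L = source.n_samples, source.n_snps, E.shape[1]
    K = len(singular_values)
    sv = np.asarray(singular_values, dtype=np.float64)
    if np.any(np.diff(sv) > 0):
        raise ValueError("singular values must be non-increasing")
    if K * config.n_causal_gxe > M:
        raise ValueError("disjoint GxE supports do not fit: K * n_causal_gxe > n_snps")
    if C is None:
        C = leading_pc(source, seed=rng.integers(2**31))
    c_vec = np.asarray(C, dtype=np.float64)
    c_vec = c_vec[:, 0] if c_vec.ndim == 2 else c_vec

    A = rng.standard_normal((config.n_active_env, K))
    Q, _ = np.linalg.qr(A)
    W = np.zeros((L, K))
    W[: config.n_active_env, :] = Q
    eta = E @ W  # (N, K)

    perm = rng.permutation(M)
    Gamma = np.zeros((M, K))
    gxe = np.zeros(N)
    for k in range(K):
        sup = perm[k * config.n_causal_gxe : (k + 1) * config.n_causal_gxe]
        g = rng.standard_normal(config.n_causal_gxe)
        Gamma[sup, k] = sv[k] * g / np.linalg.norm(g)
        gxe = gxe + eta[:, k] * source.dot(Gamma[:, k])

    beta, _ = _spike_slab(rng, M, config.n_causal_main)
    main = source.dot(beta)
    noise = rng.standard_normal(N)
    y, scales, s_eps, fr = _exact_mix(
        [c_vec, main, gxe],
        [config.covar_frac, config.h2_main, config.h2_gxe],
        noise,
    )
    Gamma_scaled = scales[2] * Gamma
    per_es = np.array(
        [(eta[:, k] * source.dot(Gamma_scaled[:, k])).var() for k in range(K)]
    )
    truth = SimTruth(
        beta=scales[1] * beta,
        gamma=Gamma_scaled,
        w_true=W,
        eta_true=eta,
        alpha=np.array([scales[0]]),
        fractions={
            "covariates": config.covar_frac if scales[0] > 0 else 0.0,
            "main": config.h2_main,
            "gxe": config.h2_gxe,
            **fr,
        },
        per_es_scale=scales[2] * sv,
        per_es_h2=per_es,
    )
    return y, truth


def simulate_misspecified(config: SimConfig, source: GenotypeSource, E: np.ndarray, C=None,
                          alpha_s: float = 0.0, s_h2: float = 0.30, s_n_causal_ref: int = 2_500,
                          seed=None):
    """Baseline phenotype plus a squared effect of a heritable environment S.

    S is simulated from the genotypes with heritability ``s_h2`` (exact by
    rescaling) and ``s_n_causal_ref`` causal SNPs at the reference panel size
    (scaled pro rata for other M), standardized, and substituted for the last
    column of E (inactive in the true ES whenever n_active_env < n_env).
    Returns (y, SimTruth, S, E_mod) with y = alpha_s * S^2 + y_baseline.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    N, M = source.n_samples, source.n_snps
    n_causal_s = scaled_causal_count(s_n_causal_ref, M)
    beta_s, _ = _spike_slab(rng, M, n_causal_s)
    genetic = _center(source.dot(beta_s))
    e_s = _center(rng.standard_normal(N))
    e_s -= genetic * (genetic @ e_s) / (genetic @ genetic)
    S = np.sqrt(s_h2) * genetic / genetic.std() + np.sqrt(1.0 - s_h2) * e_s / e_s.std()
    S = (S - S.mean()) / S.std()

    E_mod = E.copy()
    if config.n_active_env >= config.n_env:
        warnings.warn("all environments are ES-active; the heritable environment S will carry true GxE")
    E_mod[:, -1] = S
    y_base, truth = simulate_baseline(config, source, E_mod, C=C, seed=rng.integers(2**31))
    y = alpha_s * S**2 + y_base
    return y, truth, S, E_mod


def simulate_dataset(config: SimConfig, kind: str = "baseline", alpha_s: float = 0.0,
                     singular_values=(80.0, 60.0, 40.0)) -> SimData:
    """Generate a complete dataset (genotypes, environments, covariate PC, y).

    All randomness derives from ``config.seed`` through independent child
    seeds for genotypes, environments and the phenotype.
    """
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]
    raw, freqs = simulate_genotypes(
        config.n_samples, config.n_snps, config.maf_low, config.maf_high, seed=seeds[0]
    )
    source = GenotypeSource(raw)
    E = simulate_environments(config.n_samples, config.n_env, kind=config.env_kind, seed=seeds[1])
    pc = leading_pc(source, seed=seeds[2])
    S = None
    if kind == "baseline":
        y, truth = simulate_baseline(config, source, E, C=pc, seed=seeds[3])
    elif kind == "multi_es":
        y, truth = simulate_multi_es(config, source, E, C=pc, singular_values=singular_values, seed=seeds[3])
    elif kind == "misspecified":
        y, truth, S, E = simulate_misspecified(config, source, E, C=pc, alpha_s=alpha_s, seed=seeds[3])
    else:
        raise ValueError("kind must be 'baseline', 'multi_es' or 'misspecified'")
    return SimData(
        config=config, source=source, E=E, C=pc[:, None], y=y, truth=truth,
        allele_freqs=freqs, S=S, kind=kind,
    )


def write_dataset(data: SimData, prefix) -> None:
    """Write a simulated dataset as PLINK BED/BIM/FAM + TSV tables + truth JSON."""
    import json
    from pathlib import Path

    import pandas as pd

    from .genio import write_plink

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_plink(prefix, data.source.raw, sample_ids=list(data.source.sample_ids),
                snp_ids=list(data.source.snp_ids))
    ids = pd.Index(data.source.sample_ids, name="IID")
    pd.DataFrame({"phenotype": data.y}, index=ids).to_csv(f"{prefix}.pheno.tsv", sep="\t")
    env_names = [f"env_{l+1}" for l in range(data.E.shape[1])]
    pd.DataFrame(data.E, index=ids, columns=env_names).to_csv(f"{prefix}.env.tsv", sep="\t")
    pd.DataFrame({"genetic_pc1": data.C[:, 0]}, index=ids).to_csv(f"{prefix}.covar.tsv", sep="\t")
    truth = {
        "kind": data.kind,
        "config": {k: (v if not isinstance(v, np.generic) else v.item()) for k, v in vars(data.config).items()},
        "beta": data.truth.beta.tolist(),
        "gamma": data.truth.gamma.tolist(),
        "w_true": data.truth.w_true.tolist(),
        "eta_true": data.truth.eta_true.tolist(),
        "alpha": data.truth.alpha.tolist(),
        "fractions": data.truth.fractions,
    }
    if data.truth.per_es_scale is not None:
        truth["per_es_scale"] = data.truth.per_es_scale.tolist()
        truth["per_es_h2"] = data.truth.per_es_h2.tolist()
    with open(f"{prefix}.truth.json", "w") as fh:
        json.dump(truth, fh)
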