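"""Genotype / phenotype / environment input handling.

Covers reading PLINK 1 binary genotypes (BED/BIM/FAM triplets), block-wise
genotype standardization (column mean 0, variance 1 with denominator N, so
that tr(X X^T / M) = N exactly), covariate/environment design assembly with
the environments always appended to the covariate matrix, and the optional
pre-screen for squared environmental effects.

Missing genotypes are mean-imputed per SNP before standardization, which
leaves the centered value at exactly 0 so a missing call contributes nothing
to any cross-product.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .rand_kernels import Projector

__all__ = [
    "GenotypeSource",
    "EnvCovDesign",
    "read_genotypes",
    "standardize_block",
    "assemble_design",
    "squared_effect_screen",
    "read_plink",
    "write_plink",
]

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major mode
# 2-bit PLINK codes -> allele-1 dosage; 0b01 is the missing code.
_BED_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


class ZeroVarianceError(ValueError):
    """A genotype or environment column is constant and cannot be standardized."""


def standardize_block(raw_block: np.ndarray) -> np.ndarray:
    """Standardize columns to mean 0, variance 1 (denominator N).

    ``raw_block`` is a block of 0/1/2 dosages with missing values already
    imputed.  A zero-variance column raises: such SNPs must be filtered
    upstream.
    """
    X = np.asarray(raw_block, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)  # ddof=0
    if np.any(sd == 0):
        raise ZeroVarianceError("zero-variance genotype column; filter monomorphic SNPs first")
    return (X - mu) / sd


class GenotypeSource:
    """Standardized genotypes served in column blocks.

    Holds the raw 0/1/2 dosage matrix (int8, -1 for missing) plus the
    standardized float64 matrix; at the sample sizes this package targets the
    dense copy (O(N·M) doubles) is the fastest layout, and two passes over
    the source yield bit-identical slabs.  Monomorphic columns (constant
    after mean imputation) are dropped with a warning.
    """

    def __init__(self, raw: np.ndarray, sample_ids=None, snp_ids=None):
        raw = np.asarray(raw)
        if raw.ndim != 2:
            raise ValueError("raw genotypes must be an N x M matrix")
        N, M = raw.shape
        self.sample_ids = (
            np.asarray(sample_ids, dtype=object)
            if sample_ids is not None
            else np.array([f"sample_{i+1}" for i in range(N)], dtype=object)
        )
        self.snp_ids = (
            np.asarray(snp_ids, dtype=object)
            if snp_ids is not None
            else np.array([f"snp_{j+1}" for j in range(M)], dtype=object)
        )
        if len(self.sample_ids) != N or len(self.snp_ids) != M:
            raise ValueError("ID lengths do not match the genotype matrix")

        self._raw = raw.astype(np.int8, copy=True)
        X = raw.astype(np.float64, copy=True)
        missing = X < 0
        if missing.all(axis=0).any():
            bad = self.snp_ids[missing.all(axis=0)]
            warnings.warn(f"dropping {len(bad)} all-missing SNP(s): {list(bad[:5])}")
            keep = ~missing.all(axis=0)
            self._raw = self._raw[:, keep]
            self.snp_ids = self.snp_ids[keep]
            X = X[:, keep]
            missing = missing[:, keep]
        if missing.any():
            counts = (~missing).sum(axis=0)
            sums = np.where(missing, 0.0, X).sum(axis=0)
            means = sums / counts
            X[missing] = np.broadcast_to(means, X.shape)[missing]
        self.means = X.mean(axis=0)
        self.scales = X.std(axis=0)
        poly = self.scales > 0
        if not poly.all():
            warnings.warn(
                f"dropping {int((~poly).sum())} monomorphic SNP(s): "
                f"{list(self.snp_ids[~poly][:5])}"
            )
            X = X[:, poly]
            self._raw = self._raw[:, poly]
            self.snp_ids = self.snp_ids[poly]
            self.means = self.means[poly]
            self.scales = self.scales[poly]
        self._X = (X - self.means) / self.scales

    @property
    def n_samples(self) -> int:
        return self._X.shape[0]

    @property
    def n_snps(self) -> int:
        return self._X.shape[1]

    @property
    def raw(self) -> np.ndarray:
        return self._raw

    def blocks(self, block_size: int = 1024):
        """Yield (start, stop, standardized N x block slab) over SNP columns."""
        if block_size < 1:
            raise ValueError("block_size must be >= 1")
        for j0 in range(0, self.n_snps, block_size):
            j1 = min(j0 + block_size, self.n_snps)
            yield j0, j1, self._X[:, j0:j1]

    def dot(self, beta: np.ndarray) -> np.ndarray:
        """X @ beta over standardized genotypes."""
        return self._X @ np.asarray(beta, dtype=np.float64)

    def kernel_dot(self, v: np.ndarray) -> np.ndarray:
        """(X X^T / M) v."""
        return self._X @ (self._X.T @ np.asarray(v, dtype=np.float64)) / self.n_snps

    def reorder(self, sample_ids) -> "GenotypeSource":
        """Subset/reorder samples by ID; means and scales are recomputed."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in index]
        if missing:
            raise KeyError(f"sample IDs absent from genotype data: {missing[:10]}")
        rows = np.array([index[s] for s in sample_ids])
        return GenotypeSource(self._raw[rows], sample_ids=np.asarray(sample_ids, dtype=object), snp_ids=self.snp_ids)


# ---------------------------------------------------------------------------
# PLINK 1 binary triplet
# ---------------------------------------------------------------------------

def write_plink(prefix, raw: np.ndarray, sample_ids=None, snp_ids=None, chromosomes=None, positions=None) -> None:
    """Write an N x M dosage matrix (0/1/2, -1 missing) as BED/BIM/FAM.

    The variant map is a dummy grid (chromosome 1, 1-based positions) unless
    explicit coordinates are supplied; allele identity is irrelevant after
    standardization so alleles are written as A/B.
    """
    prefix = str(prefix)
    raw = np.asarray(raw, dtype=np.int8)
    N, M = raw.shape
    if sample_ids is None:
        sample_ids = [f"sample_{i+1}" for i in range(N)]
    if snp_ids is None:
        snp_ids = [f"snp_{j+1}" for j in range(M)]
    if chromosomes is None:
        chromosomes = np.ones(M, dtype=int)
    if positions is None:
        positions = np.arange(1, M + 1)

    fam = pd.DataFrame(
        {
            "fid": sample_ids,
            "iid": sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": chromosomes,
            "snp": snp_ids,
            "cm": 0,
            "pos": positions,
            "a1": "A",
            "a2": "B",
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)

    codes = np.empty_like(raw, dtype=np.uint8)
    for dosage, code in _BED_ENCODE.items():
        codes[raw == dosage] = code
    n_pad = (-N) % 4
    if n_pad:
        codes = np.vstack([codes, np.full((n_pad, M), _BED_ENCODE[0], dtype=np.uint8)])
    quads = codes.T.reshape(M, -1, 4)
    packed = quads[:, :, 0] | (quads[:, :, 1] << 2) | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())


def read_plink(prefix):
    """Read a BED/BIM/FAM triplet; returns (raw int8 N x M, fam, bim) frames."""
    prefix = str(prefix)
    for ext in (".bed", ".bim", ".fam"):
        if not Path(prefix + ext).exists():
            raise FileNotFoundError(f"missing PLINK file: {prefix + ext}")
    fam = pd.read_csv(
        f"{prefix}.fam",
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"snp": str},
    )
    N, M = len(fam), len(bim)
    data = np.fromfile(f"{prefix}.bed", dtype=np.uint8)
    if bytes(data[:3]) != _PLINK_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK 1 BED file")
    bytes_per_snp = (N + 3) // 4
    body = data[3:]
    if body.size != bytes_per_snp * M:
        raise ValueError("BED payload size inconsistent with FAM/BIM dimensions")
    body = body.reshape(M, bytes_per_snp)
    codes = np.empty((M, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (body >> (2 * k)) & 0b11
    raw = _BED_DECODE[codes[:, :N]].T.copy()
    return raw, fam, bim


def read_genotypes(bed_prefix, sample_keep=None, snp_keep=None) -> GenotypeSource:
    """Load a PLINK triplet into a GenotypeSource.

    ``sample_keep`` / ``snp_keep`` are ID lists; sample order follows
    ``sample_keep`` when given (use this to align genotypes to a phenotype
    table), otherwise FAM order.
    """
    raw, fam, bim = read_plink(bed_prefix)
    sample_ids = fam["iid"].to_numpy(dtype=object)
    snp_ids = bim["snp"].to_numpy(dtype=object)
    if snp_keep is not None:
        keep = set(snp_keep)
        mask = np.array([s in keep for s in snp_ids])
        raw, snp_ids = raw[:, mask], snp_ids[mask]
    source = GenotypeSource(raw, sample_ids=sample_ids, snp_ids=snp_ids)
    if sample_keep is not None:
        source = source.reorder(list(sample_keep))
    return source


# ---------------------------------------------------------------------------
# Environment / covariate design
# ---------------------------------------------------------------------------

@dataclass
class EnvCovDesign:
    """Standardized environment matrix E and covariate matrix C with E ⊆ C.

    The intercept column is exempt from standardization.  ``projector``
    applies W = I - C (C^T C)^{-1} C^T implicitly.
    """

    E: np.ndarray
    C: np.ndarray
    env_names: list
    covar_names: list
    sample_ids: np.ndarray
    _projector: Projector | None = field(default=None, repr=False)

    @property
    def n_samples(self) -> int:
        return self.C.shape[0]

    @property
    def n_env(self) -> int:
        return self.E.shape[1]

    @property
    def n_covar(self) -> int:
        return self.C.shape[1]

    @property
    def projector(self) -> Projector:
        if self._projector is None:
            self._projector = Projector(self.C)
        return self._projector

    def with_covariates(self, extra: np.ndarray, names) -> "EnvCovDesign":
        C = np.column_stack([self.C, extra]) if np.size(extra) else self.C
        return EnvCovDesign(
            E=self.E,
            C=C,
            env_names=list(self.env_names),
            covar_names=list(self.covar_names) + list(names),
            sample_ids=self.sample_ids,
        )


def _standardize_columns(A: np.ndarray, names, what: str) -> np.ndarray:
    mu = A.mean(axis=0)
    sd = A.std(axis=0)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ZeroVarianceError(f"constant {what} column(s): {[names[i] for i in bad]}")
    return (A - mu) / sd


def assemble_design(env, covar=None, add_intercept: bool = True, sample_ids=None) -> EnvCovDesign:
    """Build the (E, C) design with the environments always appended to C.

    ``env``/``covar`` are DataFrames indexed by sample ID (rows with missing
    values are dropped with a warning, after aligning on the common IDs) or
    plain arrays.  Covariate columns that are collinear with columns already
    in C — including duplicates of an environment — are dropped with a
    warning, so C keeps full column rank.
    """
    if isinstance(env, pd.DataFrame):
        env_df = env
        if covar is not None and isinstance(covar, pd.DataFrame):
            common = env_df.index.intersection(covar.index)
            if len(common) < len(env_df) or len(common) < len(covar):
                warnings.warn("environment/covariate tables only partially overlap; using common IDs")
            env_df = env_df.loc[common]
            covar = covar.loc[common]
        joined = env_df if covar is None else pd.concat([env_df, covar], axis=1)
        ok = ~joined.isna().any(axis=1)
        if not ok.all():
            warnings.warn(f"dropping {int((~ok).sum())} sample(s) with missing values")
            env_df = env_df.loc[ok]
            covar = covar.loc[ok] if covar is not None else None
        sample_ids = env_df.index.to_numpy(dtype=object)
        env_names = list(env_df.columns)
        E_raw = env_df.to_numpy(dtype=np.float64)
        covar_names = list(covar.columns) if covar is not None else []
        C_user = covar.to_numpy(dtype=np.float64) if covar is not None else None
    else:
        E_raw = np.asarray(env, dtype=np.float64)
        env_names = [f"env_{l+1}" for l in range(E_raw.shape[1])]
        C_user = np.asarray(covar, dtype=np.float64) if covar is not None else None
        if C_user is not None and C_user.ndim == 1:
            C_user = C_user[:, None]
        covar_names = [f"covar_{d+1}" for d in range(C_user.shape[1])] if C_user is not None else []
        sample_ids = (
            np.asarray(sample_ids, dtype=object)
            if sample_ids is not None
            else np.array([f"sample_{i+1}" for i in range(E_raw.shape[0])], dtype=object)
        )

    N, L = E_raw.shape
    if L < 2:
        raise ValueError("at least 2 environmental variables are required")
    E = _standardize_columns(E_raw, env_names, "environment")

    cols, names = [], []
    if add_intercept:
        cols.append(np.ones(N))
        names.append("intercept")
    # E goes in first so duplicated user covariates are the ones dropped.
    base = np.column_stack(cols + [E]) if cols else E.copy()
    base_names = names + [f"E:{n}" for n in env_names]
    kept_user, kept_names = [], []
    if C_user is not None:
        C_user = _standardize_columns(C_user, covar_names, "covariate")
        Q, _ = np.linalg.qr(base)
        for d in range(C_user.shape[1]):
            col = C_user[:, d]
            resid = col - Q @ (Q.T @ col)
            if np.linalg.norm(resid) <= 1e-8 * np.linalg.norm(col):
                warnings.warn(f"dropping collinear/duplicate covariate column '{covar_names[d]}'")
                continue
            kept_user.append(col)
            kept_names.append(covar_names[d])
            q = resid / np.linalg.norm(resid)
            Q = np.column_stack([Q, q])

    user_block = np.column_stack(kept_user) if kept_user else np.empty((N, 0))
    if add_intercept:
        C = np.column_stack([np.ones(N), user_block, E])
        covar_names_out = ["intercept"] + kept_names + [f"E:{n}" for n in env_names]
    else:
        C = np.column_stack([user_block, E])
        covar_names_out = kept_names + [f"E:{n}" for n in env_names]
    if N <= C.shape[1]:
        raise ValueError(f"design is over-parameterized: N={N} <= D={C.shape[1]}")
    return EnvCovDesign(E=E, C=C, env_names=env_names, covar_names=covar_names_out, sample_ids=sample_ids)


def squared_effect_screen(y, design: EnvCovDesign, alpha_level: float = 0.01):
    """Per-environment screen for squared effects on the phenotype (+SQE).

    Each environment is tested in turn with an OLS fit of ``y`` on
    ``[C | E_l^2]`` (adjusting for the covariates already in C, which include
    the linear environment terms) and a two-sided t-test on the squared-term
    coefficient.  Squared columns with p < alpha_level / L are standardized
    and appended to C.  Returns (augmented design, report DataFrame).
    """
    y = np.asarray(y, dtype=np.float64)
    E = design.E
    L = design.n_env
    threshold = alpha_level / L
    rows, extras, extra_names = [], [], []
    for l in range(L):
        sq = E[:, l] ** 2
        sd = sq.std()
        if sd == 0:
            rows.append((design.env_names[l], np.nan, np.nan, 1.0, False))
            continue
        sq_std = (sq - sq.mean()) / sd
        res = sm.OLS(y, np.column_stack([design.C, sq_std])).fit()
        coef = float(res.params[-1])
        pval = float(res.pvalues[-1])
        include = bool(pval < threshold)
        rows.append((design.env_names[l], coef, float(res.tvalues[-1]), pval, include))
        if include:
            extras.append(sq_std)
            extra_names.append(f"SQE:{design.env_names[l]}")
    report = pd.DataFrame(rows, columns=["environment", "coefficient", "tvalue", "pvalue", "included"])
    if extras:
        new_design = design.with_covariates(np.column_stack(extras), extra_names)
    else:
        new_design = design
    return new_design, report
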