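"""Tier-1 gene analysis: principal-components regression on raw genotypes.

A gene's SNP dosage block is standardized and projected onto its principal
components.  Components carrying a negligible share of the variance are pruned
(by default 0.1% of the variance is discarded), which removes redundant
parameters under strong LD and keeps the regression identifiable.  The
retained component scores are then used as joint predictors of the phenotype
in an ordinary linear model, and the gene p-value is the F-test of the genetic
coefficients, conditional on any covariates.  The same linear model is used
for binary phenotypes; its accuracy there can be checked with the adaptive
permutation procedure implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

# Eigenvalues below this fraction of the leading eigenvalue are treated as
# numerical rank deficiency and dropped before variance pruning.
RANK_EPS = 1e-8

# Floor applied to p-values so downstream probit transforms stay finite.
P_FLOOR = 1e-300


class GeneExcluded(Exception):
    """Raised when a gene cannot be analysed (signalled, never silently skipped)."""

    def __init__(self, gene_id: str, reason: str):
        self.gene_id = gene_id
        self.reason = reason
        super().__init__(f"gene {gene_id!r} excluded: {reason}")


@dataclass
class GeneModel:
    """Per-gene orthonormal PC basis on standardized dosages.

    ``pc_scores`` holds the unit-norm, mean-centred score vectors of the
    retained components (columns mutually orthogonal); ``eigenvalues`` are the
    corresponding variances of the standardized SNP matrix, in decreasing
    order.  ``K`` (the number of retained components) is the effective gene
    size; ``density`` is K divided by the number of SNPs in the gene.
    """

    gene_id: str
    pc_scores: np.ndarray  # (n_samples, K), orthonormal columns
    eigenvalues: np.ndarray  # (K,), descending, strictly positive
    n_snps: int  # m: SNPs in the gene (after all-missing columns were dropped)

    @property
    def K(self) -> int:
        return self.pc_scores.shape[1]

    @property
    def n_samples(self) -> int:
        return self.pc_scores.shape[0]

    @property
    def density(self) -> float:
        return self.K / self.n_snps


@dataclass
class GeneRegressionFit:
    alpha0: float
    alpha: np.ndarray  # genetic (PC) effects
    beta_cov: np.ndarray  # covariate effects
    rss_full: float
    rss_null: float
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class GeneResult:
    """One gene's analysis outcome: the tier-1 -> tier-2 handoff record."""

    gene_id: str
    chromosome: str
    start_bp: int
    stop_bp: int
    n_snps: int  # m
    n_params: int  # effective gene size K (or #SNPs for SNP-wise models)
    n_used: int
    stat: float
    p: float
    z: float

    @property
    def density(self) -> float:
        return self.n_params / self.n_snps


@dataclass(frozen=True)
class AdaptiveSchedule:
    """Checkpointed adaptive permutation: stop at the first checkpoint where the
    observed statistic has been exceeded at least ``min_exceedances`` times."""

    checkpoints: tuple = (1_000, 10_000, 100_000, 1_000_000)
    min_exceedances: int = 10

    def __post_init__(self):
        if not self.checkpoints or list(self.checkpoints) != sorted(self.checkpoints):
            raise ValueError("checkpoints must be a non-empty increasing sequence")


def impute_missing(
    dosage_block: np.ndarray, snp_positions: Optional[Sequence[int]] = None
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministically fill missing genotype entries from flanking SNPs.

    Each missing entry is predicted by least squares on the nearest observed
    flanking SNP column(s) (left and right neighbour), falling back to the
    column mean when no flanking information exists.  Predictions are clipped
    into [0, 2].  Columns that are entirely missing are dropped.

    Returns ``(imputed_block, kept_column_indices)``.
    """
    X = np.asarray(dosage_block, dtype=float)
    if X.ndim != 2:
        raise ValueError("dosage block must be 2-D (samples x SNPs)")
    obs = np.isfinite(X)
    keep = obs.any(axis=0)
    if not keep.all():
        logger.info("dropping %d all-missing SNP column(s)", int((~keep).sum()))
    kept_idx = np.flatnonzero(keep)
    X = X[:, keep].copy()
    obs = obs[:, keep]
    n, m = X.shape
    col_means = np.array([X[obs[:, j], j].mean() for j in range(m)])

    for j in range(m):
        miss = ~obs[:, j]
        if not miss.any():
            continue
        neighbours = [k for k in (j - 1, j + 1) if 0 <= k < m]
        for i in np.flatnonzero(miss):
            preds = [k for k in neighbours if obs[i, k]]
            value = None
            if preds:
                rows = obs[:, j] & np.all(obs[:, preds], axis=1)
                if rows.sum() >= len(preds) + 2:
                    A = np.column_stack([np.ones(rows.sum()), X[rows][:, preds]])
                    coef, *_ = np.linalg.lstsq(A, X[rows, j], rcond=None)
                    value = coef[0] + X[i, preds] @ coef[1:]
            if value is None or not np.isfinite(value):
                value = col_means[j]
            X[i, j] = np.clip(value, 0.0, 2.0)
    return X, kept_idx


def build_gene_model(
    dosage_block: np.ndarray, prune_fraction: float = 0.999, gene_id: str = ""
) -> GeneModel:
    """Standardize a gene's SNP block and retain the top principal components.

    ``prune_fraction`` f is the fraction of the (standardized) SNP variance to
    retain: K is the smallest number of components whose cumulative eigenvalue
    share reaches f.  The default f=0.999 prunes away 0.1% of the variance.
    Zero-variance SNP columns are dropped first; eigenvalues below a relative
    rank tolerance are always discarded.
    """
    if not 0.0 < prune_fraction <= 1.0:
        raise ValueError("prune_fraction must be in (0, 1]")
    X = np.asarray(dosage_block, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise GeneExcluded(gene_id, "no SNP columns")
    if not np.isfinite(X).all():
        raise GeneExcluded(gene_id, "missing values present (impute first)")
    n, m = X.shape
    sd = X.std(axis=0, ddof=1)
    poly = sd > 0
    if not poly.any():
        raise GeneExcluded(gene_id, "all SNPs monomorphic")
    Z = (X[:, poly] - X[:, poly].mean(axis=0)) / sd[poly]
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    eig = s**2 / (n - 1)
    eig = eig[eig > RANK_EPS * eig[0]]
    k_max = len(eig)
    cum = np.cumsum(eig) / eig.sum()
    K = int(np.searchsorted(cum, prune_fraction - 1e-12) + 1)
    K = min(K, k_max)
    return GeneModel(
        gene_id=gene_id,
        pc_scores=U[:, :K],
        eigenvalues=eig[:K].copy(),
        n_snps=m,
    )


def _null_basis(n: int, covariates: Optional[np.ndarray]) -> np.ndarray:
    """Orthonormal basis of the null design [1, W]."""
    cols = [np.ones((n, 1))]
    c = 0
    if covariates is not None:
        W = np.atleast_2d(np.asarray(covariates, dtype=float))
        if W.shape[0] != n:
            W = W.T
        c = W.shape[1]
        cols.append(W)
    Xn = np.hstack(cols)
    if np.linalg.matrix_rank(Xn) < Xn.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    Q, _ = np.linalg.qr(Xn)
    return Q[:, : 1 + c]


def fit_gene_regression(
    model: GeneModel,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> GeneRegressionFit:
    """OLS of the phenotype on [1, W, PC scores] with an F-test of the PC block.

    The null model conditions on the covariates alone; the F statistic compares
    residual sums of squares between the two fits.  Binary (0/1) phenotypes are
    handled by the identical linear model.
    """
    y = np.asarray(phenotype, dtype=float)
    n = model.n_samples
    if y.shape != (n,):
        raise ValueError("phenotype length does not match model samples")
    if not np.isfinite(y).all():
        raise ValueError("phenotype contains missing values; drop samples first")
    U = model.pc_scores
    K = model.K
    cols = [np.ones((n, 1))]
    if covariates is not None:
        W = np.asarray(covariates, dtype=float)
        if W.ndim == 1:
            W = W[:, None]
        cols.append(W)
    X_null = np.hstack(cols)
    c = X_null.shape[1] - 1
    if np.linalg.matrix_rank(X_null) < X_null.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    df2 = n - K - c - 1
    if df2 <= 0:
        raise GeneExcluded(model.gene_id, f"insufficient residual df (df2={df2})")

    beta_null, *_ = np.linalg.lstsq(X_null, y, rcond=None)
    rss_null = float(np.sum((y - X_null @ beta_null) ** 2))
    X_full = np.hstack([X_null, U])
    beta_full, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    rss_full = float(np.sum((y - X_full @ beta_full) ** 2))
    rss_full = min(rss_full, rss_null)

    denom = rss_full / df2
    if denom <= 0:
        F = np.inf
    else:
        F = max((rss_null - rss_full) / K / denom, 0.0)
    p = float(np.clip(stats.f.sf(F, K, df2), P_FLOOR, 1.0))
    return GeneRegressionFit(
        alpha0=float(beta_full[0]),
        alpha=beta_full[1 + c :].copy(),
        beta_cov=beta_full[1 : 1 + c].copy(),
        rss_full=rss_full,
        rss_null=rss_null,
        F=float(F),
        df1=K,
        df2=df2,
        p=p,
    )


def _f_statistics(Y: np.ndarray, Q: np.ndarray, M: np.ndarray, df2: int) -> np.ndarray:
    """Vectorized F statistics for phenotype columns Y given the orthonormal
    null basis Q and the orthonormalized model-increment basis M."""
    K = M.shape[1]
    qy = Q.T @ Y
    my = M.T @ Y
    tot = np.einsum("ij,ij->j", Y, Y) - np.einsum("ij,ij->j", qy, qy)
    ssm = np.einsum("ij,ij->j", my, my)
    rss_full = np.maximum(tot - ssm, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssm / K) / (rss_full / df2)
    return np.where(np.isfinite(F), F, np.inf)


def permutation_pvalue(
    model: GeneModel,
    phenotype: np.ndarray,
    covariates: Optional[np.ndarray] = None,
    schedule: AdaptiveSchedule = AdaptiveSchedule(),
    rng_seed: int = 0,
    batch_size: int = 1024,
) -> tuple[float, int]:
    """Adaptive-permutation empirical p-value for the gene F statistic.

    The phenotype (its residuals from the covariate-only null model, when
    covariates are present) is permuted; the empirical p-value is
    (r+1)/(P+1) where r counts permuted F statistics at or above the observed
    one.  Permutation stops at the first schedule checkpoint with at least
    ``schedule.min_exceedances`` exceedances.  Deterministic given the seed.
    """
    y = np.asarray(phenotype, dtype=float)
    n = model.n_samples
    U = model.pc_scores
    K = model.K
    Q = _null_basis(n, covariates)
    c = Q.shape[1] - 1
    df2 = n - K - c - 1
    if df2 <= 0:
        raise GeneExcluded(model.gene_id, f"insufficient residual df (df2={df2})")
    M = U - Q @ (Q.T @ U)
    M, _ = np.linalg.qr(M)
    e = y - Q @ (Q.T @ y)
    f_obs = float(_f_statistics(e[:, None], Q, M, df2)[0])

    rng = np.random.default_rng(rng_seed)
    done = 0
    r = 0
    for checkpoint in schedule.checkpoints:
        while done < checkpoint:
            b = min(batch_size, checkpoint - done)
            perms = rng.permuted(np.broadcast_to(e, (b, n)).copy(), axis=1)
            f_perm = _f_statistics(perms.T, Q, M, df2)
            r += int(np.count_nonzero(f_perm >= f_obs))
            done += b
        if r >= schedule.min_exceedances:
            break
    return (r + 1) / (done + 1), done
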