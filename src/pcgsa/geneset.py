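"""Tier-2 gene-level regression: self-contained and competitive gene-set tests.

Gene p-values are converted to Z-values z_g = probit(1 - p_g).  The
self-contained test fits an intercept-only model to the Z-values of the set's
genes by generalized least squares (GLS) with error correlation R_s (the
gene-gene correlation submatrix) and error variance fixed at 1, testing
beta_0 > 0.  The competitive test regresses the Z-values of *all* genes on a
set-membership indicator (plus, by default, gene size and density covariates
and their logs) with GLS error structure sigma^2 R, testing beta_s > 0.  With
R = I and no covariates the competitive test is exactly a one-sided pooled
two-sample t-test, and the self-contained test a one-sided z-test of the mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import linalg, stats

from .correlation import GeneCorrelationMatrix, ridged_cholesky
from .gene_model import GeneResult

logger = logging.getLogger(__name__)

P_CLIP = 1e-12  # two-sided clipping of gene p-values before the probit
P_FLOOR = 1e-300

SIZE_CORRECTION_COLUMNS = ("n_pcs", "density", "log_n_pcs", "log_density")


class DegenerateFit(ValueError):
    """The gene-level regression fits the data perfectly (no residual df left)."""


def p_to_z(p):
    """Probit transform z = Phi^-1(1 - p) after clipping p into
    [1e-12, 1 - 1e-12].  p <= 0 is an error (upstream must not produce it)."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("p-values must be positive")
    return stats.norm.isf(np.clip(arr, P_CLIP, 1 - P_CLIP))


@dataclass
class GeneLevelDesign:
    """All-gene design for the gene-level regression: Z-values, named gene
    covariate columns, and the gene-gene correlation matrix."""

    gene_ids: list
    z: np.ndarray
    covariates: dict  # name -> vector aligned to gene_ids
    R: Union[GeneCorrelationMatrix, np.ndarray]

    def __post_init__(self):
        self._index = {g: i for i, g in enumerate(self.gene_ids)}
        self._chol = None

    def dense_R(self) -> np.ndarray:
        if isinstance(self.R, GeneCorrelationMatrix):
            return self.R.dense()
        return np.asarray(self.R, dtype=float)

    def cholesky(self) -> np.ndarray:
        if self._chol is None:
            self._chol, _ = ridged_cholesky(self.dense_R())
        return self._chol

    def indicator(self, gene_ids: Sequence[str]) -> np.ndarray:
        s = np.zeros(len(self.gene_ids))
        for g in gene_ids:
            if g in self._index:
                s[self._index[g]] = 1.0
        return s

    def subset_indices(self, gene_ids: Sequence[str]) -> list:
        return [self._index[g] for g in gene_ids if g in self._index]


def design_from_results(
    results: Sequence[GeneResult],
    R: Union[GeneCorrelationMatrix, np.ndarray],
) -> GeneLevelDesign:
    """Build the gene-level design from tier-1 results: probit Z-values plus
    effective-size/density covariate columns (and their logs)."""
    gene_ids = [r.gene_id for r in results]
    z = p_to_z([r.p for r in results])
    n_pcs = np.array([r.n_params for r in results], dtype=float)
    density = np.array([r.n_params / r.n_snps for r in results])
    covariates = {
        "n_pcs": n_pcs,
        "density": density,
        "log_n_pcs": np.log(n_pcs),
        "log_density": np.log(density),
    }
    return GeneLevelDesign(gene_ids=gene_ids, z=z, covariates=covariates, R=R)


@dataclass
class GeneSetResult:
    set_name: str
    n_genes_in_data: int
    test_type: str  # self_contained | competitive
    beta: float
    se: float
    stat: float
    p_one_sided: float
    covariates_used: list = field(default_factory=list)
    p_adjusted: Optional[float] = None
    significant: Optional[bool] = None


def self_contained_test(
    z_s: np.ndarray,
    R_s: np.ndarray,
    set_name: str = "",
) -> GeneSetResult:
    """GLS intercept-only model on the set's Z-values with sigma^2 = 1.

    Under the self-contained null every z_g is standard normal, so the
    intercept estimate divided by its (known-variance) standard error is a
    standard-normal statistic; the p-value is its one-sided upper tail.
    """
    z_s = np.asarray(z_s, dtype=float)
    if z_s.size == 0:
        raise ValueError("empty gene set")
    R_s = np.atleast_2d(np.asarray(R_s, dtype=float))
    L, _ = ridged_cholesky(R_s)
    ones = linalg.solve_triangular(L, np.ones(z_s.size), lower=True)
    zw = linalg.solve_triangular(L, z_s, lower=True)
    denom = float(ones @ ones)  # = 1' R^-1 1
    beta0 = float(ones @ zw) / denom
    se = 1.0 / np.sqrt(denom)
    stat = beta0 / se
    p = float(np.clip(stats.norm.sf(stat), P_FLOOR, 1.0))
    return GeneSetResult(
        set_name=set_name,
        n_genes_in_data=z_s.size,
        test_type="self_contained",
        beta=beta0,
        se=se,
        stat=stat,
        p_one_sided=p,
    )


def _gls_fit(
    z: np.ndarray, X: np.ndarray, names: list, L: np.ndarray
) -> tuple[np.ndarray, np.ndarray, int, float, list]:
    """GLS via whitening with the Cholesky factor of the (ridged) R.

    Collinear columns are dropped with a warning (the first occurrence of each
    linearly dependent direction is kept).  Returns (beta, se, df, sigma2,
    kept column names).
    """
    G = z.size
    Xw = linalg.solve_triangular(L, X, lower=True)
    zw = linalg.solve_triangular(L, z, lower=True)
    # ordered greedy rank selection: earlier columns (intercept, tested set)
    # take precedence over later covariates when directions coincide
    keep: list = []
    basis = np.empty((G, 0))
    for j in range(Xw.shape[1]):
        col = Xw[:, j]
        resid = col - basis @ (basis.T @ col) if basis.shape[1] else col
        norm = np.linalg.norm(resid)
        if norm > 1e-8 * max(np.linalg.norm(col), 1e-300):
            keep.append(j)
            basis = np.column_stack([basis, resid / norm])
    if len(keep) < Xw.shape[1]:
        dropped = [i for i in range(Xw.shape[1]) if i not in keep]
        logger.warning(
            "dropping collinear gene-level column(s): %s",
            ", ".join(names[i] for i in dropped),
        )
    Xw = Xw[:, keep]
    names = [names[i] for i in keep]
    df = G - Xw.shape[1]
    if df <= 0:
        raise DegenerateFit("no residual degrees of freedom")
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ zw)
    resid = zw - Xw @ beta
    rss = float(resid @ resid)
    sigma2 = rss / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = np.sqrt(np.diag(cov))
    return beta, se, df, sigma2, names


def generalized_test(
    design: GeneLevelDesign,
    columns: dict,
    tested: str,
    one_sided: bool = True,
    set_name: str = "",
    test_type: str = "competitive",
    n_genes_in_data: Optional[int] = None,
) -> GeneSetResult:
    """General gene-level GLS regression of Z on named property columns.

    ``columns`` maps column names to gene-aligned vectors (binary set
    indicators, continuous properties, interactions...).  The coefficient of
    ``tested`` is reported with a one-sided (upper-tail, enrichment) or
    two-sided t p-value with df = G - #predictors.
    """
    if tested not in columns:
        raise ValueError(f"tested column {tested!r} not in formula")
    G = len(design.gene_ids)
    names = ["intercept"] + list(columns)
    X = np.column_stack([np.ones(G)] + [np.asarray(columns[c], float) for c in columns])
    L = design.cholesky()
    beta, se, df, sigma2, kept = _gls_fit(design.z, X, names, L)
    if tested not in kept:
        raise ValueError(f"tested column {tested!r} was dropped as collinear")
    k = kept.index(tested)
    scale = float(np.mean(design.z**2))
    if sigma2 <= np.finfo(float).eps * max(scale, 1.0):
        # residual variance vanished: a zero tested coefficient (e.g. constant
        # Z) is a null result; a nonzero one is a degenerate (perfect) fit
        if abs(beta[k]) > 1e-10 * max(1.0, np.sqrt(scale)):
            raise DegenerateFit(
                f"perfect fit: column {tested!r} explains Z exactly"
            )
        return GeneSetResult(
            set_name=set_name,
            n_genes_in_data=n_genes_in_data if n_genes_in_data is not None else G,
            test_type=test_type,
            beta=0.0,
            se=float(se[k]),
            stat=0.0,
            p_one_sided=0.5,
            covariates_used=[c for c in kept if c not in ("intercept", tested)],
        )
    stat = beta[k] / se[k]
    if one_sided:
        p = stats.t.sf(stat, df)
    else:
        p = 2 * stats.t.sf(abs(stat), df)
    return GeneSetResult(
        set_name=set_name,
        n_genes_in_data=n_genes_in_data if n_genes_in_data is not None else G,
        test_type=test_type,
        beta=float(beta[k]),
        se=float(se[k]),
        stat=float(stat),
        p_one_sided=float(np.clip(p, P_FLOOR, 1.0)),
        covariates_used=[c for c in kept if c not in ("intercept", tested)],
    )


def competitive_test(
    design: GeneLevelDesign,
    set_genes: Sequence[str],
    correct_size_density: bool = True,
    set_name: str = "",
    one_sided: bool = True,
) -> GeneSetResult:
    """Competitive gene-set test over all genes in the data.

    Regresses Z on the set indicator, by default conditioning on effective
    gene size, gene density and their logs; tests beta_s > 0 (enrichment).
    """
    s = design.indicator(set_genes)
    n_in = int(s.sum())
    if n_in == 0 or n_in == len(s):
        raise ValueError("set indicator must contain both member and non-member genes")
    columns = {"set": s}
    if correct_size_density:
        for name in SIZE_CORRECTION_COLUMNS:
            if name in design.covariates:
                columns[name] = design.covariates[name]
    return generalized_test(
        design,
        columns,
        tested="set",
        one_sided=one_sided,
        set_name=set_name,
        test_type="competitive",
        n_genes_in_data=n_in,
    )


def multiple_testing_adjust(
    results: Sequence[GeneSetResult],
    method: str = "bonferroni",
    alpha: float = 0.05,
    n_tests: Optional[int] = None,
) -> list:
    """Bonferroni family-wise adjustment: p_adj = min(1, p * #sets tested)."""
    if method != "bonferroni":
        raise ValueError(f"unsupported method {method!r}")
    n = n_tests if n_tests is not None else len(results)
    for res in results:
        res.p_adjusted = min(1.0, res.p_one_sided * n)
        res.significant = res.p_adjusted < alpha
    return list(results)
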