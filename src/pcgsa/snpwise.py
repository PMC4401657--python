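"""SNP-wise gene statistics: mean chi-squared and top chi-squared.

These models combine per-SNP 1-df chi-squared association statistics into a
gene statistic, so they work both on raw genotypes (SNP tests computed
internally) and on published SNP p-values combined with LD estimated from a
reference panel of matching ancestry.

Under the null the SNP Z-scores within a gene are jointly normal with
correlation equal to the SNP LD matrix, so the sum of the chi-squared values
is distributed as a weighted sum of independent 1-df chi-squares whose weights
are the LD eigenvalues.  The mean-chi-squared p-value evaluates that tail
exactly by numerical characteristic-function inversion (Imhof's method), with
a two-moment Satterthwaite approximation as fallback.  The top statistic has
no such closed form and uses adaptive permutation of a random standard-normal
phenotype on the LD source data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, stats

from .annotation import GeneAnnotation
from .gene_model import AdaptiveSchedule
from .io import GenotypeDataset, SnpPvalueTable

logger = logging.getLogger(__name__)


class WeightedChisqError(RuntimeError):
    """Both tail evaluators failed for a gene."""


def standardize(block: np.ndarray) -> np.ndarray:
    """Mean-impute missing entries, then center/scale columns to unit
    variance.  Zero-variance columns are dropped."""
    X = np.asarray(block, dtype=float).copy()
    for j in range(X.shape[1]):
        miss = ~np.isfinite(X[:, j])
        if miss.any():
            X[miss, j] = np.nanmean(X[:, j])
    sd = X.std(axis=0, ddof=1)
    X = X[:, sd > 0]
    return (X - X.mean(axis=0)) / sd[sd > 0]


def ld_matrix(block: np.ndarray) -> np.ndarray:
    """Pearson LD matrix of a dosage block (missing entries mean-imputed)."""
    Z = standardize(block)
    n = Z.shape[0]
    R = (Z.T @ Z) / (n - 1)
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    return R


def snp_association(block: np.ndarray, phenotype: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Marginal linear-regression test per SNP.

    Returns (chi, p): 1-df chi-squared statistics obtained by transforming the
    per-SNP two-sided p-values, and those p-values.  Constant SNPs get p=1.
    """
    X = np.asarray(block, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n = len(y)
    ys = (y - y.mean())
    sy = ys.std(ddof=1)
    if sy == 0:
        raise ValueError("constant phenotype")
    ys = ys / sy
    p = np.ones(X.shape[1])
    sd = np.nanstd(X, axis=0, ddof=1)
    Z = standardize(X)
    r = Z.T @ ys / (n - 1)
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t2 = (n - 2) * r**2 / (1 - r**2)
    p_poly = stats.f.sf(t2, 1, n - 2)
    p[sd > 0] = p_poly
    chi = stats.chi2.isf(np.clip(p, 1e-300, 1.0), 1)
    return chi, p


def chisq_from_pvalues(p: np.ndarray) -> np.ndarray:
    """Inverse upper-tail 1-df chi-squared transform of SNP p-values."""
    return stats.chi2.isf(np.clip(np.asarray(p, dtype=float), 1e-300, 1.0), 1)


# ---------------------------------------------------------------------------
# Weighted chi-squared tail


def _imhof_sf(x: float, lam: np.ndarray) -> tuple[float, float]:
    """Imhof (1961) inversion: P(sum lam_i chi2_1 > x).  Returns (p, abserr)."""

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * x * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return np.sin(theta) / (u * rho)

    import warnings

    with warnings.catch_warnings():
        # the explicit error estimate below is what decides acceptance
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, err = integrate.quad(
            integrand, 0, np.inf, epsabs=1e-11, epsrel=1e-10, limit=600
        )
    return 0.5 + val / np.pi, err


def _satterthwaite_sf(x: float, lam: np.ndarray) -> float:
    """Two-moment scaled chi-squared approximation to the weighted-sum tail."""
    s1, s2 = lam.sum(), (lam**2).sum()
    scale = s2 / s1
    df = s1**2 / s2
    return float(stats.chi2.sf(x / scale, df))


def _ruben_coefficients(
    lam: np.ndarray, tol: float = 1e-13, max_terms: int = 20000
) -> Optional[tuple[float, np.ndarray]]:
    """Series representation of the weighted-chi-squared distribution as a
    mixture of central chi-squares (Ruben 1962 / Farebrother 1984).

    With beta the harmonic-type anchor 2*min*max/(min+max), the tail is
    sum_k a_k * SF_chi2(x / beta, m + 2k).  The coefficients depend only on
    the eigenvalues, so they are computed once and reused across evaluation
    points.  Returns (beta, a) or None if the series has not decayed below
    ``tol`` within ``max_terms`` terms.
    """
    m = lam.size
    beta = 2.0 * lam.min() * lam.max() / (lam.min() + lam.max())
    r = 1.0 - beta / lam  # all |r| < 1 since 0 < beta < 2*min(lam)
    a = np.empty(max_terms)
    b = np.empty(max_terms)
    a[0] = float(np.exp(0.5 * np.sum(np.log(beta / lam))))
    rk = r.copy()
    for k in range(1, max_terms):
        b[k] = rk.sum()
        rk *= r
        # a_k = (1/2k) * sum_{j=0}^{k-1} b_{k-j} a_j
        a[k] = 0.5 / k * float(np.dot(b[1 : k + 1][::-1], a[:k]))
        if k > 16 and abs(a[k]) < tol and abs(a[k - 1]) < tol:
            return beta, a[: k + 1]
    return None


class WeightedChisqTail:
    """Reusable tail evaluator for Q = sum_i w_i chi2_1 with fixed weights.

    Negative weights (reference-panel noise) are clipped to zero.  Equal
    weights reduce exactly to a scaled central chi-squared; general weights
    use the Ruben series (coefficients precomputed once), falling back to
    Imhof integration and then to a Satterthwaite approximation.
    """

    def __init__(self, weights: np.ndarray, gene_id: str = ""):
        lam = np.asarray(weights, dtype=float)
        lam = np.clip(lam, 0.0, None)
        lam = lam[lam > 1e-10 * max(lam.max(initial=0.0), 1e-300)]
        self.lam = lam
        self.gene_id = gene_id
        self._ruben = None
        self._dfs = None
        if lam.size > 1 and not np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
            self._ruben = _ruben_coefficients(lam)
            if self._ruben is not None:
                beta, a = self._ruben
                self._dfs = lam.size + 2.0 * np.arange(a.size)

    def sf(self, x: float) -> float:
        """Upper-tail probability P(Q > x)."""
        lam = self.lam
        if lam.size == 0 or x <= 0:
            return 1.0
        if lam.size == 1 or np.allclose(lam, lam[0], rtol=1e-12, atol=0.0):
            return float(np.clip(stats.chi2.sf(x / lam[0], lam.size), 1e-300, 1.0))
        if self._ruben is not None:
            beta, a = self._ruben
            terms = stats.chi2.sf(x / beta, self._dfs)
            p = float(a @ terms)
            if np.isfinite(p) and -1e-8 <= p <= 1 + 1e-8:
                return float(np.clip(p, 1e-300, 1.0))
        try:
            with np.errstate(over="ignore"):
                p, err = _imhof_sf(x, lam)
            if np.isfinite(p) and -1e-6 <= p <= 1 + 1e-6 and err < 1e-6:
                return float(np.clip(p, 1e-300, 1.0))
            logger.debug("Imhof unreliable (p=%g, err=%g)", p, err)
        except Exception:  # pragma: no cover - quad failure path
            logger.debug("Imhof integration raised; using Satterthwaite")
        p = _satterthwaite_sf(x, lam)
        if not np.isfinite(p):
            raise WeightedChisqError(
                f"tail evaluation failed for gene {self.gene_id!r}"
            )
        return float(np.clip(p, 1e-300, 1.0))


def weighted_chisq_sf(x: float, weights: np.ndarray, gene_id: str = "") -> float:
    """One-shot upper-tail probability of sum_i w_i chi2_1 at x (see
    :class:`WeightedChisqTail` for the evaluation strategy)."""
    return WeightedChisqTail(weights, gene_id=gene_id).sf(x)


def mean_chisq_pvalue(
    chi: np.ndarray, ld: np.ndarray, gene_id: str = ""
) -> tuple[float, float]:
    """Mean-chi-squared gene statistic and its weighted-chi-squared p-value."""
    chi = np.asarray(chi, dtype=float)
    ld = np.asarray(ld, dtype=float)
    if ld.shape != (chi.size, chi.size):
        raise ValueError("chi-squared vector and LD matrix dimensions disagree")
    lam = np.linalg.eigvalsh(ld)
    lam = np.clip(lam, 0.0, None)
    stat = float(chi.mean())
    p = weighted_chisq_sf(float(chi.sum()), lam, gene_id=gene_id)
    return stat, p


# ---------------------------------------------------------------------------
# Top chi-squared (adaptive permutation)


def top_chisq_pvalues(
    observed_top: Sequence[float],
    ld_source_block: np.ndarray,
    schedule: AdaptiveSchedule = AdaptiveSchedule(),
    rng_seed: int = 0,
    batch_size: int = 512,
) -> tuple[np.ndarray, int]:
    """Empirical p-values for one or more observed top-chi-squared statistics
    of the same gene, sharing one permutation stream.

    A single standard-normal phenotype is drawn on the LD-source samples and
    permuted; each permutation yields the gene's maximum marginal chi-squared.
    Permutation stops at the first schedule checkpoint where every observed
    statistic has at least ``schedule.min_exceedances`` exceedances.  Returns
    (p-values as (r+1)/(P+1), permutations used).
    """
    obs = np.asarray(observed_top, dtype=float)
    Z = standardize(ld_source_block)
    n, m = Z.shape
    if m == 0:
        raise ValueError("LD source block has no polymorphic SNPs")
    rng = np.random.default_rng(rng_seed)
    y = rng.standard_normal(n)
    y = (y - y.mean()) / y.std(ddof=1)

    counts = np.zeros(obs.shape, dtype=np.int64)
    done = 0
    for checkpoint in schedule.checkpoints:
        while done < checkpoint:
            b = min(batch_size, checkpoint - done)
            perms = rng.permuted(np.broadcast_to(y, (b, n)).copy(), axis=1)
            r = (Z.T @ perms.T) / (n - 1)
            np.clip(r, -1 + 1e-15, 1 - 1e-15, out=r)
            chi = (n - 2) * r**2 / (1 - r**2)
            top = chi.max(axis=0)
            counts += (top[None, :] >= obs[:, None]).sum(axis=1)
            done += b
        if (counts >= schedule.min_exceedances).all():
            break
    return (counts + 1) / (done + 1), done


def top_chisq_pvalue(
    chi: np.ndarray,
    ld_source_block: np.ndarray,
    schedule: AdaptiveSchedule = AdaptiveSchedule(),
    rng_seed: int = 0,
) -> tuple[float, float, int]:
    """Top-chi-squared gene statistic with its adaptive-permutation p-value."""
    stat = float(np.max(np.asarray(chi, dtype=float)))
    p, n_perms = top_chisq_pvalues([stat], ld_source_block, schedule, rng_seed)
    return stat, float(p[0]), n_perms


# ---------------------------------------------------------------------------
# Summary-statistics path


@dataclass
class GeneSummary:
    """Per-gene inputs for the SNP-wise models in summary-statistics mode."""

    gene_id: str
    chi: np.ndarray
    snp_ids: list
    ref_indices: np.ndarray  # columns of the reference dosage matrix
    ld: np.ndarray


def align_to_reference(
    pvals: SnpPvalueTable,
    annotation: GeneAnnotation,
    reference: GenotypeDataset,
) -> tuple[dict, list]:
    """Intersect annotated SNPs with the reference panel, per gene.

    The annotation indexes SNPs of the reference panel; only SNPs also present
    in the p-value table are retained (matched by id; chi-squared statistics
    are allele-flip invariant so no allele check is made).  Genes losing all
    SNPs are excluded and returned in the skipped list.
    """
    per_gene: dict = {}
    skipped: list = []
    for gid, idx in annotation.assignments.items():
        ids, cols, chi = [], [], []
        for i in idx:
            sid = reference.snps[i].snp_id
            if sid in pvals.entries:
                p, _ = pvals.entries[sid]
                ids.append(sid)
                cols.append(i)
                chi.append(stats.chi2.isf(min(max(p, 1e-300), 1.0), 1))
        if not ids:
            skipped.append(gid)
            continue
        cols = np.asarray(cols)
        block = reference.snp_block(cols)
        per_gene[gid] = GeneSummary(
            gene_id=gid,
            chi=np.asarray(chi),
            snp_ids=ids,
            ref_indices=cols,
            ld=ld_matrix(block),
        )
    if skipped:
        logger.info(
            "%d gene(s) had no SNPs present in both data and reference: %s",
            len(skipped),
            ", ".join(skipped[:10]) + ("..." if len(skipped) > 10 else ""),
        )
    return per_gene, skipped
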