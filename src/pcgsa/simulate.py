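"""Synthetic LD-structured genotypes and phenotypes.

Genotypes are generated from a latent-Gaussian AR(1) model: two independent
haplotype chains per individual follow a first-order autoregression along the
chromosome (correlation between consecutive latent values decays as
rho^(distance / snp_spacing_bp)) and are thresholded at the Hardy-Weinberg
quantile of a per-SNP minor allele frequency drawn uniformly from
``maf_range``.  The resulting diploid dosages show LD that decays with
distance, with adjacent-SNP correlation controlled by rho.  This emulates the
block-like local LD of dense GWAS chips well enough to exercise every tier of
the analysis; it does not reproduce real human haplotype-block structure.

Phenotype generators cover the simulation designs used to validate the
analysis: a global null (phenotype independent of genotype, Gaussian or
case/control), a polygenic null with a chosen heritability spread over random
causal SNPs, and a multi-marker gene effect with weak marginal associations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import GeneLocation, GenotypeDataset, SnpRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    Defaults give the scale used throughout validation: 2,000 samples, 50
    genes of 10 SNPs each on one chromosome, strong local LD (rho = 0.9),
    MAFs uniform on [0.05, 0.5], and a 50%-heritability polygenic model.
    """

    n_samples: int = 2000
    n_genes: int = 50
    n_snps_per_gene: int = 10
    ld_rho: float = 0.9
    maf_range: tuple = (0.05, 0.5)
    h2: float = 0.5
    n_causal: int = 100
    seed: int = 0
    snp_spacing_bp: int = 1000
    gene_gap_bp: int = 5000
    missing_rate: float = 0.0
    chromosome: str = "1"

    def __post_init__(self):
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")


def snp_positions(config: SimConfig) -> np.ndarray:
    """1-based SNP positions: genes laid end to end with a fixed gap."""
    span = (config.n_snps_per_gene - 1) * config.snp_spacing_bp
    starts = 1 + np.arange(config.n_genes) * (span + config.gene_gap_bp)
    offsets = np.arange(config.n_snps_per_gene) * config.snp_spacing_bp
    return (starts[:, None] + offsets[None, :]).ravel()


def gene_locations(config: SimConfig) -> list:
    """Gene locations matching :func:`snp_positions` (gene g spans its SNPs)."""
    pos = snp_positions(config).reshape(config.n_genes, config.n_snps_per_gene)
    return [
        GeneLocation(f"G{g + 1:04d}", config.chromosome, int(pos[g, 0]), int(pos[g, -1]))
        for g in range(config.n_genes)
    ]


def _latent_chain(rng: np.random.Generator, n: int, phi: np.ndarray) -> np.ndarray:
    """AR(1) latent Gaussian field of n samples x len(phi) columns.

    ``phi`` holds the lag-1 correlation between column j-1 and column j for
    j >= 1 (phi[0] unused).  Marginals are standard normal.
    """
    m = phi.size
    Z = rng.standard_normal((n, m))
    for j in range(1, m):
        Z[:, j] = phi[j] * Z[:, j - 1] + np.sqrt(1.0 - phi[j] ** 2) * Z[:, j]
    return Z


def simulate_genotypes(config: SimConfig) -> GenotypeDataset:
    """LD-structured diploid dosages (pure function of the config/seed)."""
    rng = np.random.default_rng(config.seed)
    pos = snp_positions(config)
    m = pos.size
    n = config.n_samples
    phi = np.zeros(m)
    if config.ld_rho > 0:
        gaps = np.diff(pos) / config.snp_spacing_bp
        phi[1:] = config.ld_rho ** gaps
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    thr = stats.norm.isf(maf)
    dosage = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        Z = _latent_chain(rng, n, phi)
        dosage += (Z > thr[None, :]).astype(np.int8)
    if config.missing_rate > 0:
        mask = rng.random((n, m)) < config.missing_rate
        dosage[mask] = -1
    snps = [
        SnpRecord(f"rs{j + 1}", config.chromosome, int(pos[j]), "G", "A")
        for j in range(m)
    ]
    sample_ids = [f"S{i + 1}" for i in range(n)]
    return GenotypeDataset(dosage=dosage, snps=snps, sample_ids=sample_ids)


def simulate_null_phenotype(
    dataset: GenotypeDataset,
    kind: str = "gaussian",
    case_fraction: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Phenotype independent of genotype: standard normal, or 0/1 with an
    exact case fraction (cases assigned to a random sample subset)."""
    rng = np.random.default_rng(seed)
    n = dataset.n_samples
    if kind == "gaussian":
        return rng.standard_normal(n)
    if kind == "binary":
        n_cases = int(round(case_fraction * n))
        y = np.zeros(n)
        y[rng.permutation(n)[:n_cases]] = 1.0
        return y
    raise ValueError(f"unknown phenotype kind {kind!r}")


def _standardized_columns(dataset: GenotypeDataset, idx: np.ndarray) -> np.ndarray:
    X = dataset.snp_block(idx)
    for j in range(X.shape[1]):
        miss = ~np.isfinite(X[:, j])
        if miss.any():
            X[miss, j] = np.nanmean(X[:, j])
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def simulate_polygenic_phenotype(
    dataset: GenotypeDataset,
    h2: float = 0.5,
    n_causal: int = 100,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Polygenic phenotype y = X beta + e with genetic variance fraction h2.

    Effects are drawn i.i.d. normal on ``n_causal`` randomly selected
    standardized SNPs, and the genetic and environmental components are scaled
    so the realized genetic variance fraction equals h2.  Returns
    (phenotype, causal SNP indices).
    """
    rng = np.random.default_rng(seed)
    n = dataset.n_samples
    e = rng.standard_normal(n)
    if h2 == 0 or n_causal == 0:
        return e, np.array([], dtype=int)
    causal = np.sort(rng.choice(dataset.n_snps, size=min(n_causal, dataset.n_snps), replace=False))
    Z = _standardized_columns(dataset, causal)
    beta = rng.standard_normal(causal.size)
    g = Z @ beta
    g_sd = g.std(ddof=1)
    if g_sd == 0:
        return e, causal
    y = np.sqrt(h2) * g / g_sd + np.sqrt(1.0 - h2) * e / e.std(ddof=1)
    return y, causal


def simulate_multimarker_gene(
    dataset: GenotypeDataset,
    gene_snp_indices,
    joint_r2: float = 0.01,
    marginal_cap: float = 0.005,
    seed: int = 0,
) -> np.ndarray:
    """Phenotype with a multi-marker gene effect but weak marginal signals.

    Picks the most strongly correlated SNP pair in the gene and gives the two
    SNPs opposite-signed effects, so each SNP's marginal variance explained
    stays at or below ``marginal_cap`` while the joint gene effect explains
    ``joint_r2`` of the phenotypic variance.
    """
    rng = np.random.default_rng(seed)
    idx = np.asarray(gene_snp_indices)
    n = dataset.n_samples
    e = rng.standard_normal(n)
    if joint_r2 == 0:
        return e
    if idx.size < 2:
        raise ValueError("multi-marker effect needs at least 2 SNPs")
    Z = _standardized_columns(dataset, idx)
    C = np.corrcoef(Z, rowvar=False)
    np.fill_diagonal(C, 0.0)
    a, b = np.unravel_index(np.argmax(np.abs(C)), C.shape)
    r = C[a, b]
    g = Z[:, a] - np.sign(r) * Z[:, b]
    g = (g - g.mean()) / g.std(ddof=1)
    for j in (a, b):
        marg = np.corrcoef(g, Z[:, j])[0, 1] ** 2 * joint_r2
        if marg > marginal_cap * 1.5:
            logger.warning(
                "marginal R^2 %.4g exceeds cap %.4g (pair LD r=%.3f too weak)",
                marg,
                marginal_cap,
                r,
            )
    return np.sqrt(joint_r2) * g + np.sqrt(1.0 - joint_r2) * e / e.std(ddof=1)


def random_gene_sets(
    gene_ids,
    n_sets: int = 100,
    set_size: int = 10,
    seed: int = 0,
) -> dict:
    """Random gene sets (without replacement within a set) for null studies."""
    rng = np.random.default_rng(seed)
    gene_ids = list(gene_ids)
    return {
        f"SET{k + 1:04d}": list(rng.choice(gene_ids, size=set_size, replace=False))
        for k in range(n_sets)
    }
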