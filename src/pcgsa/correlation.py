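"""Closed-form gene-gene correlation matrix for the gene-set tier.

Under the joint null hypothesis of no association the model sum of squares
(SSM) of gene g's PC regression is the quadratic form y'P_g y, with P_g the
orthogonal projector onto the span of the gene's retained PC scores.  For two
genes on the same samples the null correlation of the SSM values is

    corr(SSM_g, SSM_h) = trace(P_g P_h) / sqrt(K_g K_h)
                       = ||U_g' U_h||_F^2 / sqrt(K_g K_h)

for orthonormal bases U.  These correlations reflect the LD between nearby
genes; pairs separated by more than a basepair window (default 5 Mb, measured
between the closest gene boundaries) are assumed uncorrelated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .annotation import GeneAnnotation
from .gene_model import GeneExcluded, GeneModel, build_gene_model, impute_missing
from .io import GeneLocation, GenotypeDataset

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 5_000_000

# Ridge escalation used to make the banded dense matrix positive definite.
RIDGE_STEPS = (0.0, 1e-8, 1e-6, 1e-4, 1e-2, 1e-1)


@dataclass
class GeneCorrelationMatrix:
    """Sparse symmetric gene-gene correlation store (within-window pairs only)."""

    gene_ids: list
    entries: dict  # (i, j) with i < j -> r
    window_bp: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def dense(self) -> np.ndarray:
        R = np.eye(self.n_genes)
        for (i, j), r in self.entries.items():
            R[i, j] = R[j, i] = r
        return R

    def submatrix(self, indices: Sequence[int]) -> np.ndarray:
        idx = list(indices)
        pos = {g: k for k, g in enumerate(idx)}
        R = np.eye(len(idx))
        for (i, j), r in self.entries.items():
            if i in pos and j in pos:
                R[pos[i], pos[j]] = R[pos[j], pos[i]] = r
        return R

    def banded_lists(self) -> dict:
        """Per gene, correlations against previously listed genes (for the
        gene-results file)."""
        out: dict = {gid: [] for gid in self.gene_ids}
        for (i, j), r in sorted(self.entries.items(), key=lambda kv: (kv[0][1], kv[0][0])):
            out[self.gene_ids[j]].append((self.gene_ids[i], r))
        return out

    @classmethod
    def from_banded_lists(cls, gene_ids: list, lists: dict, window_bp: int):
        index = {g: i for i, g in enumerate(gene_ids)}
        entries = {}
        for gid, pairs in lists.items():
            j = index[gid]
            for other, r in pairs:
                i = index[other]
                entries[(min(i, j), max(i, j))] = float(r)
        return cls(gene_ids=gene_ids, entries=entries, window_bp=window_bp)


def ssm_correlation(model_g: GeneModel, model_h: GeneModel) -> float:
    """Null correlation of the two genes' model sums of squares."""
    if model_g.n_samples != model_h.n_samples:
        raise ValueError("gene models were built on different samples")
    C = model_g.pc_scores.T @ model_h.pc_scores
    r = float((C * C).sum() / np.sqrt(model_g.K * model_h.K))
    return min(r, 1.0)


def boundary_distance(a: GeneLocation, b: GeneLocation) -> int:
    """Gap between the closest boundaries of two genes (0 if they overlap)."""
    return max(0, max(a.start_bp, b.start_bp) - min(a.stop_bp, b.stop_bp))


def build_correlation_matrix(
    models: Sequence[GeneModel],
    locations: Sequence[GeneLocation],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> GeneCorrelationMatrix:
    """Pairwise SSM correlations for same-chromosome gene pairs whose closest
    boundaries are within ``window_bp``; other pairs are implicitly zero."""
    if len(models) != len(locations):
        raise ValueError("models and locations must be aligned")
    for m, loc in zip(models, locations):
        if m.gene_id != loc.gene_id:
            raise ValueError("models and locations must be aligned by gene_id")
    entries: dict = {}
    # Group genes per chromosome and compute cross-products through one Gram
    # matrix per chromosome (cheap relative to per-pair matmuls).
    by_chrom: dict = {}
    for i, loc in enumerate(locations):
        by_chrom.setdefault(loc.chromosome, []).append(i)
    for chrom, idx in by_chrom.items():
        if len(idx) < 2:
            continue
        ks = [models[i].K for i in idx]
        offsets = np.concatenate([[0], np.cumsum(ks)])
        U = np.hstack([models[i].pc_scores for i in idx])
        G = U.T @ U
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                if boundary_distance(locations[i], locations[j]) > window_bp:
                    continue
                C = G[offsets[a] : offsets[a + 1], offsets[b] : offsets[b + 1]]
                r = float((C * C).sum() / np.sqrt(ks[a] * ks[b]))
                if r > 0:
                    entries[(min(i, j), max(i, j))] = min(r, 1.0)
    return GeneCorrelationMatrix(
        gene_ids=[m.gene_id for m in models], entries=entries, window_bp=window_bp
    )


def reference_correlation_matrix(
    reference: GenotypeDataset,
    annotation: GeneAnnotation,
    window_bp: int = DEFAULT_WINDOW_BP,
    prune_fraction: float = 0.999,
    gene_ids: Optional[Sequence[str]] = None,
) -> GeneCorrelationMatrix:
    """Gene-gene correlations computed from reference genotypes: builds gene
    models from the reference panel (same pruning) and delegates to
    :func:`build_correlation_matrix`."""
    wanted = list(gene_ids) if gene_ids is not None else list(annotation.assignments)
    models, locations = [], []
    for gid in wanted:
        idx = annotation.assignments.get(gid)
        if not idx:
            continue
        block, _ = impute_missing(reference.snp_block(idx))
        try:
            models.append(build_gene_model(block, prune_fraction, gene_id=gid))
        except GeneExcluded as exc:
            logger.info("reference correlation: %s", exc)
            continue
        locations.append(annotation.locations[gid])
    return build_correlation_matrix(models, locations, window_bp)


def ridged_cholesky(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factor of R + delta*I for the smallest ridge delta in an
    escalating schedule that makes the factorization succeed."""
    for delta in RIDGE_STEPS:
        try:
            L = np.linalg.cholesky(R + delta * np.eye(R.shape[0]))
        except np.linalg.LinAlgError:
            continue
        if delta > 0:
            logger.info("correlation matrix ridged with delta=%g", delta)
        return L, delta
    raise np.linalg.LinAlgError("correlation matrix could not be ridged to PD")
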