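"""End-to-end orchestration of the two analysis tiers.

Tier 1 (``run_gene_analysis``) reads genotypes or summary statistics, maps
SNPs to genes, computes per-gene association p-values under the chosen model
(PC regression, mean chi-squared, or top chi-squared), and the banded
gene-gene correlation matrix.  Its output — a plain-text gene-results file —
is the only input tier 2 needs: ``run_geneset_analysis`` converts the gene
p-values to Z-scores and runs the self-contained and competitive GLS tests
for each gene set.  The two tiers can therefore run at different times or
places.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

from . import __version__
from .annotation import GeneAnnotation, annotate, write_annotation
from .correlation import (
    DEFAULT_WINDOW_BP,
    build_correlation_matrix,
    GeneCorrelationMatrix,
    reference_correlation_matrix,
)
from .gene_model import (
    GeneExcluded,
    GeneResult,
    build_gene_model,
    fit_gene_regression,
    impute_missing,
)
from .geneset import (
    competitive_test,
    design_from_results,
    multiple_testing_adjust,
    self_contained_test,
)
from .io import (
    GeneResultsFile,
    GenotypeDataset,
    read_gene_locations,
    read_gene_results,
    read_gene_sets,
    read_plink,
    read_snp_pvalues,
    write_gene_results,
)
from .snpwise import (
    align_to_reference,
    ld_matrix,
    mean_chisq_pvalue,
    snp_association,
    top_chisq_pvalue,
)
from .geneset import p_to_z

logger = logging.getLogger(__name__)

MODELS = ("pcr", "snp-mean", "snp-top")


class UsageError(ValueError):
    """Invalid or conflicting run configuration."""


@dataclass
class RunConfig:
    model: str = "pcr"
    bfile: Optional[str] = None  # raw-data mode: PLINK prefix
    pval_file: Optional[str] = None  # summary mode: SNP p-value table
    pval_id_col: str = "SNP"
    pval_p_col: str = "P"
    pval_n_col: Optional[str] = None
    bref: Optional[str] = None  # summary mode: reference panel prefix
    gene_loc: Optional[str] = None
    window_bp: int = 0
    prune_fraction: float = 0.999
    corr_window_bp: int = DEFAULT_WINDOW_BP
    seed: int = 0
    out_prefix: str = "pcgsa"

    def validate(self) -> None:
        if self.model not in MODELS:
            raise UsageError(f"unknown model {self.model!r}")
        raw = self.bfile is not None
        summary = self.pval_file is not None
        if raw == summary:
            raise UsageError("exactly one of --bfile or --pval must be given")
        if summary and self.bref is None:
            raise UsageError("summary mode requires a reference panel (--bref)")
        if summary and self.model == "pcr":
            raise UsageError("the PC regression model needs raw genotype data")
        if not 0.0 < self.prune_fraction <= 1.0:
            raise UsageError("prune_fraction must be in (0, 1]")
        if self.gene_loc is None:
            raise UsageError("a gene location file is required")


def _write_manifest(config: RunConfig, path: Path, extra: dict) -> None:
    manifest = {"config": dataclasses.asdict(config), "version": __version__}
    manifest.update(extra)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def _write_genes_out(path, results) -> None:
    with open(path, "w") as fh:
        fh.write("GENE CHR START STOP NSNPS NPARAM N STAT P\n")
        for r in results:
            fh.write(
                f"{r.gene_id} {r.chromosome} {r.start_bp} {r.stop_bp} "
                f"{r.n_snps} {r.n_params} {r.n_used} {r.stat:.6g} {r.p:.6g}\n"
            )


def analyse_genes_raw(
    dataset: GenotypeDataset,
    annotation: GeneAnnotation,
    config: RunConfig,
) -> GeneResultsFile:
    """Tier-1 analysis on raw genotypes, all three models.

    Samples with missing phenotype are dropped listwise up front, so n_used is
    identical for every gene.  Per-gene exclusions (monomorphic, insufficient
    df) are logged with their reason and omitted from the output.
    """
    if dataset.phenotype is None:
        raise UsageError("raw-data analysis requires a phenotype")
    keep = np.isfinite(dataset.phenotype)
    if dataset.covariates is not None:
        keep &= np.isfinite(dataset.covariates).all(axis=1)
    y = dataset.phenotype[keep]
    W = dataset.covariates[keep] if dataset.covariates is not None else None
    n_used = int(keep.sum())
    logger.info("using %d of %d samples", n_used, dataset.n_samples)

    results: list = []
    models: list = []
    locations: list = []
    rng = np.random.default_rng(config.seed)
    for gid, idx in annotation.assignments.items():
        loc = annotation.locations[gid]
        raw_block = dataset.snp_block(idx)[keep]
        raw_block = raw_block[:, np.isfinite(raw_block).any(axis=0)]
        if raw_block.shape[1] == 0:
            logger.info("gene %s excluded: all SNPs entirely missing", gid)
            continue
        # the PC-regression model (also behind the correlation matrix) uses
        # flanking-SNP single imputation; the SNP-wise models treat raw data
        # exactly like a reference panel (mean imputation), so the raw and
        # summary-statistics paths agree when fed the same SNP p-values
        block, _ = impute_missing(raw_block)
        try:
            model = build_gene_model(block, config.prune_fraction, gene_id=gid)
        except GeneExcluded as exc:
            logger.info("%s", exc)
            continue
        m = block.shape[1]
        if config.model == "pcr":
            try:
                fit = fit_gene_regression(model, y, W)
            except GeneExcluded as exc:
                logger.info("%s", exc)
                continue
            stat, p, n_params = fit.F, fit.p, model.K
        else:
            chi, _ = snp_association(raw_block, y)
            if config.model == "snp-mean":
                stat, p = mean_chisq_pvalue(chi, ld_matrix(raw_block), gene_id=gid)
            else:
                stat, p, _ = top_chisq_pvalue(
                    chi, raw_block, rng_seed=int(rng.integers(2**31 - 1))
                )
            n_params = m
        results.append(
            GeneResult(
                gene_id=gid,
                chromosome=loc.chromosome,
                start_bp=loc.start_bp,
                stop_bp=loc.stop_bp,
                n_snps=m,
                n_params=n_params,
                n_used=n_used,
                stat=float(stat),
                p=float(p),
                z=float(p_to_z(p)),
            )
        )
        models.append(model)
        locations.append(loc)

    R = build_correlation_matrix(models, locations, config.corr_window_bp)
    return GeneResultsFile(
        meta={
            "n": n_used,
            "model": config.model,
            "prune_fraction": config.prune_fraction,
            "corr_window_bp": config.corr_window_bp,
        },
        results=results,
        correlations=R.banded_lists(),
    )


def analyse_genes_summary(
    pvals,
    reference: GenotypeDataset,
    annotation: GeneAnnotation,
    config: RunConfig,
) -> GeneResultsFile:
    """Tier-1 analysis from SNP p-values with reference-panel LD."""
    per_gene, skipped = align_to_reference(pvals, annotation, reference)
    results: list = []
    rng = np.random.default_rng(config.seed)
    n_values = [n for p, n in pvals.entries.values() if n is not None]
    n_nominal = int(np.median(n_values)) if n_values else reference.n_samples
    for gid, summary in per_gene.items():
        loc = annotation.locations[gid]
        if config.model == "snp-mean":
            stat, p = mean_chisq_pvalue(summary.chi, summary.ld, gene_id=gid)
        else:
            block = reference.snp_block(summary.ref_indices)
            stat, p, _ = top_chisq_pvalue(
                summary.chi, block, rng_seed=int(rng.integers(2**31 - 1))
            )
        results.append(
            GeneResult(
                gene_id=gid,
                chromosome=loc.chromosome,
                start_bp=loc.start_bp,
                stop_bp=loc.stop_bp,
                n_snps=len(summary.snp_ids),
                n_params=len(summary.snp_ids),
                n_used=n_nominal,
                stat=float(stat),
                p=float(p),
                z=float(p_to_z(p)),
            )
        )
    analysed = [r.gene_id for r in results]
    R = reference_correlation_matrix(
        reference,
        annotation,
        window_bp=config.corr_window_bp,
        prune_fraction=config.prune_fraction,
        gene_ids=analysed,
    )
    # restrict the banded lists to analysed genes, in results order
    lists = {gid: R.banded_lists().get(gid, []) for gid in analysed}
    return GeneResultsFile(
        meta={
            "n": n_nominal,
            "model": config.model,
            "prune_fraction": config.prune_fraction,
            "corr_window_bp": config.corr_window_bp,
        },
        results=results,
        correlations=lists,
    )


def run_gene_analysis(config: RunConfig) -> GeneResultsFile:
    """Tier 1: chain I/O -> annotation -> gene model -> correlations; write
    <out>.genes.out, <out>.genes.results, <out>.genes.annot and a manifest."""
    config.validate()
    genes = read_gene_locations(config.gene_loc)
    if config.bfile is not None:
        dataset = read_plink(config.bfile)
        ann = annotate(dataset.snps, genes, config.window_bp)
        out = analyse_genes_raw(dataset, ann, config)
        snp_ids = [s.snp_id for s in dataset.snps]
    else:
        pvals = read_snp_pvalues(
            config.pval_file, config.pval_id_col, config.pval_p_col, config.pval_n_col
        )
        reference = read_plink(config.bref)
        ann = annotate(reference.snps, genes, config.window_bp)
        out = analyse_genes_summary(pvals, reference, ann, config)
        snp_ids = [s.snp_id for s in reference.snps]
    prefix = Path(config.out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    _write_genes_out(f"{prefix}.genes.out", out.results)
    write_gene_results(f"{prefix}.genes.results", out)
    write_annotation(f"{prefix}.genes.annot", ann, snp_ids)
    _write_manifest(
        config,
        Path(f"{prefix}.manifest.json"),
        {"n_genes_analysed": len(out.results), "n_genes_annotated": len(ann)},
    )
    return out


def run_geneset_analysis(
    gene_results: Union[str, Path, GeneResultsFile],
    set_file: Union[str, Path, dict],
    out_prefix: Optional[str] = None,
    self_contained: bool = True,
    competitive: bool = True,
    correct_size_density: bool = True,
) -> list:
    """Tier 2: gene-set analysis from a gene-results file (or in-memory
    results).  Returns GeneSetResult records; writes <out>.sets.out when an
    output prefix is given."""
    if not isinstance(gene_results, GeneResultsFile):
        gene_results = read_gene_results(gene_results)
    if isinstance(set_file, dict):
        sets = set_file
    else:
        sets = read_gene_sets(set_file).sets
    if not sets:
        raise UsageError("gene-set file contains no sets")
    results = gene_results.results
    gene_ids = [r.gene_id for r in results]
    R = GeneCorrelationMatrix.from_banded_lists(
        gene_ids, gene_results.correlations, gene_results.meta.get("corr_window_bp", 0)
    )
    design = design_from_results(results, R)
    known = set(gene_ids)
    if not any(set(members) & known for members in sets.values()):
        raise UsageError("no overlap between gene sets and gene results")

    out: list = []
    Rd = R.dense()
    for name, members in sets.items():
        present = [g for g in members if g in known]
        missing = len(members) - len(present)
        if missing:
            logger.info("set %s: %d gene(s) absent from gene results", name, missing)
        if not present:
            logger.info("set %s skipped: no genes in data", name)
            continue
        idx = design.subset_indices(present)
        if self_contained:
            out.append(
                self_contained_test(design.z[idx], Rd[np.ix_(idx, idx)], set_name=name)
            )
        if competitive:
            if 0 < len(present) < len(gene_ids):
                out.append(
                    competitive_test(
                        design,
                        present,
                        correct_size_density=correct_size_density,
                        set_name=name,
                    )
                )
            else:
                logger.info("set %s: competitive test not defined", name)
    for test_type in ("self_contained", "competitive"):
        group = [r for r in out if r.test_type == test_type]
        if group:
            multiple_testing_adjust(group)
    if out_prefix is not None:
        path = Path(f"{out_prefix}.sets.out")
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            fh.write("SET NGENES TYPE BETA SE STAT P P_BONF\n")
            for r in out:
                fh.write(
                    f"{r.set_name} {r.n_genes_in_data} {r.test_type} "
                    f"{r.beta:.6g} {r.se:.6g} {r.stat:.6g} "
                    f"{r.p_one_sided:.6g} {r.p_adjusted:.6g}\n"
                )
    return out
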