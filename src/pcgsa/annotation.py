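"""Positional SNP-to-gene annotation with an optional symmetric window.

A SNP is assigned to a gene when it lies on the same chromosome within the
closed interval [start - window, stop + window] (1-based, both ends included).
A SNP may belong to several overlapping genes; genes containing no SNPs are
omitted from the annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ANNOTATION_HEADER, FormatError, GeneLocation, SnpRecord

logger = logging.getLogger(__name__)


@dataclass
class GeneAnnotation:
    assignments: dict  # gene_id -> list of SNP indices (insertion-ordered)
    window_bp: int
    locations: dict = field(default_factory=dict)  # gene_id -> GeneLocation

    def __len__(self) -> int:
        return len(self.assignments)


def annotate(
    snps: Sequence[SnpRecord], genes: Sequence[GeneLocation], window_bp: int = 0
) -> GeneAnnotation:
    """Assign SNPs to genes by position; window_bp widens each gene
    symmetrically on both sides (strand-agnostic)."""
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    by_chrom: dict = {}
    for idx, snp in enumerate(snps):
        by_chrom.setdefault(snp.chromosome, []).append((snp.position_bp, idx))
    sorted_chrom = {}
    for chrom, items in by_chrom.items():
        items.sort()
        sorted_chrom[chrom] = (
            np.array([pos for pos, _ in items]),
            np.array([idx for _, idx in items]),
        )
    assignments: dict = {}
    locations: dict = {}
    for gene in genes:
        if gene.chromosome not in sorted_chrom:
            continue
        positions, indices = sorted_chrom[gene.chromosome]
        lo = np.searchsorted(positions, gene.start_bp - window_bp, side="left")
        hi = np.searchsorted(positions, gene.stop_bp + window_bp, side="right")
        if hi > lo:
            hits = np.sort(indices[lo:hi])
            assignments[gene.gene_id] = hits.tolist()
            locations[gene.gene_id] = gene
    return GeneAnnotation(assignments=assignments, window_bp=window_bp, locations=locations)


def write_annotation(file, annotation: GeneAnnotation, snp_ids: Sequence[str]) -> None:
    """One gene per line: gene_id, chr:start:stop, then SNP ids."""
    with open(file, "w") as fh:
        fh.write(f"{ANNOTATION_HEADER} window={annotation.window_bp}\n")
        for gid, idx in annotation.assignments.items():
            loc = annotation.locations[gid]
            ids = " ".join(snp_ids[i] for i in idx)
            fh.write(f"{gid} {loc.chromosome}:{loc.start_bp}:{loc.stop_bp} {ids}\n")


def read_annotation(file, snp_ids: Sequence[str]) -> GeneAnnotation:
    """Read an annotation file back, mapping SNP ids to indices in ``snp_ids``.
    SNP ids absent from the dataset are dropped with a logged count."""
    index = {sid: i for i, sid in enumerate(snp_ids)}
    with open(file) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith(ANNOTATION_HEADER):
        raise FormatError(f"{file}: missing annotation header")
    window_bp = int(lines[0].rsplit("window=", 1)[1])
    assignments: dict = {}
    locations: dict = {}
    n_unknown = 0
    for line in lines[1:]:
        tokens = line.split()
        if not tokens:
            continue
        gid, span, ids = tokens[0], tokens[1], tokens[2:]
        chrom, start, stop = span.rsplit(":", 2)
        hits = []
        for sid in ids:
            if sid in index:
                hits.append(index[sid])
            else:
                n_unknown += 1
        if hits:
            assignments[gid] = hits
            locations[gid] = GeneLocation(gid, chrom, int(start), int(stop))
    if n_unknown:
        logger.warning("annotation: dropped %d SNP id(s) not in dataset", n_unknown)
    return GeneAnnotation(assignments=assignments, window_bp=window_bp, locations=locations)
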