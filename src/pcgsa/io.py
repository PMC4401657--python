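"""Readers and writers for all on-disk formats.

Covers PLINK v1 binary genotype triplets (bed/bim/fam), whitespace-delimited
SNP p-value tables, gene location files, gene-set files, and the tool's own
gene-results intermediate file that carries tier-1 output (including banded
gene-gene correlations) into the gene-set tier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .gene_model import GeneResult

logger = logging.getLogger(__name__)

PLINK_MAGIC = bytes([0x6C, 0x1B])
SNP_MAJOR = 0x01
MISSING = np.int8(-1)

# PLINK 2-bit genotype codes, in code order 0b00..0b11, mapped to counts of
# the .bim A1 allele: 00 = A1/A1 (2), 01 = missing, 10 = het (1), 11 = A2/A2 (0).
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}

GENE_RESULTS_HEADER = "# pcgsa gene results v1"
ANNOTATION_HEADER = "# pcgsa annotation v1"


class FormatError(ValueError):
    """A file does not conform to its declared format."""


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chromosome: str
    position_bp: int
    allele_ref: str  # .bim A2
    allele_alt: str  # .bim A1 (the counted allele)


@dataclass
class GenotypeDataset:
    """Samples x SNPs dosage matrix (int8; counts of A1; -1 = missing) with
    SNP/sample metadata, a phenotype and optional covariates."""

    dosage: np.ndarray
    snps: list[SnpRecord]
    sample_ids: list[str]
    phenotype: Optional[np.ndarray] = None  # float; NaN = missing
    covariates: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.dosage.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError("dosage dimensions do not match metadata")
        if self.phenotype is not None and len(self.phenotype) != len(self.sample_ids):
            raise ValueError("phenotype length does not match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_block(self, indices) -> np.ndarray:
        """Float dosage block for the given SNP indices, missing as NaN."""
        block = self.dosage[:, indices].astype(float)
        block[block < 0] = np.nan
        return block


@dataclass
class SnpPvalueTable:
    entries: dict  # snp_id -> (p, n or None)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class GeneLocation:
    gene_id: str
    chromosome: str
    start_bp: int
    stop_bp: int

    def __post_init__(self):
        if self.start_bp > self.stop_bp:
            raise ValueError(f"gene {self.gene_id}: start > stop")


@dataclass
class GeneSetCollection:
    sets: dict  # set_name -> list of gene ids (insertion-ordered)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class GeneResultsFile:
    """Tier-1 output: per-gene results plus banded gene-gene correlations
    (each gene stores correlations against previously listed genes only)."""

    meta: dict  # n, model, prune_fraction, corr_window_bp
    results: list[GeneResult]
    correlations: dict = field(default_factory=dict)  # gene_id -> [(earlier_id, r)]


# ---------------------------------------------------------------------------
# PLINK binary


def _decode_bed(payload: bytes, n_samples: int, n_snps: int) -> np.ndarray:
    bytes_per_snp = (n_samples + 3) // 4
    data = np.frombuffer(payload, dtype=np.uint8)
    if data.size != n_snps * bytes_per_snp:
        raise FormatError(
            f".bed payload has {data.size} bytes, expected {n_snps * bytes_per_snp} "
            f"for {n_snps} SNPs x {n_samples} samples"
        )
    data = data.reshape(n_snps, bytes_per_snp)
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for shift in range(4):  # within a byte, the lowest-order bits come first
        codes[:, shift::4] = (data >> (2 * shift)) & 0b11
    return _CODE_TO_DOSAGE[codes[:, :n_samples]].T.copy()


def _encode_bed(dosage: np.ndarray) -> bytes:
    n_samples, n_snps = dosage.shape
    bytes_per_snp = (n_samples + 3) // 4
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    codes[:] = 0b01  # pad slots beyond n_samples are never read back
    d = np.asarray(dosage, dtype=np.int8)
    if not np.isin(d, [-1, 0, 1, 2]).all():
        raise ValueError("dosage values must be in {-1, 0, 1, 2}")
    code_map = np.zeros(4, dtype=np.uint8)
    for dose, code in _DOSAGE_TO_CODE.items():
        code_map[dose % 4] = code  # -1 -> index 3
    codes[:, :n_samples] = code_map[(d.T % 4)]
    packed = np.zeros((n_snps, bytes_per_snp), dtype=np.uint8)
    for shift in range(4):
        packed |= codes[:, shift::4] << (2 * shift)
    return packed.tobytes()


def _parse_phenotype(values: pd.Series) -> np.ndarray:
    """.fam phenotype column: 1/2 case-control coding -> 0/1; -9/0 -> missing;
    anything else is treated as a quantitative trait (-9 missing)."""
    v = values.astype(float).to_numpy()
    if np.all(np.isin(v, [1.0, 2.0, -9.0, 0.0])):
        out = np.full(v.shape, np.nan)
        out[v == 1.0] = 0.0
        out[v == 2.0] = 1.0
        return out
    out = v.copy()
    out[v == -9.0] = np.nan
    return out


def read_plink(prefix) -> GenotypeDataset:
    """Read a PLINK v1 bed/bim/fam triplet (SNP-major .bed)."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != PLINK_MAGIC:
        raise FormatError(".bed magic bytes do not match PLINK v1")
    if len(raw) < 3 or raw[2] != SNP_MAJOR:
        raise FormatError(".bed is not in SNP-major mode")
    dosage = _decode_bed(raw[3:], len(fam), len(bim))
    snps = [
        SnpRecord(r.snp_id, str(r.chrom), int(r.pos), str(r.a2), str(r.a1))
        for r in bim.itertuples()
    ]
    keys = [(s.chromosome, s.position_bp) for s in snps]
    if keys != sorted(keys):
        logger.warning("%s.bim is not sorted by (chromosome, position)", prefix)
    phenotype = _parse_phenotype(fam["pheno"]) if len(fam) else None
    return GenotypeDataset(
        dosage=dosage,
        snps=snps,
        sample_ids=fam["iid"].tolist(),
        phenotype=phenotype,
    )


def write_plink(dataset: GenotypeDataset, prefix) -> None:
    """Write bed/bim/fam (exact round-trip with read_plink, missing included)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(PLINK_MAGIC + bytes([SNP_MAJOR]))
        fh.write(_encode_bed(dataset.dosage))
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for s in dataset.snps:
            fh.write(
                f"{s.chromosome}\t{s.snp_id}\t0\t{s.position_bp}\t"
                f"{s.allele_alt}\t{s.allele_ref}\n"
            )
    pheno = dataset.phenotype
    binary = pheno is not None and np.all(
        np.isin(pheno[np.isfinite(pheno)], [0.0, 1.0])
    )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for i, sid in enumerate(dataset.sample_ids):
            if pheno is None or not np.isfinite(pheno[i]):
                code = "-9"
            elif binary:
                code = str(int(pheno[i]) + 1)
            else:
                code = repr(float(pheno[i]))
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t{code}\n")


# ---------------------------------------------------------------------------
# Text tables


def read_snp_pvalues(
    file, id_col: str = "SNP", p_col: str = "P", n_col: Optional[str] = None
) -> SnpPvalueTable:
    """Whitespace-delimited SNP p-value table with a header row.

    Rows with p outside (0, 1] are dropped with a logged count (p = 0 would
    make the chi-squared transform diverge); duplicate SNP ids are an error.
    """
    df = pd.read_csv(file, sep=r"\s+", dtype={0: str})
    for col in [id_col, p_col] + ([n_col] if n_col else []):
        if col not in df.columns:
            raise FormatError(f"column {col!r} not found in {file}")
    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise FormatError(f"duplicate SNP id {dup!r} in {file}")
    p = pd.to_numeric(df[p_col], errors="coerce").to_numpy(dtype=float)
    valid = np.isfinite(p) & (p > 0) & (p <= 1)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("dropped %d SNP(s) with p outside (0, 1]", n_dropped)
    n_vals = None
    if n_col:
        n_vals = pd.to_numeric(df[n_col], errors="coerce").to_numpy()
    entries = {}
    for i in np.flatnonzero(valid):
        n_i = int(n_vals[i]) if n_vals is not None and np.isfinite(n_vals[i]) else None
        entries[ids.iloc[i]] = (float(p[i]), n_i)
    return SnpPvalueTable(entries=entries)


def read_gene_locations(file) -> list[GeneLocation]:
    """Gene location file: gene_id, chromosome, start, stop (whitespace, no
    header).  Returned sorted by (chromosome, start)."""
    genes = []
    with open(file) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 4:
                raise FormatError(f"{file}:{lineno}: expected 4 columns")
            gid, chrom, start, stop = tokens[:4]
            try:
                loc = GeneLocation(gid, chrom, int(start), int(stop))
            except ValueError as exc:
                raise FormatError(f"{file}:{lineno}: {exc}") from exc
            genes.append(loc)
    return sorted(genes, key=lambda g: (g.chromosome, g.start_bp, g.gene_id))


def read_gene_sets(file) -> GeneSetCollection:
    """One gene set per line: set name followed by member gene ids.

    Duplicate genes within a set are deduplicated with a warning; duplicate
    set names are an error.
    """
    sets: dict = {}
    with open(file) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            name, members = tokens[0], tokens[1:]
            if name in sets:
                raise FormatError(f"{file}:{lineno}: duplicate set name {name!r}")
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning(
                    "set %s: %d duplicate gene id(s) removed",
                    name,
                    len(members) - len(unique),
                )
            sets[name] = unique
    return GeneSetCollection(sets=sets)


# ---------------------------------------------------------------------------
# Gene-results intermediate file (tier-1 -> tier-2 handoff)

_RESULT_COLUMNS = "GENE CHR START STOP NSNPS NPARAM N STAT P Z CORR".split()


def write_gene_results(file, results: GeneResultsFile) -> None:
    meta = results.meta
    with open(file, "w") as fh:
        fh.write(GENE_RESULTS_HEADER + "\n")
        fh.write(
            "# n={n} model={model} prune_fraction={prune_fraction} "
            "corr_window_bp={corr_window_bp}\n".format(
                n=meta.get("n"),
                model=meta.get("model"),
                prune_fraction=meta.get("prune_fraction"),
                corr_window_bp=meta.get("corr_window_bp"),
            )
        )
        fh.write(" ".join(_RESULT_COLUMNS) + "\n")
        for res in results.results:
            pairs = results.correlations.get(res.gene_id, [])
            corr = ",".join(f"{gid}={r:.12g}" for gid, r in pairs) if pairs else "-"
            fh.write(
                f"{res.gene_id} {res.chromosome} {res.start_bp} {res.stop_bp} "
                f"{res.n_snps} {res.n_params} {res.n_used} {res.stat:.12g} "
                f"{res.p:.12g} {res.z:.12g} {corr}\n"
            )


def read_gene_results(file) -> GeneResultsFile:
    with open(file) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != GENE_RESULTS_HEADER:
        raise FormatError(f"{file}: missing or unrecognized gene-results header")
    meta: dict = {}
    for token in lines[1].lstrip("# ").split():
        key, _, value = token.partition("=")
        if value == "None":
            meta[key] = None
        elif key in ("n", "corr_window_bp"):
            meta[key] = int(value)
        elif key == "prune_fraction":
            meta[key] = float(value)
        else:
            meta[key] = value
    if lines[2].split() != _RESULT_COLUMNS:
        raise FormatError(f"{file}: unexpected column header")
    results = []
    correlations: dict = {}
    seen = set()
    for line in lines[3:]:
        if not line.strip():
            continue
        tokens = line.split()
        gid = tokens[0]
        results.append(
            GeneResult(
                gene_id=gid,
                chromosome=tokens[1],
                start_bp=int(tokens[2]),
                stop_bp=int(tokens[3]),
                n_snps=int(tokens[4]),
                n_params=int(tokens[5]),
                n_used=int(tokens[6]),
                stat=float(tokens[7]),
                p=float(tokens[8]),
                z=float(tokens[9]),
            )
        )
        pairs = []
        if tokens[10] != "-":
            for item in tokens[10].split(","):
                other, _, r = item.partition("=")
                if other not in seen:
                    raise FormatError(
                        f"{file}: gene {gid} references {other!r} before it is listed"
                    )
                pairs.append((other, float(r)))
        correlations[gid] = pairs
        seen.add(gid)
    return GeneResultsFile(meta=meta, results=results, correlations=correlations)
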