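"""File formats shared across the pipeline.

Readers and writers for GWAS summary statistics (TSV), reference genotype
panels (VCF v4.2, GT-only), genome sequence (FASTA), gene annotation
(BED3+name), pathway gene sets (GMT) and transcription-factor motifs
(minimal MEME dialect), plus the step-1 association filters (p-value and
minor-allele-frequency cut-offs applied to the summary statistics).

All coordinates follow the conventions of their container format: VCF and
the summary-statistic table are 1-based, BED is 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from cyvcf2 import VCF

from .exceptions import FormatError, ValidationError
from .ld import GenotypePanel
from .enrich import GeneModel
from .motifs import Pwm

logger = logging.getLogger(__name__)

SUMSTAT_COLUMNS = ("snp_id", "chrom", "pos", "ref", "alt", "pval", "maf")

_BASES = frozenset("ACGT")


def norm_chrom(chrom: str) -> str:
    """Chromosome label with an optional 'chr' prefix stripped (dialect tolerance)."""
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


@dataclass(frozen=True)
class SummaryStatRecord:
    """One GWAS variant: association p-value and minor allele frequency."""

    snp_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    pval: float
    maf: float

    def validate(self) -> None:
        if not (0.0 < self.pval <= 1.0):
            raise ValidationError(
                f"{self.snp_id}: pval {self.pval} outside (0, 1]")
        if not (0.0 < self.maf <= 0.5):
            raise ValidationError(
                f"{self.snp_id}: maf {self.maf} outside (0, 0.5]")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: pos {self.pos} < 1")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValidationError(
                f"{self.snp_id}: ref/alt must be single bases in ACGT")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Variant identity; snp_id is a label, not a key."""
        return (norm_chrom(self.chrom), self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class FilterThresholds:
    """Step-1 cut-offs: keep pval < pval_max and maf > maf_min (both strict)."""

    pval_max: float = 0.001
    maf_min: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.pval_max <= 1.0):
            raise ValidationError(f"pval_max {self.pval_max} outside (0, 1]")
        if not (0.0 <= self.maf_min < 0.5):
            raise ValidationError(f"maf_min {self.maf_min} outside [0, 0.5)")


def read_sumstats(path: str | Path) -> list[SummaryStatRecord]:
    """Read and validate a summary-statistic TSV, preserving row order.

    Raises FormatError for a missing/garbled header and ValidationError for
    the first malformed row, naming its (1-based) line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip",
                         dtype={"chrom": str, "snp_id": str,
                                "ref": str, "alt": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: cannot parse as TSV: {exc}") from exc
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    records: list[SummaryStatRecord] = []
    seen: set[tuple] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        try:
            rec = SummaryStatRecord(
                snp_id=str(row.snp_id), chrom=str(row.chrom),
                pos=int(row.pos), ref=str(row.ref), alt=str(row.alt),
                pval=float(row.pval), maf=float(row.maf))
            rec.validate()
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: line {line_no}: {exc}") from exc
        if rec.key in seen:
            raise ValidationError(
                f"{path}: line {line_no}: duplicate variant {rec.key}")
        seen.add(rec.key)
        records.append(rec)
    return records


def write_sumstats(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(SUMSTAT_COLUMNS) + "\n")
        for r in records:
            fh.write(f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{r.ref}\t{r.alt}"
                     f"\t{r.pval!r}\t{r.maf!r}\n")


def filter_sumstats(records: Sequence[SummaryStatRecord],
                    thresholds: FilterThresholds = FilterThresholds(),
                    ) -> list[SummaryStatRecord]:
    """Step-1 association filters: strict pval < pval_max AND maf > maf_min.

    Order-preserving and idempotent.
    """
    kept = [r for r in records
            if r.pval < thresholds.pval_max and r.maf > thresholds.maf_min]
    logger.info("filter_sumstats: retained %d / %d records "
                "(pval < %g, maf > %g)", len(kept), len(records),
                thresholds.pval_max, thresholds.maf_min)
    return kept


def sumstats_frame(records: Sequence[SummaryStatRecord]) -> pd.DataFrame:
    """Records as a DataFrame (column order as on disk)."""
    return pd.DataFrame([r.__dict__ for r in records], columns=SUMSTAT_COLUMNS)


# ---------------------------------------------------------------------------
# VCF

def read_vcf_panel(path: str | Path) -> GenotypePanel:
    """Load a (small) VCF into a dense dosage matrix.

    Genotypes become alt-allele dosages {0, 1, 2}; missing calls become NaN.
    Only the first ALT allele is used (the pipeline is biallelic-only).
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    meta = []
    rows = []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        meta.append((var.ID or f"{var.CHROM}:{var.POS}", str(var.CHROM),
                     int(var.POS), var.REF, alt))
        g = var.gt_types.astype(float)
        g[g == 3] = np.nan  # gts012: 3 == unknown
        rows.append(g)
    if not rows:
        raise FormatError(f"{path}: no variant records")
    genotypes = np.vstack(rows).T  # samples x variants
    variants = pd.DataFrame(meta, columns=["snp_id", "chrom", "pos", "ref", "alt"])
    return GenotypePanel(genotypes=genotypes, variants=variants,
                         samples=samples)


def write_vcf_panel(panel: GenotypePanel, path: str | Path,
                    contig_lengths: dict[str, int] | None = None) -> None:
    """Write a GT-only, diploid, unphased VCF v4.2 ("0/1" dialect).

    The writer is deliberately byte-deterministic: same panel, same file.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    lines = ["##fileformat=VCFv4.2"]
    contigs = contig_lengths or {
        c: int(g["pos"].max()) + 1000
        for c, g in panel.variants.groupby("chrom", sort=False)}
    for c, ln in contigs.items():
        lines.append(f"##contig=<ID={c},length={ln}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.samples))
    gt = panel.genotypes
    for j, row in enumerate(panel.variants.itertuples(index=False)):
        calls = "\t".join(
            "./." if np.isnan(gt[i, j]) else gt_map[gt[i, j]]
            for i in range(gt.shape[0]))
        lines.append(f"{row.chrom}\t{row.pos}\t{row.snp_id}\t{row.ref}"
                     f"\t{row.alt}\t.\t.\t.\tGT\t{calls}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Contig name -> uppercase sequence."""
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# BED (0-based half-open) gene annotation

def read_bed_genes(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise FormatError(
                    f"{path}: line {line_no}: expected BED3+name (4 columns)")
            chrom, start, end, name = fields[:4]
            strand = fields[5] if len(fields) >= 6 else "+"
            start_i, end_i = int(start), int(end)
            if start_i >= end_i:
                raise ValidationError(
                    f"{path}: line {line_no}: start {start_i} >= end {end_i}")
            if name in seen:
                raise ValidationError(
                    f"{path}: line {line_no}: duplicate gene symbol {name}")
            seen.add(name)
            genes.append(GeneModel(gene_symbol=name, chrom=chrom,
                                   start=start_i, end=end_i, strand=strand))
    return genes


def write_bed_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_symbol}\n")


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Pathway id -> (description, member gene symbols)."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {line_no}: GMT needs name, description "
                    "and at least one gene")
            name, desc, *genes = fields
            sets[name] = (desc, frozenset(g for g in genes if g))
    return sets


def write_gmt(sets: dict[str, tuple[str, Iterable[str]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, genes) in sets.items():
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


# ---------------------------------------------------------------------------
# Minimal MEME motif dialect

def read_meme(path: str | Path, pseudocount: float = 1e-3) -> list[Pwm]:
    """Parse a minimal-MEME motif library into Pwm objects (rows A,C,G,T)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "minimal")
    pwms = []
    for m in parsed:
        mat = np.array([[m.pwm[b][j] for j in range(m.length)]
                        for b in "ACGT"])
        pwms.append(Pwm.from_probabilities(m.name, mat, pseudocount=pseudocount))
    if not pwms:
        raise FormatError(f"{path}: no motifs found")
    return pwms


def write_meme(pwms: Iterable[tuple[str, np.ndarray]], path: str | Path) -> None:
    """Write (motif_id, 4xL probability matrix) pairs in the minimal dialect."""
    chunks = ["MEME version 4\n",
              "ALPHABET= ACGT\n",
              "strands: + -\n",
              "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n"]
    for motif_id, mat in pwms:
        mat = np.asarray(mat, float)
        w = mat.shape[1]
        rows = "\n".join(
            " ".join(f"{mat[b, j]:.6f}" for b in range(4)) for j in range(w))
        # large nsites: parsers that roundtrip through counts keep precision
        chunks.append(f"MOTIF {motif_id}\n"
                      f"letter-probability matrix: alength= 4 w= {w} "
                      f"nsites= 1000000 E= 0\n{rows}\n")
    Path(path).write_text("\n".join(chunks))
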