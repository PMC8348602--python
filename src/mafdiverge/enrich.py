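"""SNP-to-gene mapping and hypergeometric pathway over-representation.

A SNP maps to every gene whose half-open interval contains its (0-based)
position — strict containment, no promoter extension unless a flank is
requested. Gene lists are tested against pathway gene sets with the
upper-tail hypergeometric test P(X >= k) on a user-supplied universe
(default: every gene in the annotation), BH-adjusted across pathways.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """One gene interval, 0-based half-open, as in BED."""

    gene_symbol: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"{self.gene_symbol}: start {self.start} >= end {self.end}")


@dataclass
class SnpGeneMap:
    assignments: pd.DataFrame    # snp_id, gene_symbol (one row per pair)
    unmapped: list[str]
    genes: list[str]             # deduplicated, insertion order


def map_snps_to_genes(snps, genes: Sequence[GeneModel],
                      flank: int = 0) -> SnpGeneMap:
    """Assign SNPs to containing genes (every overlapping gene is reported).

    `snps` is an iterable with snp_id/chrom/pos attributes (1-based pos).
    `flank` widens each gene interval symmetrically (default 0 = strict
    containment). Boundary: a SNP at a gene's end coordinate is outside.
    """
    from .io import norm_chrom

    rows = []
    unmapped = []
    gene_list: list[str] = []
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(norm_chrom(g.chrom), []).append(g)
    for snp in snps:
        pos0 = int(snp.pos) - 1
        found = False
        for g in by_chrom.get(norm_chrom(str(snp.chrom)), []):
            if g.start - flank <= pos0 < g.end + flank:
                rows.append((snp.snp_id, g.gene_symbol))
                if g.gene_symbol not in gene_list:
                    gene_list.append(g.gene_symbol)
                found = True
        if not found:
            unmapped.append(snp.snp_id)
    df = pd.DataFrame(rows, columns=["snp_id", "gene_symbol"])
    logger.info("map_snps_to_genes: %d assignment(s), %d unmapped SNP(s), "
                "%d distinct gene(s)", len(df), len(unmapped), len(gene_list))
    return SnpGeneMap(assignments=df, unmapped=unmapped, genes=gene_list)


def hypergeom_enrich(query_genes: Iterable[str],
                     gene_sets: Mapping[str, tuple[str, frozenset[str]] | Iterable[str]],
                     universe: Iterable[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of a gene list.

    For each pathway with K genes in the universe of size N, and a query of
    n genes of which k fall in the pathway, p_raw = P(X >= k) with
    X ~ Hypergeom(N, K, n); pathways with k = 0 get p_raw = 1. Results are
    BH-adjusted and sorted by (p_raw, pathway_id).
    """
    uni = set(universe)
    if not uni:
        raise ValidationError("empty universe")
    query = set(query_genes) & uni
    if not set(query_genes):
        raise ValidationError("empty query gene list")
    if not query:
        raise ValidationError("no query gene is in the universe")
    n = len(query)
    N = len(uni)
    rows = []
    for pid, value in gene_sets.items():
        members = value[1] if isinstance(value, tuple) else value
        in_uni = set(members) & uni
        K = len(in_uni)
        found = sorted(query & in_uni)
        k = len(found)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((pid, k, K, n, N, min(p, 1.0), ",".join(found) or "."))
    df = pd.DataFrame(rows, columns=["pathway_id", "k", "K", "n", "N",
                                     "p_raw", "genes_found"])
    from .divergence import bh_adjust
    df["p_adj"] = bh_adjust(df["p_raw"].to_numpy()) if len(df) else []
    df = df.sort_values(["p_raw", "pathway_id"], kind="mergesort",
                        ignore_index=True)
    return df[["pathway_id", "k", "K", "n", "N", "p_raw", "p_adj",
               "genes_found"]]


def write_enrichment(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
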