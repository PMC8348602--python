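"""Matched-SNP background construction (SNPsnap-style).

Every query SNP gets a background of panel SNPs with similar genomic
properties: folded MAF, number of LD buddies (panel SNPs in LD above a
threshold within a physical window), distance to the nearest gene, and local
gene density. Matching is windowed (all-or-nothing eligibility): MAF within
an absolute tolerance, the three count/distance covariates within a relative
tolerance. Two quality scores summarise a run: the percentage of queries
with fewer matches than requested ("insufficient-matches") and, over those,
the mean fraction of the request actually met ("match-size").

All positions in profiles are 0-based (VCF pos − 1); gene intervals are
0-based half-open as in BED.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .ld import GenotypePanel, panel_maf_all, r2_matrix
from .enrich import GeneModel
from .io import norm_chrom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchParams:
    """Matching tolerances (SNPsnap web-tool defaults, desk-scale n_required)."""

    n_required: int = 100
    maf_tol: float = 0.05          # ± absolute MAF window
    rel_tol: float = 0.50          # ± relative window for counts/distances
    buddy_r2: float = 0.5
    buddy_window: int = 500_000    # bp
    density_window: int = 100_000  # bp

    def __post_init__(self) -> None:
        if self.n_required < 1:
            raise ValidationError("n_required must be >= 1")
        if min(self.maf_tol, self.rel_tol) <= 0:
            raise ValidationError("tolerances must be positive")
        if min(self.buddy_window, self.density_window) <= 0:
            raise ValidationError("windows must be positive")


@dataclass(frozen=True)
class MatchProfile:
    snp_id: str
    maf: float
    ld_buddies: int
    dist_nearest_gene: int   # bp; 0 when inside a gene
    gene_density: int        # genes within ± density_window

    def __post_init__(self) -> None:
        if not (0.0 <= self.maf <= 0.5):
            raise ValidationError(f"{self.snp_id}: maf outside [0, 0.5]")
        if min(self.ld_buddies, self.dist_nearest_gene, self.gene_density) < 0:
            raise ValidationError(f"{self.snp_id}: negative profile count")


@dataclass(frozen=True)
class MatchedSet:
    query_id: str
    matched_ids: tuple[str, ...]
    insufficient: bool
    match_fraction: float  # |matched| / n_required, capped at 1

    def __post_init__(self) -> None:
        if self.query_id in self.matched_ids:
            raise ValidationError("query cannot match itself")
        if len(set(self.matched_ids)) != len(self.matched_ids):
            raise ValidationError("matched_ids must be unique")


@dataclass(frozen=True)
class MatchReport:
    insufficient_pct: float
    match_size_pct: float | None  # None when no query is insufficient


def _gene_arrays(genes: Sequence[GeneModel]):
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {norm_chrom(g.chrom) for g in genes}:
        gs = [g for g in genes if norm_chrom(g.chrom) == chrom]
        by_chrom[chrom] = (np.array([g.start for g in gs]),
                           np.array([g.end for g in gs]))
    return by_chrom


def _gene_distance(pos0: int, starts: np.ndarray, ends: np.ndarray) -> int:
    """Distance from a 0-based position to the nearest covered base."""
    if starts.size == 0:
        return 0
    inside = (starts <= pos0) & (pos0 < ends)
    if inside.any():
        return 0
    d = np.where(pos0 < starts, starts - pos0, pos0 - (ends - 1))
    return int(d.min())


def build_profiles(panel: GenotypePanel, genes: Sequence[GeneModel],
                   params: MatchParams = MatchParams(),
                   snp_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Match profiles for panel SNPs (all of them unless snp_ids is given).

    LD buddies are counted against the *whole* panel (undefined r² pairs
    contribute nothing), so profiling a subset still sees the full LD
    neighbourhood.
    """
    var = panel.variants
    mafs = panel_maf_all(panel)
    r2m = r2_matrix(panel)
    chroms = var["chrom"].map(norm_chrom).to_numpy()
    pos0 = var["pos"].to_numpy() - 1
    same_chrom = chroms[:, None] == chroms[None, :]
    in_window = np.abs(pos0[:, None] - pos0[None, :]) <= params.buddy_window
    with np.errstate(invalid="ignore"):
        buddy = (r2m >= params.buddy_r2) & same_chrom & in_window
    np.fill_diagonal(buddy, False)
    buddy_counts = buddy.sum(axis=1)

    gene_arr = _gene_arrays(genes)
    ids = list(var["snp_id"]) if snp_ids is None else list(snp_ids)
    rows = []
    col = {s: j for j, s in enumerate(var["snp_id"])}
    for sid in ids:
        j = col[sid]
        starts, ends = gene_arr.get(chroms[j], (np.array([]), np.array([])))
        p = int(pos0[j])
        dist = _gene_distance(p, starts, ends)
        lo, hi = p - params.density_window, p + params.density_window
        density = int(((starts <= hi) & (ends > lo)).sum()) if starts.size else 0
        rows.append((sid, float(mafs.loc[sid]), int(buddy_counts[j]),
                     dist, density))
    df = pd.DataFrame(rows, columns=["snp_id", "maf", "ld_buddies",
                                     "dist_nearest_gene", "gene_density"])
    return df.set_index("snp_id")


def profile_snp(panel: GenotypePanel, genes: Sequence[GeneModel],
                snp_id: str, params: MatchParams = MatchParams(),
                ) -> MatchProfile:
    """Profile of a single panel SNP."""
    row = build_profiles(panel, genes, params, snp_ids=[snp_id]).iloc[0]
    return MatchProfile(snp_id=snp_id, maf=float(row["maf"]),
                        ld_buddies=int(row["ld_buddies"]),
                        dist_nearest_gene=int(row["dist_nearest_gene"]),
                        gene_density=int(row["gene_density"]))


def _rel_window(value: float, rel_tol: float) -> tuple[float, float]:
    if value == 0:
        return 0.0, max(1.0, rel_tol * 1.0)
    return value * (1.0 - rel_tol), value * (1.0 + rel_tol)


def match_snp(query: MatchProfile, candidates: pd.DataFrame,
              params: MatchParams = MatchParams()) -> MatchedSet:
    """Select up to n_required eligible candidates for one query.

    `candidates` is a profile frame (as from build_profiles) that must not
    contain any query SNP. Eligible candidates are ranked by |maf − maf_q|
    then by snp_id, making the output deterministic.
    """
    if query.snp_id in candidates.index:
        raise ValidationError("candidates must exclude the query SNP")
    ok = (candidates["maf"] - query.maf).abs() <= params.maf_tol
    for colname, qval in (("ld_buddies", query.ld_buddies),
                          ("dist_nearest_gene", query.dist_nearest_gene),
                          ("gene_density", query.gene_density)):
        lo, hi = _rel_window(qval, params.rel_tol)
        ok &= (candidates[colname] >= lo) & (candidates[colname] <= hi)
    eligible = candidates[ok]
    dmaf = (eligible["maf"] - query.maf).abs()
    order = sorted(eligible.index, key=lambda i: (dmaf.at[i], str(i)))
    chosen = tuple(order[: params.n_required])
    insufficient = len(chosen) < params.n_required
    fraction = min(1.0, len(chosen) / params.n_required)
    return MatchedSet(query_id=query.snp_id, matched_ids=chosen,
                      insufficient=insufficient, match_fraction=fraction)


def match_all(queries: Sequence[MatchProfile], profiles: pd.DataFrame,
              params: MatchParams = MatchParams()) -> list[MatchedSet]:
    """Match every query against the panel profiles minus all query SNPs."""
    query_ids = {q.snp_id for q in queries}
    candidates = profiles.drop(index=[i for i in profiles.index
                                      if i in query_ids])
    return [match_snp(q, candidates, params) for q in queries]


def match_report(matched_sets: Sequence[MatchedSet]) -> MatchReport:
    """The two SNPsnap-style quality percentages."""
    if not matched_sets:
        raise ValidationError("match_report needs at least one query")
    insufficient = [m for m in matched_sets if m.insufficient]
    for m in insufficient:
        assert m.match_fraction < 1.0, "insufficient set with full fraction"
    pct = 100.0 * len(insufficient) / len(matched_sets)
    size = (100.0 * float(np.mean([m.match_fraction for m in insufficient]))
            if insufficient else None)
    return MatchReport(insufficient_pct=pct, match_size_pct=size)


def write_matches(matched_sets: Sequence[MatchedSet], path) -> None:
    with open(path, "w") as fh:
        fh.write("query_id\tn_matched\tinsufficient\tmatched_ids\n")
        for m in matched_sets:
            fh.write(f"{m.query_id}\t{len(m.matched_ids)}\t"
                     f"{int(m.insufficient)}\t"
                     f"{','.join(m.matched_ids) or '.'}\n")
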