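"""Genotype panel statistics and PLINK-style greedy LD clumping.

The panel stores unphased alt-allele dosages (0/1/2, NaN = missing call).
Linkage disequilibrium is the squared Pearson correlation of dosages over
jointly non-missing samples — the standard unphased approximation; no
haplotype-phase EM is attempted.

Clumping follows the greedy PLINK procedure: the most significant unassigned
SNP below the index threshold (p1) seeds a clump and absorbs every unassigned
SNP below the member threshold (p2) on the same chromosome, within the
physical window, and in LD (r² ≥ r2_min) with it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import UndefinedFrequencyError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GenotypePanel:
    """samples × variants dosage matrix plus variant metadata."""

    genotypes: np.ndarray                 # (n_samples, n_variants), float
    variants: pd.DataFrame                # snp_id chrom pos ref alt
    samples: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        if self.genotypes.ndim != 2:
            raise ValidationError("genotypes must be a 2-D matrix")
        if self.genotypes.shape[1] != len(self.variants):
            raise ValidationError(
                f"genotype columns ({self.genotypes.shape[1]}) != variant "
                f"count ({len(self.variants)})")
        if not self.samples:
            self.samples = [f"S{i:05d}" for i in range(self.genotypes.shape[0])]
        for chrom, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) < 0):
                raise ValidationError(
                    f"positions not non-decreasing on chromosome {chrom}")
        self._col: dict[str, int] = {
            s: j for j, s in enumerate(self.variants["snp_id"])}

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def column(self, snp_id: str) -> np.ndarray:
        try:
            return self.genotypes[:, self._col[snp_id]]
        except KeyError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def has(self, snp_id: str) -> bool:
        return snp_id in self._col


@dataclass(frozen=True)
class ClumpParams:
    """PLINK-style clumping thresholds (defaults as used for GWAS index SNPs)."""

    p1: float = 0.0001      # index-SNP significance threshold
    p2: float = 0.01        # clumped-member threshold
    r2_min: float = 0.1     # pairwise LD threshold
    kb_window: float = 250  # physical window, kilobases

    def __post_init__(self) -> None:
        if self.p1 > self.p2:
            raise ValidationError("p1 must be <= p2")
        if not (0.0 <= self.r2_min <= 1.0):
            raise ValidationError("r2_min outside [0, 1]")
        if self.kb_window <= 0:
            raise ValidationError("kb_window must be > 0")


@dataclass(frozen=True)
class Clump:
    index_snp: str
    members: tuple[str, ...]
    index_pval: float


@dataclass
class ClumpResult:
    clumps: list[Clump]
    unassigned: list[str]     # never an index, never a member
    absent: list[str]         # input SNPs missing from the panel (skipped)


def panel_maf(panel: GenotypePanel, snp_id: str) -> float:
    """Folded minor-allele frequency from non-missing dosages."""
    g = panel.column(snp_id)
    ok = ~np.isnan(g)
    if not ok.any():
        raise UndefinedFrequencyError(
            f"{snp_id}: all genotypes missing, frequency undefined")
    f = float(g[ok].sum()) / (2.0 * int(ok.sum()))
    return min(f, 1.0 - f)


def panel_maf_all(panel: GenotypePanel) -> pd.Series:
    """Folded MAF for every variant (NaN where all calls are missing)."""
    g = panel.genotypes
    ok = ~np.isnan(g)
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        f = np.nansum(g, axis=0) / (2.0 * n)
    f[n == 0] = np.nan
    return pd.Series(np.minimum(f, 1.0 - f),
                     index=panel.variants["snp_id"].to_numpy())


def r2(panel: GenotypePanel, snp_a: str, snp_b: str) -> float | None:
    """Squared dosage correlation over jointly non-missing samples.

    Returns None when undefined (either vector constant in the overlap, or
    fewer than two shared samples) — callers must treat None as "no LD
    evidence", never as 0 or 1.
    """
    ga, gb = panel.column(snp_a), panel.column(snp_b)
    ok = ~np.isnan(ga) & ~np.isnan(gb)
    if ok.sum() < 2:
        return None
    xa, xb = ga[ok], gb[ok]
    va, vb = xa.var(), xb.var()
    if va == 0.0 or vb == 0.0:
        return None
    r = float(np.corrcoef(xa, xb)[0, 1])
    return min(r * r, 1.0)


def r2_matrix(panel: GenotypePanel) -> np.ndarray:
    """All-pairs r²; NaN marks undefined pairs (constant column or missing).

    Missing genotypes are mean-imputed per variant before correlating — at
    panel scale this is the standard dosage shortcut; the pairwise `r2`
    function remains the exact (complete-pairs) reference.
    """
    g = panel.genotypes.copy()
    nan_mask = np.isnan(g)
    if nan_mask.any():
        col_means = np.nanmean(g, axis=0)
        col_means = np.where(np.isnan(col_means), 0.0, col_means)
        g[nan_mask] = np.take(col_means, np.nonzero(nan_mask)[1])
    sd = g.std(axis=0)
    constant = sd == 0.0
    sd_safe = np.where(constant, 1.0, sd)
    z = (g - g.mean(axis=0)) / sd_safe
    r = (z.T @ z) / g.shape[0]
    out = np.clip(r * r, 0.0, 1.0)
    out[constant, :] = np.nan
    out[:, constant] = np.nan
    return out


def clump(records, panel: GenotypePanel, params: ClumpParams = ClumpParams(),
          ) -> ClumpResult:
    """Greedy LD clumping of association records against a reference panel.

    `records` is any iterable of objects with snp_id/chrom/pos/pval
    attributes (summary-stat records work directly). Ties on p-value break
    by (chrom, pos). SNPs absent from the panel are reported and skipped;
    undefined r² never satisfies the LD condition.
    """
    rows = [(r.snp_id, str(r.chrom), int(r.pos), float(r.pval))
            for r in records]
    absent = [sid for sid, *_ in rows if not panel.has(sid)]
    present = [t for t in rows if panel.has(t[0])]
    if absent:
        logger.warning("clump: %d SNP(s) absent from panel, skipped", len(absent))

    # deterministic greedy order: (pval, chrom, pos)
    order = sorted(present, key=lambda t: (t[3], t[1], t[2]))
    assigned: set[str] = set()
    clumps: list[Clump] = []
    window = params.kb_window * 1000.0
    for sid, chrom, pos, pval in order:
        if sid in assigned or pval > params.p1:
            continue
        assigned.add(sid)
        members = []
        for osid, ochrom, opos, opval in order:
            if osid in assigned or opval > params.p2:
                continue
            if ochrom != chrom or abs(opos - pos) > window:
                continue
            ld = r2(panel, sid, osid)
            if ld is None or ld < params.r2_min:
                continue
            members.append(osid)
            assigned.add(osid)
        clumps.append(Clump(index_snp=sid, members=tuple(members),
                            index_pval=pval))
    unassigned = [sid for sid, *_ in present if sid not in assigned]
    return ClumpResult(clumps=clumps, unassigned=unassigned, absent=absent)


def write_clumps(result: ClumpResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("index_snp\tn_members\tmembers\tindex_pval\n")
        for c in result.clumps:
            fh.write(f"{c.index_snp}\t{len(c.members)}\t"
                     f"{','.join(c.members) or '.'}\t{c.index_pval:.6g}\n")
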