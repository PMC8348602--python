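"""Cross-population MAF divergence and the two Wilcoxon/BH selection rounds.

Each SNP's divergence is the absolute difference of its folded minor allele
frequencies in the two populations. Whether a SNP's divergence is unusually
large is judged with a one-sample Wilcoxon signed-rank test of a background
delta distribution against the focal SNP's delta as hypothesized location,
one-sided so that a small p-value means the focal delta sits in the upper
tail of the background. Raw p-values are Benjamini–Hochberg adjusted across
the SNPs tested in the round.

Round one ("pooled") compares each candidate against a shared background
(by default, leave-one-out over the candidates themselves). Round two
("matched") compares each query against its own matched-SNP background and
additionally requires the query's delta to exceed the median of that
background distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exceptions import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionParams:
    """Selection thresholds for the divergence rounds.

    alpha_adj: BH-adjusted p-value cut-off (strict <).
    require_above_median: apply the median delta cut-off (matched round only).
    median_mode: which distribution supplies the median —
        "matched" (default): the query's own matched-delta distribution;
        "queries": the pooled distribution of all query deltas.
    """

    alpha_adj: float = 0.001
    require_above_median: bool = True
    median_mode: str = "matched"

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha_adj < 1.0):
            raise ValidationError("alpha_adj outside (0, 1)")
        if self.median_mode not in ("matched", "queries"):
            raise ValidationError("median_mode must be 'matched' or 'queries'")


def maf_delta(maf_a: float, maf_b: float) -> float:
    """Absolute difference of two folded minor allele frequencies."""
    for v, name in ((maf_a, "maf_a"), (maf_b, "maf_b")):
        if not (0.0 <= v <= 0.5):
            raise ValidationError(f"{name} {v} outside [0, 0.5]")
    return abs(maf_a - maf_b)


def wilcoxon_signed_rank(values: Sequence[float], mu: float = 0.0,
                         alternative: str = "two-sided",
                         method: str = "auto") -> float:
    """One-sample Wilcoxon signed-rank p-value of `values` against location mu.

    Differences equal to mu are dropped (classic treatment). With
    method="auto", the exact null distribution is used for n <= 25 with no
    ties in |values - mu|, otherwise the normal approximation with tie and
    continuity corrections; "exact" / "approx" force a branch. All values
    equal to mu is degenerate: returns 1.0 with a warning.
    """
    if method not in ("auto", "exact", "approx"):
        raise ValidationError(f"unknown method {method!r}")
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0.0]
    if d.size == 0:
        warnings.warn("wilcoxon_signed_rank: all values equal mu; p = 1.0",
                      stacklevel=2)
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    if method == "auto":
        method = "exact" if d.size <= 25 and not has_ties else "approx"
    if method == "exact":
        res = stats.wilcoxon(d, alternative=alternative, method="exact")
    else:
        res = stats.wilcoxon(d, alternative=alternative, method="approx",
                             correction=True)
    return float(res.pvalue)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_divergent_pooled(deltas: Mapping[str, float] | pd.Series,
                            params: SelectionParams = SelectionParams(),
                            background_deltas: pd.Series | None = None,
                            ) -> pd.DataFrame:
    """Round-one selection of SNPs whose delta exceeds a pooled background.

    For each SNP s, p_raw(s) tests the background deltas against location
    delta_s, one-sided "less" (small p ⇔ delta_s in the upper tail). The
    background is the remaining SNPs' deltas (leave-one-out) unless an
    explicit `background_deltas` series is given, in which case the SNP's own
    entry (matched by id) is excluded from it.

    Returns a DataFrame indexed like the input with columns
    delta, p_raw, p_adj, selected.
    """
    s = pd.Series(deltas, dtype=float)
    if background_deltas is None and len(s) < 3:
        raise ValidationError(
            "pooled selection needs >= 3 SNPs (test undefined)")
    ids = list(s.index)
    vals = s.to_numpy()
    p_raw = np.empty(len(ids))
    for i, sid in enumerate(ids):
        if background_deltas is None:
            bg = np.delete(vals, i)
        else:
            bg = background_deltas.drop(sid, errors="ignore").to_numpy()
        if bg.size < 3:
            raise ValidationError(
                f"{sid}: background has fewer than 3 deltas")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_raw[i] = wilcoxon_signed_rank(bg, mu=vals[i], alternative="less")
    p_adj = bh_adjust(p_raw)
    out = pd.DataFrame({"delta": vals, "p_raw": p_raw, "p_adj": p_adj,
                        "selected": p_adj < params.alpha_adj}, index=ids)
    out.index.name = "snp_id"
    logger.info("pooled divergence: %d / %d selected at adjusted p < %g",
                int(out["selected"].sum()), len(out), params.alpha_adj)
    return out


def select_divergent_matched(query_deltas: Mapping[str, float] | pd.Series,
                             matched_deltas: Mapping[str, Sequence[float]],
                             params: SelectionParams = SelectionParams(),
                             ) -> tuple[pd.DataFrame, list[str]]:
    """Round-two selection of queries against their matched-SNP backgrounds.

    Queries with fewer than 3 matched deltas are excluded (returned in the
    second element) and do not enter the BH adjustment. A query is selected
    when its adjusted p is below alpha_adj and — if the median rule is on —
    its delta exceeds the median of the cut-off distribution (see
    SelectionParams.median_mode).
    """
    q = pd.Series(query_deltas, dtype=float)
    excluded = [sid for sid in q.index
                if len(np.asarray(matched_deltas.get(sid, []))) < 3]
    if excluded:
        logger.warning("matched divergence: %d quer%s excluded "
                       "(fewer than 3 matched deltas)", len(excluded),
                       "y" if len(excluded) == 1 else "ies")
    kept = q.drop(excluded)
    ids = list(kept.index)
    p_raw = np.empty(len(ids))
    med = np.empty(len(ids))
    n_matched = np.empty(len(ids), dtype=int)
    for i, sid in enumerate(ids):
        bg = np.asarray(matched_deltas[sid], dtype=float)
        n_matched[i] = bg.size
        med[i] = float(np.median(bg))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_raw[i] = wilcoxon_signed_rank(bg, mu=kept[sid],
                                            alternative="less")
    p_adj = bh_adjust(p_raw)
    selected = p_adj < params.alpha_adj
    if params.require_above_median and len(ids):
        if params.median_mode == "matched":
            selected = selected & (kept.to_numpy() > med)
        else:  # "queries": global median of the query deltas
            selected = selected & (kept.to_numpy() > float(np.median(
                kept.to_numpy())))
    out = pd.DataFrame({"delta": kept.to_numpy(), "n_matched": n_matched,
                        "median_matched": med, "p_raw": p_raw,
                        "p_adj": p_adj, "selected": selected}, index=ids)
    out.index.name = "snp_id"
    logger.info("matched divergence: %d / %d queries selected "
                "(%d excluded)", int(out["selected"].sum()), len(out),
                len(excluded))
    return out, excluded


def divergence_table(maf_a: pd.Series, maf_b: pd.Series) -> pd.DataFrame:
    """Per-SNP deltas for SNPs present in both series (ids aligned)."""
    shared = maf_a.index.intersection(maf_b.index)
    a = maf_a.loc[shared].astype(float)
    b = maf_b.loc[shared].astype(float)
    bad = (a < 0) | (a > 0.5) | (b < 0) | (b > 0.5)
    if bad.any():
        raise ValidationError(
            f"MAF outside [0, 0.5] for {list(shared[bad])[:5]} ...")
    return pd.DataFrame({"maf_a": a, "maf_b": b, "delta": (a - b).abs()})


def write_divergence(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=True, float_format="%.6g")
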