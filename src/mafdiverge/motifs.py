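"""Transcription-factor motif disruption scoring for SNP alleles.

A position probability matrix is scored against a window with an
information-content (relative entropy) weighted sum: each column contributes
IC_j * p_j(base), min/max-normalised so the consensus scores 1 and the
per-column worst sequence scores 0. Score p-values are tail probabilities
P(score(random L-mer) >= s) under an i.i.d. uniform base background,
computed exactly by full enumeration for 4^L <= 65,536 (L <= 8) and by a
round-down integer-grid convolution (a guaranteed upper bound on the exact
tail) for longer motifs.

A SNP "breaks" a motif when, in the best window overlapping it on either
strand, the reference or alternate allele scores a significant match
(min(p_ref, p_alt) below the cut-off); the effect size is the score change
|score_ref − score_alt|, classed strong / weak / neutral by thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

MAX_EXACT_LEN = 8  # 4^8 = 65,536 enumerated sequences


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def column_ic(column: Sequence[float]) -> float:
    """Information content of one probability column, in bits.

    IC = sum_b p_b * log2(p_b / 0.25), with 0*log(0) = 0 — the relative
    entropy against the uniform background, i.e. 2 − entropy.
    """
    p = np.asarray(column, dtype=float)
    if abs(p.sum() - 1.0) > 1e-6 or (p < 0).any():
        raise ValidationError("column must be a probability distribution")
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / 0.25)))


@dataclass
class Pwm:
    """A pseudocounted position probability matrix (rows A, C, G, T)."""

    motif_id: str
    matrix: np.ndarray   # (4, L), columns sum to 1, all entries > 0
    pseudocount: float = 1e-3
    _pv_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4 or self.matrix.ndim != 2:
            raise ValidationError(f"{self.motif_id}: matrix must be 4 x L")
        if (self.matrix <= 0).any():
            raise ValidationError(
                f"{self.motif_id}: entries must be > 0 after pseudocount")
        if np.abs(self.matrix.sum(axis=0) - 1.0).max() > 1e-9:
            raise ValidationError(f"{self.motif_id}: columns must sum to 1")

    @classmethod
    def from_probabilities(cls, motif_id: str, matrix: np.ndarray,
                           pseudocount: float = 1e-3) -> "Pwm":
        m = np.asarray(matrix, dtype=float) + pseudocount
        m = m / m.sum(axis=0, keepdims=True)
        return cls(motif_id=motif_id, matrix=m, pseudocount=pseudocount)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def ic(self) -> np.ndarray:
        return np.array([column_ic(self.matrix[:, j])
                         for j in range(self.length)])

    @property
    def contributions(self) -> np.ndarray:
        """(4, L) per-base raw score contributions IC_j * p_j(base)."""
        return self.ic[None, :] * self.matrix

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=0))


def score_window(pwm: Pwm, sequence: str) -> float:
    """Min/max-normalised IC-weighted match score of one L-long window."""
    seq = sequence.upper()
    if len(seq) != pwm.length:
        raise ValidationError(
            f"window length {len(seq)} != motif length {pwm.length}")
    try:
        idx = [_BASE_INDEX[b] for b in seq]
    except KeyError as exc:
        raise ValidationError(f"ambiguous base {exc} in window") from exc
    c = pwm.contributions
    raw = float(c[idx, np.arange(pwm.length)].sum())
    raw_min = float(c.min(axis=0).sum())
    raw_max = float(c.max(axis=0).sum())
    if raw_max == raw_min:
        return 1.0
    return (raw - raw_min) / (raw_max - raw_min)


def _enumerate_raw_scores(pwm: Pwm, max_len: int = MAX_EXACT_LEN) -> np.ndarray:
    """Raw scores of all 4^L sequences (position-wise outer accumulation)."""
    if pwm.length > max_len:
        raise ValidationError(
            f"{pwm.motif_id}: enumeration limited to L <= {max_len}")
    c = pwm.contributions
    sums = np.zeros(1)
    for j in range(pwm.length):
        sums = (sums[:, None] + c[:, j][None, :]).ravel()
    return sums


def _grid_tail(pwm: Pwm, raw_threshold: float, n_bins: int) -> float:
    """Upper bound on P(raw >= t) via round-down integer-grid convolution."""
    c = pwm.contributions
    raw_min = float(c.min(axis=0).sum())
    raw_max = float(c.max(axis=0).sum())
    if raw_max == raw_min:
        return 1.0
    w = (raw_max - raw_min) / n_bins
    q = np.floor(c / w).astype(np.int64)  # per-base integer contributions
    max_sum = int(q.max(axis=0).sum())
    dist = np.zeros(max_sum + 1)
    dist[0] = 1.0
    for j in range(pwm.length):
        nxt = np.zeros_like(dist)
        for b in range(4):
            nxt[q[b, j]:] += 0.25 * dist[: dist.size - q[b, j]]
        dist = nxt
    # floor() loses at most w per position: int_sum >= t/w - L on {raw >= t}
    t_int = int(np.ceil(raw_threshold / w - pwm.length - 1e-9))
    t_int = max(t_int, 0)
    if t_int > max_sum:
        return float(dist[-1])  # at least the top bin's mass
    return float(dist[t_int:].sum())


def score_pvalue(pwm: Pwm, score: float, method: str = "auto",
                 n_bins: int = 65_536) -> float:
    """Tail probability P(score(random L-mer) >= score), uniform background.

    method "auto": exact enumeration for L <= 8, grid convolution otherwise.
    method "exact": force enumeration (L <= 8). method "grid": force the
    round-down grid convolution, whose result is always >= the exact tail.
    """
    if not (0.0 <= score <= 1.0 + 1e-12):
        raise ValidationError(f"score {score} outside [0, 1]")
    if method not in ("auto", "exact", "grid"):
        raise ValidationError(f"unknown method {method!r}")
    if method == "auto":
        method = "exact" if pwm.length <= MAX_EXACT_LEN else "grid"

    c = pwm.contributions
    raw_min = float(c.min(axis=0).sum())
    raw_max = float(c.max(axis=0).sum())
    if raw_max == raw_min:
        return 1.0
    # small relative slack so the consensus (score 1.0) keeps its own mass
    t = raw_min + score * (raw_max - raw_min) - 1e-9 * (raw_max - raw_min)

    if method == "exact":
        key = ("exact",)
        if key not in pwm._pv_cache:
            pwm._pv_cache[key] = np.sort(_enumerate_raw_scores(pwm))
        sums = pwm._pv_cache[key]
        n_ge = sums.size - np.searchsorted(sums, t, side="left")
        return float(n_ge) / sums.size
    return min(1.0, max(_grid_tail(pwm, t, n_bins), 1e-12))


@dataclass(frozen=True)
class MotifBreakParams:
    pval_cut: float = 0.001
    strong_delta: float = 0.4
    neutral_delta: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.pval_cut <= 1):
            raise ValidationError("pval_cut outside (0, 1]")
        if self.neutral_delta > self.strong_delta:
            raise ValidationError("neutral_delta must be <= strong_delta")


@dataclass(frozen=True)
class MotifHit:
    snp_id: str
    motif_id: str
    strand: str            # '+' or '-'
    window_start: int      # 0-based genome coordinate of the scored window
    score_ref: float
    score_alt: float
    p_ref: float
    p_alt: float
    delta: float           # score_ref - score_alt
    effect: str            # strong | weak | neutral


def _classify(delta: float, params: MotifBreakParams) -> str:
    if abs(delta) >= params.strong_delta:
        return "strong"
    if abs(delta) <= params.neutral_delta:
        return "neutral"
    return "weak"


def break_snp(genome: dict[str, str], snp, pwms: Iterable[Pwm],
              params: MotifBreakParams = MotifBreakParams()) -> list[MotifHit]:
    """Score one SNP's ref and alt alleles against a motif library.

    `snp` needs snp_id/chrom/pos/ref/alt attributes (VCF-style 1-based pos).
    The reference base must match the genome at the SNP position. For each
    motif and strand, every full-length window overlapping the SNP is scored
    for both alleles; the window maximising max(score_ref, score_alt) is
    kept, and a hit is emitted when min(p_ref, p_alt) < pval_cut. Windows
    truncated by a contig edge are skipped.
    """
    from .io import norm_chrom  # local import to avoid a module cycle

    chrom_seq = None
    for name, seq in genome.items():
        if norm_chrom(name) == norm_chrom(str(snp.chrom)):
            chrom_seq = seq
            break
    if chrom_seq is None:
        raise ValidationError(f"{snp.snp_id}: contig {snp.chrom} not in genome")
    pos0 = int(snp.pos) - 1
    if not (0 <= pos0 < len(chrom_seq)):
        raise ValidationError(f"{snp.snp_id}: position outside contig")
    if chrom_seq[pos0] != snp.ref:
        raise ValidationError(
            f"{snp.snp_id}: genome base {chrom_seq[pos0]} at {snp.chrom}:"
            f"{snp.pos} does not match ref allele {snp.ref}")

    hits: list[MotifHit] = []
    for pwm in pwms:
        L = pwm.length
        for strand in ("+", "-"):
            best = None  # (max_score, start, s_ref, s_alt)
            for offset in range(L):
                start = pos0 - offset
                if start < 0 or start + L > len(chrom_seq):
                    continue  # truncated window at a contig edge
                ref_win = chrom_seq[start:start + L]
                if any(b not in "ACGT" for b in ref_win):
                    logger.warning("%s: ambiguous base near %s:%d, window "
                                   "skipped", snp.snp_id, snp.chrom, snp.pos)
                    continue
                alt_win = ref_win[:offset] + snp.alt + ref_win[offset + 1:]
                if strand == "-":
                    ref_win, alt_win = revcomp(ref_win), revcomp(alt_win)
                s_ref = score_window(pwm, ref_win)
                s_alt = score_window(pwm, alt_win)
                key = max(s_ref, s_alt)
                if best is None or key > best[0]:
                    best = (key, start, s_ref, s_alt)
            if best is None:
                continue
            _, start, s_ref, s_alt = best
            p_ref = score_pvalue(pwm, s_ref)
            p_alt = score_pvalue(pwm, s_alt)
            if min(p_ref, p_alt) < params.pval_cut:
                delta = s_ref - s_alt
                hits.append(MotifHit(
                    snp_id=snp.snp_id, motif_id=pwm.motif_id, strand=strand,
                    window_start=start, score_ref=s_ref, score_alt=s_alt,
                    p_ref=p_ref, p_alt=p_alt, delta=delta,
                    effect=_classify(delta, params)))
    return hits


def write_hits(hits: Sequence[MotifHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tmotif_id\tstrand\twindow_start\tscore_ref\t"
                 "score_alt\tp_ref\tp_alt\tdelta\teffect\n")
        for h in hits:
            fh.write(f"{h.snp_id}\t{h.motif_id}\t{h.strand}\t{h.window_start}"
                     f"\t{h.score_ref:.6g}\t{h.score_alt:.6g}\t{h.p_ref:.6g}"
                     f"\t{h.p_alt:.6g}\t{h.delta:.6g}\t{h.effect}\n")
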