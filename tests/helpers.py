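"""Independent reference implementations used as test oracles.

Everything here is deliberately naive — brute force, full enumeration or
direct formula — and shares no code path with the package.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


# --------------------------------------------------------------------------
# Wilcoxon signed-rank: exact null by sign-pattern enumeration (rank DP)

def wilcoxon_enum_pvalue(values, mu=0.0, alternative="two-sided"):
    """Exact signed-rank p via the distribution of W+ over all sign patterns.

    Tie-free |values - mu| required. The DP over ranks is equivalent to
    enumerating all 2^n sign assignments.
    """
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0.0]
    n = d.size
    absd = np.abs(d)
    assert np.unique(absd).size == n, "oracle requires tie-free data"
    ranks = np.argsort(np.argsort(absd)) + 1
    w_obs = int(ranks[d > 0].sum())
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1, dtype=object)
    counts[0] = 1
    for r in range(1, n + 1):
        new = counts.copy()
        new[r:] += counts[:max_w + 1 - r]
        counts = new
    total = 2 ** n
    p_ge = sum(counts[w_obs:]) / total
    p_le = sum(counts[: w_obs + 1]) / total
    if alternative == "greater":
        return float(p_ge)
    if alternative == "less":
        return float(p_le)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


# --------------------------------------------------------------------------
# Benjamini-Hochberg step-up, by hand

def bh_by_hand(pvals):
    p = list(map(float, pvals))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj


# --------------------------------------------------------------------------
# Hypergeometric upper tail by pmf summation

def hypergeom_tail_brute(k, N, K, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n), summed term by term."""
    denom = math.comb(N, n)
    total = 0
    for j in range(max(k, 0), min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / denom


# --------------------------------------------------------------------------
# PWM score tail by exhaustive sequence enumeration

def pwm_tail_enum(prob_matrix, score):
    """P(normalized IC score >= score) over all 4^L sequences, from scratch.

    prob_matrix is the pseudocounted 4 x L probability matrix (rows ACGT).
    Mirrors the scoring definition independently: IC_j = sum p log2(p/0.25),
    contribution IC_j * p_j(base), min/max normalisation.
    """
    m = np.asarray(prob_matrix, dtype=float)
    L = m.shape[1]
    ic = [sum(p * math.log2(p / 0.25) for p in m[:, j] if p > 0)
          for j in range(L)]
    contrib = [[ic[j] * m[b, j] for b in range(4)] for j in range(L)]
    raw_min = sum(min(c) for c in contrib)
    raw_max = sum(max(c) for c in contrib)
    t = raw_min + score * (raw_max - raw_min) - 1e-9 * (raw_max - raw_min)
    count = 0
    for seq in itertools.product(range(4), repeat=L):
        raw = 0.0
        for j, b in enumerate(seq):
            raw = raw + contrib[j][b]
        if raw >= t:
            count += 1
    return count / 4 ** L


# --------------------------------------------------------------------------
# Naive clumping: recompute eligibility from scratch at every iteration

def naive_clump(rows, r2_fn, p1, p2, r2_min, kb_window):
    """Reference greedy clumping.

    rows: list of (snp_id, chrom, pos, pval); r2_fn(a, b) -> float | None.
    Returns (list of (index, tuple(members)), unassigned ids).
    """
    assigned = set()
    clumps = []
    window = kb_window * 1000.0
    while True:
        pending = [r for r in rows
                   if r[0] not in assigned and r[3] <= p1]
        if not pending:
            break
        sid, chrom, pos, pval = min(pending, key=lambda r: (r[3], r[1], r[2]))
        assigned.add(sid)
        members = []
        for osid, ochrom, opos, opval in sorted(
                rows, key=lambda r: (r[3], r[1], r[2])):
            if osid in assigned or opval > p2:
                continue
            if ochrom != chrom or abs(opos - pos) > window:
                continue
            ld = r2_fn(sid, osid)
            if ld is None or ld < r2_min:
                continue
            members.append(osid)
            assigned.add(osid)
        clumps.append((sid, tuple(members)))
    unassigned = [r[0] for r in rows if r[0] not in assigned]
    return clumps, unassigned


# --------------------------------------------------------------------------
# Random clumping instances

def random_clump_instance(rng, max_snps=50, max_samples=30):
    """A random genotype panel + association records for oracle comparison."""
    import pandas as pd
    from mafdiverge.ld import GenotypePanel

    n_snps = int(rng.integers(2, max_snps + 1))
    n_samples = int(rng.integers(4, max_samples + 1))
    base = rng.integers(0, 3, size=(n_samples, n_snps)).astype(float)
    # correlate some neighbours so clumps actually form
    for j in range(1, n_snps):
        if rng.random() < 0.5:
            base[:, j] = base[:, j - 1]
            flip = rng.random(n_samples) < 0.2
            base[flip, j] = rng.integers(0, 3, size=int(flip.sum()))
    if rng.random() < 0.3:  # sprinkle missing calls
        miss = rng.random((n_samples, n_snps)) < 0.05
        base[miss] = np.nan
    chroms = np.sort(rng.integers(1, 3, size=n_snps)).astype(str)
    pos = np.sort(rng.choice(2_000_000, size=n_snps, replace=False))
    pvals = 10.0 ** rng.uniform(-8, 0, size=n_snps)
    if n_snps > 3 and rng.random() < 0.3:  # occasional p-value ties
        pvals[1] = pvals[0]
    ids = [f"snp{j:03d}" for j in range(n_snps)]
    variants = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": pos,
                             "ref": "A", "alt": "G"})
    panel = GenotypePanel(genotypes=base, variants=variants)
    rows = list(zip(ids, chroms, pos.tolist(), pvals.tolist()))
    return panel, rows
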