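"""IC-weighted PWM scoring, exact score p-values, and SNP disruption calls."""

import math
import types

import numpy as np
import pytest

from mafdiverge import (MotifBreakParams, Pwm, ValidationError, break_snp,
                        column_ic, revcomp, score_pvalue, score_window)
from .helpers import pwm_tail_enum


def random_pwm(rng, L, motif_id="m"):
    return Pwm.from_probabilities(motif_id, rng.dirichlet(np.ones(4), size=L).T)


def snp(snp_id="s", chrom="1", pos=1, ref="A", alt="G"):
    return types.SimpleNamespace(snp_id=snp_id, chrom=chrom, pos=pos,
                                 ref=ref, alt=alt)


class TestColumnIc:
    @pytest.mark.parametrize("col,expected", [
        ([0.25, 0.25, 0.25, 0.25], 0.0),
        ([1, 0, 0, 0], 2.0),
        ([0.5, 0.5, 0, 0], 1.0),
    ])
    def test_examples(self, col, expected):
        assert column_ic(col) == pytest.approx(expected)

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            assert column_ic(rng.dirichlet(np.ones(4))) >= 0.0


class TestScoreWindow:
    def test_consensus_scores_one(self):
        rng = np.random.default_rng(1)
        pwm = random_pwm(rng, 7)
        assert score_window(pwm, pwm.consensus) == pytest.approx(1.0)

    def test_anticonsensus_scores_zero(self):
        rng = np.random.default_rng(2)
        pwm = random_pwm(rng, 5)
        worst = "".join("ACGT"[i] for i in pwm.matrix.argmin(axis=0))
        assert score_window(pwm, worst) == pytest.approx(0.0)

    def test_two_column_hand_computation(self):
        cols = np.array([[0.7, 0.4], [0.1, 0.3], [0.1, 0.2], [0.1, 0.1]])
        pwm = Pwm("m", cols, pseudocount=0.0)
        ic = [sum(p * math.log2(p / 0.25) for p in cols[:, j])
              for j in range(2)]
        contrib = [[ic[j] * cols[b, j] for b in range(4)] for j in range(2)]
        raw = contrib[0][0] + contrib[1][1]          # "AC"
        lo = sum(min(c) for c in contrib)
        hi = sum(max(c) for c in contrib)
        assert score_window(pwm, "AC") == pytest.approx((raw - lo) / (hi - lo))

    def test_scores_bounded(self):
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng, 6)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), 6))
            assert 0.0 <= score_window(pwm, seq) <= 1.0

    def test_ambiguous_base_rejected(self):
        rng = np.random.default_rng(4)
        pwm = random_pwm(rng, 4)
        with pytest.raises(ValidationError, match="ambiguous"):
            score_window(pwm, "ACNT")


class TestScorePvalue:
    def test_score_zero_covers_support(self):
        rng = np.random.default_rng(5)
        assert score_pvalue(random_pwm(rng, 6), 0.0) == 1.0

    def test_single_column_consensus(self):
        pwm = Pwm.from_probabilities("m", np.array([[0.7, 0.1, 0.1, 0.1]]).T)
        assert score_pvalue(pwm, 1.0) == pytest.approx(0.25)

    def test_monotone_nonincreasing_in_score(self):
        rng = np.random.default_rng(6)
        pwm = random_pwm(rng, 7)
        scores = np.linspace(0, 1, 21)
        ps = [score_pvalue(pwm, s) for s in scores]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)

    @pytest.mark.parametrize("L", [1, 2, 3, 4, 5, 6])
    def test_exact_matches_enumeration_oracle(self, L):
        rng = np.random.default_rng(10 + L)
        for _ in range(3):
            pwm = random_pwm(rng, L)
            for s in (0.2, 0.5, 0.8, 0.95, 1.0):
                got = score_pvalue(pwm, s, method="exact")
                want = pwm_tail_enum(pwm.matrix, s)
                assert got == pytest.approx(want, abs=1e-12)

    def test_grid_upper_bounds_exact_within_tolerance(self):
        rng = np.random.default_rng(20)
        for _ in range(5):
            pwm = random_pwm(rng, 8)
            for s in (0.7, 0.8, 0.9, 0.97, 1.0):
                exact = score_pvalue(pwm, s, method="exact")
                grid = score_pvalue(pwm, s, method="grid")
                assert grid >= exact - 1e-12
                assert grid <= exact + 1e-3

    def test_auto_uses_grid_for_long_motifs(self):
        rng = np.random.default_rng(21)
        pwm = random_pwm(rng, 12)
        p = score_pvalue(pwm, 0.9)  # enumeration would need 4^12 sequences
        assert 0 < p <= 1
        with pytest.raises(ValidationError):
            score_pvalue(pwm, 0.9, method="exact")


class TestBreakSnp:
    GENOME = {"1": "ACGTACGTACGTACGTACGTACGT"}

    def test_ref_mismatch_names_snp(self):
        rng = np.random.default_rng(30)
        pwm = random_pwm(rng, 4)
        with pytest.raises(ValidationError, match="badsnp"):
            break_snp(self.GENOME, snp("badsnp", pos=1, ref="C", alt="G"),
                      [pwm])

    def test_alt_equal_ref_is_neutral(self):
        rng = np.random.default_rng(31)
        pwm = random_pwm(rng, 4)
        hits = break_snp(self.GENOME, snp(pos=9, ref="A", alt="A"), [pwm],
                         MotifBreakParams(pval_cut=1.0))
        assert hits
        for h in hits:
            assert h.delta == 0.0 and h.effect == "neutral"

    def test_consensus_breaking_snp_detected(self):
        # plant the consensus in the genome; alt = worst base of column 2
        rng = np.random.default_rng(32)
        pwm = random_pwm(rng, 6)
        cons = pwm.consensus
        genome = {"1": "TTTTT" + cons + "TTTTT"}
        offset = 2
        ref = cons[offset]
        worst = "ACGT"[int(pwm.matrix[:, offset].argmin())]
        if worst == ref:  # consensus base can't be the worst
            worst = "ACGT"[int(np.argsort(pwm.matrix[:, offset])[1])]
        hits = break_snp(genome, snp(pos=6 + offset, ref=ref, alt=worst),
                         [pwm], MotifBreakParams(pval_cut=0.01))
        plus = [h for h in hits if h.strand == "+"]
        assert plus and plus[0].score_ref == pytest.approx(1.0)
        assert plus[0].score_ref > plus[0].score_alt
        assert plus[0].window_start == 5

    def test_strand_symmetry(self):
        # mirroring the genome swaps strands but preserves scores
        rng = np.random.default_rng(33)
        pwm = random_pwm(rng, 5)
        fwd = {"1": "AACGTACGGTTCAAG"}
        pos, ref, alt = 8, "G", "T"
        rev = {"1": revcomp(fwd["1"])}
        rpos = len(fwd["1"]) - pos + 1
        hits_f = break_snp(fwd, snp(pos=pos, ref=ref, alt=alt), [pwm],
                           MotifBreakParams(pval_cut=1.0))
        hits_r = break_snp(rev, snp(pos=rpos, ref=revcomp(ref),
                                    alt=revcomp(alt)), [pwm],
                           MotifBreakParams(pval_cut=1.0))
        f = {h.strand: (h.score_ref, h.score_alt) for h in hits_f}
        r = {h.strand: (h.score_ref, h.score_alt) for h in hits_r}
        assert f["+"] == pytest.approx(r["-"])
        assert f["-"] == pytest.approx(r["+"])

    def test_contig_edge_windows_skipped(self):
        rng = np.random.default_rng(34)
        pwm = random_pwm(rng, 6)
        genome = {"1": "ACG"}  # shorter than the motif: no full window
        hits = break_snp(genome, snp(pos=2, ref="C", alt="T"), [pwm],
                         MotifBreakParams(pval_cut=1.0))
        assert hits == []

    def test_default_pvalue_cutoff(self):
        assert MotifBreakParams().pval_cut == 0.001

    def test_planted_bundle_snps_disrupt(self, tiny_bundle):
        """Synthetic consensus-planted SNPs all yield a non-neutral hit."""
        from mafdiverge import read_meme
        pwms = read_meme(tiny_bundle.paths["motifs"])
        genome = tiny_bundle.annotations.genome
        var = tiny_bundle.variants.set_index("snp_id")
        for sid in tiny_bundle.truth.motif_snp_ids:
            row = var.loc[sid]
            s = snp(sid, "1", int(row["pos"]), row["ref"], row["alt"])
            hits = break_snp(genome, s, pwms)
            assert hits, sid
            non_neutral = [h for h in hits if h.effect != "neutral"]
            assert non_neutral, sid
            best = max(hits, key=lambda h: h.score_ref)
            assert best.score_ref > best.score_alt
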