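"""MAF deltas, the Wilcoxon wrapper, BH adjustment, and both selection rounds."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mafdiverge import (SelectionParams, ValidationError, bh_adjust,
                        maf_delta, select_divergent_matched,
                        select_divergent_pooled, wilcoxon_signed_rank)
from .helpers import bh_by_hand, wilcoxon_enum_pvalue


class TestMafDelta:
    @pytest.mark.parametrize("a,b,expected", [
        (0.352024, 0.352024, 0.0),      # identical MAFs (rs11546322-style)
        (0.3882, 0.1, 0.2882),          # high-vs-low (rs34567530-style)
        (0.0, 0.5, 0.5),                # extreme bound
    ])
    def test_examples(self, a, b, expected):
        assert maf_delta(a, b) == pytest.approx(expected, abs=1e-12)

    def test_symmetry(self):
        assert maf_delta(0.1, 0.4) == maf_delta(0.4, 0.1)

    @pytest.mark.parametrize("a,b", [(0.6, 0.1), (-0.1, 0.2), (0.2, 0.51)])
    def test_out_of_range_rejected(self, a, b):
        with pytest.raises(ValidationError):
            maf_delta(a, b)


class TestWilcoxon:
    def test_three_values_exact(self):
        # all 2^3 sign patterns; W+ = 6 attained once -> p = 1/8
        assert wilcoxon_signed_rank([0.1, 0.2, 0.3], mu=0.0,
                                    alternative="greater") == pytest.approx(0.125)

    def test_degenerate_all_equal_mu(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank([0.5, 0.5, 0.5], mu=0.5) == 1.0

    @pytest.mark.parametrize("n", range(1, 13))
    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_branch_equals_sign_enumeration(self, n, alternative):
        rng = np.random.default_rng(n)
        for _ in range(5):
            vals = rng.normal(size=n)
            while np.unique(np.abs(vals)).size < n or (vals == 0).any():
                vals = rng.normal(size=n)
            got = wilcoxon_signed_rank(vals, mu=0.0, alternative=alternative)
            want = wilcoxon_enum_pvalue(vals, mu=0.0, alternative=alternative)
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("n", [15, 20, 25])
    def test_exact_close_to_enumeration_mid_n(self, n):
        # the wrapper still uses the exact branch here; the enumeration
        # oracle doubles as a sanity check on tie-free data
        rng = np.random.default_rng(n * 7)
        for _ in range(5):
            vals = rng.normal(loc=0.3, size=n)
            got = wilcoxon_signed_rank(vals, mu=0.0, alternative="greater")
            want = wilcoxon_enum_pvalue(vals, mu=0.0, alternative="greater")
            assert got == pytest.approx(want, abs=0.01)

    def test_normal_approximation_close_to_enumeration(self):
        # force the approximation branch (n > 25) and compare to the exact DP
        rng = np.random.default_rng(77)
        for _ in range(20):
            vals = rng.normal(loc=0.2, size=26)
            got = wilcoxon_signed_rank(vals, mu=0.0, alternative="greater")
            want = wilcoxon_enum_pvalue(vals, mu=0.0, alternative="greater")
            assert got == pytest.approx(want, abs=0.01)

    def test_handles_ties_without_error(self):
        vals = [0.1, 0.1, 0.2, -0.2, 0.3, 0.4, 0.4, 0.5, -0.1, 0.6]
        p = wilcoxon_signed_rank(vals, mu=0.0, alternative="greater")
        assert 0.0 < p <= 1.0


class TestBH:
    def test_worked_example(self):
        got = bh_adjust([0.01, 0.04, 0.03, 0.05])
        np.testing.assert_allclose(got, [0.04, 0.05, 0.05, 0.05], atol=1e-12)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_all_equal_fixed_point(self):
        np.testing.assert_allclose(bh_adjust([0.2] * 5), [0.2] * 5)

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=25),
           st.randoms(use_true_random=False))
    def test_adjusted_ge_raw_and_permutation_equivariant(self, pvals, rnd):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0 + 1e-15).all()
        np.testing.assert_allclose(adj, bh_by_hand(pvals), atol=1e-12)
        perm = list(range(len(pvals)))
        rnd.shuffle(perm)
        adj_perm = bh_adjust([pvals[i] for i in perm])
        np.testing.assert_allclose(adj_perm, [adj[i] for i in perm],
                                   atol=1e-12)


class TestPooledSelection:
    def test_outlier_detected_among_tight_background(self):
        # one delta of 0.30 among 49 deltas at ~0.01: only the outlier is
        # selected; each background SNP sees a distribution centred on its
        # own value, so its one-sided p stays high
        deltas = {f"bg{i}": 0.01 for i in range(49)}
        deltas["hit"] = 0.30
        out = select_divergent_pooled(deltas, SelectionParams())
        assert bool(out.loc["hit", "selected"])
        assert int(out["selected"].sum()) == 1

    def test_all_equal_selects_nothing(self):
        out = select_divergent_pooled({f"s{i}": 0.1 for i in range(10)})
        assert not out["selected"].any()
        assert (out["p_raw"] == 1.0).all()

    def test_fewer_than_three_refused(self):
        with pytest.raises(ValidationError):
            select_divergent_pooled({"a": 0.1, "b": 0.2})

    def test_explicit_background_excludes_own_entry(self):
        rng = np.random.default_rng(2)
        bg = pd.Series({f"bg{i}": abs(rng.normal(0.01, 0.005))
                        for i in range(200)})
        bg["q"] = 0.25
        out = select_divergent_pooled({"q": 0.25}, SelectionParams(),
                                      background_deltas=bg)
        assert bool(out.loc["q", "selected"])

    def test_monotone_in_delta(self):
        rng = np.random.default_rng(3)
        base = {f"bg{i}": abs(rng.normal(0.02, 0.01)) for i in range(30)}
        lo = select_divergent_pooled({**base, "q": 0.20})
        hi = select_divergent_pooled({**base, "q": 0.35})
        if bool(lo.loc["q", "selected"]):
            assert bool(hi.loc["q", "selected"])
        assert hi.loc["q", "p_raw"] <= lo.loc["q", "p_raw"] + 1e-12


class TestMatchedSelection:
    def test_strong_query_selected(self):
        rng = np.random.default_rng(4)
        matched = {"q": np.abs(rng.normal(0.01, 0.005, size=500))}
        out, excluded = select_divergent_matched({"q": 0.25}, matched)
        assert excluded == []
        assert bool(out.loc["q", "selected"])

    def test_query_at_matched_median_not_selected(self):
        rng = np.random.default_rng(5)
        bg = np.abs(rng.normal(0.05, 0.02, size=300))
        out, _ = select_divergent_matched({"q": float(np.median(bg))},
                                          {"q": bg})
        assert not bool(out.loc["q", "selected"])
        assert out.loc["q", "p_raw"] > 0.1

    def test_too_few_matches_excluded_with_report(self):
        rng = np.random.default_rng(6)
        matched = {"good": np.abs(rng.normal(0.01, 0.005, size=100)),
                   "thin": np.array([0.01, 0.02])}
        out, excluded = select_divergent_matched(
            {"good": 0.3, "thin": 0.3}, matched)
        assert excluded == ["thin"]
        assert list(out.index) == ["good"]

    def test_global_median_mode_blocks_lower_half(self):
        # significant against its own matched set but below the global
        # median of query deltas -> rejected under median_mode="queries"
        rng = np.random.default_rng(7)
        matched = {f"q{i}": np.abs(rng.normal(0.01, 0.003, size=200))
                   for i in range(4)}
        deltas = {"q0": 0.10, "q1": 0.20, "q2": 0.25, "q3": 0.30}
        params = SelectionParams(median_mode="queries")
        out, _ = select_divergent_matched(deltas, matched, params)
        assert not bool(out.loc["q0", "selected"])  # below global median
        assert bool(out.loc["q3", "selected"])
        default_out, _ = select_divergent_matched(deltas, matched)
        assert bool(default_out.loc["q0", "selected"])

    def test_median_rule_can_be_disabled(self):
        rng = np.random.default_rng(8)
        matched = {"q": np.abs(rng.normal(0.2, 0.001, size=100))}
        params = SelectionParams(require_above_median=False)
        out, _ = select_divergent_matched({"q": 0.15}, matched, params)
        # below the matched median: only the one-sided p keeps it out now
        assert out.loc["q", "p_raw"] > 0.5
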