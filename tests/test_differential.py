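"""Differential NFR statistics against independent brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nucdyn.differential import (
    bh_adjust,
    correlation_report,
    decile_classes,
    diff_nfr_table,
    nfr_ratio,
    scaled_chisq,
    significant_calls,
    wilcoxon_compare,
)


def chisq_oracle(a, b, c, d):
    """Direct sum((O-E)^2/E) on the 2x2 table [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    n = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / n
    return float(((table - expected) ** 2 / expected).sum())


def bh_oracle(p):
    """Min-over-suffix step-up, written independently of the implementation."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    best = float("inf")
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, p[i] * m / rank)
        q[i] = min(1.0, best)
    return q


def rank_sum_oracle(a, b):
    """Exhaustive two-sided permutation p-value for the rank-sum statistic."""
    pooled = list(a) + list(b)
    n = len(a)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n].sum()
    mu = len(a) * (len(pooled) + 1) / 2
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n):
        s = ranks[list(combo)].sum()
        total += 1
        if abs(s - mu) >= abs(obs - mu) - 1e-9:
            count += 1
    return count / total


class TestRatio:
    def test_textbook_definition_without_pseudocount(self):
        ratio, log2, direction = nfr_ratio(10, 5, pseudocount=0)
        assert (ratio, log2, direction) == (2.0, 1.0, "activated")

    def test_equal_counts_are_directionless(self):
        ratio, _, direction = nfr_ratio(7, 7)
        assert ratio == 1.0 and direction == "none"

    def test_pseudocount_guards_zero_comparison(self):
        ratio, _, direction = nfr_ratio(10, 0, pseudocount=0.5)
        assert ratio == 21.0 and direction == "activated"

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nfr_ratio(-1, 5)

    @given(st.integers(0, 1000), st.integers(0, 1000))
    @settings(max_examples=50, deadline=None)
    def test_reciprocal_symmetry(self, a, b):
        r_ab, l_ab, _ = nfr_ratio(a, b)
        r_ba, l_ba, _ = nfr_ratio(b, a)
        assert r_ab * r_ba == pytest.approx(1.0)
        assert l_ab == pytest.approx(-l_ba)


class TestScaledChisq:
    def test_equal_proportions_give_zero(self):
        chi2, p = scaled_chisq(50, 1000, 100, 2000)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_matches_direct_formula_oracle(self):
        chi2, p = scaled_chisq(50, 1000, 100, 1000)
        expected = chisq_oracle(50, 950, 100, 900)
        assert chi2 == pytest.approx(expected, abs=1e-9)
        assert p == pytest.approx(stats.chi2.sf(expected, 1), abs=1e-12)

    def test_doubling_cells_doubles_statistic(self):
        chi2, p1 = scaled_chisq(50, 1000, 100, 1000)
        chi2x2, p2 = scaled_chisq(100, 2000, 200, 2000)
        assert chi2x2 == pytest.approx(2 * chi2, rel=1e-9)
        assert p2 < p1

    def test_random_tables_against_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            rt, ct = rng.integers(50, 5000, size=2)
            a = rng.integers(0, rt + 1)
            c = rng.integers(0, ct + 1)
            if a + c == 0 or (rt - a) + (ct - c) == 0:
                continue
            chi2, _ = scaled_chisq(a, rt, c, ct)
            assert chi2 == pytest.approx(chisq_oracle(a, rt - a, c, ct - c), abs=1e-9)

    def test_degenerate_zero_margin(self):
        assert scaled_chisq(0, 100, 0, 200) == (0.0, 1.0)

    def test_count_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            scaled_chisq(101, 100, 5, 100)


class TestBenjaminiHochberg:
    def test_hand_computed_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_passes_through(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(5)
        p = rng.random(100)
        q = bh_adjust(p)
        assert (np.diff(q[np.argsort(p)]) >= -1e-15).all()

    def test_matches_oracle_on_grid_inputs(self):
        grid = np.round(np.arange(0, 1.0001, 0.05), 3)
        for n in (1, 2, 3):
            for combo in itertools.product(grid, repeat=n):
                np.testing.assert_allclose(bh_adjust(list(combo)), bh_oracle(list(combo)),
                                           atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(2)
        p = rng.random(500)
        np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1],
                                   atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])


class TestSignificanceFilter:
    def frame(self, log2, q):
        ratio = 2.0 ** np.asarray(log2)
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(log2))],
                             "ratio": ratio, "log2_ratio": log2, "q": q})

    def test_filter_requires_both_conditions(self):
        df = self.frame([1.5, 0.9, 2.0], [1e-40, 1e-40, 1e-20])
        kept = significant_calls(df, fold_log2=1.0, q_max=1e-30)
        assert list(kept["gene_id"]) == ["g0"]
        assert kept["call"].iloc[0] == "activated"
        assert list(df["call"]) == ["activated", "NS", "NS"]

    def test_repression_sign(self):
        df = self.frame([-2.0], [1e-40])
        kept = significant_calls(df)
        assert kept["call"].iloc[0] == "repressed"


class TestDeciles:
    def test_exact_decile_sizes(self):
        s = pd.Series(np.arange(100, dtype=float), index=[f"g{i:03d}" for i in range(100)])
        classes = decile_classes(s)
        counts = classes["class"].value_counts()
        assert counts["high"] == 10 and counts["low"] == 10 and counts["mid"] == 80

    def test_all_equal_values_tie_break_by_gene_id(self, caplog):
        s = pd.Series(1.0, index=[f"g{i:02d}" for i in range(20)])
        with caplog.at_level("WARNING"):
            classes = decile_classes(s)
        counts = classes["class"].value_counts()
        assert counts["high"] == 2 and counts["low"] == 2
        assert any("equal" in r.message for r in caplog.records)

    def test_rank_preserving_relabel_leaves_classes_unchanged(self):
        rng = np.random.default_rng(9)
        s = pd.Series(rng.random(50), index=[f"g{i:02d}" for i in range(50)])
        a = decile_classes(s).sort_values("gene_id").reset_index(drop=True)
        b = decile_classes(np.exp(3 * s)).sort_values("gene_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError, match="10"):
            decile_classes(pd.Series([1.0] * 9))


class TestCorrelation:
    def test_perfect_linear(self):
        x = np.arange(10.0)
        r, r2, n = correlation_report(x, 2 * x + 1)
        assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0) and n == 10

    def test_perfect_anti_linear(self):
        r, _, _ = correlation_report([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_independent_values_give_near_zero_r2(self):
        rng = np.random.default_rng(4)
        _, r2, n = correlation_report(rng.random(10_000), rng.random(10_000))
        assert r2 < 0.01 and n == 10_000

    def test_nan_pairs_dropped(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 4.0, 6.0, 8.0, 10.0]
        _, r2, n = correlation_report(x, y)
        assert n == 4 and r2 == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            correlation_report([1, 1, 1], [1, 2, 3])


class TestWilcoxon:
    def test_identical_groups_give_p_one(self):
        p, star = wilcoxon_compare([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0) and star == "ns"

    def test_fully_separated_small_groups_exact(self):
        p, _ = wilcoxon_compare([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(2 / 20)  # 2 of C(6,3)=20 assignments as extreme

    def test_exact_matches_permutation_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a = rng.normal(0, 1, rng.integers(3, 7))
            b = rng.normal(0.5, 1, rng.integers(3, 7))
            p, _ = wilcoxon_compare(a, b)
            assert p == pytest.approx(rank_sum_oracle(a, b), abs=1e-9)

    def test_star_thresholds(self):
        from nucdyn.differential import _stars

        assert _stars(0.04) == "*"
        assert _stars(0.004) == "**"
        assert _stars(0.0004) == "***"
        assert _stars(0.06) == "ns"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([], [1.0])


class TestDiffTable:
    def make_arch(self):
        rng = np.random.default_rng(3)
        n = 40
        ref = rng.poisson(25, n).astype(float)
        cmp_ = ref.copy()
        cmp_[:5] *= 4  # repressed in the comparison condition
        return pd.DataFrame({
            "gene_id": [f"g{i:03d}" for i in range(n)],
            "Gln_NFR": ref, "Pro_NFR": cmp_,
            "Gln_NFR_raw": ref, "Pro_NFR_raw": cmp_,
        })

    TOTALS = {"Gln": 100_000, "Pro": 100_000}

    def test_condition_swap_flips_signs_keeps_statistics(self):
        arch = self.make_arch()
        fwd = diff_nfr_table(arch, "Gln", "Pro", self.TOTALS)
        rev = diff_nfr_table(arch, "Pro", "Gln", self.TOTALS)
        np.testing.assert_allclose(fwd["log2_ratio"], -rev["log2_ratio"], atol=1e-12)
        np.testing.assert_allclose(fwd["chi2"], rev["chi2"], atol=1e-9)
        np.testing.assert_allclose(fwd["q"], rev["q"], atol=1e-12)

    def test_one_bh_family_per_comparison(self):
        arch = self.make_arch()
        res = diff_nfr_table(arch, "Gln", "Pro", self.TOTALS)
        np.testing.assert_allclose(res["q"], bh_oracle(list(res["p"])), atol=1e-12)

    def test_genes_without_nfr_dropped(self):
        arch = self.make_arch()
        arch.loc[0, "Gln_NFR"] = np.nan
        res = diff_nfr_table(arch, "Gln", "Pro", self.TOTALS)
        assert len(res) == len(arch) - 1
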