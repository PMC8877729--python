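"""Population accounting, test dispatch, Holm, proportions, effect sizes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somaquant.stats import (
    REACTIVITY_CLASSES,
    accounting_from_counts,
    chi_square_proportions,
    compare_groups,
    holm_adjust,
    kruskal_wallis_background,
    proportion_estimate_ci,
    select_and_run_test,
)

# Reference dataset's published detection counts (used here purely as inputs
# to the accounting arithmetic).
PRE = {"NT+NN+": 400_011, "NT+NN-": 91_778, "NT-NN+": 34_839, "NT-NN-": 2_766}
POST = {"NT+NN+": 303_381, "NT+NN-": 48_651, "NT-NN+": 18_565, "NT-NN-": 505}
DECLARED_TOTAL = 627_905


class TestAccounting:
    def test_published_post_screen_percentages(self):
        acc = accounting_from_counts(PRE, POST, DECLARED_TOTAL)
        assert acc.percentages("post") == {
            "NT+NN+": 81.8,
            "NT+NN-": 13.1,
            "NT-NN+": 5.0,
            "NT-NN-": 0.1,
        }

    def test_published_pre_screen_percentages(self):
        acc = accounting_from_counts(PRE, POST, DECLARED_TOTAL)
        assert acc.percentages("pre") == {
            "NT+NN+": 75.6,
            "NT+NN-": 17.3,
            "NT-NN+": 6.6,
            "NT-NN-": 0.5,
        }

    def test_excluded_count_from_declared_total(self):
        acc = accounting_from_counts(PRE, POST, DECLARED_TOTAL)
        assert acc.total_excluded == DECLARED_TOTAL - 371_102 == 256_803

    def test_declared_total_discrepancy_is_surfaced(self):
        acc = accounting_from_counts(PRE, POST, DECLARED_TOTAL)
        # the declared detection total exceeds the class-count sum; the
        # accounting reports the gap instead of silently reconciling
        assert acc.declared_total_discrepancy == DECLARED_TOTAL - sum(PRE.values())
        assert acc.declared_total_discrepancy > 0

    def test_single_cell_accounting(self):
        one = {"NT+NN+": 1, "NT+NN-": 0, "NT-NN+": 0, "NT-NN-": 0}
        acc = accounting_from_counts(one, one)
        assert acc.percentages("post") == {
            "NT+NN+": 100.0, "NT+NN-": 0.0, "NT-NN+": 0.0, "NT-NN-": 0.0,
        }
        assert acc.total_excluded == 0

    def test_conservation_from_tables(self, noisy_result):
        from somaquant.stats import population_accounting

        acc = population_accounting(noisy_result.all_cells, noisy_result.retained)
        assert acc.pre_total == len(noisy_result.all_cells)
        assert acc.post_total == len(noisy_result.retained)
        assert acc.total_excluded == len(noisy_result.excluded)
        for stage in ("pre", "post"):
            counts = acc.pre_counts if stage == "pre" else acc.post_counts
            assert sum(counts.values()) == (
                acc.pre_total if stage == "pre" else acc.post_total
            )


class TestProportionCI:
    def test_boundaries(self):
        est, lo, hi = proportion_estimate_ci(0, 10)
        assert est == 0 and lo == 0
        est, lo, hi = proportion_estimate_ci(10, 10)
        assert est == 1 and hi == 1

    def test_wilson_closed_form(self):
        # independent closed-form Wilson interval
        k, n, z = 50, 100, 1.959963984540054
        p = k / n
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        est, lo, hi = proportion_estimate_ci(k, n)
        assert lo == pytest.approx(center - half, rel=1e-9)
        assert hi == pytest.approx(center + half, rel=1e-9)
        assert lo <= est <= hi

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            proportion_estimate_ci(1, 0)
        with pytest.raises(ValueError):
            proportion_estimate_ci(5, 3)


class TestDispatcher:
    def test_identical_samples_null_result(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        res = select_and_run_test(a, list(a))
        assert res.p_raw > 0.9
        assert res.effect_size == pytest.approx(0.0, abs=0.1)

    def test_separated_normal_samples_choose_welch(self, rng):
        a = rng.normal(0, 1, 7)
        b = rng.normal(10, 1, 7)
        res = select_and_run_test(a, b)
        assert res.test == "Welch"
        assert res.p_raw < 0.001
        assert res.effect_size > 0.9

    def test_heavy_tailed_samples_choose_brunner_munzel(self, rng):
        # lognormal samples with an extreme outlier fail Shapiro-Wilk
        a = np.exp(rng.normal(0, 1.5, 12)); a[0] = 2000.0
        b = np.exp(rng.normal(0.3, 1.5, 12)); b[0] = 1500.0
        res = select_and_run_test(a, b)
        assert res.test == "Brunner-Munzel"

    def test_paired_variants(self, rng):
        a = rng.normal(0, 1, 8)
        res = select_and_run_test(a, a + rng.normal(2, 0.3, 8), paired=True)
        assert res.test == "pairwise Welch"
        assert res.p_raw < 0.01
        skew = np.exp(rng.normal(0, 1.5, 12)); skew[0] = 500.0
        res = select_and_run_test(skew, skew * 1.5 + 1, paired=True)
        assert res.test == "Wilcoxon signed-rank"

    def test_insufficient_samples_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            select_and_run_test([1.0, 2.0], [1.0, 2.0, 3.0])

    def test_zero_variance_flagged(self):
        res = select_and_run_test([5.0] * 5, [5.0] * 5)
        assert "zero-variance" in res.flags
        assert res.p_raw == 1.0

    def test_type_one_error_within_band(self):
        """Null normal data, n=7 per group: rejection rate near nominal 5%."""
        rng = np.random.default_rng(2024)
        n_reps = 2000
        rej = 0
        for _ in range(n_reps):
            res = select_and_run_test(rng.normal(0, 1, 7), rng.normal(0, 1, 7))
            rej += res.p_raw < 0.05
        assert 0.03 <= rej / n_reps <= 0.07


def _holm_oracle(ps):
    """Explicit step-down enumeration of Holm's method."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    out = [0.0] * m
    prev = 0.0
    for rank, i in enumerate(order):
        val = min(1.0, max(prev, (m - rank) * ps[i]))
        out[i] = val
        prev = val
    return out


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == [0.2]

    def test_hand_computed_three_values(self):
        # sorted: .01*3=.03, .03*2=.06, .04*1=.04 -> monotone cap .06
        assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])

    def test_all_ones(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_grid_of_three_element_sets_matches_enumeration(self):
        grid = [0.001, 0.005, 0.01, 0.02, 0.04, 0.05, 0.1, 0.3, 0.5, 0.9, 1.0]
        for p1 in grid:
            for p2 in grid:
                for p3 in grid:
                    ps = [p1, p2, p3]
                    assert holm_adjust(ps) == pytest.approx(_holm_oracle(ps))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        ps = rng.uniform(0, 1, 20)
        _, adj, _, _ = multipletests(ps, method="holm")
        np.testing.assert_allclose(holm_adjust(ps), adj, rtol=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_never_below_raw_and_monotone(self, ps):
        adj = holm_adjust(ps)
        assert all(a >= p - 1e-15 for a, p in zip(adj, ps))
        order = np.argsort(ps, kind="stable")
        sorted_adj = [adj[i] for i in order]
        assert all(x <= y + 1e-15 for x, y in zip(sorted_adj, sorted_adj[1:]))


class TestChiSquare:
    def test_identical_proportions(self):
        res = chi_square_proportions(10, 30, 10, 30)
        assert res.statistic == pytest.approx(0.0)
        assert res.effect_size == pytest.approx(1.0)

    def test_cross_product_odds_ratio(self):
        res = chi_square_proportions(10, 30, 30, 70)
        assert res.effect_size == pytest.approx((10 * 40) / (20 * 30))

    def test_zero_cell_flags_continuity_correction(self):
        res = chi_square_proportions(0, 10, 5, 10)
        assert "zero-cell-continuity-corrected-OR" in res.flags
        assert res.effect_size == pytest.approx((0.5 * 5.5) / (10.5 * 5.5))

    def test_matches_scipy_contingency(self, rng):
        from scipy.stats import chi2_contingency

        for _ in range(100):
            n1, n2 = rng.integers(2, 21, 2)
            k1 = rng.integers(1, n1)
            k2 = rng.integers(1, n2)
            mine = chi_square_proportions(k1, n1, k2, n2)
            table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
            if (table.sum(axis=0) == 0).any():
                continue
            ref = chi2_contingency(table, correction=False)
            assert mine.statistic == pytest.approx(ref.statistic, rel=1e-10)
            assert mine.p_raw == pytest.approx(ref.pvalue, rel=1e-10)

    def test_brute_force_enumeration_small_margins(self):
        """Statistic and OR agree with direct formulas for all 2x2 tables
        with both sample sizes up to 20."""
        from scipy.stats import chi2

        for n1 in range(1, 21):
            for n2 in range(1, 21):
                for k1 in range(n1 + 1):
                    for k2 in range(n2 + 1):
                        res = chi_square_proportions(k1, n1, k2, n2)
                        a, b, c, d = k1, n1 - k1, k2, n2 - k2
                        n = n1 + n2
                        if (a + c) == 0 or (b + d) == 0:
                            assert res.statistic == 0.0 and res.p_raw == 1.0
                            continue
                        expected = (
                            n * (a * d - b * c) ** 2
                            / ((a + b) * (c + d) * (a + c) * (b + d))
                        )
                        assert res.statistic == pytest.approx(expected, rel=1e-12)
                        assert res.p_raw == pytest.approx(
                            float(chi2.sf(expected, 1)), rel=1e-12
                        )
                        if min(a, b, c, d) > 0:
                            assert res.effect_size == pytest.approx(
                                (a * d) / (b * c), rel=1e-12
                            )


class TestKruskalWallis:
    def test_identical_groups_h_near_zero(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = kruskal_wallis_background([g, list(g), list(g)])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_all_identical_values_flagged(self):
        res = kruskal_wallis_background([[3.0, 3.0], [3.0, 3.0]])
        assert res.p_raw == 1.0 and "all-identical" in res.flags

    def test_type_one_error_and_power(self):
        rng = np.random.default_rng(99)
        n_reps = 1000
        rej_null = sum(
            kruskal_wallis_background(
                [rng.normal(0, 1, 7) for _ in range(5)]
            ).p_raw < 0.05
            for _ in range(n_reps)
        )
        assert 0.03 <= rej_null / n_reps <= 0.07
        rej_alt = sum(
            kruskal_wallis_background(
                [rng.normal(0, 1, 7) for _ in range(4)] + [rng.normal(3, 1, 7)]
            ).p_raw < 0.05
            for _ in range(200)
        )
        assert rej_alt / 200 > 0.8


class TestCompareGroups:
    def test_holm_applied_within_family(self, rng):
        values = {
            g: rng.normal(mu, 1, 7)
            for g, mu in (("SH", 0), ("AS", 3), ("AR", 4), ("CS", 1), ("CR", 1))
        }
        results = compare_groups(values, endpoint="pcjun_fraction")
        assert len(results) == 8
        for r in results:
            assert r.p_holm is not None and r.p_holm >= r.p_raw
        adj = holm_adjust([r.p_raw for r in results])
        np.testing.assert_allclose([r.p_holm for r in results], adj)

    def test_missing_groups_are_skipped(self, rng):
        values = {"SH": rng.normal(0, 1, 7), "AS": rng.normal(1, 1, 7)}
        results = compare_groups(values)
        assert [r.contrast for r in results] == ["SH vs AS"]
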