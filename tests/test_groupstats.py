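"""Exact and asymptotic rank tests, group summaries."""

import warnings
from itertools import combinations, product
from math import sqrt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from itraqdiff import (
    UndefinedTestError,
    ValidationError,
    mann_whitney_u,
    summarize_groups,
    wilcoxon_signed_rank,
)
from itraqdiff.groupstats import _signed_rank_sums


def brute_force_signed_rank_p(diffs):
    """Literal enumeration of all 2^n sign assignments (independent oracle)."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s > 0) for signs in product([-1, 1], repeat=len(d))]
    )
    eps = 1e-9
    return min(1.0, 2 * min((ws <= w_obs + eps).mean(), (ws >= w_obs - eps).mean()))


def brute_force_rank_sum_p(a, b):
    """Literal enumeration over all C(n1+n2, n1) group assignments."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n1 = len(a)
    ranks = stats.rankdata(np.concatenate([a, b]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = np.array(
        [
            sum(ranks[i] for i in idx) - n1 * (n1 + 1) / 2
            for idx in combinations(range(len(ranks)), n1)
        ]
    )
    eps = 1e-9
    return min(1.0, 2 * min((us <= u_obs + eps).mean(), (us >= u_obs - eps).mean()))


class TestSignedRank:
    def test_exact_n5_all_positive_is_2_over_32(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [2, 4, 6, 8, 11], method="exact")
        assert res.p_two_sided == pytest.approx(2 / 32)
        assert res.p_two_sided == 0.0625
        assert res.method == "exact" and res.n == 5

    def test_exact_with_tied_differences_still_enumerates(self):
        # the |differences| 1,1,2,3,4 contain a tie; enumeration over
        # mid-ranks still gives the all-positive extreme p = 2/32
        with pytest.warns(UserWarning, match="mid-ranks"):
            res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [2, 3, 5, 7, 9], method="exact")
        assert res.p_two_sided == pytest.approx(0.0625)

    def test_normal_approx_n5_all_same_sign(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5], [2, 4, 6, 8, 11], method="normal_approx")
        assert res.statistic == 15
        assert 7.5 / sqrt(13.75) == pytest.approx(2.0226, abs=1e-4)
        assert res.p_two_sided == pytest.approx(0.0431, abs=5e-4)
        assert round(res.p_two_sided, 3) == 0.043

    def test_normal_approx_n6_all_same_sign(self):
        res = wilcoxon_signed_rank(
            [1, 2, 3, 4, 5, 6], [2, 4, 6, 9, 11, 14], method="normal_approx"
        )
        assert 10.5 / sqrt(22.75) == pytest.approx(2.2014, abs=1e-4)
        assert res.p_two_sided == pytest.approx(0.0277, abs=5e-4)
        assert round(res.p_two_sided, 3) == 0.028

    def test_zero_differences_dropped_and_counted(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4], [1, 4, 6, 8], method="exact")
        assert res.zero_diffs_dropped == 1 and res.n == 3

    def test_all_zero_differences_undefined(self):
        with pytest.raises(UndefinedTestError):
            wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])

    def test_matches_brute_force_enumeration_up_to_n10(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            n = int(rng.integers(2, 11))
            b = rng.normal(0, 1, n)
            a = b + rng.normal(0.3, 1, n)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = wilcoxon_signed_rank(b, a, method="exact").p_two_sided
            assert p == pytest.approx(brute_force_signed_rank_p(a - b), abs=1e-12)

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            d = rng.normal(0.2, 1, 8)
            p = wilcoxon_signed_rank(np.zeros(8), d, method="exact").p_two_sided
            assert p == pytest.approx(stats.wilcoxon(d, mode="exact").pvalue)

    def test_exact_p_invariant_under_sign_flip(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            d = rng.normal(0.3, 1, 7)
            p1 = wilcoxon_signed_rank(np.zeros(7), d, method="exact").p_two_sided
            p2 = wilcoxon_signed_rank(np.zeros(7), -d, method="exact").p_two_sided
            assert p1 == pytest.approx(p2)

    def test_rejection_rate_under_continuous_null_bounded_by_alpha(self):
        rng = np.random.default_rng(101)
        n_sims, n = 1000, 8
        rejections = 0
        for _ in range(n_sims):
            d = rng.normal(0, 1, n)
            p = wilcoxon_signed_rank(np.zeros(n), d, method="exact").p_two_sided
            rejections += p <= 0.05
        rate = rejections / n_sims
        assert rate <= 0.05 + 2 * sqrt(0.05 * 0.95 / n_sims)

    def test_normal_approx_converges_to_exact(self):
        """Discrepancy shrinks with n; below 0.01 in the p <= 0.1 region at n=15."""

        def max_gap(n, p_cap=1.0):
            ranks = np.arange(1, n + 1, dtype=float)
            sums = _signed_rank_sums(ranks)
            mean, var = n * (n + 1) / 4, n * (n + 1) * (2 * n + 1) / 24
            gaps = []
            for w in range(int(n * (n + 1) / 2) + 1):
                pe = min(1.0, 2 * min((sums <= w + 1e-9).mean(), (sums >= w - 1e-9).mean()))
                pa = min(1.0, 2 * stats.norm.sf(abs(w - mean) / sqrt(var)))
                if pe <= p_cap:
                    gaps.append(abs(pe - pa))
            return max(gaps)

        assert max_gap(15, p_cap=0.1) < 0.01
        assert max_gap(18) < max_gap(12) < max_gap(6)

    def test_large_n_falls_back_to_normal_with_warning(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0.5, 1, 25)
        with pytest.warns(UserWarning, match="falling back"):
            res = wilcoxon_signed_rank(np.zeros(25), d, method="exact")
        assert res.method == "normal_approx"


class TestMannWhitney:
    def test_separated_groups_exact_p_is_0_1(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6], method="exact")
        assert res.p_two_sided == pytest.approx(0.1)
        assert res.statistic == 0

    def test_fully_tied_groups_give_p_1(self):
        with pytest.warns(UserWarning, match="tie"):
            res = mann_whitney_u([1, 2], [1, 2], method="exact")
        assert res.p_two_sided == 1.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.5, 1, n2)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = mann_whitney_u(a, b, method="exact").p_two_sided
            assert p == pytest.approx(brute_force_rank_sum_p(a, b), abs=1e-12)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(31)
        a, b = rng.normal(0, 1, 5), rng.normal(0.8, 1, 6)
        p_exact = mann_whitney_u(a, b, method="exact").p_two_sided
        assert p_exact == pytest.approx(stats.mannwhitneyu(a, b, method="exact").pvalue)
        p_approx = mann_whitney_u(a, b, method="normal_approx").p_two_sided
        assert p_approx == pytest.approx(
            stats.mannwhitneyu(a, b, method="asymptotic", use_continuity=False).pvalue
        )

    def test_p_invariant_under_group_swap(self):
        rng = np.random.default_rng(29)
        a, b = rng.normal(0, 1, 4), rng.normal(1, 1, 5)
        assert mann_whitney_u(a, b, "exact").p_two_sided == pytest.approx(
            mann_whitney_u(b, a, "exact").p_two_sided
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1, 2])


def _measurements(rows):
    return pd.DataFrame(
        rows, columns=["subject_id", "group", "timepoint", "analyte", "concentration", "unit"]
    )


class TestSummaries:
    def test_median_and_range(self):
        df = _measurements(
            [
                (f"s{i}", "copd", "baseline", "PRDX1", v, "pg/mL")
                for i, v in enumerate([1.0, 2.0, 3.0])
            ]
        )
        out = summarize_groups(df)["summary"]
        row = out.iloc[0]
        assert (row["median"], row["min"], row["max"], row["n"]) == (2.0, 1.0, 3.0, 3)

    def test_subject_missing_after_record_excluded_from_pairing(self):
        rows = []
        for i in range(6):
            rows.append((f"s{i}", "copd", "baseline", "PRDX1", 10.0 + i, "pg/mL"))
            if i < 5:  # one subject has no after-smoking bronchoscopy
                rows.append((f"s{i}", "copd", "after_smoking", "PRDX1", 14.0 + 2 * i, "pg/mL"))
        out = summarize_groups(_measurements(rows))
        assert out["paired_tests"].iloc[0]["n_pairs"] == 5
        base = out["summary"].query("timepoint == 'baseline'").iloc[0]
        assert base["n"] == 6  # still counted at baseline

    def test_inconsistent_units_rejected(self):
        df = _measurements(
            [
                ("s1", "copd", "baseline", "PRDX1", 1.0, "pg/mL"),
                ("s2", "copd", "baseline", "PRDX1", 1.0, "ug/mL"),
            ]
        )
        with pytest.raises(ValidationError, match="unit"):
            summarize_groups(df)

    def test_change_comparison_detects_group_difference_with_power(self):
        """A large injected difference in smoke response is detected (p<0.05)
        in >= 90% of simulated studies."""
        rng = np.random.default_rng(77)
        n_sims, hits = 40, 0
        for _ in range(n_sims):
            rows = []
            for i in range(8):  # responders: concentrations drop after smoking
                base = rng.lognormal(3, 0.3)
                rows.append((f"a{i}", "young_non_susceptible", "baseline", "X", base, "pg/mL"))
                rows.append(
                    (f"a{i}", "young_non_susceptible", "after_smoking", "X",
                     base * rng.uniform(0.2, 0.5), "pg/mL")
                )
            for i in range(8):  # non-responders
                base = rng.lognormal(3, 0.3)
                rows.append((f"b{i}", "young_susceptible", "baseline", "X", base, "pg/mL"))
                rows.append(
                    (f"b{i}", "young_susceptible", "after_smoking", "X",
                     base * rng.uniform(0.9, 1.1), "pg/mL")
                )
            out = summarize_groups(_measurements(rows))
            p = out["change_tests"].iloc[0]["p_two_sided"]
            hits += p < 0.05
        assert hits / n_sims >= 0.9
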