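"""Association statistics and screening-cascade accounting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sstats

from lynchtriage.cohort_stats import (
    ContingencyTable2x2,
    SummaryStats,
    cascade_summary,
    chi_squared,
    odds_ratio_auto,
    odds_ratio_exact,
    odds_ratio_woolf,
    predictive_frequency,
    t_test_summary,
)
from lynchtriage.triage import GermlineOutcome, GermlineResult, triage_patient
from lynchtriage.assay_calls import IhcPattern, MsiCall, MsiStatus

cells = st.integers(min_value=1, max_value=60)
tables = st.builds(ContingencyTable2x2, cells, cells, cells, cells)

# the published comparison of suspected-Lynch vs MMR-proficient cases:
# age under 50 at diagnosis (7/27 suspected vs 16/146 proficient)
AGE_TABLE = ContingencyTable2x2(7, 20, 16, 130)
OVARIAN_TABLE = ContingencyTable2x2(5, 22, 22, 103)


class TestWoolfOddsRatio:
    def test_age_under_50_association(self):
        r = odds_ratio_woolf(AGE_TABLE)
        assert round(r.odds_ratio, 2) == 2.84
        assert round(r.ci_low, 2) == 1.04
        assert round(r.ci_high, 2) == 7.77

    def test_synchronous_ovarian_association(self):
        r = odds_ratio_woolf(OVARIAN_TABLE)
        assert round(r.odds_ratio, 2) == 1.06
        assert round(r.ci_low, 2) == 0.36
        # published upper bound 3.11 carries intermediate rounding; the
        # Woolf formula gives 3.1165
        assert abs(r.ci_high - 3.11) <= 0.01

    def test_symmetric_table_is_null(self):
        for k in (1, 4, 25):
            r = odds_ratio_woolf(ContingencyTable2x2(k, k, k, k))
            assert r.odds_ratio == pytest.approx(1.0)
            assert r.ci_low < 1.0 < r.ci_high

    @given(tables)
    def test_row_swap_inverts_the_odds_ratio(self, t):
        r = odds_ratio_woolf(t)
        swapped = odds_ratio_woolf(ContingencyTable2x2(t.c, t.d, t.a, t.b))
        assert r.odds_ratio * swapped.odds_ratio == pytest.approx(1.0)
        assert r.ci_low * swapped.ci_high == pytest.approx(1.0)

    @given(tables)
    def test_ci_width_shrinks_with_sample_size(self, t):
        widths = []
        for k in (1, 2, 4):
            scaled = ContingencyTable2x2(k * t.a, k * t.b, k * t.c, k * t.d)
            r = odds_ratio_woolf(scaled)
            widths.append(math.log(r.ci_high) - math.log(r.ci_low))
        assert widths[0] > widths[1] > widths[2]

    def test_zero_cell_is_an_explicit_error(self):
        with pytest.raises(ValueError, match=r"\['b'\]"):
            odds_ratio_woolf(ContingencyTable2x2(3, 0, 2, 5))

    def test_haldane_correction_opt_in(self):
        r = odds_ratio_woolf(ContingencyTable2x2(3, 0, 2, 5),
                             zero_cell_correction=True)
        assert math.isfinite(r.odds_ratio) and math.isfinite(r.ci_high)


class TestExactOddsRatio:
    def test_sparse_table_matches_conditional_mle_oracle(self):
        # independent oracle: scipy's conditional odds ratio
        t = ContingencyTable2x2(5, 3, 1, 10)
        r = odds_ratio_exact(t)
        oracle = sstats.contingency.odds_ratio([[5, 3], [1, 10]],
                                               kind="conditional")
        ci = oracle.confidence_interval(0.95)
        assert r.odds_ratio == pytest.approx(oracle.statistic, rel=1e-4)
        assert r.ci_low == pytest.approx(ci.low, rel=1e-4)
        assert r.ci_high == pytest.approx(ci.high, rel=1e-4)
        # sample cross-product lies near the published 16.67 and the exact
        # interval is wider than Woolf's
        assert (t.a * t.d) / (t.b * t.c) == pytest.approx(16.67, abs=0.01)
        w = odds_ratio_woolf(t)
        assert r.ci_low < w.ci_low and r.ci_high > w.ci_high

    @given(tables)
    def test_matches_scipy_on_random_tables(self, t):
        r = odds_ratio_exact(t)
        oracle = sstats.contingency.odds_ratio(
            [[int(t.a), int(t.b)], [int(t.c), int(t.d)]], kind="conditional"
        )
        assert r.odds_ratio == pytest.approx(oracle.statistic, rel=1e-3, abs=1e-6)

    def test_symmetric_table_is_null(self):
        r = odds_ratio_exact(ContingencyTable2x2(6, 6, 6, 6))
        assert r.odds_ratio == pytest.approx(1.0, abs=1e-6)

    def test_edge_table_has_one_sided_interval(self):
        r = odds_ratio_exact(ContingencyTable2x2(1, 0, 0, 1))
        assert r.odds_ratio == math.inf
        assert r.ci_high == math.inf
        assert 0 < r.ci_low < 1

    def test_haldane_correction_gives_finite_interval(self):
        r = odds_ratio_exact(ContingencyTable2x2(1, 0, 0, 1),
                             zero_cell_correction=True)
        assert math.isfinite(r.odds_ratio)
        assert math.isfinite(r.ci_low) and math.isfinite(r.ci_high)
        assert r.ci_low < r.odds_ratio < r.ci_high

    @pytest.mark.parametrize("table", [(5, 3, 1, 10), (2, 8, 7, 4)])
    def test_tail_inversion_against_grid_oracle(self, table):
        """Brute-force the noncentral hypergeometric tails over a psi grid."""
        a, b, c, d = table
        m1, n1, N = a + b, a + c, a + b + c + d
        xs = np.arange(max(0, m1 + n1 - N), min(m1, n1) + 1)
        logw = np.array([math.lgamma(m1 + 1) - math.lgamma(x + 1)
                         - math.lgamma(m1 - x + 1)
                         + math.lgamma(N - m1 + 1) - math.lgamma(n1 - x + 1)
                         - math.lgamma(N - m1 - n1 + x + 1) for x in xs])
        log_grid = np.linspace(-12, 12, 20001)
        w = np.exp(logw[None, :] + np.outer(log_grid, xs))  # (grid, support)
        total = w.sum(axis=1)
        tail_ge = w[:, xs >= a].sum(axis=1) / total  # increasing in psi
        tail_le = w[:, xs <= a].sum(axis=1) / total  # decreasing in psi
        lo = math.exp(log_grid[np.searchsorted(tail_ge, 0.025)])
        hi = math.exp(log_grid[np.searchsorted(-tail_le, -0.025)])
        r = odds_ratio_exact(ContingencyTable2x2(a, b, c, d))
        assert r.ci_low == pytest.approx(lo, rel=0.01)
        assert r.ci_high == pytest.approx(hi, rel=0.01)


class TestChiSquared:
    def test_age_table_p_value(self):
        stat, p = chi_squared(AGE_TABLE)
        assert round(p, 2) == 0.04

    def test_flat_table_is_exactly_null(self):
        stat, p = chi_squared(ContingencyTable2x2(9, 9, 9, 9))
        assert stat == 0.0 and p == 1.0

    def test_matches_expected_counts_oracle(self):
        # independent oracle: generic observed-vs-expected Pearson statistic
        t = ContingencyTable2x2(30, 10, 10, 30)
        stat, p = chi_squared(t)
        obs = np.array([[30, 10], [10, 30]])
        oracle_stat, oracle_p, _, _ = sstats.chi2_contingency(obs,
                                                              correction=False)
        assert stat == pytest.approx(oracle_stat)
        assert p == pytest.approx(oracle_p)

    def test_yates_correction_matches_scipy(self):
        stat, p = chi_squared(AGE_TABLE, continuity_correction=True)
        oracle_stat, oracle_p, _, _ = sstats.chi2_contingency(
            np.array([[7, 20], [16, 130]]), correction=True
        )
        assert stat == pytest.approx(oracle_stat)
        assert p == pytest.approx(oracle_p)

    @given(tables)
    def test_invariant_under_transposition(self, t):
        stat, _ = chi_squared(t)
        stat_t, _ = chi_squared(ContingencyTable2x2(t.a, t.c, t.b, t.d))
        assert stat == pytest.approx(stat_t)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError, match="margin"):
            chi_squared(ContingencyTable2x2(0, 0, 3, 4))


class TestTTestSummary:
    def test_age_comparison_from_published_summaries(self):
        r = t_test_summary(SummaryStats(57.70, 12.45, 27),
                           SummaryStats(64.31, 12.12, 146))
        assert round(r.p, 2) == 0.01
        assert r.df == 171

    def test_identical_groups_are_null(self):
        r = t_test_summary(SummaryStats(50, 10, 30), SummaryStats(50, 10, 30))
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_antisymmetric_under_group_swap(self):
        g1, g2 = SummaryStats(55, 9, 20), SummaryStats(60, 11, 35)
        r12, r21 = t_test_summary(g1, g2), t_test_summary(g2, g1)
        assert r12.t == pytest.approx(-r21.t)
        assert r12.p == pytest.approx(r21.p)

    def test_pooled_formula_oracle(self):
        g1, g2 = SummaryStats(57.70, 12.45, 27), SummaryStats(64.31, 12.12, 146)
        sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / (g1.n + g2.n - 2)
        t_manual = (g1.mean - g2.mean) / math.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
        assert t_test_summary(g1, g2).t == pytest.approx(t_manual)

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError):
            SummaryStats(50, 10, 1)
        with pytest.raises(ValueError):
            SummaryStats(50, 0, 10)


class TestCascade:
    def test_empty_cohort_is_an_error(self):
        with pytest.raises(ValueError, match="empty cohort"):
            cascade_summary([])

    def test_all_proficient_cohort(self):
        mss = MsiCall(MsiStatus.MSS, 0, 5)
        decisions = [triage_patient(IhcPattern(), mss) for _ in range(10)]
        s = cascade_summary(decisions)
        assert s.n_suspected == 0
        assert s.prevalence_observed == 0.0
        with pytest.raises(ValueError, match="no tested"):
            predictive_frequency(s)

    def test_germline_for_non_suspected_patient_warns(self):
        mss = MsiCall(MsiStatus.MSS, 0, 5)
        decisions = [triage_patient(IhcPattern(), mss, patient_id="p1")]
        germ = [[GermlineResult("MLH1", GermlineOutcome.NEGATIVE)]]
        with pytest.warns(UserWarning, match="non-suspected"):
            s = cascade_summary(decisions, germ)
        assert s.n_tested == 0

    def test_conservation_identity_on_simulated_cohorts(self):
        from lynchtriage import (cascade_summary, default_params,
                                 simulate_cohort, triage_cohort)

        for seed in range(5):
            params = default_params().model_copy(update={"seed": seed})
            cohort = simulate_cohort(params)
            decisions = triage_cohort(cohort)
            s = cascade_summary(decisions, [p.germline for p in cohort])
            assert s.n_mmr_deficient == (
                s.n_sporadic_methylated + s.n_suspected
                + s.n_epimutation_suspected + s.n_pending
            )

    def test_predictive_frequency_reduces_to_prevalence_without_attrition(self):
        from lynchtriage import (cascade_summary, default_params,
                                 simulate_cohort, triage_cohort)

        params = default_params().model_copy(
            update={"p_tested_given_suspected": 1.0, "seed": 3}
        )
        cohort = simulate_cohort(params)
        decisions = triage_cohort(cohort)
        s = cascade_summary(decisions, [p.germline for p in cohort])
        assert s.n_tested == s.n_suspected
        if s.n_tested:
            assert predictive_frequency(s) == pytest.approx(s.prevalence_observed)

    def test_auto_method_selects_exact_for_sparse_cells(self):
        assert odds_ratio_auto(ContingencyTable2x2(2, 8, 7, 40)).method == "exact"
        assert odds_ratio_auto(AGE_TABLE).method == "woolf"
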