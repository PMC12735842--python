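"""Contingency assembly, ROR/Wald inference and exact conditional inference.

The exact-inference machinery is cross-checked against two independent
routes: a rational-arithmetic enumeration oracle for the two-sided p-value
and scipy's hypergeometric / conditional odds-ratio implementations.
"""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from pvsignal import (
    ContingencyTable,
    StatsConfig,
    analyze_drug_set,
    build_contingency,
    classify,
    contingency_from_flags,
    contingency_from_margins,
    fisher_exact,
    generate_margins_fixture,
    hypergeom_logpmf,
    ror_wald,
    round_half_away,
)
from conftest import fisher_p_bruteforce, make_report

PRECISE = StatsConfig(cmle_solver="precise")

cells = st.integers(min_value=0, max_value=25)


def positive_tables(draw_min: int = 1):
    return st.tuples(
        st.integers(draw_min, 25), st.integers(draw_min, 25),
        st.integers(draw_min, 25), st.integers(draw_min, 25),
    ).map(lambda t: ContingencyTable(*t))


class TestTableConstruction:
    def test_margin_reconstruction_published_class_row(self):
        t = contingency_from_margins(1345, 27202, 5215, 11_451_738)
        assert t.cells() == (1345, 25857, 3870, 11_420_666)
        assert t.grand == 11_451_738

    def test_margin_reconstruction_per_drug(self):
        t = contingency_from_margins(595, 2722, 5215, 11_451_738)
        assert t.cells() == (595, 2127, 4620, 11_444_396)

    def test_degenerate_margins(self):
        assert contingency_from_margins(4, 4, 4, 4).cells() == (4, 0, 0, 0)

    def test_inconsistent_margins_raise(self):
        with pytest.raises(ValueError, match="drug_total"):
            contingency_from_margins(10, 9, 50, 100)
        with pytest.raises(ValueError, match="event_total"):
            contingency_from_margins(10, 20, 9, 100)
        with pytest.raises(ValueError, match="grand_total"):
            contingency_from_margins(10, 20, 30, 35)

    def test_raw_b_input_mode(self):
        t = contingency_from_margins(
            1345, 25857, 5215, 11_451_738, drug_total_includes_cases=False
        )
        assert t.cells() == (1345, 25857, 3870, 11_420_666)

    def test_report_level_one_per_stratum(self, design, small_reports):
        classified = classify(small_reports, design)
        t = build_contingency(classified, design.exposure_drugs)
        assert t.cells() == (1, 1, 1, 1)

    def test_all_exposed_cases_degenerate(self, design):
        classified = classify([make_report(f"R{i}") for i in range(5)], design)
        t = build_contingency(classified, design.exposure_drugs)
        assert t.cells() == (5, 0, 0, 0)

    def test_empty_input_raises(self, design):
        with pytest.raises(ValueError):
            build_contingency([], design.exposure_drugs)

    def test_flag_construction_matches_report_level(self, design, small_reports):
        classified = classify(small_reports, design)
        t1 = build_contingency(classified, design.exposure_drugs)
        is_case = np.array([c.is_case for c in classified])
        exposed = np.array([c.exposed for c in classified])
        assert contingency_from_flags(is_case, exposed).cells() == t1.cells()


class TestRorWald:
    def test_published_class_level_values(self):
        res = ror_wald(ContingencyTable(1345, 25857, 3870, 11_420_666))
        assert round_half_away(res.ror) == 153.5
        assert round_half_away(res.wald_low) == 144.1
        assert round_half_away(res.wald_high) == 163.5

    def test_symmetric_table_is_null(self):
        res = ror_wald(ContingencyTable(10, 10, 10, 10))
        assert res.ror == 1.0
        assert res.wald_low < 1.0 < res.wald_high

    def test_zero_a_reports_ror_zero_without_ci(self):
        res = ror_wald(ContingencyTable(0, 2, 5215, 11_446_521))
        assert res.ror == 0.0 and res.zero_cell
        assert res.wald_low is None and res.wald_high is None

    def test_zero_denominator_flags_infinite(self):
        res = ror_wald(ContingencyTable(5, 0, 3, 10))
        assert res.ror is None and res.ror_infinite and res.zero_cell

    def test_haldane_policy_gives_finite_estimate(self):
        res = ror_wald(
            ContingencyTable(0, 2, 5215, 11_446_521),
            StatsConfig(zero_cell_policy="haldane_half"),
        )
        assert res.ror is not None and res.wald_low is not None
        assert res.zero_cell

    def test_z_choice_invisible_at_printed_precision(self):
        """Exact 97.5% quantile vs 1.96: identical point estimates on every
        study row and identical class-level CI at one decimal.  (On the
        smallest-count row a single CI digit straddles the rounding
        boundary between the two quantiles, so per-drug CI digits are not
        asserted here.)"""
        margins = generate_margins_fixture()
        for rec in margins.records:
            if rec.a == 0:
                continue
            t = contingency_from_margins(
                rec.a, rec.drug_total, margins.event_total, margins.grand_total
            )
            exact = ror_wald(t, StatsConfig(z=1.959964))
            approx = ror_wald(t, StatsConfig(z=1.96))
            assert round_half_away(exact.ror) == round_half_away(approx.ror)
        t = contingency_from_margins(1345, 27202, 5215, 11_451_738)
        exact = ror_wald(t, StatsConfig(z=1.959964))
        approx = ror_wald(t, StatsConfig(z=1.96))
        for attr in ("ror", "wald_low", "wald_high"):
            assert round_half_away(getattr(exact, attr)) == round_half_away(
                getattr(approx, attr)
            )

    @given(positive_tables())
    @settings(max_examples=60, derandomize=True)
    def test_row_swap_inverts_ror(self, t):
        r1 = ror_wald(t).ror
        r2 = ror_wald(ContingencyTable(t.b, t.a, t.d, t.c)).ror
        assert r1 * r2 == pytest.approx(1.0, rel=1e-12)

    @given(positive_tables())
    @settings(max_examples=60, derandomize=True)
    def test_transpose_invariance(self, t):
        tt = ContingencyTable(t.a, t.c, t.b, t.d)
        assert ror_wald(t).ror == pytest.approx(ror_wald(tt).ror, rel=1e-12)
        assert fisher_exact(t).fisher_p == pytest.approx(
            fisher_exact(tt).fisher_p, rel=1e-9
        )

    @given(positive_tables(), st.integers(2, 5))
    @settings(max_examples=30, derandomize=True)
    def test_ci_contains_point_and_shrinks_when_scaled(self, t, k):
        res = ror_wald(t)
        assert res.wald_low <= res.ror <= res.wald_high
        scaled = ror_wald(ContingencyTable(k * t.a, k * t.b, k * t.c, k * t.d))
        assert scaled.ror == pytest.approx(res.ror, rel=1e-12)
        assert (scaled.wald_high / scaled.wald_low) < (res.wald_high / res.wald_low)


class TestHypergeomLogpmf:
    def test_small_enumeration(self):
        # N=4, m1=2, n1=2, k=1: C(2,1)C(2,1)/C(4,2) = 4/6
        assert hypergeom_logpmf(1, 2, 2, 4) == pytest.approx(math.log(2 / 3))

    def test_support_edges_finite_outside_log_zero(self):
        assert math.isfinite(hypergeom_logpmf(0, 5, 5, 20))
        assert math.isfinite(hypergeom_logpmf(5, 5, 5, 20))
        assert hypergeom_logpmf(6, 5, 5, 20) == -math.inf
        assert hypergeom_logpmf(-1, 5, 5, 20) == -math.inf

    @given(st.integers(1, 40), st.integers(1, 40), st.integers(2, 60))
    @settings(max_examples=60, derandomize=True)
    def test_normalizes_and_matches_scipy(self, m1, n1, N):
        m1, n1 = min(m1, N), min(n1, N)
        lo, hi = max(0, n1 + m1 - N), min(m1, n1)
        total = sum(math.exp(hypergeom_logpmf(k, m1, n1, N)) for k in range(lo, hi + 1))
        assert total == pytest.approx(1.0, abs=1e-10)
        k = (lo + hi) // 2
        assert hypergeom_logpmf(k, m1, n1, N) == pytest.approx(
            sps.hypergeom.logpmf(k, N, m1, n1), abs=1e-9
        )


class TestFisherExact:
    def test_small_table_against_bruteforce(self):
        res = fisher_exact(ContingencyTable(3, 1, 1, 3))
        assert res.fisher_p == pytest.approx(fisher_p_bruteforce(3, 1, 1, 3), rel=1e-9)

    def test_symmetric_mode_table_has_p_one(self):
        assert fisher_exact(ContingencyTable(5, 5, 5, 5)).fisher_p == pytest.approx(1.0)

    def test_published_class_level_fisher_column(self):
        """The conditional-MLE column of the study's class-level row."""
        res = fisher_exact(ContingencyTable(1345, 25857, 3870, 11_420_666))
        assert round_half_away(res.cmle_or) == 154.2
        assert round_half_away(res.exact_low) == 144.5
        assert round_half_away(res.exact_high) == 164.8
        assert res.exact_low < res.cmle_or < res.exact_high

    def test_precise_solver_solves_conditional_mean_equation(self):
        """The precise root makes E[X | psi] equal the observed cell."""
        from pvsignal.stats import _ConditionalDist

        t = ContingencyTable(1345, 25857, 3870, 11_420_666)
        res = fisher_exact(t, PRECISE)
        dist = _ConditionalDist(t)
        assert dist.mean(res.cmle_or) == pytest.approx(1345, abs=1e-5)

    @given(st.tuples(cells, cells, cells, cells))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_p_matches_rational_enumeration(self, abcd):
        a, b, c, d = abcd
        if a + b + c + d == 0 or (a + c == 0) or (b + d == 0):
            return
        res = fisher_exact(ContingencyTable(a, b, c, d))
        assert res.fisher_p == pytest.approx(
            fisher_p_bruteforce(a, b, c, d), rel=1e-9, abs=1e-12
        )

    @given(positive_tables())
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_p_matches_scipy(self, t):
        expected = sps.fisher_exact([[t.a, t.b], [t.c, t.d]]).pvalue
        assert fisher_exact(t).fisher_p == pytest.approx(expected, rel=1e-7)

    @given(positive_tables())
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_cmle_and_ci_match_scipy_conditional(self, t):
        res = fisher_exact(t, PRECISE)
        ref = sps.contingency.odds_ratio([[t.a, t.b], [t.c, t.d]], kind="conditional")
        ci = ref.confidence_interval(0.95)
        assert res.cmle_or == pytest.approx(ref.statistic, rel=1e-4)
        assert res.exact_low == pytest.approx(ci.low, rel=1e-3)
        assert res.exact_high == pytest.approx(ci.high, rel=1e-3)

    @given(positive_tables())
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_cmle_inside_exact_ci(self, t):
        res = fisher_exact(t)
        assert res.exact_low <= res.cmle_or <= res.exact_high

    def test_tail_probability_increases_in_psi(self):
        """P(X >= a | psi) is strictly increasing, so CI roots are unique."""
        from pvsignal.stats import _ConditionalDist

        dist = _ConditionalDist(ContingencyTable(6, 4, 3, 9))
        psis = np.logspace(-2, 2, 25)
        tails = [dist.cdf_upper(6, p) for p in psis]
        assert all(x < y for x, y in zip(tails, tails[1:]))

    def test_support_boundary_gives_zero_and_inf_bounds(self):
        res = fisher_exact(ContingencyTable(0, 5, 5, 5))
        assert res.cmle_or == 0.0 and res.exact_low == 0.0
        assert math.isfinite(res.exact_high)
        res = fisher_exact(ContingencyTable(5, 0, 0, 5))
        assert res.cmle_or == math.inf and res.exact_high == math.inf

    @given(positive_tables())
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_exact_ci_excludes_one_iff_a_tail_rejects(self, t):
        """The CI excludes the null exactly when a one-sided exact test at
        alpha/2 rejects it (tail monotonicity makes this a biconditional)."""
        from pvsignal.stats import _ConditionalDist

        res = fisher_exact(t, PRECISE)
        dist = _ConditionalDist(t)
        rejects = (
            dist.cdf_upper(t.a, 1.0) < 0.025 or dist.cdf_lower(t.a, 1.0) < 0.025
        )
        excludes_one = res.exact_low > 1.0 or res.exact_high < 1.0
        assert excludes_one == rejects


class TestAnalyzeDrugSet:
    def test_margin_mode_published_rows(self):
        margins = generate_margins_fixture()
        [sita] = analyze_drug_set(margins, {"sitagliptin"}, label="sitagliptin")
        assert round_half_away(sita.ror) == 37.7
        [tene] = analyze_drug_set(margins, {"teneligliptin"}, label="teneligliptin")
        assert round_half_away(tene.ror) == 394.5

    def test_null_synthetic_distribution_is_near_one(self, design):
        from pvsignal import GeneratorConfig, contingency_from_flags, generate_frame

        cfg = GeneratorConfig(
            n_reports=40_000, seed=3,
            drug_exposure_probs={"vildagliptin": 0.2},
            target_ror={"vildagliptin": 1.0},
            baseline_event_prob=0.05,
            confounder_contamination=0.0,
        )
        frame = generate_frame(cfg)
        t = contingency_from_flags(
            frame.is_case.to_numpy(), (frame.primary_drug == "vildagliptin").to_numpy()
        )
        res = ror_wald(t)
        assert res.wald_low < 1.0 < res.wald_high
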