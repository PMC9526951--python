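"""incidence_estimator: rates, recursion, hazard-based CIs, score CIs."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from riskband import (
    PersonTimeTable,
    air,
    compare_methods,
    cumulative_recursion,
    estimate_curve,
    nelson_aalen_poisson,
    score_ci,
    weighted_mean_curves,
)
from riskband.estimate import IncidenceCurve, incidence_risk, score_interval_rate
from riskband.records import N_BANDS, REPORT_AGES
from .conftest import random_table, zero_table


def single_band_table(band: int, d: int, t: float, fill_t: float = 1000.0):
    """All person-time everywhere, events in one band only."""
    events = [0] * N_BANDS
    years = [fill_t] * N_BANDS
    events[band] = d
    years[band] = t
    return PersonTimeTable("MLH1", "male", "All", tuple(events), tuple(years))


class TestAir:
    def test_definition_arithmetic(self):
        table = single_band_table(0, 2, 500.0)
        rates = air(table)
        assert rates[0] == pytest.approx(0.004)
        assert incidence_risk(rates)[0] == pytest.approx(0.02)

    def test_zero_events_zero_rate(self):
        table = single_band_table(3, 0, 300.0)
        assert air(table)[3] == 0.0

    def test_hand_table_rate(self, hand_table):
        # d=1, T=6.5 in [35,40)
        assert air(hand_table)[2] == pytest.approx(1 / 6.5, abs=1e-12)
        assert air(hand_table)[2] == pytest.approx(0.1538, abs=5e-4)

    def test_empty_band_is_zero_not_error(self):
        table = PersonTimeTable(
            "MLH1", "male", "All", (0,) * N_BANDS, (0.0,) * N_BANDS
        )
        assert np.all(air(table) == 0.0)

    def test_ir_capped_at_one(self):
        assert incidence_risk([0.5] * 9).max() == 1.0


class TestRecursion:
    def test_null_hazard(self):
        q = cumulative_recursion([0.0] * 9)
        assert np.all(q == 0.0)

    def test_certain_event_in_first_band(self):
        q = cumulative_recursion([1.0] + [0.0] * 8, report_ages=(25, 26, 30, 70))
        assert q[0] == 0.0
        assert q[1] == 1.0  # Q(26) = 1
        assert q[2] == 1.0
        assert q[3] == 1.0

    def test_constant_rate_closed_form(self):
        q = cumulative_recursion([0.01] * 9)
        assert q[-1] == pytest.approx(1 - 0.99**45, abs=1e-12)

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            cumulative_recursion([1.5] + [0.0] * 8)
        with pytest.raises(ValueError):
            cumulative_recursion([-0.1] + [0.0] * 8)

    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=9, max_size=9))
    @settings(max_examples=100, deadline=None)
    def test_recursion_equals_product_oracle(self, airs):
        """Annual stepping equals 1 - prod(1 - AIR) over elapsed years exactly."""
        q = cumulative_recursion(airs)
        for i, age in enumerate(REPORT_AGES):
            survival = 1.0
            for year in range(25, age):
                survival *= 1.0 - airs[(year - 25) // 5]
            assert q[i] == pytest.approx(1.0 - survival, abs=1e-12)


class TestNelsonAalenPoisson:
    def test_no_events_flat_zero(self):
        curve = nelson_aalen_poisson(zero_table())
        assert all(q == 0.0 for q in curve.q)
        assert all(lo == 0.0 for lo in curve.ci_lo)
        # upper bounds positive once person-time accrues
        assert curve.ci_hi[0] == 0.0
        assert all(hi > 0.0 for hi in curve.ci_hi[1:])

    def test_single_band_closed_form(self):
        table = single_band_table(0, 4, 1000.0, fill_t=0.0)
        curve = nelson_aalen_poisson(table)
        h = 5 * 4 / 1000.0
        assert -math.log(1 - curve.at(30)[0]) == pytest.approx(h, abs=1e-14)
        assert curve.at(30)[0] == pytest.approx(1 - math.exp(-0.02), abs=1e-14)
        # log-normal interval around H
        z = stats.norm.ppf(0.975)
        se = math.sqrt(25 * 4 / 1000.0**2)
        factor = math.exp(z * se / h)
        assert curve.at(30)[1] == pytest.approx(1 - math.exp(-h / factor), abs=1e-14)
        assert curve.at(30)[2] == pytest.approx(1 - math.exp(-h * factor), abs=1e-14)

    def test_zero_event_upper_bound_is_exact_poisson(self):
        curve = nelson_aalen_poisson(zero_table())
        # 9 bands x 100 person-years elapsed by 70
        lam_hi = -math.log(0.025) / 900.0
        assert curve.at(70)[2] == pytest.approx(1 - math.exp(-lam_hi * 45), rel=1e-10)

    def test_invalid_level_rejected(self, hand_table):
        with pytest.raises(ValueError):
            nelson_aalen_poisson(hand_table, level=1.0)

    def test_lifelines_oracle_equivalence(self):
        """Point estimates match weighted left-truncated Nelson-Aalen fits."""
        from .conftest import lifelines_cumhaz

        rng = np.random.default_rng(2024)
        for _ in range(20):
            table = random_table(rng)
            curve = nelson_aalen_poisson(table)
            oracle = lifelines_cumhaz(table)
            for age, q in zip(curve.ages, curve.q):
                if age == 25:
                    continue
                assert -math.log(1 - q) == pytest.approx(oracle[age], abs=1e-10)


class TestScoreCI:
    def test_zero_events_boundary(self):
        curve = score_ci(zero_table())
        assert curve.at(70)[0] == 0.0
        assert curve.at(70)[1] == 0.0
        assert curve.at(70)[2] > 0.0

    def test_quadratic_solution(self):
        """Endpoints solve (D - lambda T)^2 = z^2 lambda T."""
        z = stats.norm.ppf(0.975)
        lo, hi = score_interval_rate(4, 1000.0, z)
        for lam in (lo, hi):
            assert (4 - lam * 1000.0) ** 2 == pytest.approx(
                z**2 * lam * 1000.0, rel=1e-9
            )
        expected_lo = (4 + z**2 / 2 - z * math.sqrt(4 + z**2 / 4)) / 1000.0
        expected_hi = (4 + z**2 / 2 + z * math.sqrt(4 + z**2 / 4)) / 1000.0
        assert lo == pytest.approx(expected_lo, abs=1e-15)
        assert hi == pytest.approx(expected_hi, abs=1e-15)

    def test_point_matches_hazard_method_single_band(self):
        table = single_band_table(0, 4, 1000.0, fill_t=0.0)
        score = score_ci(table)
        na = nelson_aalen_poisson(table)
        assert score.at(30)[0] == pytest.approx(na.at(30)[0], abs=1e-12)

    def test_first_order_agreement_with_lognormal_at_large_d(self):
        # homogeneous rates, 400 events per band: both intervals shrink to the
        # same normal limit on the hazard scale
        table = PersonTimeTable(
            "MLH1", "male", "All", (400,) * 9, (100000.0,) * 9
        )
        score = score_ci(table)
        na = nelson_aalen_poisson(table)
        for a, b in zip(score.ci_lo[1:], na.ci_lo[1:]):
            assert a == pytest.approx(b, rel=0.02)
        for a, b in zip(score.ci_hi[1:], na.ci_hi[1:]):
            assert a == pytest.approx(b, rel=0.02)


class TestCompareMethods:
    def test_zero_table_identical(self):
        comparison = compare_methods(zero_table())
        assert comparison.max_abs_diff == 0.0
        assert comparison.flagged_ages == ()

    def test_small_rate_gap_is_small_but_nonzero(self):
        table = PersonTimeTable(
            "MLH1", "male", "All", (1,) * 9, (100.0,) * 9  # air = 0.01
        )
        comparison = compare_methods(table)
        assert 0.001 <= comparison.max_abs_diff <= 0.01

    def test_large_rate_gap_is_visible(self):
        # air = 0.2 in one band: 1 - 0.8^5 vs 1 - e^-1
        table = single_band_table(0, 200, 1000.0, fill_t=0.0)
        comparison = compare_methods(table, tolerance=0.01)
        expected = abs((1 - 0.8**5) - (1 - math.exp(-1.0)))
        assert comparison.max_abs_diff == pytest.approx(expected, abs=1e-12)
        assert 30 in comparison.flagged_ages

    def test_vanishing_rates_methods_agree(self):
        rng = np.random.default_rng(5)
        t = 100000.0
        events = tuple(int(d) for d in rng.integers(0, 100, 9))  # air <= 1e-3
        table = PersonTimeTable("MLH1", "male", "All", events, (t,) * 9)
        assert max(air(table)) <= 1e-3
        comparison = compare_methods(table)
        assert comparison.max_abs_diff <= 1e-4


class TestWeightedMean:
    def test_single_curve_identity(self, hand_table):
        curve = nelson_aalen_poisson(hand_table)
        pooled = weighted_mean_curves([curve], [1.0])
        assert pooled.q == curve.q
        assert pooled.ci_approximate

    def test_idempotence_on_identical_curves(self, hand_table):
        curve = nelson_aalen_poisson(hand_table)
        pooled = weighted_mean_curves([curve, curve], [2.0, 5.0])
        assert pooled.q == pytest.approx(curve.q, abs=1e-15)

    def test_weighted_arithmetic(self):
        def flat(q):
            return IncidenceCurve(
                gene="MLH1", sex="male", region="All", method="reference",
                ages=(25, 70), q=(0.0, q), ci_lo=(0.0, q), ci_hi=(0.0, q),
            )

        pooled = weighted_mean_curves([flat(0.2), flat(0.4)], [3.0, 1.0])
        assert pooled.q[1] == pytest.approx(0.25, abs=1e-15)

    def test_mismatched_grids_rejected(self):
        a = IncidenceCurve("MLH1", "male", "All", "reference",
                           (25, 70), (0.0, 0.1), (0.0, 0.1), (0.0, 0.1))
        b = IncidenceCurve("MLH1", "male", "All", "reference",
                           (25, 60), (0.0, 0.1), (0.0, 0.1), (0.0, 0.1))
        with pytest.raises(ValueError, match="identical age grid"):
            weighted_mean_curves([a, b], [1.0, 1.0])

    def test_bad_weights_rejected(self, hand_table):
        curve = nelson_aalen_poisson(hand_table)
        with pytest.raises(ValueError):
            weighted_mean_curves([curve], [-1.0])
        with pytest.raises(ValueError):
            weighted_mean_curves([curve], [0.0])


# -- cross-method invariants --------------------------------------------------

@given(st.integers(0, 2**32 - 1))
@settings(max_examples=50, deadline=None)
def test_curve_invariants_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    table = random_table(rng)
    for method in ("recursion", "nelson_aalen_poisson", "score"):
        curve = estimate_curve(table, method=method)
        assert curve.at(25)[0] == 0.0
        if method != "score":  # pooled score curve is not monotone by design
            assert all(b >= a - 1e-12 for a, b in zip(curve.q, curve.q[1:]))
        for q, lo, hi in zip(curve.q, curve.ci_lo, curve.ci_hi):
            if not math.isnan(lo):
                assert 0.0 <= lo <= q + 1e-12
            if not math.isnan(hi):
                assert q - 1e-12 <= hi <= 1.0


def test_unknown_method_rejected(hand_table):
    with pytest.raises(ValueError, match="unknown method"):
        estimate_curve(hand_table, method="kaplan_meier")
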