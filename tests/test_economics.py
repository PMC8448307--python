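"""Cost and value arithmetic: exact-cents identities and table builders."""

from decimal import Decimal
from fractions import Fraction

import pytest
from hypothesis import given, settings, strategies as st

from aphasia_econ.cohort import AphasiaType, Dimension, derive_improvement
from aphasia_econ.economics import (
    UndefinedValueError,
    build_cost_summary,
    build_cost_value_table,
    expected_benefit,
    expected_cost,
    footer_ranges,
    net_benefit,
    net_cost,
    round_cents,
    value_per_qcl,
)
from aphasia_econ.fixtures import table5_fixture

from test_cohort import make_record


class TestNetCost:
    @pytest.mark.parametrize("sessions,total", [(12, 1296), (5, 540), (0, 0), (6, 648)])
    def test_session_costs_at_default_rate(self, sessions, total):
        assert net_cost(sessions) == total

    def test_negative_sessions_rejected(self):
        with pytest.raises(ValueError):
            net_cost(-1)

    def test_non_positive_rate_rejected(self):
        with pytest.raises(ValueError):
            net_cost(3, rate=0)


class TestExpectedCost:
    def test_certainty_and_half(self):
        assert expected_cost(1, 1296) == 1296
        assert expected_cost("0.5", 1000) == 500
        assert expected_cost(0, 1296) == 0

    def test_unrounded_probability_reproduces_cell(self):
        # 0.716 x $1,188 — the printed 72% is this probability rounded
        assert round_cents(expected_cost(0.716, 1188)) == Decimal("850.61")

    def test_probability_bounds(self):
        with pytest.raises(ValueError):
            expected_cost(1.2, 100)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        p=st.fractions(0, 1), q=st.fractions(0, 1),
        cost=st.integers(0, 2000), extra=st.integers(0, 2000),
    )
    def test_monotone_in_probability_and_cost(self, p, q, cost, extra):
        lo_p, hi_p = min(p, q), max(p, q)
        assert expected_cost(lo_p, cost) <= expected_cost(hi_p, cost)
        assert expected_cost(p, cost) <= expected_cost(p, cost + extra)


class TestValuePerQCL:
    @pytest.mark.parametrize(
        "e_cost,dqcl,expected",
        [("850.61", "1.12", "759.47"),
         ("1127.06", "1.12", "1006.30"),
         ("1020.60", "0.85", "1200.71")],
    )
    def test_published_ratio_identities_to_the_cent(self, e_cost, dqcl, expected):
        assert round_cents(value_per_qcl(Decimal(e_cost), Decimal(dqcl))) == Decimal(expected)

    def test_unit_qcl_is_identity(self):
        assert value_per_qcl(850, 1) == 850

    def test_product_identity_exact_before_rounding(self):
        e, d = Fraction(85061, 100), Fraction(112, 100)
        assert value_per_qcl(e, d) * d == e

    @pytest.mark.parametrize("dqcl", [0, -0.5])
    def test_non_positive_change_undefined(self, dqcl):
        with pytest.raises(UndefinedValueError):
            value_per_qcl(100, dqcl)


class TestBenefit:
    def test_net_benefit_sum_and_symmetry(self):
        assert net_benefit(1, "0.85") == Fraction(185, 100)
        assert net_benefit(0, 0) == 0
        assert net_benefit("0.3", 2) == net_benefit(2, "0.3")

    def test_expected_benefit_limits_and_midpoint(self):
        assert expected_benefit(1, 1, "0.85", 4, 3) == Fraction(185, 100)
        assert expected_benefit(0, 1, "0.85", 4, 3) == 7
        assert expected_benefit("0.5", 1, 1, 4, 3) == Fraction(9, 2)


class TestCostSummary:
    def test_totals_match_brute_force(self, study_cohort):
        for dimension in Dimension:
            outcomes = derive_improvement(study_cohort, dimension)
            summary = build_cost_summary(study_cohort, outcomes)
            improved = {o.patient_id for o in outcomes if o.improved}
            brute = sum(
                108 * r.sessions_attended for r in study_cohort
                if r.patient_id in improved
            )
            assert summary.total_cost == brute
            assert summary.average_cost * summary.improver_count == summary.total_cost

    def test_single_improver(self):
        records = [make_record(sessions_attended=10)]
        outcomes = derive_improvement(records, Dimension.VERBAL)
        summary = build_cost_summary(records, outcomes)
        assert summary.total_cost == summary.average_cost == 1080

    def test_zero_improvers_average_absent(self):
        records = [make_record(noms_verbal_final=4)]
        outcomes = derive_improvement(records, Dimension.VERBAL)
        summary = build_cost_summary(records, outcomes)
        assert summary.improver_count == 0
        assert summary.average_cost is None
        assert summary.total_cost == 0


class TestCostValueTable:
    def test_identical_patients_zero_width_ranges(self):
        records = [make_record(patient_id=f"p-{i}") for i in range(3)]
        probs = {r.patient_id: 0.5 for r in records}
        rows = build_cost_value_table(records, probs, probs)
        ranges = footer_ranges(rows, mode="pooled")[AphasiaType.ANOMIC]
        assert ranges["e_cost"][0] == ranges["e_cost"][1]
        assert ranges["value"][0] == ranges["value"][1]

    def test_non_positive_qcl_change_row_retained_value_undefined(self):
        records = [make_record(qcl_initial=3.0, qcl_final=3.0)]
        rows = build_cost_value_table(records, {"p-01": 0.4}, {"p-01": 0.6})
        assert len(rows) == 1
        assert rows[0].value_verbal is None and rows[0].value_comp is None
        assert rows[0].e_cost_comp == Fraction(6, 10) * 1080

    def test_probabilities_propagate_exactly(self):
        records = [make_record(sessions_attended=11, qcl_initial=2.0, qcl_final=3.12)]
        rows = build_cost_value_table(records, {"p-01": "0.72"}, {"p-01": "0.95"})
        row = rows[0]
        assert row.total_treatment_cost == 1188
        assert round_cents(row.e_cost_verbal) == Decimal("855.36")
        assert row.value_verbal * row.qcl_improvement == row.e_cost_verbal


class TestPublishedTableRanges:
    """Per-type footer ranges over the published 16-row cost/value table."""

    def test_row_structure(self):
        rows = table5_fixture()
        assert len(rows) == 16
        counts = {t: sum(r.aphasia_type is t for r in rows) for t in AphasiaType}
        assert counts == {
            AphasiaType.ANOMIC: 9, AphasiaType.BROCA: 5,
            AphasiaType.CONDUCTION: 1, AphasiaType.GLOBAL: 1,
        }
        first, last = rows[0], rows[-1]
        assert first.total_treatment_cost == 1188
        assert first.p_verbal == Fraction(72, 100)
        assert first.p_comp == Fraction(95, 100)
        assert first.qcl_improvement == Fraction(112, 100)
        assert last.total_treatment_cost == 1296
        assert last.qcl_improvement == Fraction(85, 100)

    def test_pooled_ranges_for_self_consistent_types(self):
        ranges = footer_ranges(table5_fixture(), mode="pooled")
        anomic = ranges[AphasiaType.ANOMIC]
        assert tuple(map(round_cents, anomic["e_cost"])) == (
            Decimal("207.17"), Decimal("1160.96"))
        conduction = ranges[AphasiaType.CONDUCTION]
        assert tuple(map(round_cents, conduction["e_cost"])) == (
            Decimal("786.41"), Decimal("1050.67"))
        assert tuple(map(round_cents, conduction["value"])) == (
            Decimal("1404.31"), Decimal("1876.19"))

    def test_by_dimension_ranges_for_singleton_type(self):
        ranges = footer_ranges(table5_fixture(), mode="by_dimension")
        glob = ranges[AphasiaType.GLOBAL]
        assert round_cents(glob["e_cost_verbal"][0]) == Decimal("1100.56")
        assert round_cents(glob["e_cost_comp"][0]) == Decimal("1020.60")
        assert round_cents(glob["value_comp"][0]) == Decimal("1200.71")
        assert round_cents(glob["value_verbal"][0]) == Decimal("1294.78")

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            footer_ranges(table5_fixture(), mode="median")
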