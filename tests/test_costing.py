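"""Unit-cost valuation, perspectives, winsorization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trialcea import ParticipantRecord
from trialcea.costing import (
    UnitCostEntry,
    UnitCostTable,
    cost_participant,
    default_unit_cost_table,
    indirect_cost,
    inflate,
    productivity_days_lost,
    read_unit_cost_table,
    winsorize_totals,
    write_unit_cost_table,
)

CPI = {2018: 103.8, 2019: 105.3, 2020: 105.8}


class TestInflate:
    def test_identity_same_year(self):
        assert inflate(123.4, 2020, 2020, CPI) == 123.4

    def test_proportionality(self):
        assert inflate(100.0, 2019, 2020, {2019: 100.0, 2020: 105.0}) == pytest.approx(105.0)

    def test_missing_year_raises(self):
        with pytest.raises(KeyError, match="2015"):
            inflate(10.0, 2015, 2020, CPI)

    @settings(deadline=None, derandomize=True)
    @given(x=st.floats(0.0, 1e6), a=st.sampled_from(list(CPI)), b=st.sampled_from(list(CPI)))
    def test_roundtrip(self, x, a, b):
        assert inflate(inflate(x, a, b, CPI), b, a, CPI) == pytest.approx(x, rel=1e-12, abs=1e-9)


class TestIndirectCosts:
    def test_full_performance_loses_nothing(self):
        for d in (0.0, 10.0, 80.0):
            assert productivity_days_lost(10.0, d) == 0.0

    def test_zero_performance_loses_every_day(self):
        assert productivity_days_lost(0.0, 20.0) == 20.0

    def test_half_performance(self):
        assert productivity_days_lost(5.0, 20.0) == 10.0

    def test_bounds(self):
        with pytest.raises(ValueError):
            productivity_days_lost(11.0, 5.0)
        with pytest.raises(ValueError):
            productivity_days_lost(5.0, -1.0)

    def test_one_absent_day_at_25_euro_8h(self):
        uc = UnitCostTable(entries={}, cpi=CPI, gross_wage_per_hour=25.0, hours_per_workday=8.0)
        assert indirect_cost(1.0, 0.0, uc) == pytest.approx(200.0)
        assert indirect_cost(0.0, 0.0, uc) == 0.0

    def test_additivity_in_day_arguments(self):
        uc = UnitCostTable(entries={}, cpi=CPI)
        total = indirect_cost(3.0, 2.0, uc)
        assert total == pytest.approx(indirect_cost(3.0, 0.0, uc) + indirect_cost(0.0, 2.0, uc))


def _fixture_table(informal_societal_only=True):
    return UnitCostTable(
        entries={
            "gp_visit": UnitCostEntry("contact", 30.0, 2020),
            "informal_care": UnitCostEntry(
                "hour", 0.0, 2020, care_wage=True, societal_only=informal_societal_only
            ),
            "intervention": UnitCostEntry("euro", 1.0, 2020),
        },
        cpi=CPI,
        care_wage_per_hour=25.0,
        gross_wage_per_hour=25.0,
    )


def _rec(**kw):
    base = dict(participant_id="P1", arm="CG", gender_identity="trans_masculine")
    base.update(kw)
    return ParticipantRecord(**base)


class TestCostParticipant:
    def test_all_zero_quantities_cg_pp(self):
        rec = _rec(resource_use_t1={"gp_visit": 0.0, "informal_care": 0.0})
        bd = cost_participant(rec, "T1", _fixture_table(), perspective="PP")
        assert bd.total == 0.0

    def test_intervention_only_ig_t1(self):
        uc = _fixture_table()
        rec = _rec(arm="IG", resource_use_t1={"intervention": 734.0})
        assert cost_participant(rec, "T1", uc).total == pytest.approx(734.0)
        # not at baseline, not for the CG, overridable as a scalar
        assert cost_participant(rec, "T0", uc).total == 0.0
        assert cost_participant(_rec(arm="CG"), "T1", uc).total == 0.0
        assert cost_participant(rec, "T1", uc, intervention_cost=1100.0).total == 1100.0

    def test_hand_computed_fixture_with_societal_only_care(self):
        # 2 GP visits at 30 euros; 4 h informal care at the 25 euro care wage
        # flagged societal-only: payer sees 60, society 160
        rec = _rec(resource_use_t1={"gp_visit": 2.0, "informal_care": 4.0})
        uc = _fixture_table(informal_societal_only=True)
        assert cost_participant(rec, "T1", uc, perspective="PP").total == pytest.approx(60.0)
        assert cost_participant(rec, "T1", uc, perspective="SP").total == pytest.approx(160.0)
        # with work data the societal total additionally carries indirect costs
        rec2 = _rec(
            resource_use_t1={"gp_visit": 2.0, "informal_care": 4.0},
            work_days_absent_t1=1.0,
            work_days_present_t1=0.0,
            work_performance_t1=10.0,
        )
        sp = cost_participant(rec2, "T1", uc, perspective="SP")
        assert sp.indirect_cost == pytest.approx(200.0)
        assert sp.total == pytest.approx(360.0)
        # the payer perspective drops exactly the indirect component
        pp = cost_participant(rec2, "T1", uc, perspective="PP")
        assert pp.total == pytest.approx(60.0)

    def test_unknown_category_is_named(self):
        rec = _rec(resource_use_t1={"acupuncture": 1.0})
        with pytest.raises(KeyError, match="acupuncture"):
            cost_participant(rec, "T1", _fixture_table())

    def test_unreported_quantity_contributes_nothing(self):
        rec = _rec(resource_use_t1={"gp_visit": None, "informal_care": 2.0})
        bd = cost_participant(rec, "T1", _fixture_table(), perspective="SP")
        assert bd.total == pytest.approx(50.0)
        assert "gp_visit" not in bd.category_costs

    def test_category_subset_reproduces_subset_sum(self):
        rec = _rec(resource_use_t1={"gp_visit": 2.0, "informal_care": 4.0})
        uc = _fixture_table(informal_societal_only=False)
        full = cost_participant(rec, "T1", uc, perspective="SP")
        only_gp = cost_participant(
            rec, "T1", uc, perspective="SP", categories=frozenset({"gp_visit"})
        )
        assert only_gp.total == pytest.approx(full.category_costs["gp_visit"])
        assert full.total - only_gp.total == pytest.approx(full.category_costs["informal_care"])

    def test_perspective_monotone_on_generated_cohort(self, cohort, unit_costs):
        for rec in cohort.records[::7]:
            for window in ("T0", "T1"):
                sp = cost_participant(rec, window, unit_costs, perspective="SP").total
                pp = cost_participant(rec, window, unit_costs, perspective="PP").total
                assert sp >= pp - 1e-9

    def test_total_identity(self):
        rec = _rec(
            arm="IG",
            resource_use_t1={"gp_visit": 3.0, "informal_care": 2.0, "intervention": 700.0},
            work_days_absent_t1=2.0,
        )
        bd = cost_participant(rec, "T1", _fixture_table(), perspective="SP")
        assert bd.total == pytest.approx(
            sum(bd.category_costs.values()) + bd.intervention_cost + bd.indirect_cost, abs=1e-6
        )

    def test_unit_cost_inflation_applied(self):
        uc = UnitCostTable(
            entries={"gp_visit": UnitCostEntry("contact", 30.0, 2019)}, cpi=CPI, target_year=2020
        )
        rec = _rec(resource_use_t1={"gp_visit": 1.0})
        expected = 30.0 * CPI[2020] / CPI[2019]
        assert cost_participant(rec, "T1", uc).total == pytest.approx(expected)


class TestWinsorize:
    def test_all_equal_unchanged(self):
        vals = np.full(10, 7.0)
        assert np.array_equal(winsorize_totals(vals, 95.0), vals)

    def test_against_sorted_array_oracle(self):
        vals = np.arange(1.0, 101.0)
        out = winsorize_totals(vals, 95.0)
        # lower order-statistic cap on 1..100: element at floor(0.95*(n-1))
        cap = np.sort(vals)[int(np.floor(0.95 * 99))]
        assert cap == 95.0
        assert np.all(out <= cap)
        assert np.array_equal(out[vals <= cap], vals[vals <= cap])  # below: untouched
        assert np.all(out[vals > cap] == cap)
        assert out.mean() <= vals.mean()

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        vals = rng.lognormal(5, 2, size=200)
        once = winsorize_totals(vals, 95.0)
        assert np.allclose(winsorize_totals(once, 95.0), once)

    def test_empty_and_bad_percentile(self):
        with pytest.raises(ValueError):
            winsorize_totals([], 95.0)
        with pytest.raises(ValueError):
            winsorize_totals([1.0], 100.0)


def test_unit_cost_table_roundtrip(tmp_path, unit_costs):
    path = tmp_path / "uc.csv"
    write_unit_cost_table(unit_costs, path)
    back = read_unit_cost_table(path, cpi=unit_costs.cpi, target_year=unit_costs.target_year)
    assert set(back.entries) == set(unit_costs.entries)
    for cat in unit_costs.entries:
        assert back.entries[cat] == unit_costs.entries[cat]


def test_default_table_has_care_and_intervention_conventions(unit_costs):
    assert unit_costs.entries["informal_care"].care_wage
    assert unit_costs.entries["intervention"].euro_per_unit == 1.0
    assert "medical_counseling" in unit_costs.mental_health_categories
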