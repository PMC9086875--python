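"""Costing: unit-cost table, micro-costing formulas, patient-related costs,
per-patient breakdowns and arm summaries."""

import dataclasses

import numpy as np
import pytest

from boxcea.costing import (CpiIndex, MissingPriceError,
                            PatientCostParams, PriceTable,
                            allocate_shared_cost, arm_cost_summary,
                            eur_to_usd, inflate_to_2020,
                            patient_cost_breakdown, patient_related_box_cost,
                            patient_related_visit_cost, round_euros,
                            unit_cost_evisit, unit_cost_in_office)

#: Published unit costs (2020 euros) the shipped table must reproduce.
PUBLISHED_PRICES = {
    "the_box": 318, "stress_echo": 542, "tte": 117, "holter": 152,
    "e_visit": 44, "in_office": 96, "technical_support": 1758,
    "np_contact": 4, "catheterization": 2037, "single_vessel_pci": 5999,
    "multivessel_pci": 6428, "hospitalization": 684,
    "inhospital_support": 15367,
}


class TestPriceTable:
    def test_default_table_matches_published_values(self, prices):
        for item, value in PUBLISHED_PRICES.items():
            assert prices[item].unit_cost == value
            assert prices[item].price_year == 2020

    def test_missing_item_raises_named_error(self, prices):
        with pytest.raises(MissingPriceError, match="levitation_therapy"):
            prices["levitation_therapy"]

    def test_csv_round_trip(self, prices, tmp_path):
        path = tmp_path / "prices.csv"
        prices.to_csv(path)
        assert PriceTable.from_csv(path).entries == prices.entries


class TestCurrencyAndInflation:
    def test_reference_year_identity(self):
        assert inflate_to_2020(100.0, 2020) == pytest.approx(100.0)

    def test_index_ratio(self):
        cpi = CpiIndex(values={2016: 0.95, 2020: 1.0})
        assert inflate_to_2020(100.0, 2016, cpi) == pytest.approx(105.26,
                                                                  abs=0.01)

    def test_zero_amount(self):
        assert inflate_to_2020(0.0, 2016) == 0.0

    def test_unknown_year_raises(self):
        with pytest.raises(LookupError):
            inflate_to_2020(10.0, 1950)

    def test_published_usd_amounts(self):
        # Headline totals: 2417 EUR -> 2657 USD, 471 EUR -> 518 USD.
        assert eur_to_usd(2417) == pytest.approx(2657.3, abs=0.1)
        assert round(eur_to_usd(471)) == 518
        assert eur_to_usd(0) == 0

    def test_bad_rate(self):
        with pytest.raises(ValueError):
            eur_to_usd(1.0, rate=0.0)


class TestMicroCosting:
    def test_evisit_unit_cost(self):
        assert unit_cost_evisit(55_000, 5500, 1.22) == pytest.approx(12.20)
        assert unit_cost_evisit(0) == 0.0
        # Inverting the published 44 EUR e-visit price gives the implied
        # subscription, which must map back to exactly 44.
        subscription = 44 / 1.22 * 5500
        assert unit_cost_evisit(subscription) == pytest.approx(44.0)

    def test_evisit_bad_capacity(self):
        with pytest.raises(ValueError):
            unit_cost_evisit(1000, capacity_per_year=0)

    def test_in_office_overhead(self):
        # Any component sum of 66.67 reproduces the published 96 EUR visit.
        assert unit_cost_in_office([50, 16.67]) == pytest.approx(96.0, abs=0.01)
        assert unit_cost_in_office([]) == 0.0
        assert unit_cost_in_office([100], overhead=1.0) == 100.0

    def test_shared_support_allocation(self):
        # In-hospital (15367) plus vendor (1758) support over 88 patients
        # gives the published 195 EUR/patient support row.
        assert round_euros(allocate_shared_cost(15367 + 1758, 88)) == 195
        assert allocate_shared_cost(0, 88) == 0.0
        assert allocate_shared_cost(100, 1) == 100.0
        with pytest.raises(ValueError):
            allocate_shared_cost(100, 0)


class TestPatientRelatedCosts:
    def test_in_office_visit_cost(self, params):
        # 2 x 7 km x 0.19 + 3.20 parking + 4.5 h x blended wage = 140.56
        assert patient_related_visit_cost(params, "in_office") == \
            pytest.approx(140.563, abs=1e-3)

    def test_e_visit_cost(self, params):
        assert patient_related_visit_cost(params, "e_visit") == \
            pytest.approx(14.967, abs=1e-3)

    def test_blended_wage(self, params):
        assert params.blended_wage == pytest.approx(0.7 * 37.05 + 0.3 * 13.33)

    def test_one_way_travel(self, params):
        one_way = dataclasses.replace(params, round_trip=False)
        delta = (patient_related_visit_cost(params, "in_office")
                 - patient_related_visit_cost(one_way, "in_office"))
        assert delta == pytest.approx(7 * 0.19)

    def test_all_zero_params(self):
        zero = PatientCostParams(travel_km_one_way=0, km_rate=0, parking=0,
                                 hours_in_office=0, hours_e_visit=0,
                                 wage_productive=0, wage_nonproductive=0,
                                 box_minutes_per_week=0)
        assert patient_related_visit_cost(zero, "in_office") == 0.0
        assert patient_related_visit_cost(zero, "e_visit") == 0.0
        assert patient_related_box_cost(zero) == 0.0

    def test_box_time_cost(self, params):
        # 10 min/week over a 50-week clinic year at the non-productive wage
        assert patient_related_box_cost(params) == pytest.approx(111.083,
                                                                 abs=1e-3)
        hour = dataclasses.replace(params, box_minutes_per_week=60,
                                   weeks_per_year=52)
        assert patient_related_box_cost(hour) == pytest.approx(693.16,
                                                               abs=0.01)

    def test_unknown_visit_type(self, params):
        with pytest.raises(ValueError):
            patient_related_visit_cost(params, "house_call")

    def test_invalid_productive_fraction(self):
        with pytest.raises(ValueError):
            PatientCostParams(productive_fraction=1.5)


class TestBreakdown:
    def test_department_total_is_item_sum(self, trial, prices):
        for record in trial[:25]:
            b = patient_cost_breakdown(record, prices)
            assert b.total_department == pytest.approx(sum(b.items.values()))
            assert b.total_combined == b.total_department

    def test_combined_adds_patient_related(self, trial, prices, params):
        for record in trial[:25]:
            b = patient_cost_breakdown(record, prices, params,
                                       perspective="combined")
            assert b.total_combined == pytest.approx(
                b.total_department + b.total_patient_related)
            assert b.total_combined >= b.total_department

    def test_combined_control_visit_arithmetic(self, trial, prices, params):
        record = next(r for r in trial if r.arm == "control")
        record = dataclasses.replace(
            record, item_counts={**record.item_counts, "in_office": 4,
                                 "e_visit": 0})
        b = patient_cost_breakdown(record, prices, params,
                                   perspective="combined")
        assert b.total_patient_related == pytest.approx(4 * 140.563, abs=0.01)

    def test_intervention_combined_includes_box_time(self, trial, prices,
                                                     params):
        record = next(r for r in trial if r.arm == "intervention")
        zeroed = dataclasses.replace(
            record, item_counts={k: 0 for k in record.item_counts})
        b = patient_cost_breakdown(zeroed, prices, params,
                                   perspective="combined")
        assert b.total_patient_related == pytest.approx(
            patient_related_box_cost(params))

    def test_unpriced_item_raises(self, trial, prices):
        record = dataclasses.replace(
            trial[0], item_costs={**trial[0].item_costs, "teleportation": 5.0})
        with pytest.raises(MissingPriceError, match="teleportation"):
            patient_cost_breakdown(record, prices)


class TestArmSummary:
    def test_single_patient(self, trial):
        summary = arm_cost_summary(trial[:1], trial[0].arm)
        total = summary[summary["item"] == "total"].iloc[0]
        assert total["mean"] == pytest.approx(sum(trial[0].item_costs.values()))
        assert total["sd"] == 0.0

    def test_two_identical_patients_sd_zero(self, trial):
        summary = arm_cost_summary([trial[0], trial[0]], trial[0].arm)
        assert (summary["sd"] == 0.0).all()

    def test_item_means_sum_to_total(self, trial):
        summary = arm_cost_summary(trial, "control")
        items = summary[summary["item"] != "total"]["mean"].sum()
        total = summary.loc[summary["item"] == "total", "mean"].iloc[0]
        assert items == pytest.approx(total)

    def test_empty_arm_raises(self, trial):
        with pytest.raises(ValueError):
            arm_cost_summary([r for r in trial if r.arm == "control"],
                             "intervention")


def test_round_euros_is_bankers():
    assert round_euros(194.5) == 194
    assert round_euros(195.5) == 196
    assert (round_euros(np.array([0.5, 1.5])) == np.array([0, 2])).all()
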