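import numpy as np
import pandas as pd
import pytest

from intecost.errors import ParameterError
from intecost.money import MoneyAmount, TimeValuationPolicy, default_economy
from intecost.patient import (
    PATIENT_COMPONENTS,
    PatientCostOptions,
    compute_patient_costs,
    compute_societal_costs,
    patient_cost_per_visit,
    provider_share_of_societal,
    societal_cost_per_visit,
)


HV_UGX = MoneyAmount(500.0, "UGX", 2021)  # 500 UGX per hour


def q_record(**overrides):
    base = {
        "participant_id": "p1",
        "currency": "UGX",
        "price_year": 2021,
        "medication_expense": 0.0,
        "other_medical_expense": 0.0,
        "travel_expense": 0.0,
        "travel_time_h": 0.0,
        "facility_time_h": 0.0,
        "childcare_time_h": 0.0,
    }
    base.update(overrides)
    return base


class TestPatientCostPerVisit:
    def test_integrated_example(self, economy):
        # 1 h + 2 h at 500 UGX/h plus 2621.2 UGX travel -> (1500+2621.2)/1310.6
        q = q_record(travel_time_h=1.0, facility_time_h=2.0, travel_expense=2621.2)
        out = patient_cost_per_visit(q, HV_UGX, "HIV", "integrated", economy)
        assert out["total"] == pytest.approx((1500.0 + 2621.2) / 1310.6)
        assert out["total"] == pytest.approx(3.14, abs=0.005)

    def test_standard_multimorbid_doubles_time(self, economy):
        q = q_record(travel_time_h=1.0, facility_time_h=2.0)
        out = patient_cost_per_visit(q, HV_UGX, "HIV+DM", "standard", economy)
        base = patient_cost_per_visit(q, HV_UGX, "HIV+DM", "integrated", economy)
        assert out["travel_time_cost"] == pytest.approx(2 * base["travel_time_cost"])
        assert out["facility_time_cost"] == pytest.approx(2 * base["facility_time_cost"])

    def test_single_condition_standard_not_doubled(self, economy):
        q = q_record(travel_time_h=1.0)
        out = patient_cost_per_visit(q, HV_UGX, "HIV", "standard", economy)
        assert out["travel_time_cost"] == pytest.approx(500.0 / 1310.6)

    def test_all_zero_questionnaire(self, economy):
        out = patient_cost_per_visit(q_record(), HV_UGX, "HTN+DM", "standard", economy)
        assert out["total"] == 0.0

    def test_doubling_touches_only_time_fields(self, economy):
        q = q_record(medication_expense=1000.0, other_medical_expense=500.0,
                     travel_time_h=1.0, facility_time_h=1.0, childcare_time_h=1.0)
        opts = PatientCostOptions(double_travel_expense=False)
        std = patient_cost_per_visit(q, HV_UGX, "HIV+HTN", "standard", economy, opts)
        integ = patient_cost_per_visit(q, HV_UGX, "HIV+HTN", "integrated", economy, opts)
        for comp in ("medication_expense", "other_medical", "travel_expense"):
            assert std[comp] == integ[comp]
        for comp in ("travel_time_cost", "facility_time_cost", "caregiver_time_cost"):
            assert std[comp] == pytest.approx(2 * integ[comp])

    def test_travel_expense_doubling_flag(self, economy):
        q = q_record(travel_expense=1310.6)
        on = patient_cost_per_visit(q, HV_UGX, "HTN+DM", "standard", economy)
        off = patient_cost_per_visit(
            q, HV_UGX, "HTN+DM", "standard", economy, PatientCostOptions(double_travel_expense=False)
        )
        assert on["travel_expense"] == pytest.approx(2.0)
        assert off["travel_expense"] == pytest.approx(1.0)

    def test_n_conditions_multiplier(self, economy):
        q = q_record(facility_time_h=1.0)
        opts = PatientCostOptions(time_multiplier="n_conditions")
        out = patient_cost_per_visit(q, HV_UGX, "HIV+HTN+DM", "standard", economy, opts)
        assert out["facility_time_cost"] == pytest.approx(3 * 500.0 / 1310.6)

    def test_missing_hourly_value(self, economy):
        with pytest.raises(ParameterError):
            patient_cost_per_visit(q_record(), None, "HIV", "integrated", economy)

    def test_monotone_in_hours(self, economy):
        rng = np.random.default_rng(5)
        for _ in range(25):
            hours = rng.uniform(0, 5, 3)
            q1 = q_record(travel_time_h=hours[0], facility_time_h=hours[1], childcare_time_h=hours[2])
            q2 = q_record(travel_time_h=hours[0] + 1, facility_time_h=hours[1], childcare_time_h=hours[2])
            arm = rng.choice(["integrated", "standard"])
            t1 = patient_cost_per_visit(q1, HV_UGX, "HTN+DM", arm, economy)["total"]
            t2 = patient_cost_per_visit(q2, HV_UGX, "HTN+DM", arm, economy)["total"]
            assert t2 >= t1


class TestComputePatientCosts:
    def test_component_additivity(self, small_trial, economy):
        out = compute_patient_costs(small_trial.questionnaires, small_trial.participants, economy)
        assert np.allclose(out["total"], sum(out[c] for c in PATIENT_COMPONENTS))

    def test_expense_equality_assumption(self, small_trial, economy):
        out = compute_patient_costs(small_trial.questionnaires, small_trial.participants, economy)
        integ = out[out["arm"] == "integrated"]
        means = integ.groupby(["country", "profile", "facility_level"])["medication_expense"].mean()
        std = out[out["arm"] == "standard"]
        checked = 0
        for row in std.itertuples(index=False):
            key = (row.country, row.profile, row.facility_level)
            if key in means.index:
                checked += 1
                assert row.medication_expense == pytest.approx(means[key])
        assert checked > 0

    def test_equalisation_can_be_disabled(self, small_trial, economy):
        opts = PatientCostOptions(equalise_expenses=False)
        out = compute_patient_costs(
            small_trial.questionnaires, small_trial.participants, economy, options=opts
        )
        std = out[out["arm"] == "standard"]
        # self-reported values retain per-record variation
        assert std.groupby(["country", "profile"])["medication_expense"].nunique().max() > 1

    def test_22_day_policy_scales_time_costs_exactly(self, small_trial, economy):
        base = compute_patient_costs(
            small_trial.questionnaires, small_trial.participants, economy,
            TimeValuationPolicy(days_per_month=30),
        )
        alt = compute_patient_costs(
            small_trial.questionnaires, small_trial.participants, economy,
            TimeValuationPolicy(days_per_month=22),
        )
        for comp in ("travel_time_cost", "facility_time_cost", "caregiver_time_cost"):
            assert np.allclose(alt[comp], base[comp] * 30 / 22)
        assert np.allclose(alt["medication_expense"], base["medication_expense"])

    def test_zero_wage_reduces_to_out_of_pocket(self, small_trial):
        economy0 = default_economy(consumption_ugx=0.0, consumption_tzs=0.0)
        out = compute_patient_costs(small_trial.questionnaires, small_trial.participants, economy0)
        assert (out[["travel_time_cost", "facility_time_cost", "caregiver_time_cost"]] == 0).all().all()
        expected = out["medication_expense"] + out["other_medical"] + out["travel_expense"]
        assert np.allclose(out["total"], expected)


class TestSocietal:
    def test_record_level_sum(self):
        assert societal_cost_per_visit(150.0, 10.0) == 160.0
        assert societal_cost_per_visit(150.0, 0.0) == 150.0

    def test_additivity_in_group_means(self, small_trial, provider_costs, economy):
        patient = compute_patient_costs(small_trial.questionnaires, small_trial.participants, economy)
        societal = compute_societal_costs(provider_costs, patient)
        assert np.allclose(
            societal["societal_total"], societal["provider_total"] + societal["patient_total"]
        )
        by_group = societal.groupby(["country", "arm", "profile"]).mean(numeric_only=True)
        assert np.allclose(
            by_group["societal_total"], by_group["provider_total"] + by_group["patient_total"]
        )


class TestProviderShare:
    def test_ninety_ten_split(self):
        df = pd.DataFrame(
            {"country": ["Uganda"] * 4, "provider_total": [90.0] * 4,
             "patient_total": [10.0] * 4, "societal_total": [100.0] * 4}
        )
        out = provider_share_of_societal(df)
        assert out.loc[0, "mean"] == pytest.approx(90.0)

    def test_zero_provider(self):
        df = pd.DataFrame(
            {"country": ["Uganda"], "provider_total": [0.0],
             "patient_total": [10.0], "societal_total": [10.0]}
        )
        assert provider_share_of_societal(df).loc[0, "mean"] == 0.0

    def test_matches_per_record_ratio_oracle(self, small_trial, provider_costs, economy):
        patient = compute_patient_costs(small_trial.questionnaires, small_trial.participants, economy)
        societal = compute_societal_costs(provider_costs, patient)
        out = provider_share_of_societal(societal).set_index("country")
        for country, grp in societal.groupby("country"):
            ratios = [
                p / s * 100.0
                for p, s in zip(grp["provider_total"], grp["societal_total"])
                if s != 0
            ]
            assert out.loc[country, "mean"] == pytest.approx(np.mean(ratios))
            assert out.loc[country, "sd"] == pytest.approx(np.std(ratios, ddof=1))

    def test_zero_societal_excluded(self):
        df = pd.DataFrame(
            {"country": ["Uganda", "Uganda", "Uganda"], "provider_total": [90.0, 0.0, 80.0],
             "patient_total": [10.0, 0.0, 20.0], "societal_total": [100.0, 0.0, 100.0]}
        )
        out = provider_share_of_societal(df)
        assert out.loc[0, "n"] == 2
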