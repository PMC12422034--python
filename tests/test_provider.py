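import numpy as np
import pandas as pd
import pytest

from intecost.conditions import profile_from_label
from intecost.errors import AllocationError, DataError
from intecost.money import MoneyAmount, default_economy, annuitize
from intecost.provider import (
    PROVIDER_COMPONENTS,
    AllocatedFacilityRates,
    ProviderCostingOptions,
    allocate_top_down,
    compute_provider_costs,
    ingredients_cost,
    provider_cost_per_visit,
    summarize_costs,
    summarize_provider_costs,
)
from intecost.records import CapitalItem, FacilityCostLedger


def make_ledger(
    personnel=0.0,
    overhead=0.0,
    capital_items=(),
    stream_visits=None,
    weights=None,
    currency="INTD",
    arm="integrated",
):
    return FacilityCostLedger(
        facility_id="F1",
        country="Uganda",
        arm=arm,
        facility_level="primary",
        monthly_personnel_cost=MoneyAmount(personnel, currency, 2021),
        monthly_overhead_cost=MoneyAmount(overhead, currency, 2021),
        capital_items=list(capital_items),
        monthly_patient_counts={},
        monthly_stream_visits=stream_visits or {},
        stream_weights=weights,
    )


class TestAllocateTopDown:
    def test_single_stream_division(self, economy):
        ledger = make_ledger(personnel=10_000.0, stream_visits={"HIV": 100.0})
        rates = allocate_top_down(ledger, economy)
        assert rates.rates["HIV"]["personnel"] == pytest.approx(100.0)

    def test_two_equal_streams_uniform_rates(self, economy):
        # proportional-share oracle: equal volumes split each pool equally
        ledger = make_ledger(
            personnel=9000.0, overhead=3000.0, stream_visits={"HIV": 50.0, "HTN": 50.0}
        )
        rates = allocate_top_down(ledger, economy)
        for cond in ("HIV", "HTN"):
            assert rates.rates[cond]["personnel"] == pytest.approx(90.0)
            assert rates.rates[cond]["overhead"] == pytest.approx(30.0)

    def test_capital_composed_with_annuitization(self, economy):
        item = CapitalItem(MoneyAmount(1000.0, "INTD", 2021), useful_life_years=5.0)
        ledger = make_ledger(capital_items=[item], stream_visits={"HIV": 100.0})
        rates = allocate_top_down(ledger, economy, capital_rate=0.03)
        annual = annuitize(item.price, 0.03, 5.0).value  # ~218.35
        assert rates.rates["HIV"]["capital"] == pytest.approx(annual / 12.0 / 100.0)
        assert rates.rates["HIV"]["capital"] == pytest.approx(0.182, abs=1e-3)

    def test_zero_visits_nonzero_costs_rejected(self, economy):
        ledger = make_ledger(personnel=500.0, stream_visits={})
        with pytest.raises(AllocationError):
            allocate_top_down(ledger, economy)

    def test_local_currency_pools_convert(self, economy):
        ledger = make_ledger(personnel=1310.6 * 100, stream_visits={"HIV": 1.0}, currency="UGX")
        rates = allocate_top_down(ledger, economy)
        assert rates.rates["HIV"]["personnel"] == pytest.approx(100.0)

    def test_explicit_weights_split_pool(self, economy):
        ledger = make_ledger(
            personnel=1000.0,
            stream_visits={"HIV": 10.0, "HTN": 10.0},
            weights={"personnel": {"HIV": 0.8, "HTN": 0.2}},
        )
        rates = allocate_top_down(ledger, economy)
        assert rates.rates["HIV"]["personnel"] == pytest.approx(80.0)
        assert rates.rates["HTN"]["personnel"] == pytest.approx(20.0)

    def test_weighted_stream_without_visits_rejected(self, economy):
        ledger = make_ledger(
            personnel=1000.0,
            stream_visits={"HIV": 10.0},
            weights={"personnel": {"HIV": 0.5, "DM": 0.5}},
        )
        with pytest.raises(AllocationError):
            allocate_top_down(ledger, economy)

    def test_scale_equivariance(self, economy):
        base = make_ledger(personnel=9000.0, overhead=3000.0,
                           stream_visits={"HIV": 50.0, "DM": 25.0})
        scaled = make_ledger(personnel=3 * 9000.0, overhead=3 * 3000.0,
                             stream_visits={"HIV": 50.0, "DM": 25.0})
        r1 = allocate_top_down(base, economy)
        r2 = allocate_top_down(scaled, economy)
        for cond in r1.rates:
            for comp in ("personnel", "overhead"):
                assert r2.rates[cond][comp] == pytest.approx(3 * r1.rates[cond][comp])


def make_rates(arm, **totals):
    """Build rates with the given per-stream facility totals (all personnel)."""
    return AllocatedFacilityRates(
        facility_id="F1",
        country="Uganda",
        arm=arm,
        rates={
            cond: {"personnel": t, "overhead": 0.0, "capital": 0.0}
            for cond, t in totals.items()
        },
    )


def dispensing_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["participant_id", "visit_id", "item_code", "item_class",
                 "units", "unit_price", "currency", "price_year"],
    )


class TestIngredientsCost:
    def test_metformin_plus_hba1c(self, economy):
        records = dispensing_frame(
            [
                ("p1", "v1", "metformin", "medication", 60, 0.05, "INTD", 2021),
                ("p1", "v1", "hba1c", "diagnostic", 1, 4.00, "INTD", 2021),
            ]
        )
        assert ingredients_cost(records, economy) == (pytest.approx(3.0), pytest.approx(4.0))

    def test_empty(self, economy):
        assert ingredients_cost(dispensing_frame([]), economy) == (0.0, 0.0)

    def test_negative_units_identified(self, economy):
        records = dispensing_frame(
            [("p1", "v1", "metformin", "medication", -1, 0.05, "INTD", 2021)]
        )
        with pytest.raises(DataError, match="metformin"):
            ingredients_cost(records, economy)

    def test_matches_brute_force_on_random_fixtures(self, economy):
        rng = np.random.default_rng(77)
        for _ in range(20):
            n = rng.integers(1, 8)
            rows = [
                ("p", "v", f"item{i}", rng.choice(["medication", "diagnostic"]),
                 float(rng.integers(0, 90)), float(rng.uniform(0, 20)), "INTD", 2021)
                for i in range(n)
            ]
            records = dispensing_frame(rows)
            med = sum(r[4] * r[5] for r in rows if r[3] == "medication")
            diag = sum(r[4] * r[5] for r in rows if r[3] == "diagnostic")
            got = ingredients_cost(records, economy)
            assert got[0] == pytest.approx(med) and got[1] == pytest.approx(diag)

    def test_local_currency_converted(self, economy):
        records = dispensing_frame(
            [("p1", "v1", "arv", "medication", 1, 1310.6, "UGX", 2021)]
        )
        assert ingredients_cost(records, economy)[0] == pytest.approx(1.0)


class TestComorbidityRules:
    def test_integrated_hiv_dm_uses_hiv_rate_once(self, economy):
        rates = make_rates("integrated", HIV=150.0, DM=40.0)
        disp = dispensing_frame(
            [
                ("p", "v", "MED-HIV", "medication", 1, 20.0, "INTD", 2021),
                ("p", "v", "MED-DM", "medication", 1, 10.0, "INTD", 2021),
            ]
        )
        out = provider_cost_per_visit(profile_from_label("HIV+DM"), "integrated", rates, disp, economy)
        assert out["total"] == pytest.approx(180.0)

    def test_standard_hiv_dm_sums_vertical_visits(self, economy):
        rates = make_rates("standard", HIV=150.0, DM=40.0)
        disp = dispensing_frame(
            [("p", "v", "MED", "medication", 1, 30.0, "INTD", 2021)]
        )
        out = provider_cost_per_visit(profile_from_label("HIV+DM"), "standard", rates, disp, economy)
        assert out["total"] == pytest.approx(220.0)

    def test_single_condition_identical_across_arms(self, economy):
        disp = dispensing_frame([("p", "v", "MED", "medication", 1, 5.0, "INTD", 2021)])
        profile = profile_from_label("HTN")
        out_i = provider_cost_per_visit(
            profile, "integrated", make_rates("integrated", HTN=80.0), disp, economy
        )
        out_s = provider_cost_per_visit(
            profile, "standard", make_rates("standard", HTN=80.0), disp, economy
        )
        assert out_i == out_s

    def test_integrated_htn_dm_charges_shared_rate_once(self, economy):
        rates = make_rates("integrated", HTN=80.0, DM=60.0)
        out = provider_cost_per_visit(
            profile_from_label("HTN+DM"), "integrated", rates, dispensing_frame([]), economy
        )
        assert out["total"] == pytest.approx(80.0)  # max rule, not 140

    @pytest.mark.parametrize("rule, expected", [("htn", 80.0), ("dm", 60.0), ("mean", 70.0)])
    def test_htn_dm_rule_variants(self, economy, rule, expected):
        rates = make_rates("integrated", HTN=80.0, DM=60.0)
        out = provider_cost_per_visit(
            profile_from_label("HTN+DM"), "integrated", rates, dispensing_frame([]),
            economy, ProviderCostingOptions(htn_dm_rule=rule),
        )
        assert out["total"] == pytest.approx(expected)

    def test_missing_stream_raises(self, economy):
        rates = make_rates("standard", HIV=150.0)
        with pytest.raises(AllocationError):
            provider_cost_per_visit(
                profile_from_label("HIV+DM"), "standard", rates, dispensing_frame([]), economy
            )


class TestPipelineInvariants:
    def test_component_additivity(self, provider_costs):
        total = sum(provider_costs[c] for c in PROVIDER_COMPONENTS)
        assert np.allclose(provider_costs["total"], total)

    def test_all_components_nonnegative(self, provider_costs):
        assert (provider_costs[list(PROVIDER_COMPONENTS)].to_numpy() >= 0).all()

    def test_short_enrolment_excluded(self, small_trial, provider_costs):
        short = small_trial.participants.loc[
            small_trial.participants["months_enrolled"] < 2, "participant_id"
        ]
        assert not provider_costs["participant_id"].isin(set(short)).any()

    def test_standard_multimorbid_dominates_constituents(self, small_trial, provider_costs, economy):
        # facility components of a composite vertical visit >= those of its
        # most expensive constituent single condition at the same facility
        facility = provider_costs[["facility_id", "arm", "profile", "personnel", "overhead", "capital"]]
        facility = facility.assign(fac_total=lambda d: d.personnel + d.overhead + d.capital)
        std = facility[facility["arm"] == "standard"]
        per_fac = std.groupby(["facility_id", "profile"])["fac_total"].first()
        checked = 0
        for (fid, label), total in per_fac.items():
            profile = profile_from_label(label)
            if not profile.is_multimorbid:
                continue
            singles = [
                per_fac.get((fid, p.label)) for p in profile.singles()
                if (fid, p.label) in per_fac
            ]
            if singles:
                checked += 1
                assert total >= max(singles) - 1e-9
        assert checked > 0

    def test_integrated_hiv_multimorbid_equals_hiv_alone(self, provider_costs):
        fac = provider_costs.assign(fac_total=lambda d: d.personnel + d.overhead + d.capital)
        integ = fac[fac["arm"] == "integrated"]
        per_fac = integ.groupby(["facility_id", "profile"])["fac_total"].first()
        checked = 0
        for (fid, label), total in per_fac.items():
            profile = profile_from_label(label)
            if profile.is_multimorbid and "HIV" in profile.conditions and (fid, "HIV") in per_fac:
                checked += 1
                assert total == pytest.approx(per_fac[(fid, "HIV")])
        assert checked > 0

    def test_allocation_recovers_generated_rates(self, small_trial, economy):
        # ledgers were built so that top-down allocation is exact
        for ledger in small_trial.ledgers[:4]:
            rates = allocate_top_down(ledger, economy)
            for cond, comps in rates.rates.items():
                assert all(v >= 0 for v in comps.values())


class TestSummaries:
    def test_degenerate_summary(self, degenerate_trial, degenerate_config, economy):
        costs = compute_provider_costs(
            degenerate_trial.participants, degenerate_trial.visits,
            degenerate_trial.dispensing, degenerate_trial.ledgers, economy,
        )
        summary = summarize_provider_costs(costs)
        gt = degenerate_trial.ground_truth
        for row in summary.itertuples(index=False):
            assert row.sd == pytest.approx(0.0, abs=1e-9)
            assert row.mean == pytest.approx(
                gt.expected_provider_visit_cost(row.country, row.arm, row.profile), rel=1e-9
            )

    def test_single_observation_flagged(self):
        df = pd.DataFrame(
            {"country": ["Uganda"], "arm": ["integrated"], "profile": ["HIV"], "total": [27.18]}
        )
        out = summarize_costs(df)
        assert out.loc[0, "mean"] == 27.18
        assert out.loc[0, "sd"] == 0.0
        assert bool(out.loc[0, "single_obs"])

    def test_matches_independent_groupby(self, provider_costs):
        summary = summarize_provider_costs(provider_costs).set_index(["country", "arm", "profile"])
        # brute-force oracle over python loops
        groups = {}
        for row in provider_costs.itertuples(index=False):
            groups.setdefault((row.country, row.arm, row.profile), []).append(row.total)
        for key, values in groups.items():
            v = np.asarray(values)
            assert summary.loc[key, "n"] == len(v)
            assert summary.loc[key, "mean"] == pytest.approx(v.mean())
            if len(v) > 1:
                assert summary.loc[key, "sd"] == pytest.approx(v.std(ddof=1))

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            summarize_costs(pd.DataFrame(columns=["country", "arm", "profile", "total"]))
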