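"""End-to-end orchestration: simulate -> cost -> compare -> scale-up ->
sensitivity, with every assumption flag echoed into the run log and every
rendered number mirrored in a machine-readable metrics file."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .compare import compare_all
from .errors import ConfigurationError
from .money import EconomyParameters, TimeValuationPolicy, default_economy, economy_from_dict
from .patient import (
    PatientCostOptions,
    compute_patient_costs,
    compute_societal_costs,
    provider_share_of_societal,
)
from .provider import ProviderCostingOptions, compute_provider_costs, summarize_provider_costs, summarize_costs
from .scaleup import ScaleUpScenario, national_totals, scenario_from_dict
from .sensitivity import time_valuation_variants, two_way_grid, uplift_comparisons
from .synthetic import TrialConfig, default_trial_config, generate_trial, trial_config_from_dict

logger = logging.getLogger(__name__)

_KNOWN_FLAGS = {
    "double_travel_expense": True,
    "time_multiplier": "two",
    "equalise_expenses": True,
    "uplift_includes_capital": False,
    "cluster_robust": False,
    "htn_dm_rule": "max",
    "include_questionnaires": True,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    trial: TrialConfig = field(default_factory=default_trial_config)
    economy: EconomyParameters = field(default_factory=default_economy)
    flags: dict[str, Any] = field(default_factory=lambda: dict(_KNOWN_FLAGS))
    scale_up: list[ScaleUpScenario] = field(default_factory=list)
    uplift_factors: tuple[float, ...] = (1.10, 1.20, 1.50)
    time_policies: dict[str, TimeValuationPolicy] = field(
        default_factory=lambda: {
            "base_30d_consumption": TimeValuationPolicy(30, 8, "consumption"),
            "days22_consumption": TimeValuationPolicy(22, 8, "consumption"),
            "days30_median_salary": TimeValuationPolicy(30, 8, "median_salary"),
        }
    )

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        known_keys = {"seed", "trial", "economy", "flags", "scale_up", "sensitivity"}
        unknown = set(raw) - known_keys
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        flags = dict(_KNOWN_FLAGS)
        for k, v in (raw.get("flags") or {}).items():
            if k not in _KNOWN_FLAGS:
                raise ConfigurationError(f"unknown assumption flag {k!r}")
            flags[k] = v
        trial_raw = raw.get("trial") or {}
        if "countries" in trial_raw:
            trial = trial_config_from_dict(trial_raw)
        else:
            trial = default_trial_config(**trial_raw)
        economy = (
            economy_from_dict(raw["economy"]) if raw.get("economy") else default_economy()
        )
        scenarios = []
        for entry in raw.get("scale_up") or []:
            if isinstance(entry, (str, Path)):
                with open(entry) as fh:
                    entry = yaml.safe_load(fh)
            scenarios.append(scenario_from_dict(entry))
        sens = raw.get("sensitivity") or {}
        policies = {}
        for name, p in (sens.get("time_policies") or {}).items():
            policies[name] = TimeValuationPolicy(
                days_per_month=int(p.get("days_per_month", 30)),
                hours_per_day=int(p.get("hours_per_day", 8)),
                wage_basis=p.get("wage_basis", "consumption"),
            )
        kwargs: dict[str, Any] = {
            "seed": int(raw.get("seed", 0)),
            "trial": trial,
            "economy": economy,
            "flags": flags,
            "scale_up": scenarios,
        }
        if "uplift_factors" in sens:
            kwargs["uplift_factors"] = tuple(float(f) for f in sens["uplift_factors"])
        if policies:
            kwargs["time_policies"] = policies
        return cls(**kwargs)

    def patient_options(self) -> PatientCostOptions:
        return PatientCostOptions(
            double_travel_expense=self.flags["double_travel_expense"],
            time_multiplier=self.flags["time_multiplier"],
            equalise_expenses=self.flags["equalise_expenses"],
        )

    def provider_options(self) -> ProviderCostingOptions:
        return ProviderCostingOptions(htn_dm_rule=self.flags["htn_dm_rule"])


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full pipeline and write the report bundle to ``outdir``.

    Returns the metrics mapping (the machine-readable twin of every rendered
    table)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    metrics: dict[str, Any] = {"seed": config.seed, "flags": dict(config.flags)}
    log_lines = [
        f"intecost {__version__} on python {platform.python_version()}",
        f"seed: {config.seed}",
        "assumption flags:",
    ]
    log_lines += [f"  {k}: {v}" for k, v in sorted(config.flags.items())]

    trial = generate_trial(config.trial, config.seed, config.economy)
    trial.write_csv(outdir / "synthetic")

    provider_costs = compute_provider_costs(
        trial.participants, trial.visits, trial.dispensing, trial.ledgers,
        config.economy, config.provider_options(),
    )
    table1 = summarize_provider_costs(provider_costs)
    table1.to_csv(outdir / "table1_provider_costs.csv", index=False)
    metrics["provider_cost_summary"] = table1.to_dict(orient="records")

    comparisons = [compare_all(provider_costs, "total", "provider")]

    include_q = config.flags["include_questionnaires"] and not trial.questionnaires.empty
    if include_q:
        base_policy = list(config.time_policies.values())[0]
        patient_costs = compute_patient_costs(
            trial.questionnaires, trial.participants, config.economy,
            base_policy, config.patient_options(),
        )
        table2 = summarize_costs(patient_costs, value="total")
        table2.to_csv(outdir / "table2_patient_costs.csv", index=False)
        metrics["patient_cost_summary"] = table2.to_dict(orient="records")

        societal = compute_societal_costs(provider_costs, patient_costs)
        table3 = summarize_costs(societal, value="societal_total")
        table3.to_csv(outdir / "table3_societal_costs.csv", index=False)
        metrics["societal_cost_summary"] = table3.to_dict(orient="records")
        share = provider_share_of_societal(societal)
        metrics["provider_share_of_societal"] = share.to_dict(orient="records")

        comparisons.append(compare_all(patient_costs, "total", "patient"))
        comparisons.append(compare_all(societal, "societal_total", "societal"))
    else:
        log_lines.append("questionnaires absent: provider-only report")
        logger.info("questionnaires absent: patient/societal tables skipped")

    comparison_df = pd.concat(comparisons, ignore_index=True)
    comparison_df.to_csv(outdir / "comparisons.csv", index=False)
    metrics["comparisons"] = comparison_df.to_dict(orient="records")

    metrics["scale_up"] = {}
    for scenario in config.scale_up:
        result = national_totals(scenario, "current")
        frame = result.to_frame()
        frame.to_csv(outdir / f"table4_scale_up_{scenario.country}.csv", index=False)
        metrics["scale_up"][scenario.country] = frame.to_dict(orient="records")
        has_ci = all(
            p.mean_monthly_cost_ci is not None and p.proportion_ci is not None
            for p in scenario.profiles.values()
        )
        if has_ci:
            grid = two_way_grid(scenario, "current")
            grid.to_frame().to_csv(
                outdir / f"sensitivity_grid_{scenario.country}.csv", index=False
            )
            metrics["scale_up"][scenario.country + "_grid"] = {
                "min_difference": grid.min_difference,
                "max_difference": grid.max_difference,
                "all_cost_saving": grid.all_cost_saving,
            }

    uplifted = uplift_comparisons(
        provider_costs, config.uplift_factors, config.flags["uplift_includes_capital"]
    )
    metrics["uplift"] = {}
    for factor, table in uplifted.items():
        table.to_csv(outdir / f"sensitivity_uplift_{int(round(factor * 100))}.csv", index=False)
        metrics["uplift"][f"{factor:.2f}"] = table.to_dict(orient="records")

    if include_q and len(config.time_policies) > 1:
        variants, concordance = time_valuation_variants(
            trial.questionnaires, trial.participants, provider_costs,
            config.economy, config.time_policies, config.patient_options(),
        )
        concordance.to_csv(outdir / "sensitivity_time_valuation_concordance.csv", index=False)
        metrics["time_valuation_concordance"] = concordance.to_dict(orient="records")

    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=1, sort_keys=True, default=str)
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return metrics
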