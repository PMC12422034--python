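"""Deterministic sensitivity analyses.

Three frameworks: (1) uplift of integrated-arm personnel and overhead costs
by +10/20/50% with the arm comparison re-run; (2) a two-way grid varying
condition-mix proportions and mean monthly provider costs across their 95%
confidence limits in the scale-up model; (3) alternative time-valuation
policies (22-day month, median salary) for patient and societal costs.
All runs are pure functions of their inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field
from typing import Mapping, Sequence

import pandas as pd

from .compare import compare_all
from .errors import ParameterError
from .money import EconomyParameters, TimeValuationPolicy
from .patient import PatientCostOptions, compute_patient_costs, compute_societal_costs
from .provider import PROVIDER_COMPONENTS
from .scaleup import (
    Coverage,
    ProfileScaleInputs,
    ScaleUpResult,
    ScaleUpScenario,
    national_totals,
)

UPLIFT_FACTORS = (1.10, 1.20, 1.50)
GRID_LEVELS = ("low", "point", "high")


@dataclass(frozen=True)
class SensitivityScenario:
    """One sensitivity run specification (exactly one kind active)."""

    kind: str  # "uplift" | "two_way_grid" | "time_valuation"
    uplift_factor: float | None = None
    grid_levels: Sequence[str] = GRID_LEVELS
    time_policy: TimeValuationPolicy | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uplift", "two_way_grid", "time_valuation"):
            raise ParameterError(f"unknown sensitivity kind {self.kind!r}")
        if self.kind == "uplift" and (self.uplift_factor is None or self.uplift_factor <= 0):
            raise ParameterError("uplift requires a positive uplift_factor")
        if self.kind == "time_valuation" and self.time_policy is None:
            raise ParameterError("time_valuation requires a time_policy")


def apply_uplift(
    provider_costs: pd.DataFrame, factor: float, include_capital: bool = False
) -> pd.DataFrame:
    """Scale integrated-arm personnel and overhead components by ``factor``.

    Capital is excluded by default (only personnel and overheads are named
    in the base assumption being varied); medications and diagnostics are
    never touched. Totals are recomputed.
    """
    if factor <= 0:
        raise ParameterError(f"uplift factor must be > 0, got {factor}")
    out = provider_costs.copy()
    mask = out["arm"] == "integrated"
    components = ["personnel", "overhead"] + (["capital"] if include_capital else [])
    for comp in components:
        out.loc[mask, comp] = out.loc[mask, comp] * factor
    out["total"] = sum(out[c] for c in PROVIDER_COMPONENTS)
    return out


def uplift_comparisons(
    provider_costs: pd.DataFrame,
    factors: Sequence[float] = UPLIFT_FACTORS,
    include_capital: bool = False,
) -> dict[float, pd.DataFrame]:
    """Re-run the full arm comparison under each uplift factor."""
    return {
        f: compare_all(apply_uplift(provider_costs, f, include_capital), "total", "provider")
        for f in factors
    }


@dataclass(frozen=True)
class GridResult:
    """3x3 grid of scale-up results over (cost level, proportion level)."""

    cells: Mapping[tuple[str, str], ScaleUpResult]

    @property
    def differences(self) -> dict[tuple[str, str], float]:
        return {k: r.overall_difference for k, r in self.cells.items()}

    @property
    def min_difference(self) -> float:
        return min(self.differences.values())

    @property
    def max_difference(self) -> float:
        return max(self.differences.values())

    @property
    def all_cost_saving(self) -> bool:
        return all(d < 0 for d in self.differences.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cost_level": ck, "proportion_level": pk,
                "integrated": r.grand_total("integrated"),
                "standard": r.grand_total("standard"),
                "difference": r.overall_difference,
            }
            for (ck, pk), r in self.cells.items()
        ]
        return pd.DataFrame(rows)


def _at_level(point: float, ci: tuple[float, float] | None, level: str, what: str) -> float:
    if level == "point" or ci is None:
        if level != "point" and ci is None:
            raise ParameterError(f"missing confidence interval for {what}")
        return point
    low, high = ci
    if low > high:
        raise ParameterError(f"inconsistent CI for {what}: low {low} > high {high}")
    return low if level == "low" else high


def _perturb_scenario(
    scenario: ScaleUpScenario, cost_level: str, prop_level: str
) -> ScaleUpScenario:
    new_profiles: dict[str, ProfileScaleInputs] = {}
    raw_props: dict[str, float] = {}
    for label, p in scenario.profiles.items():
        costs = {
            arm: _at_level(
                p.mean_monthly_cost[arm],
                (p.mean_monthly_cost_ci or {}).get(arm) if p.mean_monthly_cost_ci else None,
                cost_level,
                f"{label} {arm} cost",
            )
            for arm in p.mean_monthly_cost
        }
        raw_props[label] = _at_level(p.proportion, p.proportion_ci, prop_level, f"{label} proportion")
        new_profiles[label] = replace(p, mean_monthly_cost=costs)

    # renormalise proportions so each decomposition group keeps its mass
    groups = dict(scenario.decomposition) or {"all": tuple(scenario.profiles)}
    props = dict(raw_props)
    for labels in groups.values():
        orig = sum(scenario.profiles[l].proportion for l in labels)
        pert = sum(raw_props[l] for l in labels)
        scale = orig / pert if pert > 0 else 0.0
        for l in labels:
            props[l] = raw_props[l] * scale
    new_profiles = {l: replace(p, proportion=props[l]) for l, p in new_profiles.items()}
    return replace(scenario, profiles=new_profiles)


def two_way_grid(
    scenario: ScaleUpScenario,
    coverage: Coverage = "current",
    levels: Sequence[str] = GRID_LEVELS,
) -> GridResult:
    """National totals over the CI grid of costs x proportions."""
    cells = {}
    for cost_level in levels:
        for prop_level in levels:
            perturbed = _perturb_scenario(scenario, cost_level, prop_level)
            cells[(cost_level, prop_level)] = national_totals(perturbed, coverage)
    return GridResult(cells=cells)


def time_valuation_variants(
    questionnaires: pd.DataFrame,
    participants: pd.DataFrame,
    provider_costs: pd.DataFrame,
    economy: EconomyParameters,
    policies: Mapping[str, TimeValuationPolicy],
    options: PatientCostOptions = PatientCostOptions(),
) -> tuple[dict[str, dict[str, pd.DataFrame]], pd.DataFrame]:
    """Patient and societal comparisons recomputed under each time policy.

    Returns per-policy comparison tables and a concordance table of
    significance categories against the first (base) policy.
    """
    if not policies:
        raise ParameterError("policies must be nonempty")
    results: dict[str, dict[str, pd.DataFrame]] = {}
    for name, policy in policies.items():
        patient = compute_patient_costs(questionnaires, participants, economy, policy, options)
        societal = compute_societal_costs(provider_costs, patient)
        results[name] = {
            "patient": compare_all(patient, "total", "patient"),
            "societal": compare_all(societal, "societal_total", "societal"),
        }
    return results, significance_concordance(results)


def _significance(row) -> str:
    if not row["estimable"]:
        return "not_estimable"
    if row["p_value"] < 0.05:
        return "saving" if row["diff"] > 0 else "extra_cost"
    return "not_significant"


def significance_concordance(results: Mapping[str, dict[str, pd.DataFrame]]) -> pd.DataFrame:
    """Significance category of every arm-contrast cell under each policy."""
    frames = []
    for name, tables in results.items():
        for perspective, table in tables.items():
            arm_cells = table[table["contrast"] == "arm"].copy()
            arm_cells["policy"] = name
            arm_cells["category"] = arm_cells.apply(_significance, axis=1)
            frames.append(arm_cells[["policy", "perspective", "country", "group", "category"]])
    long = pd.concat(frames, ignore_index=True)
    wide = long.pivot_table(
        index=["perspective", "country", "group"],
        columns="policy",
        values="category",
        aggfunc="first",
    ).reset_index()
    wide.columns.name = None
    base = list(results)[0]
    policy_cols = [c for c in wide.columns if c not in ("perspective", "country", "group")]
    wide["concordant"] = wide[policy_cols].eq(wide[base], axis=0).all(axis=1)
    return wide
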