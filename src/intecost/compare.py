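"""Between-group mean cost comparisons.

Welch's unequal-variance t-test with Satterthwaite degrees of freedom is the
default for every cell; a pooled-variance variant and a facility-level
bootstrap are available for robustness checks. The declared orientation is
``diff = mean_b - mean_a``: calling with (integrated, standard) makes a
positive difference a saving from integrated care, matching the reported
table convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .conditions import PROFILE_LABELS, profile_from_label
from .errors import InsufficientDataError

MULTI_LABELS = tuple(l for l in PROFILE_LABELS if profile_from_label(l).is_multimorbid)
SINGLE_LABELS = tuple(l for l in PROFILE_LABELS if not profile_from_label(l).is_multimorbid)


@dataclass(frozen=True)
class ComparisonResult:
    """A two-group mean difference with its 95% CI and two-sided p-value."""

    group_key: tuple
    mean_a: float
    mean_b: float
    diff: float
    ci_low: float
    ci_high: float
    p_value: float
    n_a: int
    n_b: int
    df: float = float("nan")
    estimable: bool = True

    def __post_init__(self) -> None:
        if self.estimable:
            assert self.ci_low <= self.diff <= self.ci_high
            assert 0.0 <= self.p_value <= 1.0


def not_estimable(group_key: tuple, n_a: int = 0, n_b: int = 0) -> ComparisonResult:
    nan = float("nan")
    return ComparisonResult(group_key, nan, nan, nan, nan, nan, nan, n_a, n_b, estimable=False)


def welch_from_stats(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    group_key: tuple = (),
    alpha: float = 0.05,
    pooled: bool = False,
) -> ComparisonResult:
    """Welch test from group summary statistics (usable on published tables).

    ``pooled=True`` switches to the classical equal-variance t-test.
    """
    if n_a < 2 or n_b < 2:
        raise InsufficientDataError(f"need n >= 2 in both groups, got {n_a}, {n_b}")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    diff = mean_b - mean_a
    if pooled:
        sp2 = ((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / (n_a + n_b - 2)
        se = math.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        dof = float(n_a + n_b - 2)
    else:
        se = math.sqrt(va + vb)
        dof = (
            (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
            if va + vb > 0
            else float(n_a + n_b - 2)
        )
    if se == 0:
        p = 1.0 if diff == 0 else 0.0
        return ComparisonResult(group_key, mean_a, mean_b, diff, diff, diff, p, n_a, n_b, dof)
    t = diff / se
    p = 2.0 * stats.t.sf(abs(t), dof)
    half = stats.t.ppf(1.0 - alpha / 2.0, dof) * se
    return ComparisonResult(
        group_key, mean_a, mean_b, diff, diff - half, diff + half, float(p), n_a, n_b, dof
    )


def welch_test(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    group_key: tuple = (),
    alpha: float = 0.05,
    pooled: bool = False,
) -> ComparisonResult:
    """Welch test from raw samples; diff = mean(sample_b) - mean(sample_a)."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(f"need n >= 2 in both groups, got {len(a)}, {len(b)}")
    return welch_from_stats(
        a.mean(), a.std(ddof=1), len(a),
        b.mean(), b.std(ddof=1), len(b),
        group_key=group_key, alpha=alpha, pooled=pooled,
    )


def cluster_bootstrap_test(
    costs: pd.DataFrame,
    value: str,
    arm_a: str = "integrated",
    arm_b: str = "standard",
    cluster: str = "facility_id",
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Facility-level bootstrap of the arm mean difference (percentile CI).

    Off by default in the pipeline, mirroring the unclustered published
    t-tests; provided as a robustness option.
    """
    rng = np.random.default_rng(seed)
    groups = {
        arm: [g[value].to_numpy() for _, g in costs[costs["arm"] == arm].groupby(cluster)]
        for arm in (arm_a, arm_b)
    }
    if min(len(groups[arm_a]), len(groups[arm_b])) < 2:
        raise InsufficientDataError("need at least 2 clusters per arm")
    point = float(
        np.concatenate(groups[arm_b]).mean() - np.concatenate(groups[arm_a]).mean()
    )
    draws = np.empty(n_boot)
    for i in range(n_boot):
        means = {}
        for arm in (arm_a, arm_b):
            idx = rng.integers(0, len(groups[arm]), len(groups[arm]))
            means[arm] = np.concatenate([groups[arm][j] for j in idx]).mean()
        draws[i] = means[arm_b] - means[arm_a]
    lo, hi = np.quantile(draws, [alpha / 2.0, 1.0 - alpha / 2.0])
    p = 2.0 * min((draws <= 0).mean(), (draws >= 0).mean())
    na = sum(len(g) for g in groups[arm_a])
    nb = sum(len(g) for g in groups[arm_b])
    return ComparisonResult(
        ("cluster_bootstrap",), float("nan"), float("nan"), point,
        min(float(lo), point), max(float(hi), point), min(p, 1.0), na, nb,
    )


def _cell(costs: pd.DataFrame, value: str, mask_a, mask_b, key: tuple) -> ComparisonResult:
    a = costs.loc[mask_a, value].to_numpy()
    b = costs.loc[mask_b, value].to_numpy()
    if len(a) < 2 or len(b) < 2:
        return not_estimable(key, len(a), len(b))
    return welch_test(a, b, group_key=key)


def compare_all(
    costs: pd.DataFrame, value: str = "total", perspective: str = "provider"
) -> pd.DataFrame:
    """One Welch comparison per (country, profile) cell plus pooled contrasts.

    Arm cells are oriented standard-minus-integrated (positive = saving from
    integrated care); condition and country contrasts follow the reported
    orientation (HIV minus HTN, multimorbid minus single, Uganda minus
    Tanzania). Pooled contrasts pool visits without reweighting by country.
    """
    results: list[ComparisonResult] = []
    is_int = costs["arm"] == "integrated"
    is_std = costs["arm"] == "standard"
    multi = costs["profile"].isin(MULTI_LABELS)

    for country in sorted(costs["country"].unique()):
        in_country = costs["country"] == country
        for label in PROFILE_LABELS:
            mask = in_country & (costs["profile"] == label)
            results.append(
                _cell(costs, value, mask & is_int, mask & is_std, (country, label, "arm"))
            )
        results.append(
            _cell(costs, value, in_country & is_int & multi, in_country & is_std & multi,
                  (country, "multimorbid", "arm"))
        )
        results.append(
            _cell(costs, value, in_country & is_int & ~multi, in_country & is_std & ~multi,
                  (country, "single", "arm"))
        )

    results.append(_cell(costs, value, is_int & multi, is_std & multi, ("pooled", "multimorbid", "arm")))
    results.append(_cell(costs, value, is_int & ~multi, is_std & ~multi, ("pooled", "single", "arm")))
    results.append(
        _cell(costs, value, costs["profile"] == "HTN", costs["profile"] == "HIV",
              ("pooled", "HIV_vs_HTN", "condition"))
    )
    results.append(
        _cell(costs, value, costs["profile"] == "DM", costs["profile"] == "HIV",
              ("pooled", "HIV_vs_DM", "condition"))
    )
    results.append(_cell(costs, value, ~multi, multi, ("pooled", "multi_vs_single", "condition")))
    results.append(
        _cell(costs, value, costs["country"] == "Tanzania", costs["country"] == "Uganda",
              ("pooled", "Uganda_vs_Tanzania", "country"))
    )
    return comparison_table(results, perspective)


def comparison_table(results: Sequence[ComparisonResult], perspective: str) -> pd.DataFrame:
    rows = []
    for r in results:
        country, group, contrast = r.group_key
        rows.append(
            {
                "perspective": perspective,
                "country": country,
                "group": group,
                "contrast": contrast,
                "mean_a": r.mean_a,
                "mean_b": r.mean_b,
                "diff": r.diff,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_value": r.p_value,
                "n_a": r.n_a,
                "n_b": r.n_b,
                "estimable": r.estimable,
            }
        )
    return pd.DataFrame(rows)
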