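"""Chronic-condition profiles: the seven single/multiple condition categories.

Every costing rule downstream is keyed on one of these profiles, so the
canonical labels and the subset <-> label bijection live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import FrozenSet, Iterable

CONDITIONS = ("HIV", "HTN", "DM")

#: Canonical label order used in every rendered table.
PROFILE_LABELS = (
    "HIV",
    "HTN",
    "DM",
    "HIV+HTN",
    "HIV+DM",
    "HTN+DM",
    "HIV+HTN+DM",
)


@dataclass(frozen=True)
class ConditionProfile:
    """A nonempty subset of {HIV, HTN, DM} with its canonical label."""

    conditions: FrozenSet[str]
    label: str = field(init=False)

    def __post_init__(self) -> None:
        conds = frozenset(self.conditions)
        if not conds or not conds <= set(CONDITIONS):
            raise ValueError(
                f"conditions must be a nonempty subset of {set(CONDITIONS)}, got {set(self.conditions)}"
            )
        object.__setattr__(self, "conditions", conds)
        # label follows the fixed HIV, HTN, DM ordering
        label = "+".join(c for c in CONDITIONS if c in conds)
        object.__setattr__(self, "label", label)

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def is_multimorbid(self) -> bool:
        return self.n_conditions >= 2

    def singles(self) -> tuple["ConditionProfile", ...]:
        """Constituent single-condition profiles, in canonical order."""
        return tuple(profile_from_label(c) for c in CONDITIONS if c in self.conditions)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@lru_cache(maxsize=None)
def profile_from_label(label: str) -> ConditionProfile:
    """Parse a canonical label like ``"HIV+DM"`` into a profile."""
    parts = label.split("+")
    if sorted(set(parts)) != sorted(parts):
        raise ValueError(f"duplicate condition in label {label!r}")
    return ConditionProfile(frozenset(parts))


def all_profiles() -> tuple[ConditionProfile, ...]:
    """The seven profiles in canonical table order."""
    return tuple(profile_from_label(lbl) for lbl in PROFILE_LABELS)


def profile_from_conditions(conditions: Iterable[str]) -> ConditionProfile:
    return ConditionProfile(frozenset(conditions))
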