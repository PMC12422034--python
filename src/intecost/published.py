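"""Access to the published national scale-up reference table.

The per-profile annual totals and arm-level budget shares shipped with the
package are treated as *inputs*: the aggregation operations recompute grand
totals, differences and budget-impact shares from them, which is how the
arithmetic is validated.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .scaleup import ScaleUpResult, aggregate_profile_totals

_DATA = "scale_up_published_2021.yaml"


def load_published_scale_up() -> dict:
    """Raw published table as a nested mapping, keyed by country."""
    with resources.files("intecost.data").joinpath(_DATA).open() as fh:
        return yaml.safe_load(fh)


def published_result(country: str) -> ScaleUpResult:
    """The published per-profile totals of one country as a scale-up result
    (grand totals and differences are recomputed, not copied)."""
    raw = load_published_scale_up()[country]
    return aggregate_profile_totals(country, raw["profile_totals"])
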