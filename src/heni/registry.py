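"""Registry of dietary risk components recognized by the Global Burden of
Disease comparative risk framework.

All component amounts are standardized in grams. Beneficial components carry
negative Dietary Risk Factors (μDALY/g), detrimental ones positive. Fibers are
split by botanical source (fruit, vegetable, legume, whole-grain vs. other)
because each source carries its own dose-response evidence. Sugar-sweetened
beverage (SSB) amounts are recorded as beverage grams, not sugar grams — a
provisional convention, documented here because composition databases differ.

The registry is extensible: pass extra identifiers to :func:`make_registry`
or list them under ``extra_components`` in a YAML config.
"""

from __future__ import annotations

from typing import FrozenSet, Iterable

#: Built-in GBD dietary risk components (identifiers used across the package).
DEFAULT_COMPONENTS: FrozenSet[str] = frozenset(
    {
        # beneficial (negative DRF)
        "fluid_milk",
        "nuts_seeds",
        "fruit",
        "calcium",
        "seafood_omega3",
        "fruit_fiber",
        "vegetable_fiber",
        "legume_fiber",
        "whole_grain_fiber",
        "other_fiber",
        "pufa",
        # detrimental (positive DRF)
        "processed_meat",
        "red_meat",
        "trans_fat",
        "ssb",
        "sodium",
    }
)


class UnknownComponentError(KeyError):
    """A component identifier is not in the active registry."""

    def __init__(self, component_id: str, registry: FrozenSet[str]):
        self.component_id = component_id
        super().__init__(
            f"unknown dietary risk component {component_id!r}; "
            f"registered: {', '.join(sorted(registry))}"
        )


def make_registry(extra: Iterable[str] = ()) -> FrozenSet[str]:
    """Return the default registry extended with ``extra`` identifiers."""
    extra = frozenset(extra)
    for cid in extra:
        if not cid or not isinstance(cid, str):
            raise ValueError(f"invalid component identifier: {cid!r}")
    return DEFAULT_COMPONENTS | extra


def check_component(component_id: str, registry: FrozenSet[str] | None = None) -> str:
    """Validate ``component_id`` against ``registry`` (default registry if None)."""
    reg = DEFAULT_COMPONENTS if registry is None else registry
    if component_id not in reg:
        raise UnknownComponentError(component_id, reg)
    return component_id
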