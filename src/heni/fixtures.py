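"""Packaged worked example: a three-ingredient strawberry yogurt.

One 170 g serving (127.4 kcal) of corn syrup + strawberries + plain low-fat
yogurt, with per-ingredient risk-component amounts and the accompanying
Dietary Risk Factor row. Per-ingredient mass fractions are back-computed
from the published per-serving amounts so that resolve_components reproduces
the published totals: fruit fiber 0.12, calcium 0.28, PUFA 0.08, fruit 5.95,
sodium 0.114, trans fat 0.030 g/serving.

Note on rounding: the published calcium amount is the rounded 0.28 g, whose
minute-scaled cell recomputes to −0.76 rather than the printed −0.77 (the
unrounded input was ≈0.283 g). The fixture stores the printed 0.28 and
accepts the ±0.01 consequence.

The yogurt ingredient's category is ``yogurt``, not ``fluid_milk``: yogurt
does not count as milk in the GBD component list, so its calcium is counted
rather than excluded by the milk/calcium double-counting rule.
"""

from __future__ import annotations

from typing import Tuple

from .characterization import DRFTable
from .composition import ComponentProfile, Ingredient, Recipe

#: Published per-serving component totals (g/serving) for the yogurt example.
YOGURT_EXPECTED_AMOUNTS = {
    "fruit_fiber": 0.12,
    "calcium": 0.28,
    "pufa": 0.08,
    "fruit": 5.95,
    "sodium": 0.114,
    "trans_fat": 0.030,
}

#: Published DRF row (μDALY/g; negative = beneficial).
YOGURT_DRF_VALUES = {
    "fruit_fiber": -0.18,
    "calcium": -5.15,
    "pufa": -0.61,
    "fruit": -0.19,
    "sodium": 13.90,
    "trans_fat": 4.44,
}


def _profiles(mass: float, per_serving: dict) -> Tuple[ComponentProfile, ...]:
    return tuple(
        ComponentProfile(component_id=cid, content=amount / mass)
        for cid, amount in per_serving.items()
    )


def yogurt_fixture() -> Tuple[Recipe, DRFTable]:
    """The strawberry-yogurt worked example: (recipe, DRF table)."""
    recipe = Recipe(
        name="strawberry yogurt",
        ingredients=(
            Ingredient(
                name="Corn syrup",
                mass_per_serving=10.0,
                energy_per_serving=28.4,
                category="sweetener",
                profiles=_profiles(10.0, {"sodium": 0.006, "trans_fat": 0.003}),
            ),
            Ingredient(
                name="Strawberries",
                mass_per_serving=6.0,
                energy_per_serving=1.9,
                category="fruit",
                profiles=_profiles(
                    6.0, {"fruit_fiber": 0.12, "pufa": 0.01, "fruit": 5.95}
                ),
            ),
            Ingredient(
                name="Yogurt plain low fat milk",
                mass_per_serving=154.0,
                energy_per_serving=97.1,
                category="yogurt",
                profiles=_profiles(
                    154.0,
                    {
                        "calcium": 0.28,
                        "pufa": 0.07,
                        "sodium": 0.108,
                        "trans_fat": 0.027,
                    },
                ),
            ),
        ),
    )
    drf = DRFTable(
        entries=dict(YOGURT_DRF_VALUES),
        provenance="packaged strawberry-yogurt worked example (US population DRFs)",
    )
    return recipe, drf


__all__ = ["yogurt_fixture", "YOGURT_EXPECTED_AMOUNTS", "YOGURT_DRF_VALUES"]
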