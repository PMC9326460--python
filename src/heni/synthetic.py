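"""Synthetic recipe/DRF generator with independently computed expectations.

Draws ingredient masses, energies, component mass fractions and DRFs from
documented ranges (below), and returns the expected health-impact result
computed by a deliberately plain, separate summation — not by calling the
pipeline — so tests can compare the two routes. Same seed → identical output.

Ranges (chosen to span realistic food-composition magnitudes):

* ingredient mass: U(5, 200) g/serving; energy: U(1, 300) kcal/serving
* each ingredient carries each candidate component with probability 0.6,
  content U(0, 0.05) g/g (trace-to-minor constituents; the fruit component
  of a fruit ingredient can reach ≈1 g/g, but small fractions exercise the
  arithmetic identically)
* DRF: U(−6, 15) μDALY/g, spanning the strongest published beneficial
  (calcium ≈ −5.15) and detrimental (sodium ≈ +13.9) factors
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .characterization import DRFTable, HealthImpactResult
from .composition import Basis, ComponentProfile, Ingredient, Recipe
from .registry import DEFAULT_COMPONENTS


def generate_synthetic(
    seed: int, n_ingredients: int = 3, n_components: int = 4
) -> Tuple[Recipe, DRFTable, HealthImpactResult]:
    """Generate (recipe, DRF table, independently-summed expected result).

    ``n_components`` candidate components are sampled from the registry;
    every candidate receives a DRF, and each ingredient carries a random
    subset of them. Ingredients have no category, so no exclusion rule
    applies and the expectation is the plain mass × content × DRF sum.
    """
    if n_ingredients < 0:
        raise ValueError(f"n_ingredients must be ≥ 0, got {n_ingredients}")
    if not 0 <= n_components <= len(DEFAULT_COMPONENTS):
        raise ValueError(f"n_components out of range: {n_components}")
    rng = np.random.default_rng(seed)
    components = sorted(
        rng.choice(sorted(DEFAULT_COMPONENTS), size=n_components, replace=False)
    )

    ingredients = []
    for i in range(n_ingredients):
        profiles = tuple(
            ComponentProfile(component_id=cid, content=float(rng.uniform(0.0, 0.05)))
            for cid in components
            if rng.random() < 0.6
        )
        ingredients.append(
            Ingredient(
                name=f"ingredient-{i}",
                mass_per_serving=float(rng.uniform(5.0, 200.0)),
                energy_per_serving=float(rng.uniform(1.0, 300.0)),
                profiles=profiles,
            )
        )
    recipe = Recipe(name=f"synthetic-{seed}", ingredients=tuple(ingredients))
    drf = DRFTable(
        entries={cid: float(rng.uniform(-6.0, 15.0)) for cid in components},
        provenance=f"synthetic (seed={seed})",
    )

    # Independent expectation: plain nested loops, no pipeline calls.
    amounts: Dict[str, float] = {}
    for ing in recipe.ingredients:
        for prof in ing.profiles:
            amounts[prof.component_id] = (
                amounts.get(prof.component_id, 0.0)
                + ing.mass_per_serving * prof.content
            )
    per_udaly = {cid: amt * drf.entries[cid] for cid, amt in amounts.items()}
    expected = HealthImpactResult(
        basis=Basis.SERVING,
        per_component_udaly=per_udaly,
        total_udaly=sum(per_udaly.values()),
    )
    return recipe, drf, expected


__all__ = ["generate_synthetic"]
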