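"""Ingredient-level food composition → dietary-risk-component amounts (d_r).

A :class:`Recipe` is an ordered list of ingredients, each with a mass and
energy per serving and a set of component mass fractions (g of risk component
per g of ingredient). :func:`resolve_components` aggregates these into a
:class:`RiskComponentVector` — the inventory flows d_r in grams per functional
unit — applying declarative double-counting exclusion rules (e.g. calcium is
not counted for fluid-milk ingredients because milk itself is already a
beneficial component). :func:`convert_functional_unit` rescales a vector
between the three functional-unit bases used in food LCA: per serving,
per 100 g, and per kcal.
"""

from __future__ import annotations

import enum
from typing import Dict, List, Optional, Sequence, Tuple

from pydantic import BaseModel, Field, field_validator, model_validator

from .registry import DEFAULT_COMPONENTS, check_component


class Basis(str, enum.Enum):
    """Functional-unit basis of a risk-component vector."""

    SERVING = "serving"
    PER_100G = "per-100g"
    PER_KCAL = "per-kcal"

    @classmethod
    def _missing_(cls, value: object) -> "Basis | None":
        aliases = {"100g": cls.PER_100G, "kcal": cls.PER_KCAL}
        if isinstance(value, str):
            return aliases.get(value.lower())
        return None


class ComponentProfile(BaseModel):
    """Content of one risk component in one ingredient.

    ``content`` is a dimensionless mass fraction: grams of component per gram
    of ingredient (composition databases publishing per-100 g values are
    converted at parse time by the readers).
    """

    model_config = {"frozen": True}

    component_id: str
    content: float = Field(ge=0.0)

    @field_validator("component_id")
    @classmethod
    def _known_component(cls, v: str) -> str:
        return check_component(v)


class Ingredient(BaseModel):
    """One recipe ingredient: mass, energy, and component mass fractions.

    ``category`` is an optional free-text food category (e.g. ``fluid_milk``,
    ``yogurt``, ``fruit``) consulted by exclusion rules; ingredients without a
    category are never excluded.
    """

    model_config = {"frozen": True}

    name: str
    mass_per_serving: float = Field(ge=0.0, description="g per serving")
    energy_per_serving: float = Field(ge=0.0, description="kcal per serving")
    profiles: Tuple[ComponentProfile, ...] = ()
    category: Optional[str] = None

    @model_validator(mode="after")
    def _unique_components(self) -> "Ingredient":
        seen = [p.component_id for p in self.profiles]
        if len(seen) != len(set(seen)):
            dupes = sorted({c for c in seen if seen.count(c) > 1})
            raise ValueError(
                f"ingredient {self.name!r} has duplicate component profiles: {dupes}"
            )
        return self

    def content(self, component_id: str) -> float:
        """Mass fraction of ``component_id`` (0 if absent)."""
        for p in self.profiles:
            if p.component_id == component_id:
                return p.content
        return 0.0


class Recipe(BaseModel):
    """An ordered list of ingredients making up one serving of a food."""

    model_config = {"frozen": True}

    name: str
    ingredients: Tuple[Ingredient, ...] = ()

    @property
    def serving_mass(self) -> float:
        """Total mass of one serving (g) — exact sum, no renormalization."""
        return sum(i.mass_per_serving for i in self.ingredients)

    @property
    def serving_energy(self) -> float:
        """Total energy of one serving (kcal)."""
        return sum(i.energy_per_serving for i in self.ingredients)


class ExclusionRule(BaseModel):
    """Suppress counting of one component for one ingredient category.

    Declarative double-counting guard: an ingredient whose ``category``
    equals ``ingredient_category`` contributes 0 to ``component_id``.
    """

    model_config = {"frozen": True}

    ingredient_category: str
    component_id: str

    @field_validator("component_id")
    @classmethod
    def _known_component(cls, v: str) -> str:
        return check_component(v)


#: Default GBD double-counting rule: calcium is not counted for fluid milk,
#: whose benefit is already captured by the milk component itself.
DEFAULT_EXCLUSIONS: Tuple[ExclusionRule, ...] = (
    ExclusionRule(ingredient_category="fluid_milk", component_id="calcium"),
)


class RiskComponentVector(BaseModel):
    """Amounts d_r (g) of each dietary risk component per functional unit."""

    model_config = {"frozen": True}

    basis: Basis = Basis.SERVING
    amounts: Dict[str, float] = Field(default_factory=dict)

    @field_validator("amounts")
    @classmethod
    def _valid_amounts(cls, v: Dict[str, float]) -> Dict[str, float]:
        for cid, amt in v.items():
            check_component(cid)
            if amt < 0:
                raise ValueError(f"negative amount for {cid!r}: {amt}")
        return v

    def amount(self, component_id: str) -> float:
        """d_r for one component (0 if absent)."""
        return self.amounts.get(component_id, 0.0)

    def __add__(self, other: "RiskComponentVector") -> "RiskComponentVector":
        if self.basis != other.basis:
            raise ValueError(
                f"cannot add vectors on different bases: {self.basis} vs {other.basis}"
            )
        keys = list(self.amounts) + [k for k in other.amounts if k not in self.amounts]
        return RiskComponentVector(
            basis=self.basis,
            amounts={k: self.amount(k) + other.amount(k) for k in keys},
        )


def resolve_components(
    recipe: Recipe,
    exclusion_rules: Sequence[ExclusionRule] = DEFAULT_EXCLUSIONS,
) -> RiskComponentVector:
    """Aggregate ingredient compositions into per-serving inventory flows d_r.

    Each amount is the sum over ingredients of mass × content, with
    (ingredient-category, component) pairs named by an exclusion rule
    contributing 0. The result is on the serving basis; convert with
    :func:`convert_functional_unit` for per-100 g or per-kcal reporting.
    """
    excluded = {(r.ingredient_category, r.component_id) for r in exclusion_rules}
    amounts: Dict[str, float] = {}
    for ing in recipe.ingredients:
        for prof in ing.profiles:
            if ing.category is not None and (ing.category, prof.component_id) in excluded:
                continue
            amounts[prof.component_id] = (
                amounts.get(prof.component_id, 0.0)
                + ing.mass_per_serving * prof.content
            )
    return RiskComponentVector(basis=Basis.SERVING, amounts=amounts)


def recipe_totals(recipe: Recipe) -> Tuple[float, float]:
    """Return (serving mass in g, serving energy in kcal) as exact sums."""
    return recipe.serving_mass, recipe.serving_energy


def convert_functional_unit(
    vector: RiskComponentVector,
    target_basis: Basis | str,
    serving_mass: float,
    serving_energy: float,
) -> RiskComponentVector:
    """Rescale a risk-component vector to another functional-unit basis.

    Conversions route through the serving basis, so any pair of bases
    composes and inverts consistently: serving → per-100g multiplies by
    100/serving_mass, serving → per-kcal by 1/serving_energy.

    Raises :class:`ValueError` when the conversion needs a zero denominator
    (zero serving mass for a per-100g target, zero energy for per-kcal).
    """
    target = Basis(target_basis)
    if target == vector.basis:
        return vector

    def factor_to_serving(basis: Basis) -> float:
        # multiplier taking amounts on `basis` back to per-serving amounts
        if basis == Basis.SERVING:
            return 1.0
        if basis == Basis.PER_100G:
            _require_positive(serving_mass, "serving_mass", "per-100g")
            return serving_mass / 100.0
        _require_positive(serving_energy, "serving_energy", "per-kcal")
        return serving_energy

    def factor_from_serving(basis: Basis) -> float:
        if basis == Basis.SERVING:
            return 1.0
        if basis == Basis.PER_100G:
            _require_positive(serving_mass, "serving_mass", "per-100g")
            return 100.0 / serving_mass
        _require_positive(serving_energy, "serving_energy", "per-kcal")
        return 1.0 / serving_energy

    f = factor_to_serving(vector.basis) * factor_from_serving(target)
    return RiskComponentVector(
        basis=target, amounts={k: v * f for k, v in vector.amounts.items()}
    )


def _require_positive(value: float, name: str, basis: str) -> None:
    if value <= 0:
        raise ValueError(
            f"cannot convert to/from {basis} basis: {name} = {value} is a "
            "degenerate denominator (must be > 0)"
        )


__all__ = [
    "Basis",
    "ComponentProfile",
    "Ingredient",
    "Recipe",
    "ExclusionRule",
    "DEFAULT_EXCLUSIONS",
    "RiskComponentVector",
    "resolve_components",
    "recipe_totals",
    "convert_functional_unit",
    "DEFAULT_COMPONENTS",
]
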