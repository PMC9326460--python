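"""Readers and writers for recipes, DRF tables, epidemiological inputs,
and result reports.

CSV dialect: UTF-8, comma-separated, period decimal separator, one header
row. Numeric cells accept both the ASCII hyphen-minus and the typographic
en/em dashes that published tables often carry. Malformed input is rejected
with the offending row number and file path.

Formats
-------
Recipe CSV       ``ingredient,mass_g,energy_kcal[,category],<component_id>...``
                 component columns in g per 100 g of ingredient (converted to
                 mass fractions at parse time).
Recipe JSON      explicit ``content_basis`` declaration (``per-100g`` or
                 ``fraction``) plus the same fields.
DRF CSV          ``component_id,drf_udaly_per_g[,age_group,sex]`` — rows with
                 age_group/sex populate the stratified table, rows without
                 (or with ``all``) the aggregate entries.
Burden CSV       ``outcome,age_group,sex,daly_per_person_year``.
Epi JSON bundle  curves (knots + tmrel), intake distributions, and optional
                 per-component burden lists, for DRF derivation and diet
                 scenarios.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Any, Dict, List, Optional, Sequence, Tuple

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .characterization import (
    DRFTable,
    HealthImpactResult,
    StratumDRF,
)
from .composition import Basis, ComponentProfile, Ingredient, Recipe
from .epi import BurdenRate, IntakeDistribution, RRCurve, TMRELRange
from .registry import check_component

_RESERVED_RECIPE_COLUMNS = ("ingredient", "mass_g", "energy_kcal", "category")
_DASHES = str.maketrans({"–": "-", "—": "-", "−": "-"})


class FormatError(ValueError):
    """Malformed input file; message carries path and row location."""


def _num(value: Any, path: Path, row: int, column: str) -> float:
    """Parse a numeric cell, accepting typographic minus signs."""
    if isinstance(value, (int, float)):
        if isinstance(value, float) and math.isnan(value):
            return 0.0  # empty cell → absent component
        return float(value)
    text = str(value).strip().translate(_DASHES)
    if text == "":
        return 0.0
    try:
        return float(text)
    except ValueError:
        raise FormatError(
            f"{path}: row {row}: non-numeric value {value!r} in column {column!r}"
        ) from None


class RunConfig(BaseModel):
    """Reproducibility envelope for a CLI run; unknown keys are rejected."""

    model_config = {"extra": "forbid"}

    recipe_path: Optional[str] = None
    drf_path: Optional[str] = None
    basis: Basis = Basis.SERVING
    extra_components: Tuple[str, ...] = ()
    delta: float = Field(default=1.0, gt=0.0, description="g/day FD step")
    tolerance: float = Field(default=1e-9, gt=0.0)
    seed: int = 0
    output_format: str = "json"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()[:16]


def read_registry_config(
    path: str | Path,
) -> Tuple[frozenset, Tuple["ExclusionRule", ...]]:
    """Read registry extensions and exclusion rules from a YAML config.

    Layout::

        extra_components: [resistant_starch, ...]
        exclusions:
          - {ingredient_category: fluid_milk, component_id: calcium}

    Returns (extended registry, exclusion rules). Unknown top-level keys are
    rejected. Note: component validation elsewhere uses the default
    registry; extra components are available to callers that pass the
    returned registry explicitly.
    """
    from .composition import ExclusionRule
    from .registry import make_registry

    path = Path(path)
    data = yaml.safe_load(path.read_text(encoding="utf-8")) or {}
    unknown = set(data) - {"extra_components", "exclusions"}
    if unknown:
        raise FormatError(f"{path}: unknown config keys: {sorted(unknown)}")
    registry = make_registry(data.get("extra_components", ()))
    rules = tuple(
        ExclusionRule.model_validate(r) for r in data.get("exclusions", ())
    )
    return registry, rules


def read_recipe(path: str | Path) -> Recipe:
    """Read a recipe from CSV or JSON (dispatch on file extension)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_recipe_json(path)
    return _read_recipe_csv(path)


def _read_recipe_csv(path: Path) -> Recipe:
    try:
        df = pd.read_csv(path, dtype=str, encoding="utf-8")
    except Exception as exc:  # noqa: BLE001 - rewrap with location
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    cols = list(df.columns)
    if len(cols) != len(set(cols)):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise FormatError(f"{path}: duplicate columns: {dupes}")
    for required in ("ingredient", "mass_g", "energy_kcal"):
        if required not in cols:
            raise FormatError(f"{path}: missing header column {required!r}")
    component_cols = [c for c in cols if c not in _RESERVED_RECIPE_COLUMNS]
    for c in component_cols:
        check_component(c)

    ingredients: List[Ingredient] = []
    for i, rec in enumerate(df.to_dict(orient="records")):
        row = i + 2  # 1-based, after the header row
        mass = _num(rec["mass_g"], path, row, "mass_g")
        energy = _num(rec["energy_kcal"], path, row, "energy_kcal")
        if mass < 0:
            raise FormatError(f"{path}: row {row}: negative mass {mass}")
        if energy < 0:
            raise FormatError(f"{path}: row {row}: negative energy {energy}")
        profiles = []
        for c in component_cols:
            per100g = _num(rec.get(c), path, row, c)
            if per100g < 0:
                raise FormatError(
                    f"{path}: row {row}: negative content {per100g} for {c!r}"
                )
            if per100g > 0:
                profiles.append(
                    ComponentProfile(component_id=c, content=per100g / 100.0)
                )
        category = rec.get("category")
        if isinstance(category, float) and math.isnan(category):
            category = None
        ingredients.append(
            Ingredient(
                name=str(rec["ingredient"]),
                mass_per_serving=mass,
                energy_per_serving=energy,
                profiles=tuple(profiles),
                category=category if category else None,
            )
        )
    return Recipe(name=path.stem, ingredients=tuple(ingredients))


def _read_recipe_json(path: Path) -> Recipe:
    data = json.loads(path.read_text(encoding="utf-8"))
    content_basis = data.get("content_basis", "fraction")
    if content_basis not in ("fraction", "per-100g"):
        raise FormatError(
            f"{path}: content_basis must be 'fraction' or 'per-100g', "
            f"got {content_basis!r}"
        )
    scale = 0.01 if content_basis == "per-100g" else 1.0
    ingredients = []
    for i, ing in enumerate(data.get("ingredients", [])):
        profiles = tuple(
            ComponentProfile(component_id=cid, content=_num(v, path, i, cid) * scale)
            for cid, v in ing.get("components", {}).items()
        )
        ingredients.append(
            Ingredient(
                name=ing["name"],
                mass_per_serving=_num(ing["mass_g"], path, i, "mass_g"),
                energy_per_serving=_num(ing["energy_kcal"], path, i, "energy_kcal"),
                profiles=profiles,
                category=ing.get("category"),
            )
        )
    return Recipe(name=data.get("name", path.stem), ingredients=tuple(ingredients))


def write_recipe_json(recipe: Recipe, path: str | Path) -> None:
    """Serialize a recipe as JSON with mass-fraction contents (lossless)."""
    payload = {
        "name": recipe.name,
        "content_basis": "fraction",
        "ingredients": [
            {
                "name": ing.name,
                "mass_g": ing.mass_per_serving,
                "energy_kcal": ing.energy_per_serving,
                "category": ing.category,
                "components": {p.component_id: p.content for p in ing.profiles},
            }
            for ing in recipe.ingredients
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def read_drf(path: str | Path) -> DRFTable:
    """Read a Dietary Risk Factor table from CSV or JSON."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        return DRFTable.model_validate(data)
    try:
        df = pd.read_csv(path, dtype=str, encoding="utf-8")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    for required in ("component_id", "drf_udaly_per_g"):
        if required not in df.columns:
            raise FormatError(f"{path}: missing header column {required!r}")
    stratified = "age_group" in df.columns and "sex" in df.columns
    entries: Dict[str, float] = {}
    strata: Dict[str, List[StratumDRF]] = {}
    for i, rec in enumerate(df.to_dict(orient="records")):
        row = i + 2
        cid = str(rec["component_id"]).strip()
        check_component(cid)
        drf = _num(rec["drf_udaly_per_g"], path, row, "drf_udaly_per_g")
        age = str(rec.get("age_group", "") or "").strip() if stratified else ""
        sex = str(rec.get("sex", "") or "").strip() if stratified else ""
        if age in ("", "all", "nan") and sex in ("", "all", "nan"):
            if cid in entries:
                raise FormatError(
                    f"{path}: row {row}: duplicate aggregate DRF for {cid!r}"
                )
            entries[cid] = drf
        else:
            strata.setdefault(cid, []).append(
                StratumDRF(age_group=age, sex=sex, drf_udaly_per_g=drf)
            )
    return DRFTable(
        entries=entries,
        strata={k: tuple(v) for k, v in strata.items()},
        provenance=str(path),
    )


def write_drf_json(table: DRFTable, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(table.model_dump(mode="json"), indent=1), encoding="utf-8"
    )


def read_burdens(path: str | Path) -> List[BurdenRate]:
    """Read burden rates from CSV ``outcome,age_group,sex,daly_per_person_year``."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, encoding="utf-8")
    except Exception as exc:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse CSV: {exc}") from exc
    for required in ("outcome", "daly_per_person_year"):
        if required not in df.columns:
            raise FormatError(f"{path}: missing header column {required!r}")
    out = []
    for i, rec in enumerate(df.to_dict(orient="records")):
        row = i + 2
        rate = _num(rec["daly_per_person_year"], path, row, "daly_per_person_year")
        if rate < 0:
            raise FormatError(f"{path}: row {row}: negative burden rate {rate}")
        out.append(
            BurdenRate(
                outcome=str(rec["outcome"]).strip(),
                age_group=str(rec.get("age_group", "all") or "all").strip(),
                sex=str(rec.get("sex", "all") or "all").strip(),
                rate=rate,
            )
        )
    return out


def read_rr_curve(path: str | Path) -> RRCurve:
    """Read one RR curve from JSON: knots + tmrel (+ component_id)."""
    path = Path(path)
    data = json.loads(path.read_text(encoding="utf-8"))
    return _curve_from_dict(data)


def _curve_from_dict(data: Dict[str, Any]) -> RRCurve:
    tmrel = data.get("tmrel", {})
    low = tmrel.get("low", 0.0)
    high = tmrel.get("high")
    return RRCurve(
        component_id=data["component_id"],
        knots=tuple((float(x), float(r)) for x, r in data["knots"]),
        tmrel=TMRELRange(low=float(low), high=math.inf if high is None else float(high)),
    )


def read_intake(path: str | Path) -> IntakeDistribution:
    """Read one intake distribution from JSON (type + parameters or bins)."""
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    return IntakeDistribution.model_validate(data)


def read_epi_bundle(
    path: str | Path,
) -> Tuple[
    Dict[str, RRCurve],
    Dict[str, IntakeDistribution],
    Dict[str, List[BurdenRate]],
]:
    """Read a JSON bundle of curves, intakes and burdens for diet scenarios.

    Layout: ``{"curves": {cid: {...}}, "intakes": {cid: {...}},
    "burdens": {cid: [{outcome, age_group, sex, rate}, ...]}}``.
    """
    data = json.loads(Path(path).read_text(encoding="utf-8"))
    curves = {
        cid: _curve_from_dict({"component_id": cid, **c})
        for cid, c in data.get("curves", {}).items()
    }
    intakes = {
        cid: IntakeDistribution.model_validate(d)
        for cid, d in data.get("intakes", {}).items()
    }
    burdens = {
        cid: [BurdenRate.model_validate(b) for b in lst]
        for cid, lst in data.get("burdens", {}).items()
    }
    return curves, intakes, burdens


def report_payload(
    result: HealthImpactResult, config: Optional[RunConfig] = None
) -> Dict[str, Any]:
    """Assemble the result report with both sign conventions and provenance."""
    config = config or RunConfig()
    return {
        "tool": "heni",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "basis": result.basis.value,
        "per_component_udaly": result.per_component_udaly,
        "total_udaly": result.total_udaly,
        "heni_minutes_gained": {
            "per_component": result.per_component_minutes,
            "total": result.heni_minutes,
            "sign_convention": "positive = healthy life gained",
        },
        "minutes_udaly_sign": {
            "per_component": result.per_component_minutes_udaly_sign,
            "total": result.total_minutes_udaly_sign,
            "sign_convention": "positive = damage (μDALY sign retained)",
        },
        "uncharacterized_g_per_fu": result.uncharacterized,
    }


def write_report(
    result: HealthImpactResult,
    path: str | Path,
    config: Optional[RunConfig] = None,
) -> None:
    """Write the result report as JSON (or CSV of the per-component rows)."""
    config = config or RunConfig()
    path = Path(path)
    payload = report_payload(result, config)
    if config.output_format == "csv":
        rows = [
            {
                "component_id": cid,
                "udaly_per_fu": udaly,
                "minutes_gained": result.per_component_minutes[cid],
                "minutes_udaly_sign": result.per_component_minutes_udaly_sign[cid],
            }
            for cid, udaly in result.per_component_udaly.items()
        ]
        pd.DataFrame(rows).to_csv(path, index=False)
    else:
        path.write_text(json.dumps(payload, indent=1), encoding="utf-8")


__all__ = [
    "FormatError",
    "RunConfig",
    "read_registry_config",
    "read_recipe",
    "write_recipe_json",
    "read_drf",
    "write_drf_json",
    "read_burdens",
    "read_rr_curve",
    "read_intake",
    "read_epi_bundle",
    "report_payload",
    "write_report",
]
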