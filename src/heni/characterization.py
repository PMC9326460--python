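"""Characterize risk-component amounts into health impact and HENI minutes.

The core operation multiplies each inventory flow d_r (g per functional unit)
by its Dietary Risk Factor DRF_r (μDALY per g; negative = beneficial) and sums
across components:

    impact [μDALY/FU] = Σ_r d_r × DRF_r
    HENI   [min/FU]   = −0.526 × impact

Sign conventions, made explicit because the source material mixes them:

* μDALY is the canonical internal quantity; positive = damage.
* HENI minutes are positive-is-gained (the leading minus in the equation).
* ``*_minutes_udaly_sign`` attributes keep the μDALY sign after the ×0.526
  minute scaling (negative = beneficial), the convention used by published
  per-component breakdown tables.

Dietary impacts in μDALY live in the same damage-level unit as environmental
human-health impacts (fine particulate, climate change, toxicity …), so
:func:`combine_with_environmental` can sum them directly while keeping track
of each labeled contribution.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from pydantic import BaseModel, Field, field_validator, model_validator

from .composition import Basis, RiskComponentVector
from .registry import check_component

#: Minutes of healthy life per μDALY: a year holds ≈0.526 million minutes
#: (525,960), so 1 μDALY = 1e-6 year ≈ 0.526 min.
MINUTES_PER_UDALY = 0.526


class StratumDRF(BaseModel):
    """DRF value for one (age group, sex) population stratum."""

    model_config = {"frozen": True}

    age_group: str
    sex: str
    drf_udaly_per_g: float


class DRFTable(BaseModel):
    """Dietary Risk Factors, μDALY per g of component consumed.

    ``entries`` holds aggregate (population-level) values. ``strata`` may
    additionally carry per-(age group, sex) values; aggregate over them with
    :meth:`aggregate_entry` and caller-supplied population weights, since the
    source framework stratifies by 15 age groups and sex but population
    structure is study-specific. ``uncharacterized`` lists registry components
    deliberately left without a DRF (surfaced, never silently zeroed).
    """

    model_config = {"frozen": True}

    entries: Dict[str, float] = Field(default_factory=dict)
    strata: Dict[str, Tuple[StratumDRF, ...]] = Field(default_factory=dict)
    uncharacterized: Tuple[str, ...] = ()
    provenance: str = ""

    @field_validator("entries")
    @classmethod
    def _finite_entries(cls, v: Dict[str, float]) -> Dict[str, float]:
        for cid, drf in v.items():
            check_component(cid)
            if not math.isfinite(drf):
                raise ValueError(f"non-finite DRF for {cid!r}: {drf}")
        return v

    @field_validator("uncharacterized")
    @classmethod
    def _known_uncharacterized(cls, v: Tuple[str, ...]) -> Tuple[str, ...]:
        for cid in v:
            check_component(cid)
        return v

    def drf(self, component_id: str) -> Optional[float]:
        """Aggregate DRF for a component, or None if uncharacterized."""
        return self.entries.get(component_id)

    def aggregate_entry(
        self, component_id: str, weights: Mapping[Tuple[str, str], float]
    ) -> float:
        """Population-weighted mean of the stratified DRFs for one component.

        ``weights`` maps (age_group, sex) → population fraction; they must
        cover every stratum present and sum to 1 (±1e-9).
        """
        strata = self.strata.get(component_id)
        if not strata:
            raise KeyError(f"no stratified DRFs for {component_id!r}")
        total_w = 0.0
        acc = 0.0
        for s in strata:
            key = (s.age_group, s.sex)
            if key not in weights:
                raise KeyError(f"missing population weight for stratum {key}")
            w = weights[key]
            if w < 0:
                raise ValueError(f"negative weight for stratum {key}: {w}")
            total_w += w
            acc += w * s.drf_udaly_per_g
        if abs(total_w - 1.0) > 1e-9:
            raise ValueError(f"stratum weights sum to {total_w}, expected 1")
        return acc


class HealthImpactResult(BaseModel):
    """Dietary human-health impact of one functional unit of a food."""

    model_config = {"frozen": True}

    basis: Basis
    per_component_udaly: Dict[str, float] = Field(default_factory=dict)
    total_udaly: float = 0.0
    uncharacterized: Dict[str, float] = Field(
        default_factory=dict,
        description="component → amount (g/FU) present but lacking a DRF; "
        "candidates for midpoint-level reporting",
    )

    @model_validator(mode="after")
    def _consistent_total(self) -> "HealthImpactResult":
        s = sum(self.per_component_udaly.values())
        tol = 1e-9 * max(1.0, abs(s))
        if abs(s - self.total_udaly) > tol:
            raise ValueError(
                f"total_udaly {self.total_udaly} does not equal the "
                f"per-component sum {s}"
            )
        return self

    # --- HENI minute representations -------------------------------------

    @property
    def heni_minutes(self) -> float:
        """Minutes of healthy life gained per FU (positive = gained)."""
        return heni_minutes(self.total_udaly)

    @property
    def per_component_minutes(self) -> Dict[str, float]:
        """Per-component minutes gained (positive = gained)."""
        return {k: heni_minutes(v) for k, v in self.per_component_udaly.items()}

    @property
    def per_component_minutes_udaly_sign(self) -> Dict[str, float]:
        """Per-component minutes keeping the μDALY sign (negative = beneficial)."""
        return {
            k: MINUTES_PER_UDALY * v for k, v in self.per_component_udaly.items()
        }

    @property
    def total_minutes_udaly_sign(self) -> float:
        """Minute-scaled total keeping the μDALY sign (negative = beneficial)."""
        return MINUTES_PER_UDALY * self.total_udaly


def dietary_impact(
    vector: RiskComponentVector,
    drf: DRFTable,
    *,
    reporting_basis: Optional[Basis | str] = None,
) -> HealthImpactResult:
    """Multiply amounts by Dietary Risk Factors and sum into total impact.

    Components present in ``vector`` but uncharacterized in ``drf`` are
    reported in ``result.uncharacterized`` (amount in g/FU), never silently
    dropped or folded into the DALY total. If ``reporting_basis`` is given it
    must equal the vector's basis (conversion is the composition module's
    job; a mismatch here is treated as a caller error, not silently rescaled).
    """
    if reporting_basis is not None and Basis(reporting_basis) != vector.basis:
        raise ValueError(
            f"vector is on basis {vector.basis.value!r} but reporting basis "
            f"{Basis(reporting_basis).value!r} was requested; convert the "
            "vector first"
        )
    per: Dict[str, float] = {}
    uncharacterized: Dict[str, float] = {}
    for cid, amount in vector.amounts.items():
        factor = drf.drf(cid)
        if factor is None:
            uncharacterized[cid] = amount
        else:
            per[cid] = amount * factor
    return HealthImpactResult(
        basis=vector.basis,
        per_component_udaly=per,
        total_udaly=sum(per.values()),
        uncharacterized=uncharacterized,
    )


def heni_minutes(total_udaly: float) -> float:
    """Convert μDALY/FU to HENI minutes of healthy life gained per FU.

    Strictly decreasing linear map: −0.526 × total_udaly. Damage (positive
    μDALY) becomes minutes lost (negative), benefit becomes minutes gained.
    """
    if not math.isfinite(total_udaly):
        raise ValueError(f"non-finite impact: {total_udaly}")
    return -MINUTES_PER_UDALY * total_udaly


class ContributionSplit(BaseModel):
    """Beneficial/detrimental decomposition of a health impact result."""

    model_config = {"frozen": True}

    beneficial_minutes: float
    detrimental_minutes: float
    per_component_minutes: Dict[str, float]

    @property
    def net_minutes(self) -> float:
        return self.beneficial_minutes - self.detrimental_minutes


def contribution_split(result: HealthImpactResult) -> ContributionSplit:
    """Split the HENI score into minutes gained vs minutes lost.

    ``beneficial_minutes`` sums the positive per-component minute
    contributions (gained sign), ``detrimental_minutes`` the magnitudes of
    the negative ones, so beneficial − detrimental = heni_minutes exactly.
    """
    minutes = result.per_component_minutes
    beneficial = sum(v for v in minutes.values() if v > 0)
    detrimental = -sum(v for v in minutes.values() if v < 0)
    return ContributionSplit(
        beneficial_minutes=beneficial,
        detrimental_minutes=detrimental,
        per_component_minutes=minutes,
    )


class DamageContribution(BaseModel):
    """One labeled damage-level human-health contribution (μDALY/FU)."""

    model_config = {"frozen": True}

    label: str
    udaly_per_fu: float

    @field_validator("udaly_per_fu")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError(f"non-finite damage contribution: {v}")
        return v


class CombinedDamageReport(BaseModel):
    """Dietary + environmental human-health damages, summed at damage level."""

    model_config = {"frozen": True}

    basis: Basis
    contributions: Tuple[DamageContribution, ...]
    total_udaly: float

    @property
    def total_minutes(self) -> float:
        return heni_minutes(self.total_udaly)

    @property
    def absolute_shares(self) -> Dict[str, float]:
        """Each contribution's share of the total absolute damage (sums to 1)."""
        denom = sum(abs(c.udaly_per_fu) for c in self.contributions)
        if denom == 0.0:
            return {c.label: 0.0 for c in self.contributions}
        return {c.label: abs(c.udaly_per_fu) / denom for c in self.contributions}


def combine_with_environmental(
    dietary: HealthImpactResult,
    environmental: Sequence[DamageContribution],
    *,
    environmental_basis: Optional[Basis | str] = None,
    dietary_label: str = "dietary",
) -> CombinedDamageReport:
    """Sum dietary and environmental human-health damages at damage level.

    All contributions must be expressed per the same functional unit;
    ``environmental_basis`` (default: assumed to match) is checked against the
    dietary result's basis. Labels must be unique so each contribution stays
    traceable in the combined report.
    """
    if environmental_basis is not None and Basis(environmental_basis) != dietary.basis:
        raise ValueError(
            f"environmental contributions on basis "
            f"{Basis(environmental_basis).value!r} cannot be combined with a "
            f"dietary result on basis {dietary.basis.value!r}"
        )
    contributions: List[DamageContribution] = [
        DamageContribution(label=dietary_label, udaly_per_fu=dietary.total_udaly)
    ]
    contributions.extend(environmental)
    labels = [c.label for c in contributions]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate contribution labels: {dupes}")
    return CombinedDamageReport(
        basis=dietary.basis,
        contributions=tuple(contributions),
        total_udaly=sum(c.udaly_per_fu for c in contributions),
    )


__all__ = [
    "MINUTES_PER_UDALY",
    "StratumDRF",
    "DRFTable",
    "HealthImpactResult",
    "dietary_impact",
    "heni_minutes",
    "ContributionSplit",
    "contribution_split",
    "DamageContribution",
    "CombinedDamageReport",
    "combine_with_environmental",
]
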