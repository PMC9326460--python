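"""Non-marginal dietary changes via multiplicative attributable fractions.

Marginal DRFs characterize small intake perturbations around the current
diet. For substantial dietary shifts the attributable fractions of the risk
factors sharing a disease outcome must be combined multiplicatively,

    PAF_combined = 1 − Π_i (1 − PAF_i),

and outcome-level attributable burdens summed. :func:`diet_delta` evaluates
a :class:`DietScenario` — a set of signed mean-intake shifts — against
baseline intake distributions, returning the change in attributable burden
(ΔDALY per person-year). For a single small shift δ it converges to
marginal_drf × δ × 365 / 10⁶, which is the consistency check between the
marginal and multiplicative routes.

:func:`active_range_report` reports how much of the population sits outside
the TMREL range — the "active range" where marginal consumption changes
actually alter risk — so users can see when marginal characterization is
inapplicable.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .epi import (
    BurdenRate,
    DistributionKind,
    IntakeDistribution,
    RRCurve,
    TMRELRange,
    paf,
)
from .registry import check_component


class DietScenario(BaseModel):
    """Signed changes in mean daily intake (g/day) per risk component."""

    model_config = {"frozen": True}

    name: str
    intake_shifts: Dict[str, float] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _valid_shifts(self) -> "DietScenario":
        for cid, shift in self.intake_shifts.items():
            check_component(cid)
            if not math.isfinite(shift):
                raise ValueError(f"non-finite intake shift for {cid!r}: {shift}")
        return self


def multiplicative_combined_paf(pafs: Sequence[float]) -> float:
    """Combine attributable fractions of co-acting risk factors.

    1 − Π(1 − PAF_i): order-invariant, 0 for an empty list, identical to the
    single PAF for one element, and subadditive for non-negative inputs.
    Rejects any PAF ≥ 1 (total attribution leaves nothing to combine).
    """
    for p in pafs:
        if not math.isfinite(p):
            raise ValueError(f"non-finite PAF: {p}")
        if p >= 1.0:
            raise ValueError(f"PAF ≥ 1 is degenerate (total attribution): {p}")
    prod = 1.0
    for p in pafs:
        prod *= 1.0 - p
    return 1.0 - prod


def _outcome_pools(
    burdens: Mapping[str, Sequence[BurdenRate]], components: Iterable[str]
) -> Tuple[Dict[str, float], Dict[str, List[str]]]:
    """Per-outcome burden pool (DALY/person-year) and affecting components.

    Rates for an outcome are summed over strata within each component; the
    pooled rate must agree across all components naming the outcome, since
    it describes one and the same disease-burden pool.
    """
    pools: Dict[str, float] = {}
    members: Dict[str, List[str]] = {}
    for cid in components:
        per_outcome: Dict[str, float] = {}
        for b in burdens[cid]:
            per_outcome[b.outcome] = per_outcome.get(b.outcome, 0.0) + b.rate
        for outcome, rate in per_outcome.items():
            if outcome in pools:
                ref = pools[outcome]
                if abs(rate - ref) > 1e-9 * max(1.0, abs(ref)):
                    raise ValueError(
                        f"inconsistent burden pool for outcome {outcome!r}: "
                        f"{rate} vs {ref} (one pool per outcome)"
                    )
            else:
                pools[outcome] = rate
            members.setdefault(outcome, []).append(cid)
    return pools, members


def diet_delta(
    baseline: Mapping[str, IntakeDistribution],
    scenario: DietScenario,
    curves: Mapping[str, RRCurve],
    burdens: Mapping[str, Sequence[BurdenRate]],
) -> float:
    """Change in attributable burden under a diet scenario (ΔDALY/person-year).

    Within each outcome the attributable fractions of its risk factors are
    combined multiplicatively (baseline and shifted alike); outcome-level
    attributable burdens are summed; Δ is shifted minus baseline. Components
    affecting disjoint outcomes therefore contribute additively, and a null
    scenario gives exactly 0.

    Every shifted component must come with a baseline distribution, an RR
    curve, and burden rates.
    """
    for cid in scenario.intake_shifts:
        if cid not in baseline:
            raise KeyError(f"scenario shifts {cid!r} but no baseline intake given")
        if cid not in curves:
            raise KeyError(f"scenario shifts {cid!r} but no RR curve given")
        if cid not in burdens:
            raise KeyError(f"scenario shifts {cid!r} but no burden rates given")

    components = [c for c in baseline if c in curves and c in burdens]
    pools, members = _outcome_pools(burdens, components)

    base_paf: Dict[str, float] = {}
    shift_paf: Dict[str, float] = {}
    for cid in components:
        dist = baseline[cid]
        base_paf[cid] = paf(curves[cid], dist)
        delta = scenario.intake_shifts.get(cid, 0.0)
        if delta == 0.0:
            shift_paf[cid] = base_paf[cid]
        else:
            shifted, _ = dist.shifted(delta)
            shift_paf[cid] = paf(curves[cid], shifted)

    total = 0.0
    for outcome, pool in pools.items():
        cids = members[outcome]
        ab_base = multiplicative_combined_paf([base_paf[c] for c in cids]) * pool
        ab_shift = multiplicative_combined_paf([shift_paf[c] for c in cids]) * pool
        total += ab_shift - ab_base
    return total


def active_range_report(dist: IntakeDistribution, tmrel: TMRELRange) -> float:
    """Fraction of the population outside the TMREL (in the active range).

    This is the probability mass at intakes below ``tmrel.low`` or above
    ``tmrel.high`` — the share of the population for which a marginal
    consumption change actually changes risk. Report it alongside any
    marginal score: near 0, marginal characterization is inapplicable.
    """
    lo, hi = tmrel.low, tmrel.high
    if dist.kind == DistributionKind.POINT:
        return 0.0 if tmrel.contains(dist.point_intake) else 1.0
    if dist.kind == DistributionKind.HISTOGRAM:
        e = np.asarray(dist.bin_edges, dtype=float)
        p = np.asarray(dist.bin_probs, dtype=float)
        inside = 0.0
        for a, b, prob in zip(e[:-1], e[1:], p):
            overlap = max(0.0, min(b, hi) - max(a, lo))
            width = b - a
            inside += prob * (overlap / width if width > 0 else 0.0)
        return float(max(0.0, 1.0 - inside))
    frozen = stats.lognorm(
        s=dist.sigma, scale=math.exp(dist.mu), loc=dist.shift
    )
    # intake = max(X, 0): clamped mass sits at 0, inside iff low ≤ 0
    upper_cdf = float(frozen.cdf(hi)) if math.isfinite(hi) else 1.0
    lower_cdf = float(frozen.cdf(lo)) if lo > 0 else 0.0
    return float(max(0.0, 1.0 - (upper_cdf - lower_cdf)))


__all__ = [
    "DietScenario",
    "multiplicative_combined_paf",
    "diet_delta",
    "active_range_report",
]
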