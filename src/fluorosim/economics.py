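"""Costs, QALY decrements, national scaling and incremental outcomes.

All costs are 2024 USD from a health-care-sector perspective. Disutility
weights are annual QALY decrements for being in a disease state; within a
cycle they add (capped at one whole QALY). Per-capita outcomes are scaled
to national counts through the survey weights, which sum to the configured
national child population (default 80 million, ages 0-19).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .parameters import ParameterSet

__all__ = [
    "IncrementalResult",
    "cycle_cost",
    "cycle_disutility",
    "scale_to_national",
]


@dataclass
class IncrementalResult:
    """National, discounted scenario-minus-reference differences.

    QALY losses are negative (a scenario that harms health has
    ``d_qalys < 0``); costs are positive when the scenario costs more.
    ``cost_components`` decomposes ``d_cost_usd`` exactly into
    restoration / complication / fluorosis / program parts.
    """

    scenario: str
    reference: str
    protection_model: str
    horizon_years: int
    d_prevalence_pp: float
    d_decayed_teeth: float
    d_fluorosis: float
    d_qalys: float
    d_cost_usd: float
    national_population: float
    n: int
    seed: int
    cost_components: dict[str, float] = field(default_factory=dict)
    by_insurance: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "scenario": self.scenario,
            "reference": self.reference,
            "protection_model": self.protection_model,
            "horizon_years": self.horizon_years,
            "d_prevalence_pp": self.d_prevalence_pp,
            "d_decayed_teeth": self.d_decayed_teeth,
            "d_fluorosis": self.d_fluorosis,
            "d_qalys": self.d_qalys,
            "d_cost_usd": self.d_cost_usd,
        }
        return d


def cycle_cost(
    events: Mapping[str, float], params: ParameterSet, n_protected_capita: float = 0.0
) -> float:
    """Undiscounted cost of one cycle's events.

    ``events`` maps event names to counts: ``treated_caries`` (restorative
    visit: examination + restoration), ``abscess``, ``extraction``,
    ``fluorosis_onset`` (one-off cosmetic restoration). The fluoridation
    program charges its annual per-capita cost for every person whose water
    system fluoridates under the scenario.
    """
    cost = events.get("treated_caries", 0) * (params.cost_exam + params.cost_caries)
    cost += events.get("abscess", 0) * params.cost_abscess
    cost += events.get("extraction", 0) * params.cost_extraction
    cost += events.get("fluorosis_onset", 0) * params.cost_fluorosis
    cost += params.fluoridation_cost_per_capita_yr * n_protected_capita
    return float(cost)


def cycle_disutility(state, params: ParameterSet) -> float:
    """QALY decrement for one child-cycle, additive across states, capped
    at 1.0.

    ``state`` needs boolean attributes ``active_caries`` (a decayed tooth
    incident this cycle, or an untreated one still in the mouth),
    ``abscess_this_cycle``, and ``any_tooth_lost`` (chronic from the
    extraction cycle onward).
    """
    du = 0.0
    if getattr(state, "active_caries", False):
        du += params.disutility_caries
    if getattr(state, "abscess_this_cycle", False):
        du += params.disutility_abscess
    if getattr(state, "any_tooth_lost", False):
        du += params.disutility_toothloss
    return min(du, 1.0)


def scale_to_national(per_capita: float, national_population: float) -> float:
    """Scale a per-capita mean to a national total."""
    if national_population <= 0:
        raise ValueError("national_population must be > 0")
    return per_capita * national_population
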