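"""Convert intervention effect rates into unrounded annual outcome deltas.

Each effect rate is a proportion of the intervention's target-group size, so a
delta is simply ``rate x denominator``: spontaneous pregnancies gained, ART
cycles avoided per modality, complication cases avoided per type.  Outcomes
with no published evidence are structurally zero.

``display_round`` implements the publication's printing convention (nearest
multiple of a resolution, ties away from zero); it is used by reporting and by
the audit, never inside the arithmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort_model import BaselineVolumes
from .config_io import EffectSpec, PopulationSpec, Scenario, TargetGroup

__all__ = [
    "DeltaOutcomes",
    "InfeasibleEffectError",
    "apply_intervention",
    "display_round",
    "resolve_target_group",
]


class InfeasibleEffectError(ValueError):
    """An effect would avoid more cycles than the baseline performs."""


@dataclass(frozen=True)
class DeltaOutcomes:
    """Unrounded annual changes attributable to one intervention.

    All magnitudes are non-negative; direction is fixed by semantics (gains for
    spontaneous pregnancies, reductions for cycles and complications).  Outcomes
    without published evidence are absent from the maps (``spontaneous_gain`` is
    ``None``); an explicit zero rate yields an explicit 0.0 delta.
    ``complication_denominators`` records the denominator used per complication,
    which may differ from ``denominator_used`` for combined programs.
    """

    spontaneous_gain: float | None
    cycles_avoided: dict[str, float]
    complications_avoided: dict[str, float]
    denominator_used: float
    complication_denominators: dict[str, float]


_GROUP_FIELD: dict[TargetGroup, str] = {
    "whole-cohort": "n_couples",
    "obese-subset": "n_obese_women",
    "smoking-men": "n_smoking_men",
    "first-cycle-women": "n_first_cycle_women",
}


def resolve_target_group(group: TargetGroup, population: PopulationSpec) -> int:
    """Size of the named target group in the model population."""
    try:
        field = _GROUP_FIELD[group]
    except KeyError:
        raise ValueError(f"unknown target group: {group!r}") from None
    return getattr(population, field)


def display_round(x: float, resolution: float) -> float:
    """Round to the nearest multiple of ``resolution``, ties away from zero.

    Idempotent; this is purely a printing convention.
    """
    if resolution <= 0:
        raise ValueError(f"resolution must be > 0 (got {resolution})")
    return math.copysign(math.floor(abs(x) / resolution + 0.5) * resolution, x)


def apply_intervention(
    effect: EffectSpec,
    population: PopulationSpec,
    baseline: BaselineVolumes,
    scenario: Scenario = "central",
) -> DeltaOutcomes:
    """Annual outcome deltas of one intervention at one scenario point.

    Deltas are linear: ``rate x denominator-group size``.  Modalities or
    complications without an entry in the effect maps yield exactly 0.  Raises
    :class:`InfeasibleEffectError` if an avoided-cycle count would exceed the
    baseline volume for that modality.
    """
    denom = float(resolve_target_group(effect.denominator_group, population))

    spont = (
        effect.uplift_spontaneous.get(scenario) * denom
        if effect.uplift_spontaneous is not None
        else None
    )

    cycles: dict[str, float] = {}
    for m, rate in effect.reduction_rate.items():
        avoided = rate.get(scenario) * denom
        if avoided > baseline.cycles_per_modality[m] + 1e-9:
            raise InfeasibleEffectError(
                f"{effect.intervention_id}: {avoided:.1f} avoided {m} cycles exceed "
                f"the baseline volume {baseline.cycles_per_modality[m]:.1f}"
            )
        cycles[m] = avoided

    comps: dict[str, float] = {}
    comp_denoms: dict[str, float] = {}
    for c, rate in effect.complication_reduction.items():
        group = effect.complication_denominator.get(c, effect.denominator_group)
        cdenom = float(resolve_target_group(group, population))
        comps[c] = rate.get(scenario) * cdenom
        comp_denoms[c] = cdenom

    return DeltaOutcomes(
        spontaneous_gain=spont,
        cycles_avoided=cycles,
        complications_avoided=comps,
        denominator_used=denom,
        complication_denominators=comp_denoms,
    )
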