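"""Baseline annual ART activity for the model population, before any intervention.

The cohort is modelled at the mean: ``share[m] * n_couples`` couples per modality,
each receiving ``mean_cycles[m]`` cycles.  Volumes are kept as exact real numbers;
rounding is strictly a display concern (published percentages only reconcile with
unrounded intermediates).
"""

from __future__ import annotations

from dataclasses import dataclass

from .config_io import PopulationSpec, TreatmentMixSpec

__all__ = ["BaselineVolumes", "baseline_volumes"]


@dataclass(frozen=True)
class BaselineVolumes:
    """Annual couples and ART cycles per modality, unrounded."""

    couples_per_modality: dict[str, float]
    cycles_per_modality: dict[str, float]
    total_cycles: float


def baseline_volumes(
    population: PopulationSpec, mix: TreatmentMixSpec
) -> BaselineVolumes:
    """Annual treatment volumes implied by the population and treatment mix.

    Exact products, no rounding: ``couples[m] = share[m] * n_couples`` and
    ``cycles[m] = couples[m] * mean_cycles[m]``.
    """
    couples = {m: mix.share[m] * population.n_couples for m in mix.modalities}
    cycles = {m: couples[m] * mix.mean_cycles[m] for m in mix.modalities}
    return BaselineVolumes(
        couples_per_modality=couples,
        cycles_per_modality=cycles,
        total_cycles=sum(cycles.values()),
    )
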