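"""Scenario propagation (least/central/most) and Monte Carlo sensitivity analysis.

The two-point bound propagation mirrors the published sensitivity analysis:
every uncertain quantity sits at its pessimistic or optimistic value and the
deterministic model is re-evaluated.  Interventions are treated independently
(no shared-parameter correlation), matching the per-row bounds.

``run_psa`` extends the two-point bounds to a probabilistic analysis: per-couple
benefits are drawn independently per intervention from a uniform or triangular
distribution on [least, most] (triangular mode at central).  Each intervention
gets its own deterministic child stream of the root seed, so adding an
intervention never perturbs another's draws.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .cohort_model import BaselineVolumes, baseline_volumes
from .config_io import SCENARIOS, ModelConfig, Scenario
from .costing import (
    CostResult,
    cost_result_from_deltas,
    cost_result_from_printed,
)
from .effects import DeltaOutcomes, apply_intervention, resolve_target_group

__all__ = [
    "BenefitMode",
    "InterventionResult",
    "ScenarioResult",
    "PsaSummary",
    "PsaResult",
    "run_scenarios",
    "run_psa",
]

BenefitMode = Literal["printed-benefit", "computed-from-deltas"]
Distribution = Literal["uniform", "triangular"]


@dataclass(frozen=True)
class InterventionResult:
    """Deltas and savings for one intervention at all three scenario points."""

    intervention_id: str
    group_size: int
    deltas: dict[Scenario, DeltaOutcomes]
    cost: CostResult


@dataclass(frozen=True)
class ScenarioResult:
    baseline: BaselineVolumes
    interventions: dict[str, InterventionResult]
    mode: BenefitMode


def run_scenarios(
    config: ModelConfig, mode: BenefitMode = "printed-benefit"
) -> ScenarioResult:
    """Evaluate effects and costing at least/central/most for every intervention.

    Deterministic.  In ``printed-benefit`` mode the per-couple benefit triples
    (and ART-only triples, when a printed table block is present) are taken as
    primitive inputs; in ``computed-from-deltas`` mode they are derived from the
    unit costs.
    """
    baseline = baseline_volumes(config.population, config.mix)
    results: dict[str, InterventionResult] = {}
    for effect in config.effects:
        iid = effect.intervention_id
        group = resolve_target_group(effect.target_group, config.population)
        deltas = {
            s: apply_intervention(effect, config.population, baseline, s)
            for s in SCENARIOS
        }
        if mode == "printed-benefit":
            try:
                pcb_triple = config.per_couple_benefit_printed[iid]
            except KeyError:
                raise ValueError(
                    f"printed-benefit mode needs per_couple_benefit_printed[{iid}]"
                ) from None
            pcb = {s: pcb_triple.get(s) for s in SCENARIOS}
            if config.printed is not None and iid in config.printed.table4:
                art_t = config.printed.table4[iid].art
                art = dict(zip(SCENARIOS, art_t))
            else:
                computed = cost_result_from_deltas(deltas, config.costs[iid], group)
                art = computed.art_only_saving
            cost = cost_result_from_printed(pcb, art, group)
        elif mode == "computed-from-deltas":
            cost = cost_result_from_deltas(deltas, config.costs[iid], group)
        else:
            raise ValueError(f"unknown benefit mode: {mode!r}")
        results[iid] = InterventionResult(
            intervention_id=iid, group_size=group, deltas=deltas, cost=cost
        )
    return ScenarioResult(baseline=baseline, interventions=results, mode=mode)


# --------------------------------------------------------------------------
# Probabilistic sensitivity analysis


@dataclass(frozen=True)
class PsaSummary:
    """Empirical summaries of annual total saving (EUR) for one intervention."""

    group_size: int
    mean: float
    sd: float
    q2_5: float
    q97_5: float
    min: float
    max: float

    @property
    def per_couple_mean(self) -> float:
        return self.mean / self.group_size


@dataclass(frozen=True)
class PsaResult:
    n_draws: int
    seed: int
    distribution: Distribution
    interventions: dict[str, PsaSummary]


def _child_rng(seed: int, intervention_id: str) -> np.random.Generator:
    # stable, collision-resistant per-intervention stream independent of
    # iteration order and of the other interventions present
    digest = hashlib.sha256(intervention_id.encode("utf-8")).digest()
    key = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, key]))


def run_psa(
    config: ModelConfig,
    n_draws: int,
    seed: int,
    distribution: Distribution = "uniform",
) -> PsaResult:
    """Monte Carlo propagation of per-couple benefit uncertainty.

    Per-couple benefits are sampled on [least, most] per intervention (mode at
    central for the triangular option) and multiplied by the group size.
    Reproducible: identical (seed, n_draws, distribution) give identical output.
    """
    if n_draws < 1:
        raise ValueError(f"n_draws must be >= 1 (got {n_draws})")
    if distribution not in ("uniform", "triangular"):
        raise ValueError(f"unknown distribution: {distribution!r}")

    summaries: dict[str, PsaSummary] = {}
    for effect in config.effects:
        iid = effect.intervention_id
        try:
            triple = config.per_couple_benefit_printed[iid]
        except KeyError:
            raise ValueError(
                f"PSA needs per_couple_benefit_printed[{iid}]"
            ) from None
        lo, mid, hi = triple.as_tuple()
        group = resolve_target_group(effect.target_group, config.population)
        rng = _child_rng(seed, iid)
        if hi == lo:
            draws = np.full(n_draws, mid)
        elif distribution == "uniform":
            draws = rng.uniform(lo, hi, size=n_draws)
        else:
            draws = rng.triangular(lo, mid, hi, size=n_draws)
        totals = draws * group
        summaries[iid] = PsaSummary(
            group_size=group,
            mean=float(np.mean(totals)),
            sd=float(np.std(totals, ddof=1)) if n_draws > 1 else 0.0,
            q2_5=float(np.percentile(totals, 2.5)),
            q97_5=float(np.percentile(totals, 97.5)),
            min=float(np.min(totals)),
            max=float(np.max(totals)),
        )
    return PsaResult(
        n_draws=n_draws, seed=seed, distribution=distribution, interventions=summaries
    )
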