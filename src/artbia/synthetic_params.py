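"""Seeded generation of random valid parameter sets, for property testing.

The generator emulates the structure the analysis assumes - a cohort with
subgroups, a treatment mix summing to one, ordered (least, central, most)
effect triples, non-negative unit costs - while every cardinality (number of
interventions, modalities, complication types) is a parameter.  Generated
configs are self-consistent: the per-couple benefit triples and the "printed"
table block are produced by running the model itself, so a self-audit matches
every cell.

Boundary cases appear with positive probability: zero-effect interventions,
degenerate scenario triples, and program costs exceeding gross savings
(negative benefit).  Ranges are test scaffolding, not realistic cost surveys.
"""

from __future__ import annotations

import copy
from typing import Optional

import numpy as np
from pydantic import Field, field_validator, model_validator

from .config_io import (
    SCENARIOS,
    CellAnomaly,
    ConfigValidationError,
    CostSpec,
    DisplayConvention,
    EffectSpec,
    ModelConfig,
    PopulationSpec,
    PrintedCell,
    PrintedTable4Row,
    PrintedTables,
    TargetGroup,
    TreatmentMixSpec,
    Triple,
    _Base,
)
from .effects import display_round
from .scenarios import run_scenarios

__all__ = ["GeneratorSpec", "generate_config", "perturb_config", "FieldPathError"]

_GROUPS: tuple[TargetGroup, ...] = (
    "whole-cohort",
    "obese-subset",
    "smoking-men",
    "first-cycle-women",
)

_DEFAULT_MODALITIES = ("IVF", "ICSI", "IUI")
_DEFAULT_COMPLICATIONS = (
    "IUGR",
    "gestational_diabetes",
    "hypertensive",
    "preterm",
)


class GeneratorSpec(_Base):
    """Knobs for the random config generator; defaults mirror the shipped study shape."""

    seed: int = Field(ge=0)
    n_couples_range: tuple[int, int] = (1000, 100000)
    n_interventions: int = Field(default=5, ge=1)
    n_modalities: int = Field(default=3, ge=1)
    n_complications: int = Field(default=4, ge=0)
    rate_ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "uplift": (0.0, 0.3),
            "reduction": (0.0, 0.2),
            "complication": (0.0, 0.1),
        }
    )
    cost_ranges: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {
            "cycle": (500.0, 5000.0),
            "complication": (1000.0, 30000.0),
            "intervention": (0.0, 600.0),
        }
    )
    bound_spread: float = Field(default=0.5, ge=0.0)
    p_zero_effect: float = Field(default=0.1, ge=0.0, le=1.0)
    p_degenerate_bounds: float = Field(default=0.15, ge=0.0, le=1.0)
    p_costly_intervention: float = Field(default=0.1, ge=0.0, le=1.0)
    include_printed: bool = True

    @field_validator("n_couples_range")
    @classmethod
    def _couples_range(cls, v: tuple[int, int]) -> tuple[int, int]:
        lo, hi = v
        if not (1 <= lo <= hi):
            raise ValueError(f"n_couples_range must satisfy 1 <= lo <= hi (got {v})")
        return v

    @model_validator(mode="after")
    def _ranges_ordered(self) -> "GeneratorSpec":
        for key in ("uplift", "reduction", "complication"):
            lo, hi = self.rate_ranges[key]
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(
                    f"rate_ranges[{key}]={lo, hi} must satisfy 0 <= lo <= hi <= 1"
                )
        for key in ("cycle", "complication", "intervention"):
            lo, hi = self.cost_ranges[key]
            if not (0.0 <= lo <= hi):
                raise ValueError(
                    f"cost_ranges[{key}]={lo, hi} must satisfy 0 <= lo <= hi"
                )
        return self


def _names(prefix: str, defaults: tuple[str, ...], n: int) -> list[str]:
    if n == len(defaults):
        return list(defaults)
    return [f"{prefix}{i + 1}" for i in range(n)]


def _triple(
    rng: np.random.Generator, central: float, spread: float, cap: float, p_degen: float
) -> Triple:
    central = min(central, cap)
    if rng.random() < p_degen:
        return Triple.constant(central)
    least = central * (1.0 - spread * rng.random())
    most = min(central * (1.0 + spread * rng.random()), cap)
    most = max(most, central)
    return Triple(least=least, central=central, most=most)


def generate_config(spec: GeneratorSpec) -> ModelConfig:
    """Draw a fully validated, self-consistent :class:`ModelConfig`.

    Deterministic per ``spec.seed``: identical specs give identical configs.
    """
    rng = np.random.default_rng(spec.seed)
    modalities = _names("MOD", _DEFAULT_MODALITIES, spec.n_modalities)
    complications = _names("COMP", _DEFAULT_COMPLICATIONS, spec.n_complications)

    lo, hi = spec.n_couples_range
    n_couples = int(rng.integers(lo, hi + 1))
    population = PopulationSpec(
        n_couples=n_couples,
        n_obese_women=int(rng.integers(1, n_couples + 1)),
        n_smoking_men=int(rng.integers(1, n_couples + 1)),
        n_first_cycle_women=int(rng.integers(1, n_couples + 1)),
        incidence_annual=int(rng.integers(0, n_couples + 1)),
        prevalence_men=float(rng.uniform(0.0, 0.05)),
        prevalence_women=float(rng.uniform(0.0, 0.05)),
    )

    weights = rng.uniform(0.05, 1.0, size=len(modalities))
    shares = (weights / weights.sum()).tolist()
    shares[-1] = 1.0 - sum(shares[:-1])  # exact sum-to-one
    mix = TreatmentMixSpec(
        share=dict(zip(modalities, shares)),
        mean_cycles={m: float(rng.uniform(1.0, 4.0)) for m in modalities},
    )
    cycles_per_modality = {
        m: mix.share[m] * n_couples * mix.mean_cycles[m] for m in modalities
    }

    group_sizes = {
        "whole-cohort": population.n_couples,
        "obese-subset": population.n_obese_women,
        "smoking-men": population.n_smoking_men,
        "first-cycle-women": population.n_first_cycle_women,
    }

    effects: list[EffectSpec] = []
    costs: dict[str, CostSpec] = {}
    for i in range(spec.n_interventions):
        iid = f"intervention_{i:02d}"
        group: TargetGroup = _GROUPS[int(rng.integers(0, len(_GROUPS)))]
        denom = group_sizes[group]
        zero = rng.random() < spec.p_zero_effect

        uplift: Optional[Triple] = None
        if zero or rng.random() < 0.8:
            c = 0.0 if zero else float(rng.uniform(*spec.rate_ranges["uplift"]))
            uplift = _triple(rng, c, spec.bound_spread, 1.0, spec.p_degenerate_bounds)

        reduction: dict[str, Triple] = {}
        for m in modalities:
            if not (zero or rng.random() < 0.75):
                continue
            cap = min(1.0, cycles_per_modality[m] / denom)
            c = 0.0 if zero else float(rng.uniform(*spec.rate_ranges["reduction"]))
            reduction[m] = _triple(
                rng, c, spec.bound_spread, cap, spec.p_degenerate_bounds
            )

        comp_rates: dict[str, Triple] = {}
        comp_denoms: dict[str, TargetGroup] = {}
        for comp in complications:
            if not (zero or rng.random() < 0.6):
                continue
            c = 0.0 if zero else float(rng.uniform(*spec.rate_ranges["complication"]))
            comp_rates[comp] = _triple(
                rng, c, spec.bound_spread, 1.0, spec.p_degenerate_bounds
            )
            if rng.random() < 0.25:
                comp_denoms[comp] = _GROUPS[int(rng.integers(0, len(_GROUPS)))]

        effect = EffectSpec(
            intervention_id=iid,
            target_group=group,
            uplift_spontaneous=uplift,
            reduction_rate=reduction,
            complication_reduction=comp_rates,
            complication_denominator=comp_denoms,
        )
        effects.append(effect)

        cycle_costs = {
            m: float(rng.uniform(*spec.cost_ranges["cycle"])) for m in modalities
        }
        comp_costs = {
            c: float(rng.uniform(*spec.cost_ranges["complication"]))
            for c in comp_rates
        }
        gross_central = sum(
            reduction[m].central * denom * cycle_costs[m] for m in reduction
        ) + sum(
            comp_rates[c].central
            * group_sizes[comp_denoms.get(c, group)]
            * comp_costs[c]
            for c in comp_rates
        )
        if rng.random() < spec.p_costly_intervention:
            # program cost exceeding gross savings: negative benefit on purpose
            program = gross_central / denom * float(rng.uniform(1.1, 2.0)) + float(
                rng.uniform(0.0, 100.0)
            )
        else:
            program = float(rng.uniform(*spec.cost_ranges["intervention"]))
        provenance = {
            **{f"unit_cost_cycle.{m}": "assumption" for m in cycle_costs},
            **{f"unit_cost_complication.{c}": "assumption" for c in comp_costs},
            "intervention_cost_per_couple": "assumption",
            "eur_to_usd_rate": "assumption",
        }
        costs[iid] = CostSpec(
            unit_cost_cycle=cycle_costs,
            unit_cost_complication=comp_costs,
            intervention_cost_per_couple=program,
            eur_to_usd_rate=float(rng.uniform(0.8, 1.5)),
            provenance=provenance,
        )

    config = ModelConfig(
        population=population,
        mix=mix,
        effects=effects,
        costs=costs,
        display=DisplayConvention(),
    )

    # Derive per-couple benefit triples (and, optionally, a self-consistent
    # "printed" block) by running the model itself.
    computed = run_scenarios(config, mode="computed-from-deltas")
    pcb_printed = {
        iid: Triple(
            least=ir.cost.per_couple_benefit["least"],
            central=ir.cost.per_couple_benefit["central"],
            most=ir.cost.per_couple_benefit["most"],
        )
        for iid, ir in computed.interventions.items()
    }
    printed = _self_printed(computed, config.display) if spec.include_printed else None
    return ModelConfig(
        population=population,
        mix=mix,
        effects=effects,
        costs=costs,
        per_couple_benefit_printed=pcb_printed,
        display=config.display,
        printed=printed,
    )


def _self_printed(computed, display: DisplayConvention) -> PrintedTables:
    """Table cells as the model itself would print them (audit-self all-match)."""

    def cell(delta: float, denom: float) -> PrintedCell:
        return PrintedCell(
            count=display_round(delta, display.count_resolution),
            pct=round(delta / denom * 100.0, 1),
        )

    table2: dict[str, dict[str, PrintedCell]] = {}
    table3: dict[str, dict[str, PrintedCell]] = {}
    table4: dict[str, PrintedTable4Row] = {}
    for iid, ir in computed.interventions.items():
        d = ir.deltas["central"]
        t2: dict[str, PrintedCell] = {}
        if d.spontaneous_gain is not None:
            t2["spontaneous"] = cell(d.spontaneous_gain, d.denominator_used)
        for m, v in d.cycles_avoided.items():
            t2[m] = cell(v, d.denominator_used)
        if t2:
            table2[iid] = t2
        t3 = {
            c: cell(v, d.complication_denominators[c])
            for c, v in d.complications_avoided.items()
        }
        if t3:
            table3[iid] = t3
        totals = tuple(ir.cost.total_saving[s] for s in SCENARIOS)
        resolutions = tuple(display.money_resolution(t) for t in totals)
        table4[iid] = PrintedTable4Row(
            per_couple=tuple(ir.cost.per_couple_benefit[s] for s in SCENARIOS),
            group_size=ir.group_size,
            incidence=0,
            total=tuple(display_round(t, r) for t, r in zip(totals, resolutions)),
            total_resolution=resolutions,
            art=tuple(ir.cost.art_only_saving[s] for s in SCENARIOS),
            art_resolution=resolutions,
        )
    return PrintedTables(
        table2=table2, table3=table3, table4=table4, anomalies=[]
    )


class FieldPathError(ValueError):
    """A perturbation addressed a field that does not exist."""


def _navigate(data, segments: list[str], path: str):
    node = data
    for seg in segments[:-1]:
        node = _step(node, seg, path)
    return node, segments[-1]


def _step(node, seg: str, path: str):
    if isinstance(node, dict):
        if seg not in node:
            raise FieldPathError(f"unknown field path {path!r}: no key {seg!r}")
        return node[seg]
    if isinstance(node, list):
        # lists of effects may be addressed by index or by intervention_id
        if seg.isdigit() and int(seg) < len(node):
            return node[int(seg)]
        for item in node:
            if isinstance(item, dict) and item.get("intervention_id") == seg:
                return item
        raise FieldPathError(f"unknown field path {path!r}: no element {seg!r}")
    raise FieldPathError(f"unknown field path {path!r}: cannot descend into {type(node).__name__}")


def perturb_config(config: ModelConfig, field_path: str, delta: float) -> ModelConfig:
    """Return a copy of ``config`` with one numeric leaf shifted by ``delta``.

    The path is dot-separated (``costs.lifestyle.unit_cost_cycle.IVF``;
    list elements may be addressed by index or intervention id).  The perturbed
    copy is re-validated, so a perturbation that breaks an invariant raises
    :class:`~artbia.config_io.ConfigValidationError`; the original is untouched.
    """
    data = copy.deepcopy(config.model_dump(mode="python"))
    parent, leaf = _navigate(data, field_path.split("."), field_path)
    if isinstance(parent, dict):
        if leaf not in parent:
            raise FieldPathError(f"unknown field path {field_path!r}: no key {leaf!r}")
        old = parent[leaf]
        if not isinstance(old, (int, float)) or isinstance(old, bool):
            raise FieldPathError(
                f"field {field_path!r} is not numeric (got {type(old).__name__})"
            )
        parent[leaf] = old + delta
    elif isinstance(parent, list) and leaf.isdigit() and int(leaf) < len(parent):
        idx = int(leaf)
        old = parent[idx]
        if not isinstance(old, (int, float)) or isinstance(old, bool):
            raise FieldPathError(
                f"field {field_path!r} is not numeric (got {type(old).__name__})"
            )
        parent[idx] = old + delta
    else:
        raise FieldPathError(f"unknown field path {field_path!r}")
    from pydantic import ValidationError

    try:
        return ModelConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigValidationError.from_pydantic(exc) from exc
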