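"""Turn outcome deltas into per-couple and total annual cost savings.

The business case per couple is

    benefit = (sum_m cycles_avoided[m] * cost_cycle[m]
               + sum_c complications_avoided[c] * cost_complication[c]) / group
              - program_cost_per_couple

and the annual population saving is the exact product ``benefit * group``.  A
negative benefit is legal: a cheap effect can be outweighed by the program cost.

Two sources for per-couple benefits coexist: ``computed-from-deltas`` (derived
from unit costs, which for the shipped fixture are assumption-tagged) and
``printed-benefit`` (published per-couple values taken as primitive; the
reconciliation surface, since the publication omits its unit costs).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .config_io import SCENARIOS, CostSpec, Scenario
from .effects import DeltaOutcomes, display_round

__all__ = [
    "CostResult",
    "per_couple_benefit",
    "art_only_per_couple",
    "total_saving",
    "eur_to_usd",
]


@dataclass(frozen=True)
class CostResult:
    """Savings for one intervention across the three scenario points (EUR)."""

    per_couple_benefit: dict[Scenario, float]
    total_saving: dict[Scenario, float]
    art_only_saving: dict[Scenario, float]
    group_size: int
    source: Literal["computed-from-deltas", "printed-benefit"]

    def ordered(self) -> bool:
        """True if every saving respects least <= central <= most."""
        return all(
            d["least"] <= d["central"] <= d["most"]
            for d in (self.per_couple_benefit, self.total_saving, self.art_only_saving)
        )


def per_couple_benefit(
    delta: DeltaOutcomes, costs: CostSpec, group_size: int
) -> float:
    """Net annual saving per couple in the target group; may be negative."""
    if group_size <= 0:
        raise ValueError(f"group_size must be > 0 (got {group_size})")
    gross = sum(
        n * costs.unit_cost_cycle[m] for m, n in delta.cycles_avoided.items()
    )
    gross += sum(
        n * costs.unit_cost_complication[c]
        for c, n in delta.complications_avoided.items()
    )
    return gross / group_size - costs.intervention_cost_per_couple


def art_only_per_couple(
    delta: DeltaOutcomes, costs: CostSpec, group_size: int
) -> float:
    """The avoided-treatment term alone (no complications, no program cost)."""
    if group_size <= 0:
        raise ValueError(f"group_size must be > 0 (got {group_size})")
    return (
        sum(n * costs.unit_cost_cycle[m] for m, n in delta.cycles_avoided.items())
        / group_size
    )


def total_saving(per_couple: float, group_size: int) -> float:
    """Annual saving for the whole target group: exact product."""
    return per_couple * group_size


def eur_to_usd(amount_eur: float, rate: float) -> float:
    """Convert to USD at the given rate, rounded to cents (display only)."""
    if rate <= 0:
        raise ValueError(f"exchange rate must be > 0 (got {rate})")
    return display_round(amount_eur * rate, 0.01)


def cost_result_from_printed(
    per_couple: dict[Scenario, float],
    art_only: dict[Scenario, float],
    group_size: int,
) -> CostResult:
    """Assemble a :class:`CostResult` from published per-couple and ART values."""
    return CostResult(
        per_couple_benefit=dict(per_couple),
        total_saving={s: total_saving(per_couple[s], group_size) for s in SCENARIOS},
        art_only_saving=dict(art_only),
        group_size=group_size,
        source="printed-benefit",
    )


def cost_result_from_deltas(
    deltas: dict[Scenario, DeltaOutcomes], costs: CostSpec, group_size: int
) -> CostResult:
    """Assemble a :class:`CostResult` from unit costs and scenario deltas."""
    pcb = {s: per_couple_benefit(deltas[s], costs, group_size) for s in SCENARIOS}
    art = {
        s: total_saving(art_only_per_couple(deltas[s], costs, group_size), group_size)
        for s in SCENARIOS
    }
    return CostResult(
        per_couple_benefit=pcb,
        total_saving={s: total_saving(pcb[s], group_size) for s in SCENARIOS},
        art_only_saving=art,
        group_size=group_size,
        source="computed-from-deltas",
    )
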