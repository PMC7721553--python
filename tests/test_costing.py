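"""Cost aggregation: per-couple benefit, totals, currency, monotonicity."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from artbia import (
    CostSpec,
    eur_to_usd,
    netherlands_2016,
    per_couple_benefit,
    perturb_config,
    run_scenarios,
    total_saving,
)
from artbia.effects import DeltaOutcomes


def _delta(cycles=None, comps=None, denom=1000.0):
    return DeltaOutcomes(
        spontaneous_gain=None,
        cycles_avoided=cycles or {},
        complications_avoided=comps or {},
        denominator_used=denom,
        complication_denominators={c: denom for c in (comps or {})},
    )


def _costs(cycle=None, comp=None, program=0.0):
    cycle = cycle or {}
    comp = comp or {}
    return CostSpec(
        unit_cost_cycle=cycle,
        unit_cost_complication=comp,
        intervention_cost_per_couple=program,
        eur_to_usd_rate=1.19,
        provenance={
            **{f"unit_cost_cycle.{m}": "assumption" for m in cycle},
            **{f"unit_cost_complication.{c}": "assumption" for c in comp},
            "intervention_cost_per_couple": "assumption",
            "eur_to_usd_rate": "assumption",
        },
    )


class TestPerCoupleBenefit:
    def test_zero_deltas_zero_program_cost(self):
        assert per_couple_benefit(_delta(), _costs(cycle={"IVF": 3000.0}), 1000) == 0.0

    def test_hand_arithmetic(self):
        """100 avoided IVF cycles at 3000 over 1000 couples minus 50 program cost."""
        benefit = per_couple_benefit(
            _delta(cycles={"IVF": 100.0}),
            _costs(cycle={"IVF": 3000.0}, program=50.0),
            1000,
        )
        assert benefit == pytest.approx(300.0 - 50.0)

    def test_complication_savings_enter_the_sum(self):
        benefit = per_couple_benefit(
            _delta(cycles={"IVF": 10.0}, comps={"preterm": 5.0}),
            _costs(cycle={"IVF": 1000.0}, comp={"preterm": 2000.0}),
            100,
        )
        assert benefit == pytest.approx((10 * 1000 + 5 * 2000) / 100)

    def test_program_cost_can_exceed_savings(self):
        """A negative net benefit is legal (cf. the smoking least-favorable bound)."""
        benefit = per_couple_benefit(
            _delta(cycles={"IVF": 1.0}),
            _costs(cycle={"IVF": 100.0}, program=500.0),
            1000,
        )
        assert benefit < 0

    def test_zero_group_is_domain_error(self):
        with pytest.raises(ValueError):
            per_couple_benefit(_delta(), _costs(cycle={"IVF": 1.0}), 0)


class TestTotalSaving:
    @pytest.mark.parametrize(
        ("per_couple", "group", "expected"),
        [
            (513.0, 46000, 23_598_000.0),  # displays as EUR 24 M
            (41.0, 3200, 131_200.0),  # displays as EUR 0.13 M
            (0.0, 99999, 0.0),
            (-20.0, 3200, -64_000.0),
        ],
    )
    def test_exact_products(self, per_couple, group, expected):
        assert total_saving(per_couple, group) == expected

    @given(
        benefit=st.floats(min_value=-1e4, max_value=1e4, allow_nan=False),
        group=st.integers(min_value=1, max_value=10**6),
    )
    def test_inverse_identity(self, benefit, group):
        """total / group recovers the per-couple benefit to machine precision."""
        assert total_saving(benefit, group) / group == pytest.approx(
            benefit, rel=1e-12, abs=1e-12
        )


class TestCurrency:
    @pytest.mark.parametrize(
        ("eur", "rate", "usd"),
        [
            (1163.0, 1.1867, 1380.13),  # published pair: 1380.18 (rate ~1.18674)
            (100.0, 1.19, 119.00),
            (0.0, 1.5, 0.0),
        ],
    )
    def test_conversion_rounds_to_cents(self, eur, rate, usd):
        assert eur_to_usd(eur, rate) == pytest.approx(usd, abs=5e-3)

    def test_backfitted_rate_reproduces_published_pairs(self, nl):
        """All five published EUR/USD pairs agree with the fixture rate to ~5 cents."""
        pairs = [(41, 48.66), (360, 427.23), (513, 608.80), (586, 695.43), (1163, 1380.18)]
        rate = nl.costs["lifestyle"].eur_to_usd_rate
        for eur, usd in pairs:
            assert eur_to_usd(eur, rate) == pytest.approx(usd, abs=0.06)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            eur_to_usd(10.0, 0.0)


class TestMonotonicity:
    """Per-couple benefit is monotone in unit costs/deltas, antitone in program cost."""

    @pytest.mark.parametrize("modality", ["IVF", "ICSI", "IUI"])
    def test_nondecreasing_in_unit_cycle_cost(self, modality):
        config = netherlands_2016()
        base = run_scenarios(config, mode="computed-from-deltas")
        for iid in config.intervention_ids:
            bumped = perturb_config(config, f"costs.{iid}.unit_cost_cycle.{modality}", 100.0)
            after = run_scenarios(bumped, mode="computed-from-deltas")
            b0 = base.interventions[iid].cost.per_couple_benefit["central"]
            b1 = after.interventions[iid].cost.per_couple_benefit["central"]
            assert b1 >= b0 - 1e-9
            rate = config.effect(iid).reduction_rate.get(modality)
            if rate is not None and rate.central > 0:
                assert b1 > b0

    def test_strictly_decreasing_in_program_cost(self):
        config = netherlands_2016()
        base = run_scenarios(config, mode="computed-from-deltas")
        bumped = perturb_config(
            config, "costs.smarter_pregnancy.intervention_cost_per_couple", 10.0
        )
        after = run_scenarios(bumped, mode="computed-from-deltas")
        assert (
            after.interventions["smarter_pregnancy"].cost.per_couple_benefit["central"]
            == pytest.approx(
                base.interventions["smarter_pregnancy"].cost.per_couple_benefit["central"] - 10.0
            )
        )


def test_computed_mode_reproduces_published_central_benefits(nl):
    """With the back-fitted program costs, unit-cost mode recovers the published
    central per-couple benefits exactly."""
    results = run_scenarios(nl, mode="computed-from-deltas")
    for iid, triple in nl.per_couple_benefit_printed.items():
        assert results.interventions[iid].cost.per_couple_benefit["central"] == pytest.approx(
            triple.central, abs=1e-6
        )
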