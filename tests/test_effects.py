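"""Outcome deltas: rate x denominator, display rounding, linearity, monotonicity."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from artbia import (
    EffectSpec,
    InfeasibleEffectError,
    Triple,
    apply_intervention,
    baseline_volumes,
    display_round,
    resolve_target_group,
)
from artbia.config_io import SCENARIOS
from artbia.synthetic_params import GeneratorSpec, generate_config


class TestDisplayRound:
    @pytest.mark.parametrize(
        ("x", "resolution", "expected"),
        [
            (5980.0, 100, 6000.0),  # 13.0% of 46,000 prints as +6000
            (1080.0, 100, 1100.0),  # 20.0% of 5400 prints as -1100
            (-237.6, 100, -200.0),  # 4.4% of 5400 prints as -200
            (162.0, 100, 200.0),
            (123.3, 100, 100.0),
            (50.0, 100, 100.0),  # ties away from zero
            (-50.0, 100, -100.0),
            (23.598e6, 1e6, 24e6),
            (0.0, 100, 0.0),
        ],
    )
    def test_examples(self, x, resolution, expected):
        assert display_round(x, resolution) == pytest.approx(expected)

    @given(
        x=st.floats(min_value=-1e7, max_value=1e7, allow_nan=False),
        resolution=st.sampled_from([1.0, 0.01, 100.0, 1e5]),
    )
    def test_nearest_multiple_against_enumeration(self, x, resolution):
        """Brute force over neighbouring multiples: the result is a closest one."""
        rounded = display_round(x, resolution)
        k = rounded / resolution
        assert k == pytest.approx(round(k)), "result is a multiple of the resolution"
        best = min(
            abs(x - m * resolution)
            for m in range(int(math.floor(x / resolution)) - 1, int(math.ceil(x / resolution)) + 2)
        )
        assert abs(x - rounded) <= best + 1e-6 * max(1.0, abs(x))

    @given(
        x=st.floats(min_value=-1e7, max_value=1e7, allow_nan=False),
        resolution=st.sampled_from([1.0, 100.0]),
    )
    def test_idempotent(self, x, resolution):
        once = display_round(x, resolution)
        assert display_round(once, resolution) == once

    def test_rejects_nonpositive_resolution(self):
        with pytest.raises(ValueError):
            display_round(1.0, 0.0)


class TestApplyIntervention:
    @pytest.mark.parametrize(
        ("intervention", "kind", "key", "expected", "denominator"),
        [
            ("smarter_pregnancy", "spont", None, 0.130 * 46000, 46000),  # 5980
            ("smarter_pregnancy", "cycles", "IUI", 0.234 * 46000, 46000),  # 10,764
            ("smarter_pregnancy", "comp", "IUGR", 0.026 * 46000, 46000),
            ("lifestyle", "comp", "gestational_diabetes", 0.044 * 5400, 5400),  # 237.6
            ("lifestyle", "comp", "preterm", 0.030 * 5400, 5400),  # 162
            ("lifestyle", "cycles", "IUI", 0.200 * 5400, 5400),  # 1080
            # the combined program applies maternal complications to the obese
            # subset but growth restriction to the whole cohort
            ("smarter_pregnancy_plus_lifestyle", "comp", "gestational_diabetes", 0.044 * 5400, 46000),
            ("smarter_pregnancy_plus_lifestyle", "comp", "IUGR", 0.026 * 46000, 46000),
            ("smoking_cessation", "cycles", "IVF", 300.0, 3200),
            ("mindfulness", "cycles", "IVF", 0.118 * 13700, 13700),  # 1616.6
        ],
    )
    def test_central_deltas_are_unrounded_products(
        self, nl, nl_baseline, intervention, kind, key, expected, denominator
    ):
        delta = apply_intervention(
            nl.effect(intervention), nl.population, nl_baseline, "central"
        )
        assert delta.denominator_used == denominator
        value = {
            "spont": delta.spontaneous_gain,
            "cycles": delta.cycles_avoided.get(key),
            "comp": delta.complications_avoided.get(key),
        }[kind]
        assert value == pytest.approx(expected)

    def test_no_evidence_outcomes_are_absent(self, nl, nl_baseline):
        delta = apply_intervention(
            nl.effect("smoking_cessation"), nl.population, nl_baseline
        )
        assert delta.spontaneous_gain is None
        assert "IUI" not in delta.cycles_avoided
        assert delta.complications_avoided == {}

    def test_all_zero_rates_give_zero_deltas(self, nl, nl_baseline):
        effect = EffectSpec(
            intervention_id="null",
            target_group="whole-cohort",
            uplift_spontaneous=Triple.constant(0.0),
            reduction_rate={m: Triple.constant(0.0) for m in ("IVF", "ICSI", "IUI")},
            complication_reduction={"IUGR": Triple.constant(0.0)},
        )
        delta = apply_intervention(effect, nl.population, nl_baseline)
        assert delta.spontaneous_gain == 0.0
        assert all(v == 0.0 for v in delta.cycles_avoided.values())
        assert all(v == 0.0 for v in delta.complications_avoided.values())

    @given(rate=st.floats(min_value=0.0, max_value=0.3), scale=st.integers(1, 20))
    def test_linearity_in_rate_and_denominator(self, nl, nl_baseline, rate, scale):
        """Deltas are linear in the effect rate and the denominator size."""
        base = nl.effect("mindfulness")
        effect = base.model_copy(
            update={"reduction_rate": {"IVF": Triple.constant(rate)}}
        )
        delta = apply_intervention(effect, nl.population, nl_baseline)
        assert delta.cycles_avoided["IVF"] == pytest.approx(rate * 13700, rel=1e-12)
        doubled = base.model_copy(
            update={"reduction_rate": {"IVF": Triple.constant(rate / 2)}}
        )
        half = apply_intervention(doubled, nl.population, nl_baseline)
        assert delta.cycles_avoided["IVF"] == pytest.approx(
            2 * half.cycles_avoided["IVF"], rel=1e-9, abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(25))
    def test_scenario_monotonicity_on_synthetic_configs(self, seed):
        """Ordered rate triples give least <= central <= most for every delta."""
        config = generate_config(GeneratorSpec(seed=seed, include_printed=False))
        baseline = baseline_volumes(config.population, config.mix)
        for effect in config.effects:
            deltas = {
                s: apply_intervention(effect, config.population, baseline, s)
                for s in SCENARIOS
            }
            lo, mid, hi = (deltas[s] for s in SCENARIOS)
            if lo.spontaneous_gain is not None:
                assert lo.spontaneous_gain <= mid.spontaneous_gain <= hi.spontaneous_gain
            for m in lo.cycles_avoided:
                assert (
                    lo.cycles_avoided[m] <= mid.cycles_avoided[m] <= hi.cycles_avoided[m]
                )
            for c in lo.complications_avoided:
                assert (
                    lo.complications_avoided[c]
                    <= mid.complications_avoided[c]
                    <= hi.complications_avoided[c]
                )

    def test_avoided_cycles_cannot_exceed_baseline(self, nl, nl_baseline):
        effect = EffectSpec(
            intervention_id="too_strong",
            target_group="whole-cohort",
            reduction_rate={"IVF": Triple.constant(1.0)},  # 46,000 > 16,560 cycles
        )
        with pytest.raises(InfeasibleEffectError):
            apply_intervention(effect, nl.population, nl_baseline)


def test_target_group_resolution(nl):
    sizes = {
        "whole-cohort": 46000,
        "obese-subset": 5400,
        "smoking-men": 3200,
        "first-cycle-women": 13700,
    }
    for group, size in sizes.items():
        assert resolve_target_group(group, nl.population) == size
    with pytest.raises(ValueError, match="unknown target group"):
        resolve_target_group("left-handed", nl.population)
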