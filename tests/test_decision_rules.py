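"""Allocation and stopping rules: frozen arithmetic, presets, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from castsim import (
    ARMS,
    CONTROL_ARM,
    INTERVENTION_ARMS,
    AllocationState,
    DesignSpec,
    PosteriorDraws,
    apply_arm_dropping,
    design6_decision,
    design_preset,
    efficacy_stop,
    final_success,
    futility_stop,
    rar_probabilities,
)


def _state():
    return AllocationState.equal(ARMS)


class TestRar:
    def test_powered_renormalisation_arithmetic(self):
        # (0.6, 0.3, 0.1)^0.6 renormalised = (0.4997, 0.3297, 0.1706)
        spec = design_preset(6)
        pb = dict(zip(ARMS[:3], (0.6, 0.3, 0.1)))
        # restrict to a 3-arm state so no control policy interferes
        st3 = AllocationState.equal(ARMS[:3])
        out = rar_probabilities(pb, spec, st3)
        got = [out.probabilities[a] for a in ARMS[:3]]
        np.testing.assert_allclose(got, (0.49974, 0.32971, 0.17055), atol=1e-4)

    def test_suspension_renormalises_survivors(self):
        # a post-normalisation vector (0.55, 0.36, 0.09): third arm suspended,
        # survivors renormalised to (0.6044, 0.3956)
        spec = design_preset(6)
        # choose raw probabilities whose powered-renormalised version is the
        # target vector: invert the gamma power
        raw = np.array([0.55, 0.36, 0.09]) ** (1 / 0.6)
        pb = dict(zip(ARMS[:3], raw / raw.sum()))
        out = rar_probabilities(pb, spec, AllocationState.equal(ARMS[:3]))
        assert out.suspended == frozenset({ARMS[2]})
        assert out.probabilities[ARMS[0]] == pytest.approx(0.55 / 0.91, abs=1e-6)
        assert out.probabilities[ARMS[1]] == pytest.approx(0.36 / 0.91, abs=1e-6)
        assert out.probabilities[ARMS[2]] == 0.0

    def test_matched_control_symmetric_case(self):
        # equal intervention probabilities with control matched to the best
        # intervention: all four arms at 0.25
        spec = design_preset(4)
        pb = {a: 1 / 3 for a in INTERVENTION_ARMS}
        out = rar_probabilities(pb, spec, _state())
        for a in ARMS:
            assert out.probabilities[a] == pytest.approx(0.25)

    def test_fixed_control_policy(self):
        spec = design_preset(5)
        pb = {a: p for a, p in zip(INTERVENTION_ARMS, (0.7, 0.25, 0.05))}
        out = rar_probabilities(pb, spec, _state())
        assert out.probabilities[CONTROL_ARM] == pytest.approx(0.40)
        interventions = np.array([out.probabilities[a] for a in INTERVENTION_ARMS])
        assert interventions.sum() + 0.40 == pytest.approx(1.0)
        # interventions share 0.60 proportionally to powered probabilities
        powered = np.array([0.7, 0.25, 0.05]) ** 0.6
        expected = 0.6 * powered / powered.sum()
        # third arm falls below 0.1 -> suspended, survivors renormalised in 0.6
        assert expected[2] < 0.1
        assert out.suspended == frozenset({INTERVENTION_ARMS[2]})
        surv = 0.6 * powered[:2] / powered[:2].sum()
        np.testing.assert_allclose(interventions[:2], surv, atol=1e-12)

    def test_gamma_limits(self):
        pb = {a: p for a, p in zip(ARMS, (0.55, 0.25, 0.15, 0.05))}
        flat = DesignSpec(6, adaptation="rar", adaptation_interval=50,
                          stopping_checks=(200,), control_policy="none", gamma=0.0,
                          suspension_threshold=0.0)
        out = rar_probabilities(pb, flat, _state())
        for a in ARMS:
            assert out.probabilities[a] == pytest.approx(0.25)
        raw = DesignSpec(6, adaptation="rar", adaptation_interval=50,
                         stopping_checks=(200,), control_policy="none", gamma=1.0,
                         suspension_threshold=0.0)
        out = rar_probabilities(pb, raw, _state())
        for a, p in zip(ARMS, (0.55, 0.25, 0.15, 0.05)):
            assert out.probabilities[a] == pytest.approx(p)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        raw=st.lists(st.floats(1e-3, 1.0), min_size=3, max_size=3),
        design=st.sampled_from([4, 5, 6]),
    )
    def test_allocations_sum_to_one(self, raw, design):
        total = sum(raw)
        if design == 6:
            pb = {a: r / (total + 0.5) for a, r in zip(INTERVENTION_ARMS, raw)}
            pb[CONTROL_ARM] = 0.5 / (total + 0.5)
        else:
            pb = {a: r / total for a, r in zip(INTERVENTION_ARMS, raw)}
        out = rar_probabilities(pb, design_preset(design), _state())
        assert sum(out.probabilities.values()) == pytest.approx(1.0)
        out.validate()


class TestArmDropping:
    def test_drop_below_threshold_equal_split(self):
        spec = design_preset(3)
        out = apply_arm_dropping(
            dict(zip(INTERVENTION_ARMS, (0.50, 0.42, 0.08))), spec, _state()
        )
        assert out.dropped == frozenset({INTERVENTION_ARMS[2]})
        for a in (CONTROL_ARM, *INTERVENTION_ARMS[:2]):
            assert out.probabilities[a] == pytest.approx(1 / 3)

    def test_no_drop_when_all_above(self):
        spec = design_preset(3)
        out = apply_arm_dropping(
            dict(zip(INTERVENTION_ARMS, (0.4, 0.35, 0.25))), spec, _state()
        )
        assert out.dropped == frozenset()
        for a in ARMS:
            assert out.probabilities[a] == pytest.approx(0.25)

    def test_double_drop_half_split(self):
        spec = design_preset(3)
        out = apply_arm_dropping(
            dict(zip(INTERVENTION_ARMS, (0.85, 0.09, 0.06))), spec, _state()
        )
        assert out.dropped == frozenset(INTERVENTION_ARMS[1:])
        assert out.probabilities[CONTROL_ARM] == pytest.approx(0.5)
        assert out.probabilities[INTERVENTION_ARMS[0]] == pytest.approx(0.5)

    def test_control_cannot_be_dropped(self):
        spec = design_preset(3)
        with pytest.raises(ValueError, match="control"):
            apply_arm_dropping({CONTROL_ARM: 0.05, "boot": 0.95}, spec, _state())

    def test_drops_are_permanent(self):
        spec = design_preset(3)
        state = apply_arm_dropping(
            dict(zip(INTERVENTION_ARMS, (0.6, 0.35, 0.05))), spec, _state()
        )
        state2 = apply_arm_dropping(
            {a: p for a, p in zip(INTERVENTION_ARMS[:2], (0.7, 0.3))}, spec, state
        )
        assert INTERVENTION_ARMS[2] in state2.dropped


class TestStoppingRules:
    @pytest.mark.parametrize(
        "p_mcid,p_best,interim,expect",
        [
            (0.80, 0.95, 1, True),  # both criteria met at S_1 = 0.75
            (0.80, 0.85, 1, False),  # best-arm gate 0.9 fails
            (0.72, 0.95, 2, True),  # S_2 = 0.70
            (0.72, 0.95, 1, False),  # same inputs fail the S_1 boundary
            (0.61, 0.95, 3, True),  # S_3 = 0.60
        ],
    )
    def test_efficacy_boundary_sequence(self, p_mcid, p_best, interim, expect):
        assert efficacy_stop(p_mcid, p_best, interim, design_preset(2)) is expect

    @pytest.mark.parametrize("p,expect", [(0.04, True), (0.05, False), (0.50, False)])
    def test_futility_strict_threshold(self, p, expect):
        assert futility_stop(p, design_preset(2)) is expect

    @pytest.mark.parametrize(
        "p,interim,verdict",
        [
            (0.98, 1, "stop-efficacy"),
            (0.08, 1, "stop-futility"),
            (0.08, 3, "stop-futility"),
            (0.95, 1, "continue"),
            (0.96, 2, "stop-efficacy"),
            (0.93, 3, "stop-efficacy"),
        ],
    )
    def test_design6_ladder(self, p, interim, verdict):
        assert design6_decision(p, interim, design_preset(6)) == verdict

    def test_efficacy_monotone_in_probabilities(self):
        spec = design_preset(2)
        grid = np.linspace(0, 1, 21)
        for interim in (1, 2, 3):
            stops = [efficacy_stop(p, 0.95, interim, spec) for p in grid]
            assert stops == sorted(stops)  # False..False True..True
            stops = [efficacy_stop(0.8, p, interim, spec) for p in grid]
            assert stops == sorted(stops)


class TestFinalSuccess:
    @staticmethod
    def _draws(mus, sds, n=100_000, seed=0):
        rng = np.random.default_rng(seed)
        return PosteriorDraws(rng.normal(mus, sds, (n, 4)), np.full(n, 400.0))

    def test_mcid_rule_designs_1_to_5(self):
        spec = design_preset(2)
        # cast clearly above control: Pr(diff > 8) > 0.5 -> success
        d = self._draws([50, 50, 50, 60], [1, 1, 1, 1], seed=1)
        ok, declared = final_success(d, spec)
        assert ok and declared == "below-knee cast"
        # contrast exactly 8: Pr(diff > 8) = 0.5, strict -> unsuccessful
        d = self._draws([50, 50, 50, 57], [1, 1, 1, 1], seed=2)
        ok, _ = final_success(d, spec)
        assert not ok

    def test_design6_rule_reports_best_even_on_failure(self):
        spec = design_preset(6)
        d = self._draws([50, 52, 55, 56], [2, 2, 2, 2], seed=3)
        ok, declared = final_success(d, spec)
        assert declared == "below-knee cast"
        assert not ok  # two similar arms: max best-arm probability < 0.9

    def test_design6_success_with_clear_winner(self):
        spec = design_preset(6)
        d = self._draws([50, 50, 50, 65], [2, 2, 2, 2], seed=4)
        ok, declared = final_success(d, spec)
        assert ok and declared == "below-knee cast"


class TestDesignSpec:
    # adaptation interval, control policy, stopping schedule per design
    ROSTER = {
        1: ("none", None, (), "equal"),
        2: ("none", 200, (200, 400, 600), "equal"),
        3: ("drop", 50, (200, 400, 600), "equal"),
        4: ("rar", 50, (200, 400, 600), "matched-to-best"),
        5: ("rar", 50, (200, 400, 600), "fixed-0.40"),
        6: ("rar", 50, (200, 400, 600), "none"),
    }

    @pytest.mark.parametrize("design_id", list(range(1, 7)))
    def test_preset_roster(self, design_id):
        spec = design_preset(design_id)
        adaptation, interval, checks, policy = self.ROSTER[design_id]
        assert spec.adaptation == adaptation
        assert spec.adaptation_interval == interval
        assert spec.stopping_checks == checks
        assert spec.control_policy == policy
        assert spec.gamma == 0.6
        assert spec.max_n == 643
        assert spec.mcid == 8.0
        assert spec.efficacy_boundaries == (0.75, 0.70, 0.60)
        assert spec.d6_efficacy_ladder == (0.975, 0.95, 0.925)

    def test_validation(self):
        with pytest.raises(ValueError):
            design_preset(7)
        with pytest.raises(ValueError, match="non-increasing"):
            DesignSpec(2, adaptation_interval=200, stopping_checks=(200,),
                       efficacy_boundaries=(0.6, 0.7, 0.75))
        with pytest.raises(ValueError, match="multiples"):
            DesignSpec(2, adaptation_interval=200, stopping_checks=(300,))
        with pytest.raises(ValueError, match="lie in"):
            DesignSpec(2, best_arm_gate=1.2)

    def test_dict_round_trip(self):
        spec = design_preset(5)
        assert DesignSpec.from_dict(spec.to_dict()) == spec
        with pytest.raises(ValueError, match="unknown"):
            DesignSpec.from_dict({**spec.to_dict(), "bogus": 1})
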