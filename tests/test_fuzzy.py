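"""Mamdani risk engine: memberships, Karvonen anchors, inference, categorization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatwatch import (
    RiskCategory,
    RiskInput,
    WorkerProfile,
    build_fuzzy_system,
    categorize_risk,
    caution_threshold,
    default_rules,
    evaluate_memberships,
    hr_max,
    mamdani_infer,
)
from heatwatch.fuzzy import PiMembership, TriMembership, FuzzySystem, Rule

from _oracle import oracle_infer


class TestHrMax:
    @pytest.mark.parametrize("age,expected", [(30, 186.0), (50, 172.0), (15, 196.5)])
    def test_direct_substitution(self, age, expected):
        assert hr_max(age) == expected

    @pytest.mark.parametrize("age", [0, 14, 81])
    def test_rejects_out_of_range_age(self, age):
        with pytest.raises(ValueError):
            hr_max(age)


class TestCautionThreshold:
    @pytest.mark.parametrize(
        "hrmax,rest,w,expected",
        [(186, 60, 0.5, 123.0), (186, 60, 1.0, 186.0), (172, 99, 0.25, 117.25)],
    )
    def test_karvonen_substitution(self, hrmax, rest, w, expected):
        assert caution_threshold(hrmax, rest, w) == expected

    def test_rejects_resting_above_max(self):
        with pytest.raises(ValueError):
            caution_threshold(150, 160, 0.5)

    def test_rejects_bad_intensity(self):
        with pytest.raises(ValueError):
            caution_threshold(186, 60, 0.0)


class TestMembershipFunctions:
    @given(x=st.floats(-10, 110, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_pi_invariants(self, x):
        mf = PiMembership(10, 20, 60, 80)
        mu = mf(x)
        assert 0.0 <= mu <= 1.0
        if x <= 10 or x >= 80:
            assert mu == 0.0
        if 20 <= x <= 60:
            assert mu == 1.0

    def test_pi_crossover_at_ramp_midpoints(self):
        mf = PiMembership(10, 20, 60, 80)
        assert mf(15.0) == pytest.approx(0.5)
        assert mf(70.0) == pytest.approx(0.5)

    @given(x=st.floats(-5, 25, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_triangle_invariants(self, x):
        mf = TriMembership(0, 10, 20)
        mu = mf(x)
        assert 0.0 <= mu <= 1.0
        if x < 0 or x > 20:
            assert mu == 0.0

    def test_triangle_apex(self):
        mf = TriMembership(0, 10, 20)
        assert mf(10.0) == 1.0
        assert mf(5.0) == pytest.approx(0.5)

    def test_pi_validates_ordering(self):
        with pytest.raises(ValueError):
            PiMembership(10, 5, 20, 30)


class TestBuildSystem:
    def test_heartbeat_normal_plateau(self, system):
        assert system.inputs["heart_rate"].membership(75.0)["normal"] == 1.0

    def test_heartbeat_danger_above_hrmax(self, system):
        # age 30 -> HRmax 186; 190 bpm is fully in the danger set
        assert system.inputs["heart_rate"].membership(190.0)["danger"] == 1.0

    def test_core_temp_normal_at_37(self, system):
        assert system.inputs["core_temp"].membership(37.0)["normal"] == 1.0

    def test_ct_breakpoint_38_is_crossover(self, system):
        mu = system.inputs["core_temp"].membership(38.0)
        assert mu["normal"] == pytest.approx(0.5)
        assert mu["high"] == pytest.approx(0.5)

    def test_karvonen_anchor_moves_with_intensity(self):
        # lower intensity value -> caution band starts lower
        hi = build_fuzzy_system(WorkerProfile(age=30, work_intensity="high"))
        light = build_fuzzy_system(WorkerProfile(age=30, work_intensity="light"))
        h = 130.0
        assert (
            hi.inputs["heart_rate"].membership(h)["caution"]
            >= light.inputs["heart_rate"].membership(h)["caution"]
        )

    @pytest.mark.parametrize("var", ["heart_rate", "core_temp", "work_intensity", "time_interval"])
    def test_universe_coverage(self, system, var):
        v = system.inputs[var]
        grid = np.linspace(*v.universe, 400)
        best = np.array([max(v.membership(x).values()) for x in grid])
        assert best.min() >= 0.01

    def test_extreme_intensity_profiles_still_ordered(self):
        # work intensity 0.25 pushes the Karvonen target below 99 bpm; the
        # constructed anchors must stay strictly ordered regardless
        for age in (15, 30, 80):
            for w in ("light", "medium", "high"):
                sys_ = build_fuzzy_system(WorkerProfile(age=age, work_intensity=w))
                sets = sys_.inputs["heart_rate"].sets
                assert sets["normal"].c < sets["caution"].b <= sets["caution"].c < sets["danger"].b

    def test_rule_referencing_unknown_set_rejected(self, system):
        bad = Rule(clauses={"heart_rate": ("sprinting",)}, consequent="safe")
        with pytest.raises(ValueError):
            FuzzySystem(inputs=system.inputs, output=system.output, rules=(bad,))

    def test_rejects_invalid_profile(self):
        with pytest.raises(ValueError):
            WorkerProfile(age=10)
        with pytest.raises(ValueError):
            WorkerProfile(age=30, work_intensity="extreme")


class TestEvaluateMemberships:
    def test_all_degrees_in_unit_interval(self, system):
        mu = evaluate_memberships(system, RiskInput(h=140, ct=38.5, w=0.5, t=20))
        for var in mu.values():
            for d in var.values():
                assert 0.0 <= d <= 1.0

    def test_out_of_universe_clamped(self, system):
        # far below the universe the input clamps to the edge, where the
        # normal set still holds full membership
        mu = evaluate_memberships(system, RiskInput(h=-50, ct=37, w=0.5, t=0))
        assert mu["heart_rate"]["normal"] == 1.0


class TestCategorize:
    @pytest.mark.parametrize(
        "rl,cat",
        [
            (5, RiskCategory.SAFE),
            (10, RiskCategory.SAFE),
            (15, RiskCategory.CONCERN),
            (25, RiskCategory.ATTENTION),
            (35, RiskCategory.DANGER),
            (40, RiskCategory.DANGER),
        ],
    )
    def test_table_ranges(self, rl, cat):
        assert categorize_risk(rl) is cat

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            categorize_risk(41.0)


class TestMamdaniInfer:
    def test_resting_input_is_safe(self, system):
        a = mamdani_infer(system, RiskInput(h=75, ct=37, w=0.5, t=2))
        assert 0 <= a.rl <= 10
        assert a.category is RiskCategory.SAFE
        assert not a.alert

    def test_severe_strain_alerts(self, system):
        a = mamdani_infer(system, RiskInput(h=196, ct=41, w=0.25, t=40))
        assert 21 <= a.rl <= 40
        assert a.category in (RiskCategory.ATTENTION, RiskCategory.DANGER)
        assert a.alert

    @given(
        h=st.floats(30, 230),
        ct=st.floats(28, 44),
        w=st.sampled_from([0.25, 0.5, 0.75]),
        t=st.floats(0, 60),
    )
    @settings(max_examples=50, deadline=None)
    def test_output_bounded(self, system, h, ct, w, t):
        a = mamdani_infer(system, RiskInput(h=h, ct=ct, w=w, t=t))
        assert 0.0 <= a.rl <= 40.0

    def test_matches_bruteforce_oracle_spot_checks(self, system):
        for h, ct, t in [(75, 37, 0), (150, 38.5, 20), (190, 41, 35), (110, 36.2, 8)]:
            x = RiskInput(h=h, ct=ct, w=0.5, t=t)
            assert mamdani_infer(system, x).rl == pytest.approx(
                oracle_infer(system, x), abs=0.05
            )

    def test_duration_escalates_risk(self, system):
        x_short = RiskInput(h=150, ct=38.5, w=0.5, t=2)
        x_long = RiskInput(h=150, ct=38.5, w=0.5, t=40)
        assert mamdani_infer(system, x_long).rl > mamdani_infer(system, x_short).rl

    def test_age_sensitivity(self):
        # at a fixed elevated heart rate, an older worker (lower HRmax, sets
        # shifted left) is assessed at least as risky
        x = RiskInput(h=160, ct=37, w=0.5, t=10)
        rl_young = mamdani_infer(build_fuzzy_system(WorkerProfile(age=25)), x).rl
        rl_old = mamdani_infer(build_fuzzy_system(WorkerProfile(age=60)), x).rl
        assert rl_old >= rl_young


class TestRules:
    def test_default_rules_load(self):
        rules = default_rules()
        assert len(rules) >= 10
        assert any(r.negate for r in rules)
        consequents = {r.consequent for r in rules}
        assert consequents == {"safe", "concern", "attention", "danger"}

    def test_or_and_not_semantics(self, system):
        # OR within a variable takes the max membership; NOT complements it
        mu = evaluate_memberships(system, RiskInput(h=75, ct=38.0, w=0.5, t=0))
        rule_or = Rule(
            clauses={"core_temp": ("normal", "high")}, consequent="attention"
        )
        assert rule_or.strength(mu) == pytest.approx(
            max(mu["core_temp"]["normal"], mu["core_temp"]["high"])
        )
        rule_not = Rule(
            clauses={"heart_rate": ("normal",)},
            consequent="attention",
            negate=("heart_rate",),
        )
        assert rule_not.strength(mu) == pytest.approx(1 - mu["heart_rate"]["normal"])

    def test_rules_roundtrip(self, tmp_path):
        import yaml

        from heatwatch import load_rules

        rules = default_rules()
        doc = {
            "rules": [
                {
                    "if": {v: list(s) for v, s in r.clauses.items()},
                    "then": r.consequent,
                    **({"not": list(r.negate)} if r.negate else {}),
                    **({"op": r.op} if r.op != "and" else {}),
                }
                for r in rules
            ]
        }
        p = tmp_path / "rules.yaml"
        p.write_text(yaml.safe_dump(doc))
        assert load_rules(p) == rules
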