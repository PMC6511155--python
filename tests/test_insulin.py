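import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoplan.core import PatientProfile, RegimenKind
from glycoplan.errors import InputError, PlannerError
from glycoplan.insulin import (
    build_insulin_plan,
    choose_regimen,
    compute_tdd,
    set_goals,
    split_fixed_twice,
    split_iit,
)
from glycoplan.knowledge import DEFAULT_KB_CONFIG, load_knowledge_base

from conftest import coded


class TestSetGoals:
    def test_pregnant_adult_rule(self, kb, pregnant_profile):
        goals = set_goals(pregnant_profile, kb)
        assert goals.hba1c_max == 6.5
        assert goals.premeal_bg_low.value == 90
        assert goals.premeal_bg_high.value == 100
        assert goals.premeal_bg_low.unit == "mg/dL"

    def test_nonpregnant_adult_uses_kb_default(self, kb, adult_profile):
        goals = set_goals(adult_profile, kb)
        assert goals == kb.goal_defaults["adult/nonpregnant"]

    def test_child_hypo_history_uses_relaxed_override(self, kb, child_profile):
        with_history = child_profile.model_copy(
            update={"history_of_hypoglycemia": 2}
        )
        relaxed = set_goals(with_history, kb)
        base = set_goals(child_profile, kb)
        assert relaxed == kb.goal_defaults["child/nonpregnant/hypo_history"]
        assert relaxed.hba1c_max > base.hba1c_max


class TestChooseRegimen:
    def test_pregnant_overrides_preference(self, pregnant_profile):
        assert pregnant_profile.regimen_preference.value == "fixed_twice"
        assert choose_regimen(pregnant_profile) is RegimenKind.IIT

    def test_child_forced_iit(self, child_profile):
        assert choose_regimen(child_profile) is RegimenKind.IIT

    def test_adult_preference_respected(self, fixed_twice_profile):
        assert choose_regimen(fixed_twice_profile) is RegimenKind.fixed_twice

    def test_no_preference_defaults_to_iit(self):
        p = PatientProfile(id="x", age=40, sex="male", weight=70, height=175)
        assert choose_regimen(p) is RegimenKind.IIT


class TestTdd:
    @pytest.mark.parametrize("weight,expected", [
        (30, 18.0), (50, 30.0), (250 / 3, 50.0),
    ])
    def test_weight_rule(self, weight, expected):
        assert compute_tdd(weight) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [0, -5, float("nan"), float("inf")])
    def test_invalid_weight(self, bad):
        with pytest.raises(InputError):
            compute_tdd(bad)


class TestSplits:
    def test_fixed_twice_reference_values(self):
        """30 kg -> TDD 18 -> morning 8+4, evening 3+3."""
        assert split_fixed_twice(compute_tdd(30)) == pytest.approx((8, 4, 3, 3))

    def test_fixed_twice_36(self):
        assert split_fixed_twice(36) == pytest.approx((16, 8, 6, 6))

    def test_fixed_twice_zero(self):
        assert split_fixed_twice(0) == (0, 0, 0, 0)

    @pytest.mark.parametrize("f,ba,bo", [(0.5, 25, 25), (0.6, 30, 20)])
    def test_iit_split(self, f, ba, bo):
        got_ba, got_bo, premeal = split_iit(50, f)
        assert (got_ba, got_bo) == pytest.approx((ba, bo))
        assert premeal == pytest.approx(bo / 3)

    def test_iit_rejects_off_grid_fraction(self):
        with pytest.raises(InputError):
            split_iit(50, 0.45)

    @settings(derandomize=True)
    @given(st.floats(0.001, 200))
    def test_dose_conservation(self, tdd):
        """Each split conserves TDD exactly before rounding."""
        assert math.isclose(sum(split_fixed_twice(tdd)), tdd, rel_tol=1e-12)
        for f in (0.3, 0.4, 0.5, 0.6):
            ba, bo, premeal = split_iit(tdd, f)
            assert math.isclose(ba + bo, tdd, rel_tol=1e-12)
            assert math.isclose(ba + 3 * premeal, tdd, rel_tol=1e-9)

    @settings(derandomize=True)
    @given(st.floats(0.001, 100))
    def test_positive_homogeneity(self, tdd):
        doubled = split_fixed_twice(2 * tdd)
        assert doubled == pytest.approx(tuple(2 * x for x in split_fixed_twice(tdd)))
        ba1, bo1, _ = split_iit(tdd, 0.4)
        ba2, bo2, _ = split_iit(2 * tdd, 0.4)
        assert (ba2, bo2) == pytest.approx((2 * ba1, 2 * bo1))


class TestBuildInsulinPlan:
    def test_fixed_twice_regimen_products_and_doses(self, kb, fixed_twice_profile):
        regimen = build_insulin_plan(fixed_twice_profile, kb)
        assert regimen.kind is RegimenKind.fixed_twice
        units = [d.units for d in regimen.doses]
        assert units == pytest.approx([8, 4, 3, 3])
        classes = [d.product.action_class.value for d in regimen.doses]
        assert classes == ["intermediate", "short", "intermediate", "short"]
        assert [d.product.code.display for d in regimen.doses[:2]] == \
            ["NPH insulin", "regular insulin"]

    def test_pregnant_gets_iit_with_basal_and_three_premeals(self, kb,
                                                            pregnant_profile):
        regimen = build_insulin_plan(pregnant_profile, kb)
        assert regimen.kind is RegimenKind.IIT
        kinds = [d.kind.value for d in regimen.doses]
        assert kinds == ["basal", "bolus", "bolus", "bolus"]
        assert regimen.doses[0].timing.value == "bedtime"
        assert regimen.total_units == pytest.approx(regimen.tdd)

    def test_two_basal_shots_split_equally(self, kb, adult_profile):
        regimen = build_insulin_plan(adult_profile, kb, basal_shots=2)
        basal = [d for d in regimen.doses if d.kind.value == "basal"]
        assert len(basal) == 2
        assert basal[0].units == pytest.approx(basal[1].units)
        assert {d.timing.value for d in basal} == {"morning", "evening"}

    def test_fixed_once_single_long_dose(self, kb):
        p = PatientProfile(id="x", age=45, sex="male", weight=60, height=170,
                           regimen_preference="fixed_once")
        regimen = build_insulin_plan(p, kb)
        assert len(regimen.doses) == 1
        assert regimen.doses[0].units == pytest.approx(36)
        assert regimen.doses[0].product.action_class.value == "long"

    def test_contradicted_long_acting_falls_back(self, kb):
        p = PatientProfile(id="x", age=45, sex="male", weight=60, height=170,
                           regimen_preference="IIT",
                           medications=[coded("beta-blocker")])
        regimen = build_insulin_plan(p, kb)
        basal = regimen.doses[0]
        assert basal.product.code.display == "insulin glargine"

    def test_all_long_acting_contradicted_raises(self):
        config = dict(DEFAULT_KB_CONFIG)
        config["drug_drug_contra"] = {
            "414518007": ["blocker-x"], "126212009": ["blocker-x"],
        }
        kb2 = load_knowledge_base(config)
        p = PatientProfile(id="x", age=45, sex="male", weight=60, height=170,
                           regimen_preference="IIT",
                           medications=[coded("blocker-x")])
        from glycoplan.errors import NoSafeInsulinError

        with pytest.raises(NoSafeInsulinError):
            build_insulin_plan(p, kb2)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(1, 200), st.sampled_from(["IIT", "fixed_once", "fixed_twice"]))
    def test_plan_dose_conservation_all_kinds(self, kb, weight, preference):
        """Planned daily units equal TDD within 0.5 U for every regimen."""
        p = PatientProfile(id="x", age=40, sex="male", weight=weight,
                           height=175, regimen_preference=preference)
        regimen = build_insulin_plan(p, kb)
        assert abs(regimen.total_units - regimen.tdd) < 0.5

    def test_pregnant_or_child_never_fixed(self, kb, pregnant_profile,
                                           child_profile):
        for profile in (pregnant_profile, child_profile):
            assert build_insulin_plan(profile, kb).kind is RegimenKind.IIT
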