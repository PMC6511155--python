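import itertools
import math
import random
from datetime import date, timedelta

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glycoplan.core import MGDL, MMOL, Quantity, Slot, convert_glucose
from glycoplan.errors import (
    DoseMappingError,
    InputError,
    InsufficientDataError,
    UnitError,
)
from glycoplan.insulin import build_insulin_plan
from glycoplan.monitor import (
    LOG_SLOTS,
    SLOT_TO_DOSE,
    AffectedDose,
    BolusAction,
    GlucoseLog,
    PatternDirection,
    PatternFinding,
    adjust_doses,
    advise_bolus,
    advise_bolus_with_exercise,
    advise_exercise_only,
    burned_calories,
    compute_icr,
    compute_isf,
    correction_band,
    detect_patterns,
    exercise_permitted,
)
from glycoplan.synth import reference_pattern_log

mgdl = lambda v: Quantity(value=v, unit=MGDL)  # noqa: E731
GOAL_70_140 = (mgdl(70), mgdl(140))


class TestFactors:
    def test_isf_1800_rule(self):
        assert compute_isf(50, MGDL) == 36

    def test_isf_100_rule(self):
        assert compute_isf(50, MMOL) == 2.0

    def test_icr_500_rule(self):
        assert compute_icr(50) == 10

    def test_icr_300_rule_small_tdd(self):
        assert compute_icr(8) == 37.5

    def test_icr_boundary_uses_500_rule(self):
        assert compute_icr(10) == 50

    @pytest.mark.parametrize("bad", [0, -1])
    def test_nonpositive_tdd_rejected(self, bad):
        with pytest.raises(InputError):
            compute_isf(bad)
        with pytest.raises(InputError):
            compute_icr(bad)

    @settings(derandomize=True)
    @given(st.floats(0.5, 300))
    def test_rule_identities(self, tdd):
        """ISF·TDD = 1800 (mg/dL) and ICR·TDD = 500 (or 300) exactly."""
        assert compute_isf(tdd, MGDL) * tdd == pytest.approx(1800, rel=1e-12)
        expected = 500 if tdd >= 10 else 300
        assert compute_icr(tdd) * tdd == pytest.approx(expected, rel=1e-12)


class TestCorrectionBand:
    GOAL = (mgdl(100), mgdl(150))

    @pytest.mark.parametrize("cbg,delta", [
        (65, -1), (120, 0), (170, 1), (220, 2), (270, 3), (310, 4), (500, 4),
        (75, 0),   # between 70 and goal low: treated as in-goal
        (100, 0), (150, 0),  # goal bounds inclusive
    ])
    def test_band_table(self, cbg, delta):
        assert correction_band(mgdl(cbg), self.GOAL) == delta

    def test_bands_anchor_at_goal_high(self):
        goal = (mgdl(80), mgdl(120))
        assert correction_band(mgdl(121), goal) == 1
        assert correction_band(mgdl(171), goal) == 2

    def test_unit_mismatch(self):
        with pytest.raises(UnitError):
            correction_band(Quantity(value=10, unit=MMOL), self.GOAL)


class TestAdviseBolus:
    def test_reference_meal_bolus(self):
        """TDD 50, 60 g meal, glucose 210 vs goal 120 -> inject 8.5 U."""
        advice = advise_bolus(mgdl(210), mgdl(120), 60, 50)
        assert advice.dbg == 90
        assert advice.n1 == pytest.approx(2.5)
        assert advice.n2 == pytest.approx(6.0)
        assert advice.bd == pytest.approx(8.5)
        assert advice.action is BolusAction.inject
        assert advice.bd_rounded == 8.5

    def test_on_target_no_meal_skips(self):
        advice = advise_bolus(mgdl(120), mgdl(120), 0, 50)
        assert advice.bd == 0
        assert advice.action is BolusAction.skip

    def test_negative_bd_converts_to_carbs(self):
        advice = advise_bolus(mgdl(84), mgdl(120), 0, 50)
        assert advice.bd == pytest.approx(-1.0)
        assert advice.action is BolusAction.eat_carbs
        assert advice.carbs_to_eat_g == pytest.approx(10.0)

    def test_unit_mismatch_rejected(self):
        with pytest.raises(UnitError):
            advise_bolus(mgdl(210), Quantity(value=6.7, unit=MMOL), 60, 50)

    def test_carbs_only_set_when_eating(self):
        assert advise_bolus(mgdl(210), mgdl(120), 60, 50).carbs_to_eat_g is None
        assert advise_bolus(mgdl(120), mgdl(120), 0, 50).carbs_to_eat_g is None

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(60, 400), st.floats(80, 180), st.floats(0, 150),
           st.floats(10, 120))
    def test_unit_conversion_invariance(self, cbg, pbg, carbs, tdd):
        """The same physiological state advised in mg/dL and mmol/L differs
        by less than 0.05 U (the 1800 vs 100 rules are near-equivalent)."""
        in_mgdl = advise_bolus(mgdl(cbg), mgdl(pbg), carbs, tdd)
        in_mmol = advise_bolus(convert_glucose(mgdl(cbg)),
                               convert_glucose(mgdl(pbg)), carbs, tdd)
        assert abs(in_mgdl.bd - in_mmol.bd) < 0.05


class TestExercise:
    def test_burned_calories(self):
        assert burned_calories(8, 70, 0.5) == 280
        assert burned_calories(6, 50, 1) == 300
        assert burned_calories(8, 70, 0) == 0

    @pytest.mark.parametrize("cbg,dka,permitted", [
        (260, False, False), (79, False, False), (150, False, True),
        (150, True, False), (80, False, True), (250, False, True),
    ])
    def test_exercise_gate(self, cbg, dka, permitted):
        assert exercise_permitted(mgdl(cbg), dka) is permitted

    def test_meal_plus_exercise_reduces_bolus(self):
        """Reference meal with 100 kcal of planned exercise: 8.5 - 2.5 = 6 U."""
        advice = advise_bolus_with_exercise(
            mgdl(210), mgdl(120), 60, 50, met=4, weight_kg=50, duration_h=0.5)
        assert advice.exercise_offset == pytest.approx(2.5)  # (100/4)/10
        assert advice.bd == pytest.approx(6.0)

    def test_zero_burn_equals_plain_advice(self):
        with_ex = advise_bolus_with_exercise(
            mgdl(210), mgdl(120), 60, 50, met=0, weight_kg=70, duration_h=1)
        plain = advise_bolus(mgdl(210), mgdl(120), 60, 50)
        assert with_ex.bd == plain.bd
        assert with_ex.n1 == plain.n1 and with_ex.n2 == plain.n2

    def test_gated_exercise_drops_offset(self):
        advice = advise_bolus_with_exercise(
            mgdl(260), mgdl(120), 60, 50, met=8, weight_kg=70, duration_h=1)
        assert advice.exercise_permitted is False
        assert advice.exercise_offset == 0
        assert advice.bd == pytest.approx(advise_bolus(
            mgdl(260), mgdl(120), 60, 50).bd)

    def test_exercise_only_overweight_subtracts(self):
        # N1 = 2 (DBG 72 / ISF 36), BC = 80 -> (80/4)/10 = 2 -> dose 0
        advice = advise_exercise_only(
            mgdl(192), mgdl(120), 50, met=4, weight_kg=40, duration_h=0.5,
            weight_status="overweight")
        assert advice.n1 == pytest.approx(2.0)
        assert advice.bd == pytest.approx(0.0)
        assert advice.action is BolusAction.skip
        assert advice.carbs_to_eat_g is None

    def test_exercise_only_normal_weight_eats_carbs(self):
        advice = advise_exercise_only(
            mgdl(120), mgdl(120), 50, met=4, weight_kg=40, duration_h=0.5,
            weight_status="normal")
        assert advice.carbs_to_eat_g == pytest.approx(20.0)  # BC/4
        # the stated rule adds the equivalent units to N1
        assert advice.bd == pytest.approx(2.0)

    def test_exercise_only_zero_burn_is_pure_correction(self):
        advice = advise_exercise_only(
            mgdl(156), mgdl(120), 50, met=0, weight_kg=70, duration_h=1)
        assert advice.bd == pytest.approx(1.0)
        assert advice.carbs_to_eat_g is None


def make_log(values_by_day, unit=MGDL, start=date(2024, 3, 1)):
    entries = {}
    for offset, per_slot in enumerate(values_by_day):
        day = start + timedelta(days=offset)
        for slot, value in per_slot.items():
            if value is not None:
                entries[(day, Slot(slot))] = Quantity(value=value, unit=unit)
    return GlucoseLog(entries)


def brute_force_patterns(log, low, high):
    """Independent oracle: enumerate all consecutive-3-day windows per slot."""
    findings = {}
    days = log.dates()
    for i, j, k in itertools.combinations(range(len(days)), 3):
        if not (days[j] == days[i] + timedelta(days=1)
                and days[k] == days[i] + timedelta(days=2)):
            continue
        for slot in LOG_SLOTS:
            vals = [log.value(days[x], slot) for x in (i, j, k)]
            if any(v is None for v in vals):
                continue
            nums = [v.value for v in vals]
            if all(n > high for n in nums):
                findings[slot] = ("high", (days[i], days[j], days[k]))
            elif all(n < low for n in nums):
                findings[slot] = ("low", (days[i], days[j], days[k]))
    return findings


class TestDetectPatterns:
    def test_reference_log_single_fasting_finding(self):
        """Persistent fasting hyperglycemia -> raise the bedtime basal by
        at least 10 %; the single before-dinner excursion is ignored."""
        findings = detect_patterns(reference_pattern_log(), GOAL_70_140)
        assert len(findings) == 1
        finding = findings[0]
        assert finding.slot is Slot.before_breakfast
        assert finding.direction is PatternDirection.high
        assert finding.affected_dose is AffectedDose.bedtime_basal
        assert finding.adjustment_fraction >= 0.10

    def test_single_excursion_never_triggers(self):
        log = make_log([
            {"before_dinner": 100}, {"before_dinner": 300},
            {"before_dinner": 100},
        ])
        assert detect_patterns(log, GOAL_70_140) == []

    def test_all_in_range_no_findings(self):
        log = make_log([{s.value: 100 for s in LOG_SLOTS}] * 4)
        assert detect_patterns(log, GOAL_70_140) == []

    def test_low_pattern_direction(self):
        log = make_log([{"before_lunch": 60}] * 3)
        findings = detect_patterns(log, GOAL_70_140)
        assert findings[0].direction is PatternDirection.low
        assert findings[0].affected_dose is AffectedDose.before_breakfast_bolus

    @pytest.mark.parametrize("slot,dose", list(SLOT_TO_DOSE.items()))
    def test_slot_to_dose_mapping(self, slot, dose):
        log = make_log([{slot.value: 400}] * 3)
        findings = detect_patterns(log, GOAL_70_140)
        assert findings[0].affected_dose is dose

    def test_insufficient_data(self):
        log = make_log([{"before_lunch": 100}] * 2)
        with pytest.raises(InsufficientDataError):
            detect_patterns(log, GOAL_70_140)

    def test_non_consecutive_days_insufficient(self):
        entries = {
            (date(2024, 3, 1), Slot.before_lunch): mgdl(100),
            (date(2024, 3, 3), Slot.before_lunch): mgdl(100),
            (date(2024, 3, 5), Slot.before_lunch): mgdl(100),
        }
        with pytest.raises(InsufficientDataError):
            detect_patterns(GlucoseLog(entries), GOAL_70_140)

    def test_longer_log_keeps_most_recent_window(self):
        log = make_log([
            {"before_breakfast": 300}, {"before_breakfast": 300},
            {"before_breakfast": 300}, {"before_breakfast": 100},
            {"before_breakfast": 300}, {"before_breakfast": 300},
            {"before_breakfast": 300},
        ])
        findings = detect_patterns(log, GOAL_70_140)
        assert findings[0].window[0] == date(2024, 3, 5)

    def test_agrees_with_brute_force_on_random_logs(self):
        """1000 random logs: detector == exhaustive window scan."""
        rng = random.Random(20240301)
        for _ in range(1000):
            days = rng.randint(3, 7)
            values = []
            for _ in range(days):
                per_slot = {}
                for slot in LOG_SLOTS:
                    if rng.random() < 0.15:
                        per_slot[slot.value] = None
                    else:
                        per_slot[slot.value] = rng.choice(
                            [40, 60, 100, 120, 139, 141, 200, 350])
                values.append(per_slot)
            log = make_log(values)
            try:
                findings = detect_patterns(log, GOAL_70_140)
            except InsufficientDataError:
                continue
            expected = brute_force_patterns(log, 70, 140)
            got = {f.slot: (f.direction.value, f.window) for f in findings}
            assert got == expected


class TestAdjustDoses:
    def regimen(self, kb):
        from glycoplan.core import PatientProfile

        p = PatientProfile(id="x", age=40, sex="male", weight=250 / 3,
                           height=178, regimen_preference="IIT")
        return build_insulin_plan(p, kb)

    def finding(self, dose, direction="high", fraction=0.10):
        return PatternFinding(
            slot=next(s for s, d in SLOT_TO_DOSE.items() if d is dose),
            direction=direction, affected_dose=dose,
            adjustment_fraction=fraction,
            window=(date(2024, 3, 1), date(2024, 3, 2), date(2024, 3, 3)),
        )

    def test_high_fasting_raises_bedtime_basal_10_percent(self, kb):
        regimen = self.regimen(kb)
        basal_before = regimen.doses[0].units
        adjusted = adjust_doses(regimen, [self.finding(AffectedDose.bedtime_basal)])
        assert adjusted.doses[0].units == pytest.approx(1.10 * basal_before)

    def test_other_doses_untouched(self, kb):
        regimen = self.regimen(kb)
        adjusted = adjust_doses(regimen, [self.finding(AffectedDose.bedtime_basal)])
        assert [d.units for d in adjusted.doses[1:]] == \
            [d.units for d in regimen.doses[1:]]
        assert adjusted.tdd == pytest.approx(adjusted.total_units)

    def test_no_findings_identity(self, kb):
        regimen = self.regimen(kb)
        adjusted = adjust_doses(regimen, [])
        assert [d.units for d in adjusted.doses] == \
            [d.units for d in regimen.doses]

    def test_low_pattern_decreases(self, kb):
        regimen = self.regimen(kb)
        finding = self.finding(AffectedDose.before_lunch_bolus, "low", 0.20)
        adjusted = adjust_doses(regimen, [finding])
        lunch = next(d for d in adjusted.doses
                     if d.timing.value == "before_lunch")
        original = next(d for d in regimen.doses
                        if d.timing.value == "before_lunch")
        assert lunch.units == pytest.approx(0.80 * original.units)

    def test_fraction_outside_band_rejected(self):
        with pytest.raises(ValueError):
            self.finding(AffectedDose.bedtime_basal, fraction=0.25)
        with pytest.raises(ValueError):
            self.finding(AffectedDose.bedtime_basal, fraction=0.05)

    def test_disjoint_adjustments_commute(self, kb):
        regimen = self.regimen(kb)
        f1 = self.finding(AffectedDose.bedtime_basal)
        f2 = self.finding(AffectedDose.before_dinner_bolus, "low")
        one = adjust_doses(adjust_doses(regimen, [f1]), [f2])
        other = adjust_doses(adjust_doses(regimen, [f2]), [f1])
        assert [d.units for d in one.doses] == \
            pytest.approx([d.units for d in other.doses])

    def test_missing_dose_raises_mapping_error(self, kb):
        from glycoplan.core import PatientProfile

        p = PatientProfile(id="x", age=40, sex="male", weight=70,
                           height=175, regimen_preference="IIT")
        regimen = build_insulin_plan(p, kb, basal_shots=2)  # no bedtime dose
        with pytest.raises(DoseMappingError):
            adjust_doses(regimen, [self.finding(AffectedDose.bedtime_basal)])

    def test_fixed_regimen_rejected(self, kb, fixed_twice_profile):
        regimen = build_insulin_plan(fixed_twice_profile, kb)
        with pytest.raises(InputError):
            adjust_doses(regimen, [])
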