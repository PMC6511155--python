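"""Real-time bolus advice and multi-day glucose pattern management.

Bolus advice (IIT patients only) follows the correction-factor arithmetic:

* ISF (insulin sensitivity factor) by the 1800 rule in mg/dL, 100 rule in
  mmol/L: ISF = f / TDD.
* ICR (insulin-to-carb ratio) by the 500 rule, or the 300 rule for small
  total daily doses (TDD < 10 U, typically children): ICR = 500/TDD or
  300/TDD grams per unit.
* DBG = CBG − PBG, N1 = DBG/ISF (correction), N2 = MC/ICR (carb cover),
  BD = N1 + N2. Positive BD → inject; zero → skip; negative → eat carbs.
* Planned exercise burns BC = MET × weight × duration(h) kcal; within
  3 h of a meal the bolus is reduced by (BC/4)/ICR units.

Pattern management scans a per-slot glucose log: three consecutive days
out of goal on the same side in the same slot trigger a 10–20 % adjustment
of the dose responsible for that slot (the before-breakfast slot reflects
the bedtime basal; each pre-meal slot reflects the previous meal's bolus).
A single excursion never triggers anything.
"""

from __future__ import annotations

import enum
import math
from datetime import date, timedelta
from typing import Iterable, Mapping, Optional

from pydantic import BaseModel, ConfigDict, field_validator

from .core import MGDL, Quantity, Slot, to_mgdl
from .errors import (
    DoseMappingError,
    InputError,
    InsufficientDataError,
    UnitError,
)
from .insulin import DoseKind, DoseTiming, InsulinRegimen
from .core import RegimenKind

__all__ = [
    "BolusAction",
    "BolusAdvice",
    "GlucoseLog",
    "AffectedDose",
    "PatternDirection",
    "PatternFinding",
    "compute_isf",
    "compute_icr",
    "correction_band",
    "advise_bolus",
    "burned_calories",
    "exercise_permitted",
    "advise_bolus_with_exercise",
    "advise_exercise_only",
    "detect_patterns",
    "adjust_doses",
]

#: Exercise is forbidden outside this glucose window (mg/dL) or with DKA.
EXERCISE_BG_LOW_MGDL = 80.0
EXERCISE_BG_HIGH_MGDL = 250.0

#: Pattern-driven dose changes must stay within this fraction band.
MIN_ADJUSTMENT = 0.10
MAX_ADJUSTMENT = 0.20

#: Slots scanned by pattern management (chronological order).
LOG_SLOTS = (
    Slot.before_breakfast,
    Slot.before_lunch,
    Slot.before_dinner,
    Slot.before_bedtime,
)


class BolusAction(str, enum.Enum):
    inject = "inject"
    skip = "skip"
    eat_carbs = "eat_carbs"


class BolusAdvice(BaseModel):
    """A bolus recommendation with its audit-trail intermediates.

    ``bd`` is the exact computed dose; ``bd_rounded`` is the display value
    rounded to the nearest 0.5 U. ``carbs_to_eat_g`` is set when the
    patient should eat carbohydrate instead of (or, for exercise-only
    advice at healthy weight, alongside) injecting.
    """

    model_config = ConfigDict(frozen=True)

    dbg: float
    n1: float
    n2: float
    exercise_offset: float = 0.0
    bd: float
    action: BolusAction
    carbs_to_eat_g: Optional[float] = None
    exercise_permitted: bool = True

    @property
    def bd_rounded(self) -> float:
        return _round_half_unit(self.bd)


def _round_half_unit(x: float) -> float:
    """Round to the nearest 0.5 U, halves away from zero."""
    return math.copysign(math.floor(abs(x) * 2.0 + 0.5) / 2.0, x)


def compute_isf(tdd: float, unit: str = MGDL) -> float:
    """Insulin sensitivity factor: 1800/TDD (mg/dL) or 100/TDD (mmol/L)."""
    if not (tdd > 0):
        raise InputError(f"tdd must be positive, got {tdd!r}")
    if unit == MGDL:
        return 1800.0 / tdd
    if unit == "mmol/L":
        return 100.0 / tdd
    raise UnitError(f"unknown glucose unit {unit!r}")


def compute_icr(tdd: float) -> float:
    """Insulin-to-carb ratio: 500/TDD, or 300/TDD when TDD < 10 U."""
    if not (tdd > 0):
        raise InputError(f"tdd must be positive, got {tdd!r}")
    rule = 500.0 if tdd >= 10.0 else 300.0
    return rule / tdd


def correction_band(cbg: Quantity, goal: tuple[Quantity, Quantity]) -> int:
    """Banded dose delta (units) relative to the planned bolus.

    Below 70 mg/dL the planned dose drops by one unit; inside the goal
    range the planned dose stands; above the goal's upper bound the dose
    rises one unit per started 50 mg/dL band, capped at +4. The band
    between 70 mg/dL and the goal's lower bound is treated as in-goal
    (the published table leaves it unstated). Bands are anchored at the
    goal bounds so the rule is total over arbitrary goal ranges.
    """
    low, high = goal
    if not (cbg.unit == low.unit == high.unit):
        raise UnitError(
            f"correction_band requires one unit, got {cbg.unit!r}, "
            f"{low.unit!r}, {high.unit!r}"
        )
    value = to_mgdl(cbg)
    low_mgdl, high_mgdl = to_mgdl(low), to_mgdl(high)
    if value < 70.0:
        return -1
    if value <= high_mgdl:
        return 0
    return min(4, math.ceil((value - high_mgdl) / 50.0))


def advise_bolus(
    cbg: Quantity,
    goal_pbg: Quantity,
    meal_carbs_g: float,
    tdd: float,
) -> BolusAdvice:
    """Meal bolus advice from current glucose, goal, carbs and TDD.

    All quantities must share one glucose unit. DBG = CBG − PBG,
    N1 = DBG/ISF, N2 = MC/ICR, BD = N1 + N2. A negative BD converts to
    carbohydrate to eat: (−BD)·ICR grams.
    """
    if cbg.unit != goal_pbg.unit:
        raise UnitError(
            f"CBG and PBG must share a unit, got {cbg.unit!r} and {goal_pbg.unit!r}"
        )
    if meal_carbs_g < 0:
        raise InputError(f"meal carbs must be non-negative, got {meal_carbs_g!r}")
    isf = compute_isf(tdd, cbg.unit)
    icr = compute_icr(tdd)
    dbg = cbg.value - goal_pbg.value
    n1 = dbg / isf
    n2 = meal_carbs_g / icr
    return _finish_advice(dbg, n1, n2, 0.0, icr, permitted=True)


def _finish_advice(
    dbg: float, n1: float, n2: float, offset: float, icr: float, permitted: bool
) -> BolusAdvice:
    bd = n1 + n2 - offset
    if bd > 0:
        action = BolusAction.inject
        carbs = None
    elif bd == 0:
        action = BolusAction.skip
        carbs = None
    else:
        action = BolusAction.eat_carbs
        carbs = -bd * icr
    return BolusAdvice(dbg=dbg, n1=n1, n2=n2, exercise_offset=offset, bd=bd,
                       action=action, carbs_to_eat_g=carbs,
                       exercise_permitted=permitted)


def burned_calories(met: float, weight_kg: float, duration_h: float) -> float:
    """Energy expenditure of an activity: BC = MET × weight × duration."""
    if met < 0 or weight_kg < 0 or duration_h < 0:
        raise InputError("MET, weight and duration must be non-negative")
    return met * weight_kg * duration_h


def exercise_permitted(cbg: Quantity, has_dka: bool = False) -> bool:
    """Exercise safety gate: glucose must sit in (80, 250) mg/dL and the
    patient must be free of diabetic ketoacidosis."""
    value = to_mgdl(cbg)
    if has_dka:
        return False
    return EXERCISE_BG_LOW_MGDL <= value <= EXERCISE_BG_HIGH_MGDL


def advise_bolus_with_exercise(
    cbg: Quantity,
    goal_pbg: Quantity,
    meal_carbs_g: float,
    tdd: float,
    met: float,
    weight_kg: float,
    duration_h: float,
    has_dka: bool = False,
) -> BolusAdvice:
    """Meal bolus when exercise is planned within 3 h after the meal.

    The bolus is reduced by the insulin equivalent of the calories burned,
    BD = N1 + N2 − (BC/4)/ICR. If the safety gate forbids exercising, the
    offset is zero and the advice is flagged exercise_permitted = False.
    """
    if cbg.unit != goal_pbg.unit:
        raise UnitError(
            f"CBG and PBG must share a unit, got {cbg.unit!r} and {goal_pbg.unit!r}"
        )
    if meal_carbs_g < 0:
        raise InputError(f"meal carbs must be non-negative, got {meal_carbs_g!r}")
    isf = compute_isf(tdd, cbg.unit)
    icr = compute_icr(tdd)
    dbg = cbg.value - goal_pbg.value
    n1 = dbg / isf
    n2 = meal_carbs_g / icr
    permitted = exercise_permitted(cbg, has_dka)
    offset = 0.0
    if permitted:
        bc = burned_calories(met, weight_kg, duration_h)
        offset = (bc / 4.0) / icr
    return _finish_advice(dbg, n1, n2, offset, icr, permitted)


def advise_exercise_only(
    cbg: Quantity,
    goal_pbg: Quantity,
    tdd: float,
    met: float,
    weight_kg: float,
    duration_h: float,
    weight_status: str = "normal",
    has_dka: bool = False,
) -> BolusAdvice:
    """Advice for exercise not within 3 h of any meal (no carb cover, N2=0).

    Underweight or normal-weight patients are told to eat the equivalent
    carb grams (BC/4), with the matching insulin units (BC/4)/ICR added to
    the correction dose N1 — implemented exactly as stated. Overweight
    patients have those units subtracted from N1 instead, with no carbs.
    """
    isf = compute_isf(tdd, cbg.unit)
    icr = compute_icr(tdd)
    dbg = cbg.value - goal_pbg.value
    n1 = dbg / isf
    permitted = exercise_permitted(cbg, has_dka)
    if not permitted:
        return _finish_advice(dbg, n1, 0.0, 0.0, icr, permitted=False)
    from .diet import WeightStatus

    bc = burned_calories(met, weight_kg, duration_h)
    equiv_units = (bc / 4.0) / icr
    if WeightStatus(weight_status) is WeightStatus.overweight:
        return _finish_advice(dbg, n1, 0.0, equiv_units, icr, permitted=True)
    # underweight / normal: carbs to eat plus the stated unit addition
    bd = n1 + equiv_units
    if bd > 0:
        action = BolusAction.inject
    elif bd == 0:
        action = BolusAction.skip
    else:
        action = BolusAction.eat_carbs
    carbs = bc / 4.0 if bc > 0 else None
    return BolusAdvice(dbg=dbg, n1=n1, n2=0.0, exercise_offset=-equiv_units,
                       bd=bd, action=action, carbs_to_eat_g=carbs,
                       exercise_permitted=True)


# ---------------------------------------------------------------------------
# Pattern management
# ---------------------------------------------------------------------------


class GlucoseLog:
    """Per-day, per-slot glucose readings, all in one unit.

    ``entries`` maps (date, slot) to a glucose Quantity; at most one value
    per cell. Iteration over dates is chronological.
    """

    def __init__(self, entries: Mapping[tuple[date, Slot], Quantity]):
        unit: Optional[str] = None
        self.entries: dict[tuple[date, Slot], Quantity] = {}
        for (day, slot), value in entries.items():
            slot = Slot(slot)
            if slot not in LOG_SLOTS:
                raise InputError(f"log slot must be one of {LOG_SLOTS}, got {slot}")
            if unit is None:
                unit = value.unit
            elif value.unit != unit:
                raise UnitError(
                    f"log values must share a unit, got {unit!r} and {value.unit!r}"
                )
            if (day, slot) in self.entries:
                raise InputError(f"duplicate entry for {day} {slot.value}")
            self.entries[(day, slot)] = value
        self.unit = unit or MGDL

    def dates(self) -> list[date]:
        return sorted({day for day, _ in self.entries})

    def value(self, day: date, slot: Slot) -> Optional[Quantity]:
        return self.entries.get((day, slot))

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GlucoseLog) and self.entries == other.entries


class PatternDirection(str, enum.Enum):
    high = "high"
    low = "low"


class AffectedDose(str, enum.Enum):
    before_breakfast_bolus = "before_breakfast_bolus"
    before_lunch_bolus = "before_lunch_bolus"
    before_dinner_bolus = "before_dinner_bolus"
    bedtime_basal = "bedtime_basal"


#: Which planned dose each out-of-goal slot reflects: a pre-meal reading
#: reflects the previous meal's bolus; the fasting (before-breakfast)
#: reading reflects the bedtime basal.
SLOT_TO_DOSE: dict[Slot, AffectedDose] = {
    Slot.before_lunch: AffectedDose.before_breakfast_bolus,
    Slot.before_dinner: AffectedDose.before_lunch_bolus,
    Slot.before_bedtime: AffectedDose.before_dinner_bolus,
    Slot.before_breakfast: AffectedDose.bedtime_basal,
}


class PatternFinding(BaseModel):
    model_config = ConfigDict(frozen=True)

    slot: Slot
    direction: PatternDirection
    affected_dose: AffectedDose
    adjustment_fraction: float = MIN_ADJUSTMENT
    window: tuple[date, date, date]

    @field_validator("adjustment_fraction")
    @classmethod
    def _fraction_band(cls, v: float) -> float:
        if not (MIN_ADJUSTMENT <= v <= MAX_ADJUSTMENT):
            raise ValueError(
                f"adjustment_fraction must lie in [{MIN_ADJUSTMENT}, "
                f"{MAX_ADJUSTMENT}], got {v}"
            )
        return v


def detect_patterns(
    log: GlucoseLog,
    goal: tuple[Quantity, Quantity],
    adjustment_fraction: float = MIN_ADJUSTMENT,
) -> list[PatternFinding]:
    """Scan every 3-consecutive-day window for same-slot, same-side runs.

    A finding is emitted for a slot iff all three values of some window lie
    outside the goal range on the same side; single excursions never
    trigger. Longer logs are scanned window by window and findings are
    deduplicated per slot, keeping the most recent window. Requires at
    least three consecutive calendar dates in the log.
    """
    low, high = goal
    low_v = _goal_in_unit(low, log.unit)
    high_v = _goal_in_unit(high, log.unit)
    days = log.dates()
    windows = [
        (days[i], days[i + 1], days[i + 2])
        for i in range(len(days) - 2)
        if days[i + 1] == days[i] + timedelta(days=1)
        and days[i + 2] == days[i] + timedelta(days=2)
    ]
    if not windows:
        raise InsufficientDataError(
            "pattern management needs at least three consecutive days of readings"
        )
    latest: dict[Slot, PatternFinding] = {}
    for window in windows:
        for slot in LOG_SLOTS:
            values = [log.value(day, slot) for day in window]
            if any(v is None for v in values):
                continue
            nums = [v.value for v in values]  # type: ignore[union-attr]
            if all(v > high_v for v in nums):
                direction = PatternDirection.high
            elif all(v < low_v for v in nums):
                direction = PatternDirection.low
            else:
                continue
            latest[slot] = PatternFinding(
                slot=slot,
                direction=direction,
                affected_dose=SLOT_TO_DOSE[slot],
                adjustment_fraction=adjustment_fraction,
                window=window,
            )
    return sorted(latest.values(), key=lambda f: LOG_SLOTS.index(f.slot))


def _goal_in_unit(q: Quantity, unit: str) -> float:
    if q.unit == unit:
        return q.value
    if unit == MGDL:
        return to_mgdl(q)
    from .core import to_mmol

    return to_mmol(q)


_DOSE_MATCH: dict[AffectedDose, tuple[DoseKind, DoseTiming]] = {
    AffectedDose.before_breakfast_bolus: (DoseKind.bolus, DoseTiming.before_breakfast),
    AffectedDose.before_lunch_bolus: (DoseKind.bolus, DoseTiming.before_lunch),
    AffectedDose.before_dinner_bolus: (DoseKind.bolus, DoseTiming.before_dinner),
    AffectedDose.bedtime_basal: (DoseKind.basal, DoseTiming.bedtime),
}


def adjust_doses(
    regimen: InsulinRegimen, findings: Iterable[PatternFinding]
) -> InsulinRegimen:
    """Apply pattern findings to an IIT regimen.

    Each affected dose is scaled by (1 ± adjustment_fraction) — up for a
    high pattern, down for a low one. Unaffected doses are untouched and
    the regimen's TDD is updated to the new dose sum. The plan-time basal
    fraction is retained as provenance even though the realised split
    drifts off the planning grid.
    """
    if regimen.kind is not RegimenKind.IIT:
        raise InputError("dose adjustment applies to IIT regimens only")
    doses = list(regimen.doses)
    for finding in findings:
        kind, timing = _DOSE_MATCH[finding.affected_dose]
        index = next(
            (i for i, d in enumerate(doses)
             if d.kind is kind and d.timing is timing),
            None,
        )
        if index is None:
            raise DoseMappingError(
                f"regimen has no {kind.value} dose at {timing.value} for "
                f"finding on slot {finding.slot.value}"
            )
        sign = 1.0 if finding.direction is PatternDirection.high else -1.0
        scale = 1.0 + sign * finding.adjustment_fraction
        doses[index] = doses[index].model_copy(
            update={"units": doses[index].units * scale}
        )
    new_tdd = sum(d.units for d in doses)
    return InsulinRegimen(kind=regimen.kind, tdd=new_tdd,
                          f_factor=regimen.f_factor, doses=doses)
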