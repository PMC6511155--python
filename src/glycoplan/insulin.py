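"""Long-term insulin sub-plan: goals, regimen, TDD and dose splits.

The total daily dose (TDD) is weight-based, TDD = 0.6 U/kg/day. The daily
fixed (DF) twice-daily regimen splits it 2/3 morning : 1/3 evening, the
morning dose again 2/3 intermediate : 1/3 short, the evening dose half and
half. Intensive insulin therapy (basal-bolus, IIT) splits TDD into a basal
fraction f (one of 0.3/0.4/0.5/0.6, default 0.5) and a bolus remainder
divided equally over the three meals.

Dose amounts are kept exact internally; ``InsulinDose.rounded_units``
rounds to the nearest whole unit for presentation.
"""

from __future__ import annotations

import enum
import math
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator

from .core import (
    AgeCategory,
    GoalSet,
    PatientProfile,
    RegimenKind,
    RegimenPreference,
    categorize_age,
)
from .errors import InputError
from .knowledge import (
    ActionClass,
    InsulinProduct,
    KnowledgeBase,
    contradicted_insulins,
    select_insulin,
)

__all__ = [
    "GoalSet",
    "DoseTiming",
    "DoseKind",
    "InsulinDose",
    "InsulinRegimen",
    "ALLOWED_BASAL_FRACTIONS",
    "set_goals",
    "choose_regimen",
    "compute_tdd",
    "split_fixed_twice",
    "split_iit",
    "build_insulin_plan",
]

#: TDD rule: units of insulin per kg of body weight per day.
TDD_UNITS_PER_KG = 0.6

#: Allowed basal fractions f for IIT.
ALLOWED_BASAL_FRACTIONS = (0.3, 0.4, 0.5, 0.6)


class DoseTiming(str, enum.Enum):
    morning = "morning"
    evening = "evening"
    bedtime = "bedtime"
    before_breakfast = "before_breakfast"
    before_lunch = "before_lunch"
    before_dinner = "before_dinner"


class DoseKind(str, enum.Enum):
    basal = "basal"
    bolus = "bolus"
    mixed_long = "mixed_long"
    mixed_short = "mixed_short"


class InsulinDose(BaseModel):
    model_config = ConfigDict(frozen=True)

    product: InsulinProduct
    units: float
    timing: DoseTiming
    kind: DoseKind

    @field_validator("units")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("units must be non-negative")
        return v

    @property
    def rounded_units(self) -> int:
        """Presentation rounding to the nearest whole unit (half up)."""
        return int(math.floor(self.units + 0.5))


class InsulinRegimen(BaseModel):
    kind: RegimenKind
    tdd: float
    f_factor: Optional[float] = None  # IIT basal fraction at plan time
    doses: list[InsulinDose]

    @property
    def total_units(self) -> float:
        return sum(d.units for d in self.doses)

    def dose_by(self, kind: DoseKind, timing: DoseTiming) -> Optional[InsulinDose]:
        for d in self.doses:
            if d.kind is kind and d.timing is timing:
                return d
        return None


def set_goals(profile: PatientProfile, kb: KnowledgeBase) -> GoalSet:
    """SMART goals for the patient's demographic stratum.

    The pregnant-adult stratum is rule-defined: HbA1c < 6.5 % and pre-meal
    glucose within [90, 100] mg/dL. Every other stratum comes from the
    knowledge base's goal-defaults table (a hypoglycemia history selects
    the stratum's relaxed override when configured). The diet planner
    fills in the weight goal afterwards.
    """
    age_cat = categorize_age(profile.age, kb.age_bands)
    if age_cat is AgeCategory.adult and profile.pregnant:
        # rule-pinned stratum, independent of config edits to the table
        from .core import Quantity

        base = kb.goal_default(AgeCategory.adult, True)
        return base.model_copy(update={
            "hba1c_max": 6.5,
            "premeal_bg_low": Quantity(value=90, unit="mg/dL"),
            "premeal_bg_high": Quantity(value=100, unit="mg/dL"),
        })
    return kb.goal_default(
        age_cat, profile.pregnant, hypo_history=profile.history_of_hypoglycemia > 0
    )


def choose_regimen(
    profile: PatientProfile, kb: Optional[KnowledgeBase] = None
) -> RegimenKind:
    """Regimen selection: IIT is forced for pregnant patients and children,
    adults keep their stated preference, and no preference means IIT."""
    bands = kb.age_bands if kb is not None else None
    age_cat = categorize_age(profile.age, bands)
    if profile.pregnant or age_cat is AgeCategory.child:
        return RegimenKind.IIT
    if profile.regimen_preference is RegimenPreference.none:
        return RegimenKind.IIT
    return RegimenKind(profile.regimen_preference.value)


def compute_tdd(weight: float) -> float:
    """Weight-based total daily dose: TDD = 0.6 x W units/day, unrounded."""
    if not (weight > 0) or not math.isfinite(weight):
        raise InputError(f"weight must be positive and finite, got {weight!r}")
    return TDD_UNITS_PER_KG * weight


def split_fixed_twice(tdd: float) -> tuple[float, float, float, float]:
    """DF twice-daily split: (MD_L, MD_S, ED_L, ED_S).

    MD = 2/3 TDD and ED = 1/3 TDD; the morning dose splits 2/3 long- or
    intermediate-acting vs 1/3 short-acting, the evening dose half/half.
    The four parts sum to TDD exactly (before any presentation rounding).
    """
    if tdd < 0:
        raise InputError(f"tdd must be non-negative, got {tdd!r}")
    md = 2.0 / 3.0 * tdd
    ed = tdd - md
    md_l = 2.0 / 3.0 * md
    md_s = md - md_l
    ed_l = ed / 2.0
    ed_s = ed - ed_l
    return md_l, md_s, ed_l, ed_s


def split_iit(tdd: float, f: float = 0.5) -> tuple[float, float, float]:
    """IIT split: (BA, BO, premeal) with BA = f·TDD, BO = (1−f)·TDD,
    premeal = BO/3. f must be one of 0.3, 0.4, 0.5 or 0.6."""
    if not any(math.isclose(f, allowed) for allowed in ALLOWED_BASAL_FRACTIONS):
        raise InputError(
            f"basal fraction f must be one of {ALLOWED_BASAL_FRACTIONS}, got {f!r}"
        )
    if tdd < 0:
        raise InputError(f"tdd must be non-negative, got {tdd!r}")
    ba = f * tdd
    bo = tdd - ba
    return ba, bo, bo / 3.0


def build_insulin_plan(
    profile: PatientProfile,
    kb: KnowledgeBase,
    f: float = 0.5,
    basal_shots: int = 1,
) -> InsulinRegimen:
    """Assemble the full insulin regimen for a patient.

    Composes regimen choice, TDD, the matching dose split, and safe product
    selection per action class (IIT: long-acting basal + rapid-acting
    bolus; DF twice-daily: intermediate + short, morning and evening; DF
    once-daily: a single long-acting shot). ``basal_shots`` = 2 divides the
    IIT basal dose equally between morning and evening; the default is one
    bedtime shot.
    """
    if basal_shots not in (1, 2):
        raise InputError(f"basal_shots must be 1 or 2, got {basal_shots!r}")
    kind = choose_regimen(profile, kb)
    tdd = compute_tdd(profile.weight)
    contraindicated = contradicted_insulins(profile, kb)

    def pick(action_class: ActionClass) -> InsulinProduct:
        return select_insulin(action_class, profile, kb, contraindicated)

    doses: list[InsulinDose] = []
    f_factor: Optional[float] = None
    if kind is RegimenKind.IIT:
        f_factor = f
        ba, _bo, premeal = split_iit(tdd, f)
        basal_product = pick(ActionClass.long)
        bolus_product = pick(ActionClass.rapid)
        if basal_shots == 1:
            doses.append(InsulinDose(product=basal_product, units=ba,
                                     timing=DoseTiming.bedtime, kind=DoseKind.basal))
        else:
            for timing in (DoseTiming.morning, DoseTiming.evening):
                doses.append(InsulinDose(product=basal_product, units=ba / 2.0,
                                         timing=timing, kind=DoseKind.basal))
        for timing in (DoseTiming.before_breakfast, DoseTiming.before_lunch,
                       DoseTiming.before_dinner):
            doses.append(InsulinDose(product=bolus_product, units=premeal,
                                     timing=timing, kind=DoseKind.bolus))
    elif kind is RegimenKind.fixed_twice:
        md_l, md_s, ed_l, ed_s = split_fixed_twice(tdd)
        long_product = pick(ActionClass.intermediate)
        short_product = pick(ActionClass.short)
        doses = [
            InsulinDose(product=long_product, units=md_l,
                        timing=DoseTiming.morning, kind=DoseKind.mixed_long),
            InsulinDose(product=short_product, units=md_s,
                        timing=DoseTiming.morning, kind=DoseKind.mixed_short),
            InsulinDose(product=long_product, units=ed_l,
                        timing=DoseTiming.evening, kind=DoseKind.mixed_long),
            InsulinDose(product=short_product, units=ed_s,
                        timing=DoseTiming.evening, kind=DoseKind.mixed_short),
        ]
    else:  # fixed_once: one long-acting shot covering the whole TDD
        long_product = pick(ActionClass.long)
        doses = [InsulinDose(product=long_product, units=tdd,
                             timing=DoseTiming.morning, kind=DoseKind.basal)]

    return InsulinRegimen(kind=kind, tdd=tdd, f_factor=f_factor, doses=doses)
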