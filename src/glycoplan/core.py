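"""Shared domain types, glucose unit handling, and demographic classification.

Glucose quantities circulate in either UCUM unit ``mg/dL`` or ``mmol/L``.
Arithmetic is done in whatever unit the caller supplied; whenever two
quantities of different units must be compared they are first converted to
mg/dL. The conversion factor is 18.0182 mg/dL per mmol/L (molar mass of
glucose, 180.182 g/mol, divided by 10).
"""

from __future__ import annotations

import enum
import math
from datetime import datetime
from typing import Optional

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import InputError, UnitError

#: mg/dL per mmol/L of glucose.
MGDL_PER_MMOL = 18.0182

MGDL = "mg/dL"
MMOL = "mmol/L"
_GLUCOSE_UNITS = {MGDL, MMOL}


class Coding(BaseModel):
    """A coded concept: terminology system + code + human-readable display."""

    model_config = ConfigDict(frozen=True)

    system: str
    code: str
    display: str = ""

    @field_validator("system", "code")
    @classmethod
    def _non_empty(cls, v: str) -> str:
        if not v:
            raise ValueError("system and code must be non-empty")
        return v


class Quantity(BaseModel):
    """A measured value with a UCUM unit code."""

    model_config = ConfigDict(frozen=True)

    value: float
    unit: str

    @field_validator("unit")
    @classmethod
    def _unit_non_empty(cls, v: str) -> str:
        if not v:
            raise ValueError("unit must be non-empty")
        return v

    @field_validator("value")
    @classmethod
    def _finite(cls, v: float) -> float:
        if not math.isfinite(v):
            raise ValueError("value must be finite")
        return v


class Slot(str, enum.Enum):
    """Time-of-day slot of a glucose reading."""

    before_breakfast = "before_breakfast"
    before_lunch = "before_lunch"
    before_dinner = "before_dinner"
    before_bedtime = "before_bedtime"
    other = "other"


class ObservationSource(str, enum.Enum):
    sensor = "sensor"
    manual = "manual"
    ehr = "ehr"


class ObservationRecord(BaseModel):
    """One timestamped observation (vital sign, glucose reading, ...)."""

    model_config = ConfigDict(frozen=True)

    code: Coding
    value: Quantity
    timestamp: datetime
    slot: Slot = Slot.other
    source: ObservationSource = ObservationSource.sensor


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class Lifestyle(str, enum.Enum):
    sedentary = "sedentary"
    lightly_active = "lightly_active"
    moderately_active = "moderately_active"
    very_active = "very_active"
    extra_active = "extra_active"


class EducationLevel(str, enum.Enum):
    low = "low"
    medium = "medium"
    high = "high"


class RegimenKind(str, enum.Enum):
    """Insulin regimen family: basal-bolus (IIT) or daily-fixed shots."""

    IIT = "IIT"
    fixed_once = "fixed_once"
    fixed_twice = "fixed_twice"


class RegimenPreference(str, enum.Enum):
    IIT = "IIT"
    fixed_once = "fixed_once"
    fixed_twice = "fixed_twice"
    none = "none"


class AgeCategory(str, enum.Enum):
    child = "child"
    adolescent = "adolescent"
    adult = "adult"
    oldAdult = "oldAdult"


class PatientProfile(BaseModel):
    """Everything the planners need to know about one patient.

    Demographics and anthropometrics drive the dose and calorie formulas;
    coded conditions, medications and allergies drive contraindication
    checks; preferences steer regimen, exercise and course selection.
    """

    id: str
    age: int
    sex: Sex
    pregnant: bool = False
    weight: float  # kg
    height: float  # cm
    lifestyle: Lifestyle = Lifestyle.sedentary
    education_level: EducationLevel = EducationLevel.medium
    preferred_language: str = "en"
    conditions: list[Coding] = []
    medications: list[Coding] = []
    allergies: list[Coding] = []
    food_preferences: list[str] = []
    exercise_preferences: list[Coding] = []
    regimen_preference: RegimenPreference = RegimenPreference.none
    history_of_hypoglycemia: int = 0
    history_of_hyperglycemia: int = 0
    has_dka: bool = False
    has_relative: bool = False

    @field_validator("weight", "height")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("weight and height must be positive")
        return v

    @field_validator("age")
    @classmethod
    def _age_range(cls, v: int) -> int:
        if not (0 <= v <= 130):
            raise ValueError("age must be within [0, 130] years")
        return v

    @model_validator(mode="after")
    def _pregnant_implies_female(self) -> "PatientProfile":
        if self.pregnant and self.sex is not Sex.female:
            raise ValueError("pregnant implies sex = female")
        return self

    @property
    def height_m(self) -> float:
        return self.height / 100.0

    @property
    def bmi(self) -> float:
        return self.weight / self.height_m**2

    def condition_codes(self) -> set[str]:
        return {c.code for c in self.conditions}

    def medication_codes(self) -> set[str]:
        return {m.code for m in self.medications}


class GoalSet(BaseModel):
    """SMART treatment goals attached to a care plan."""

    hba1c_max: float  # percent
    premeal_bg_low: Quantity
    premeal_bg_high: Quantity
    weight_goal: Optional[float] = None  # kg
    bp_goal: Optional[str] = None
    bedtime_bg_low: Optional[Quantity] = None
    bedtime_bg_high: Optional[Quantity] = None

    @model_validator(mode="after")
    def _ordered(self) -> "GoalSet":
        if self.hba1c_max <= 0:
            raise ValueError("hba1c_max must be positive")
        low = to_mgdl(self.premeal_bg_low)
        high = to_mgdl(self.premeal_bg_high)
        if low >= high:
            raise ValueError("premeal_bg_low must be below premeal_bg_high")
        return self


#: Default inclusive upper age bound of each band (years); ages above the
#: last bound are oldAdult. The adult band matches the 19 < age < 55 usage;
#: child matches age < 10 falling inside child; the adolescent/oldAdult
#: cut-offs are a documented convention (see docs/methods.md).
DEFAULT_AGE_BANDS: dict[str, int] = {"child": 12, "adolescent": 18, "adult": 55}


def categorize_age(age: int, bands: dict[str, int] | None = None) -> AgeCategory:
    """Classify an age in years into child / adolescent / adult / oldAdult.

    ``bands`` maps band name to its inclusive upper bound; anything above
    the adult bound is oldAdult. Bands must be total and non-overlapping,
    which the default table is by construction.
    """
    if isinstance(age, bool) or not isinstance(age, int):
        raise InputError(f"age must be an integer number of years, got {age!r}")
    if not (0 <= age <= 130):
        raise InputError(f"age must be within [0, 130], got {age}")
    b = bands or DEFAULT_AGE_BANDS
    if age <= b["child"]:
        return AgeCategory.child
    if age <= b["adolescent"]:
        return AgeCategory.adolescent
    if age <= b["adult"]:
        return AgeCategory.adult
    return AgeCategory.oldAdult


def _require_glucose_unit(unit: str) -> None:
    if unit not in _GLUCOSE_UNITS:
        raise UnitError(
            f"unknown glucose unit {unit!r}; expected {MGDL!r} or {MMOL!r}"
        )


def convert_glucose(value: Quantity) -> Quantity:
    """Convert a glucose quantity to the other unit (mg/dL <-> mmol/L)."""
    _require_glucose_unit(value.unit)
    if value.unit == MGDL:
        return Quantity(value=value.value / MGDL_PER_MMOL, unit=MMOL)
    return Quantity(value=value.value * MGDL_PER_MMOL, unit=MGDL)


def to_mgdl(value: Quantity) -> float:
    """Numeric mg/dL equivalent of a glucose quantity."""
    _require_glucose_unit(value.unit)
    if value.unit == MGDL:
        return value.value
    return value.value * MGDL_PER_MMOL


def to_mmol(value: Quantity) -> float:
    """Numeric mmol/L equivalent of a glucose quantity."""
    _require_glucose_unit(value.unit)
    if value.unit == MMOL:
        return value.value
    return value.value / MGDL_PER_MMOL


class GlucoseDanger(str, enum.Enum):
    hypoglycemia = "hypoglycemia"
    normal = "normal"
    hyperglycemia = "hyperglycemia"


#: Emergency thresholds: danger of hypoglycemia below 3.6 mmol/L and of
#: hyperglycemia above 9.0 mmol/L. Flagging only — emergency handling
#: itself is out of scope.
HYPO_THRESHOLD_MMOL = 3.6
HYPER_THRESHOLD_MMOL = 9.0


def classify_glucose_danger(value: Quantity) -> GlucoseDanger:
    """Flag a glucose reading as hypoglycemia / normal / hyperglycemia."""
    mmol = to_mmol(value)
    if mmol < HYPO_THRESHOLD_MMOL:
        return GlucoseDanger.hypoglycemia
    if mmol > HYPER_THRESHOLD_MMOL:
        return GlucoseDanger.hyperglycemia
    return GlucoseDanger.normal
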