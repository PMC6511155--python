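"""Diet sub-plan: BMR, maintenance calories, ideal weight, meals.

The pipeline is Harris-Benedict basal metabolic rate -> activity-level
multiplier -> maintenance calories (MC) -> ideal-weight range from the
healthy BMI band 18.5-25 -> daily calorie target (CpD) adjusted by the
energy content of the weight deficit/excess (7700 kcal per kg) spread over
an adjustment period d (default 90 days) -> per-meal distribution at
30 % / 35 % / 35 % for breakfast / lunch / dinner with daily carbohydrate
grams CpD/4.

Note the carb budget treats every planned calorie as carbohydrate at
4 kcal/g; that convention is implemented verbatim (see docs/methods.md).
"""

from __future__ import annotations

import enum
import math
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .core import Lifestyle, PatientProfile, Sex
from .errors import InputError, PeriodTooShortError
from .knowledge import KnowledgeBase

__all__ = [
    "UnitSystem",
    "WeightStatus",
    "MealSpec",
    "DietPlan",
    "KCAL_PER_KG",
    "MEAL_SHARES",
    "compute_bmr",
    "activity_multiplier",
    "maintenance_calories",
    "bmi",
    "ideal_weight_range",
    "plan_calories",
    "distribute_meals",
    "forbidden_foods",
    "build_diet_plan",
]

#: Energy content of one kilogram of body weight.
KCAL_PER_KG = 7700.0

#: Calorie/carb share per meal.
MEAL_SHARES: dict[str, float] = {"breakfast": 0.30, "lunch": 0.35, "dinner": 0.35}

#: kcal per gram of carbohydrate.
KCAL_PER_G_CARB = 4.0

#: Healthy BMI band (kg/m^2) used for the ideal-weight range.
BMI_LOW, BMI_HIGH = 18.5, 25.0


class UnitSystem(str, enum.Enum):
    metric = "metric"  # kg / cm
    imperial = "imperial"  # lb / in


class WeightStatus(str, enum.Enum):
    underweight = "underweight"
    normal = "normal"
    overweight = "overweight"


class MealSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str  # breakfast | lunch | dinner
    share: float
    carbs_g: float
    calories: float


class DietPlan(BaseModel):
    bmr: float
    activity_multiplier: float
    maintenance_calories: float
    ideal_weight_low: float
    ideal_weight_high: float
    weight_status: WeightStatus
    weight_goal: float
    adjustment_period_days: int
    calories_per_day: float
    total_carbs_g: float
    meals: list[MealSpec]
    forbidden_foods: list[str]
    recommended_food_groups: list[str]


# Harris-Benedict coefficients: (weight, height, age, constant)
_HB = {
    (UnitSystem.metric, Sex.male): (13.75, 5.003, 6.755, 66.5),
    (UnitSystem.metric, Sex.female): (9.563, 1.85, 4.676, 655.1),
    (UnitSystem.imperial, Sex.male): (6.2, 12.7, 6.76, 66.0),
    (UnitSystem.imperial, Sex.female): (4.35, 4.7, 4.7, 655.1),
}


def compute_bmr(
    sex: Sex,
    weight: float,
    height: float,
    age: float,
    unit_system: UnitSystem = UnitSystem.metric,
) -> float:
    """Harris-Benedict basal metabolic rate in kcal/day.

    Metric expects kg and cm; imperial expects pounds and inches. The two
    published coefficient sets differ slightly, so metric and imperial
    agree only to within about 2 % for equivalent inputs.
    """
    try:
        unit_system = UnitSystem(unit_system)
    except ValueError:
        raise InputError(f"unknown unit system {unit_system!r}") from None
    if weight <= 0 or height <= 0:
        raise InputError("weight and height must be positive")
    if not (0 <= age <= 130):
        raise InputError(f"age must be within [0, 130], got {age!r}")
    cw, ch, ca, c0 = _HB[(unit_system, Sex(sex))]
    return cw * weight + ch * height - ca * age + c0


def activity_multiplier(lifestyle: Lifestyle, kb: Optional[KnowledgeBase] = None) -> float:
    """Activity-level multiplier AL for a lifestyle (1.2 ... 1.9)."""
    lifestyle = Lifestyle(lifestyle)
    if kb is not None:
        return kb.activity_levels[lifestyle]
    return {
        Lifestyle.sedentary: 1.2,
        Lifestyle.lightly_active: 1.375,
        Lifestyle.moderately_active: 1.55,
        Lifestyle.very_active: 1.725,
        Lifestyle.extra_active: 1.9,
    }[lifestyle]


def maintenance_calories(bmr: float, al: float) -> float:
    """Calories/day to maintain current weight: MC = AL x BMR."""
    return al * bmr


def bmi(weight_kg: float, height_m: float) -> float:
    """Body-mass index in kg/m^2."""
    if height_m <= 0:
        raise InputError("height must be positive")
    return weight_kg / height_m**2


def ideal_weight_range(height_m: float) -> tuple[float, float]:
    """(LIW, HIW) in kg from the healthy BMI band 18.5-25."""
    if height_m <= 0:
        raise InputError("height must be positive")
    return BMI_LOW * height_m**2, BMI_HIGH * height_m**2


def plan_calories(
    weight: float, liw: float, hiw: float, mc: float, d: int = 90
) -> tuple[WeightStatus, float, float]:
    """(weight_status, weight_goal, CpD) for the adjustment period d (days).

    Inside the ideal range the patient maintains (CpD = MC, goal = current
    weight). Below it, the kg deficit's 7700 kcal/kg is added over d days
    and the goal is the low ideal weight; above it, the excess is
    subtracted and the goal is the high ideal weight. A reduction that
    drives CpD to zero or below raises :class:`PeriodTooShortError`.
    """
    if not liw < hiw:
        raise InputError("ideal-weight range must satisfy LIW < HIW")
    if d <= 0:
        raise InputError(f"adjustment period must be positive days, got {d!r}")
    if liw <= weight <= hiw:
        return WeightStatus.normal, weight, mc
    if weight < liw:
        ow = liw - weight
        return WeightStatus.underweight, liw, mc + ow * KCAL_PER_KG / d
    ow = weight - hiw
    cpd = mc - ow * KCAL_PER_KG / d
    if cpd <= 0:
        raise PeriodTooShortError(
            f"calorie reduction over {d} days leaves {cpd:.0f} kcal/day; "
            f"choose a period longer than {math.ceil(ow * KCAL_PER_KG / mc)} days"
        )
    return WeightStatus.overweight, hiw, cpd


def distribute_meals(cpd: float) -> list[MealSpec]:
    """Split the daily budget over three meals (30/35/35 %).

    Daily carbohydrate grams are CpD/4; each meal takes the same share of
    carbs and of calories.
    """
    if cpd <= 0:
        raise InputError(f"calories per day must be positive, got {cpd!r}")
    total_carbs = cpd / KCAL_PER_G_CARB
    return [
        MealSpec(name=name, share=share, carbs_g=share * total_carbs,
                 calories=share * cpd)
        for name, share in MEAL_SHARES.items()
    ]


def forbidden_foods(profile: PatientProfile, kb: KnowledgeBase) -> list[str]:
    """Foods contraindicated by current medications or conditions, sorted."""
    foods: set[str] = set()
    for med in profile.medication_codes():
        foods |= kb.drug_food_contra.get(med, set())
    for cond in profile.condition_codes():
        foods |= kb.disease_food_contra.get(cond, set())
    return sorted(foods)


#: Basic food groups offered when composing the recommendation list.
BASIC_FOOD_GROUPS = [
    "vegetables", "fruits", "whole grains", "lean protein", "dairy", "legumes",
]


def build_diet_plan(
    profile: PatientProfile, kb: KnowledgeBase, d: int = 90
) -> DietPlan:
    """Run the five diet steps in order and assemble the DietPlan."""
    bmr_val = compute_bmr(profile.sex, profile.weight, profile.height, profile.age)
    al = activity_multiplier(profile.lifestyle, kb)
    mc = maintenance_calories(bmr_val, al)
    liw, hiw = ideal_weight_range(profile.height_m)
    status, weight_goal, cpd = plan_calories(profile.weight, liw, hiw, mc, d)
    meals = distribute_meals(cpd)
    banned = forbidden_foods(profile, kb)
    banned_lower = {b.lower() for b in banned}
    preferred = [f for f in profile.food_preferences if f.lower() not in banned_lower]
    groups = preferred + [g for g in BASIC_FOOD_GROUPS if g not in preferred]
    return DietPlan(
        bmr=bmr_val,
        activity_multiplier=al,
        maintenance_calories=mc,
        ideal_weight_low=liw,
        ideal_weight_high=hiw,
        weight_status=status,
        weight_goal=weight_goal,
        adjustment_period_days=d,
        calories_per_day=cpd,
        total_carbs_g=cpd / KCAL_PER_G_CARB,
        meals=meals,
        forbidden_foods=banned,
        recommended_food_groups=groups,
    )
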