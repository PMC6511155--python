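"""Exercise and education sub-plans.

Exercise: eligibility gating on coded comorbidities (conjunctive with
age > 30) and pregnancy-specific contraindications, condition-specific
forbidden exercises (e.g. foot ulcers rule out jogging), then recommended
exercises = preferences minus forbidden, joined with the compendium MET
catalog into concrete plan components.

Education: a coordinator (the patient, or a relative for children and old
adults), learning styles from an (age, education) table, topics driven by
regimen and history, and courses looked up per (topic, style) pair.
"""

from __future__ import annotations

import enum
from typing import Optional

from pydantic import BaseModel, ConfigDict

from .core import AgeCategory, Coding, PatientProfile, RegimenKind, categorize_age
from .knowledge import COMPENDIUM, KnowledgeBase

__all__ = [
    "Intensity",
    "ExerciseComponent",
    "ExercisePlan",
    "LearningStyle",
    "Topic",
    "EducationPlan",
    "exercise_eligibility",
    "forbidden_exercises",
    "recommended_exercises",
    "build_exercise_plan",
    "select_learning_style",
    "select_topics",
    "assign_courses",
    "build_education_plan",
]

#: BMI below which exercise is contraindicated during pregnancy.
PREGNANCY_MIN_BMI = 12.0

#: Age above which the comorbidity list bans exercise (conjunctive rule).
EXERCISE_BAN_AGE = 30


class Intensity(str, enum.Enum):
    light = "light"
    moderate = "moderate"
    vigorous = "vigorous"


class ExerciseComponent(BaseModel):
    model_config = ConfigDict(frozen=True)

    exercise: Coding
    met: float
    frequency_per_week: int
    duration_min: int
    intensity: Intensity


class ExercisePlan(BaseModel):
    allowed: bool
    forbidden_reasons: list[str]
    forbidden_exercises: set[str]
    components: list[ExerciseComponent]
    fixed: bool = False  # DF patients may not change their activity level


class LearningStyle(str, enum.Enum):
    reading = "reading"
    visual = "visual"
    auditory = "auditory"
    games = "games"
    case_studies = "case_studies"


class Topic(str, enum.Enum):
    insulin = "insulin"
    medications = "medications"
    diet = "diet"
    monitoring = "monitoring"
    emergency = "emergency"
    exercise = "exercise"
    complications = "complications"


class Coordinator(str, enum.Enum):
    patient = "patient"
    relative = "relative"


class EducationPlan(BaseModel):
    coordinator: Coordinator
    styles: set[LearningStyle]
    topics: set[Topic]
    courses: list[str]


def exercise_eligibility(
    profile: PatientProfile, kb: KnowledgeBase
) -> tuple[bool, list[str]]:
    """(allowed, reasons) for regular exercise.

    Forbidden when the patient is over 30 and carries one of the listed
    comorbidities (hypertension, dyslipidemia, preproliferative
    retinopathy, nephropathy, smoking — the rule conjoins the age trigger
    with the condition list), or when pregnant and either extremely
    underweight (BMI < 12) or carrying a pregnancy-specific
    contraindication such as preeclampsia.
    """
    reasons: list[str] = []
    conditions = profile.condition_codes()
    comorbid = conditions & kb.exercise_forbidden_conditions
    if profile.age > EXERCISE_BAN_AGE and comorbid:
        reasons.append(
            "age over 30 with exercise-limiting comorbidity "
            f"({', '.join(sorted(comorbid))})"
        )
    if profile.pregnant:
        if profile.bmi < PREGNANCY_MIN_BMI:
            reasons.append(
                f"pregnant and extremely underweight (BMI {profile.bmi:.1f} < 12)"
            )
        preg_hits = conditions & kb.pregnancy_exercise_contra
        if preg_hits:
            reasons.append(
                "pregnancy contraindication "
                f"({', '.join(sorted(preg_hits))})"
            )
    return (not reasons), reasons


def forbidden_exercises(profile: PatientProfile, kb: KnowledgeBase) -> set[str]:
    """Exercise codes ruled out by the patient's conditions."""
    out: set[str] = set()
    for cond in profile.condition_codes():
        out |= kb.disease_exercise_contra.get(cond, set())
    return out


def recommended_exercises(
    profile: PatientProfile,
    forbidden: set[str],
    kb: Optional[KnowledgeBase] = None,
) -> set[str]:
    """Preferred-and-not-forbidden exercises; KB defaults if no preference."""
    preferred = {c.code for c in profile.exercise_preferences}
    if not preferred and kb is not None:
        preferred = set(kb.default_exercises)
    return preferred - forbidden


# Age-banded default prescription: (frequency/week, minutes, intensity).
_DEFAULT_PRESCRIPTION: dict[AgeCategory, tuple[int, int, Intensity]] = {
    AgeCategory.child: (5, 30, Intensity.moderate),
    AgeCategory.adolescent: (5, 30, Intensity.moderate),
    AgeCategory.adult: (4, 30, Intensity.moderate),
    AgeCategory.oldAdult: (3, 30, Intensity.light),
}


def build_exercise_plan(
    profile: PatientProfile,
    kb: KnowledgeBase,
    regimen_kind: Optional[RegimenKind] = None,
) -> ExercisePlan:
    """Eligibility -> forbidden -> recommended -> catalog join.

    An ineligible patient gets an empty, not-allowed plan. DF-regimen
    patients get a plan marked fixed: their activity level may not change
    downstream.
    """
    allowed, reasons = exercise_eligibility(profile, kb)
    banned = forbidden_exercises(profile, kb)
    fixed = regimen_kind in (RegimenKind.fixed_once, RegimenKind.fixed_twice)
    if not allowed:
        return ExercisePlan(allowed=False, forbidden_reasons=reasons,
                            forbidden_exercises=banned, components=[], fixed=fixed)
    chosen = recommended_exercises(profile, banned, kb)
    age_cat = categorize_age(profile.age, kb.age_bands)
    freq, minutes, intensity = _DEFAULT_PRESCRIPTION[age_cat]
    components = []
    for code in sorted(chosen):
        entry = kb.exercise_catalog.get(code)
        if entry is None:
            continue  # unknown preference: nothing to prescribe
        components.append(ExerciseComponent(
            exercise=Coding(system=COMPENDIUM, code=code, display=entry.display),
            met=entry.met,
            frequency_per_week=freq,
            duration_min=minutes,
            intensity=intensity,
        ))
    return ExercisePlan(allowed=True, forbidden_reasons=[],
                        forbidden_exercises=banned, components=components,
                        fixed=fixed)


def select_learning_style(
    age_cat: AgeCategory,
    education_level,
    language: str = "en",
    kb: Optional[KnowledgeBase] = None,
) -> set[LearningStyle]:
    """Learning styles for an (age category, education level) stratum.

    Looked up in the knowledge base's style table (highly educated adults
    get visual + reading; children get games + visual). ``language`` is
    carried for course localisation but does not alter the style set.
    """
    from .core import EducationLevel

    level = EducationLevel(education_level)
    table = kb.learning_styles if kb is not None else None
    key = f"{AgeCategory(age_cat).value}/{level.value}"
    if table is not None and key in table:
        return {LearningStyle(s) for s in table[key]}
    # fall back to the shipped defaults
    from .knowledge import DEFAULT_KB_CONFIG

    return {LearningStyle(s) for s in DEFAULT_KB_CONFIG["learning_styles"][key]}


def select_topics(
    profile: PatientProfile, regimen_kind: RegimenKind,
    exercise_allowed: bool = True,
) -> set[Topic]:
    """Learning topics from regimen, conditions, history and medications.

    Every patient learns insulin and diet management; IIT adds glucose
    monitoring; any coded complication adds the complications topic; a
    hypo-/hyperglycemia history adds emergency management; an active
    exercise plan adds the exercise topic; current medications add the
    medications topic.
    """
    topics = {Topic.insulin, Topic.diet}
    if regimen_kind is RegimenKind.IIT:
        topics.add(Topic.monitoring)
    if profile.conditions:
        topics.add(Topic.complications)
    if profile.history_of_hypoglycemia > 0 or profile.history_of_hyperglycemia > 0:
        topics.add(Topic.emergency)
    if exercise_allowed:
        topics.add(Topic.exercise)
    if profile.medications:
        topics.add(Topic.medications)
    return topics


def assign_courses(
    topics: set[Topic], styles: set[LearningStyle], kb: KnowledgeBase
) -> list[str]:
    """Courses for every (topic, style) pair present, deduplicated.

    Order is deterministic: topics in declaration order, then styles in
    declaration order, then catalog order. Missing catalog entries are
    skipped.
    """
    out: list[str] = []
    seen: set[str] = set()
    for topic in Topic:
        if topic not in topics:
            continue
        for style in LearningStyle:
            if style not in styles:
                continue
            for course in kb.course_catalog.get(f"{topic.value}/{style.value}", []):
                if course not in seen:
                    seen.add(course)
                    out.append(course)
    return out


def build_education_plan(
    profile: PatientProfile,
    regimen_kind: RegimenKind,
    kb: KnowledgeBase,
    exercise_allowed: bool = True,
) -> EducationPlan:
    """Coordinator -> styles -> topics -> courses."""
    age_cat = categorize_age(profile.age, kb.age_bands)
    coordinator = Coordinator.patient
    if age_cat in (AgeCategory.child, AgeCategory.oldAdult) and profile.has_relative:
        coordinator = Coordinator.relative
    styles = select_learning_style(
        age_cat, profile.education_level, profile.preferred_language, kb
    )
    topics = select_topics(profile, regimen_kind, exercise_allowed)
    courses = assign_courses(topics, styles, kb)
    return EducationPlan(coordinator=coordinator, styles=styles,
                         topics=topics, courses=courses)
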