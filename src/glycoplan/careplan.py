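"""Care-plan assembly and three-monthly maintenance.

A care plan bundles the four sub-plans (insulin regimen, diet, exercise,
education) with the goal set and validity metadata. Plans are proposals:
they start as drafts and only a recorded physician approval moves them to
approved. Maintenance every validity cycle compares achieved HbA1c and
weight against the goals; unmet goals trigger a rebuild from the updated
profile, met goals extend the validity window. The superseded plan is kept
(is_current = False) for audit.
"""

from __future__ import annotations

import enum
from datetime import datetime, timezone
from typing import Optional

from pydantic import BaseModel

from .core import GoalSet, PatientProfile, Quantity
from .diet import DietPlan, build_diet_plan
from .errors import GlycoplanError, PlannerError, StalePlanError
from .insulin import InsulinRegimen, build_insulin_plan, set_goals
from .knowledge import KnowledgeBase
from .lifestyle import (
    EducationPlan,
    ExercisePlan,
    build_education_plan,
    build_exercise_plan,
)
from .monitor import GlucoseLog

__all__ = ["PlanStatus", "CarePlan", "build_care_plan", "approve_plan",
           "maintain_plan"]

DEFAULT_VALID_DAYS = 90

#: Weight is considered on-goal within this margin (kg).
WEIGHT_GOAL_TOLERANCE_KG = 0.5


class PlanStatus(str, enum.Enum):
    draft = "draft"
    approved = "approved"


class CarePlan(BaseModel):
    patient_id: str
    created: datetime
    valid_days: int = DEFAULT_VALID_DAYS
    is_current: bool = True
    status: PlanStatus = PlanStatus.draft
    goals: GoalSet
    regimen: InsulinRegimen
    diet: DietPlan
    exercise: ExercisePlan
    education: EducationPlan
    profile: PatientProfile  # snapshot the plan was built from


def build_care_plan(
    profile: PatientProfile,
    kb: KnowledgeBase,
    adjustment_period_days: int = DEFAULT_VALID_DAYS,
    f: float = 0.5,
    basal_shots: int = 1,
    created: Optional[datetime] = None,
) -> CarePlan:
    """Compose goals and all four sub-plans into one draft care plan.

    Sub-planner failures are wrapped in :class:`PlannerError` naming the
    module that raised them.
    """

    def run(module: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except GlycoplanError as exc:
            raise PlannerError(module, exc) from exc

    goals = run("insulin_planner", set_goals, profile, kb)
    regimen = run("insulin_planner", build_insulin_plan, profile, kb,
                  f=f, basal_shots=basal_shots)
    diet = run("diet_planner", build_diet_plan, profile, kb,
               d=adjustment_period_days)
    exercise = run("lifestyle_planner", build_exercise_plan, profile, kb,
                   regimen_kind=regimen.kind)
    education = run("lifestyle_planner", build_education_plan, profile,
                    regimen.kind, kb, exercise_allowed=exercise.allowed)
    goals = goals.model_copy(update={"weight_goal": diet.weight_goal})
    return CarePlan(
        patient_id=profile.id,
        created=created or datetime.now(timezone.utc),
        valid_days=adjustment_period_days,
        goals=goals,
        regimen=regimen,
        diet=diet,
        exercise=exercise,
        education=education,
        profile=profile,
    )


def approve_plan(plan: CarePlan) -> CarePlan:
    """Record physician approval (a state transition, nothing more)."""
    return plan.model_copy(update={"status": PlanStatus.approved})


def maintain_plan(
    plan: CarePlan,
    latest: Optional[GlucoseLog],
    hba1c: Quantity,
    weight: Quantity,
    kb: KnowledgeBase,
    now: Optional[datetime] = None,
) -> CarePlan:
    """Three-monthly maintenance against HbA1c and weight goals.

    If either goal is unmet, the sub-plans are rebuilt from the profile
    updated with the measured weight; otherwise the same doses are carried
    into a fresh validity window. Either way the prior plan is archived
    in place (is_current = False) and the new plan returned; maintaining
    an already-superseded plan raises :class:`StalePlanError`.
    """
    if not plan.is_current:
        raise StalePlanError(
            f"plan for patient {plan.patient_id} created {plan.created} "
            "has already been superseded"
        )
    hba1c_met = hba1c.value <= plan.goals.hba1c_max
    goal_weight = plan.goals.weight_goal
    weight_met = (
        goal_weight is None
        or abs(weight.value - goal_weight) <= WEIGHT_GOAL_TOLERANCE_KG
    )
    now = now or datetime.now(timezone.utc)
    if hba1c_met and weight_met:
        new_plan = plan.model_copy(
            update={"created": now, "status": PlanStatus.draft,
                    "is_current": True}
        )
    else:
        profile = plan.profile.model_copy(update={"weight": weight.value})
        new_plan = build_care_plan(
            profile, kb,
            adjustment_period_days=plan.valid_days,
            f=plan.regimen.f_factor or 0.5,
            created=now,
        )
    plan.is_current = False
    return new_plan
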