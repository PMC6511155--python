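"""FHIR-lite JSON readers and writers.

Documents carry ``resourceType``/``id``/field names compatible with FHIR
JSON so a real server can ingest them, but only the profiled element
subset this package uses — no narrative, meta, or full STU3 conformance.
Planner-specific knowledge (meal carbs, learning styles, ...) rides in an
``extension`` object per resource. Statuses are fixed per the profiling:
observations are ``final`` and conditions ``confirmed``.

Writers emit stable, sorted-key JSON so bundles diff cleanly; the
write -> read -> bind round trip is lossless for profiles and care plans.
"""

from __future__ import annotations

import json
from datetime import datetime
from typing import Any, Iterable, Optional, Sequence

from pydantic import BaseModel, ConfigDict

from .careplan import CarePlan, PlanStatus
from .core import (
    Coding,
    ObservationRecord,
    ObservationSource,
    PatientProfile,
    Quantity,
    Slot,
)
from .diet import DietPlan, MealSpec, WeightStatus
from .errors import BundleError
from .insulin import DoseKind, DoseTiming, InsulinDose, InsulinRegimen
from .knowledge import ActionClass, InsulinProduct
from .lifestyle import (
    Coordinator,
    EducationPlan,
    ExerciseComponent,
    ExercisePlan,
    Intensity,
    LearningStyle,
    Topic,
)
from .monitor import GlucoseLog

__all__ = [
    "SUPPORTED_RESOURCE_TYPES",
    "FhirLiteDocument",
    "read_bundle",
    "bind_profile",
    "bind_careplan",
    "observations_from_documents",
    "log_from_documents",
    "write_patient_bundle",
    "write_observation_bundle",
    "write_careplan_bundle",
]

SUPPORTED_RESOURCE_TYPES = {
    "Patient", "Observation", "Condition", "MedicationStatement",
    "MedicationRequest", "AllergyIntolerance", "CarePlan", "Goal",
    "NutritionOrder", "ProcedureRequest", "Device", "Bundle",
}

LOINC = "LOINC"
WEIGHT_LOINC = "29463-7"
HEIGHT_LOINC = "8302-2"
GLUCOSE_LOINC = "2339-0"


class FhirLiteDocument(BaseModel):
    model_config = ConfigDict(frozen=True)

    resource_type: str
    id: str
    payload: dict[str, Any]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _fail(path: str, message: str) -> None:
    raise BundleError(f"{path}: {message}")


def _check_codings_and_quantities(node: Any, path: str) -> None:
    """Walk a payload: every coding needs system+code, every *Quantity
    needs numeric value + non-empty unit."""
    if isinstance(node, dict):
        for key, value in node.items():
            child = f"{path}.{key}"
            if key == "coding":
                if not isinstance(value, list) or not value:
                    _fail(child, "coding must be a non-empty list")
                for i, coding in enumerate(value):
                    if not isinstance(coding, dict) or not coding.get("system") \
                            or not coding.get("code"):
                        _fail(f"{child}[{i}]", "coding needs system and code")
            if key.endswith("Quantity") or key == "valueQuantity":
                if not isinstance(value, dict):
                    _fail(child, "quantity must be an object")
                if not isinstance(value.get("value"), (int, float)):
                    _fail(f"{child}.value", "quantity needs a numeric value")
                if not value.get("unit"):
                    _fail(f"{child}.unit", "quantity needs a unit")
            _check_codings_and_quantities(value, child)
    elif isinstance(node, list):
        for i, item in enumerate(node):
            _check_codings_and_quantities(item, f"{path}[{i}]")


_REQUIRED_FIELDS = {
    "Observation": ("code", "valueQuantity", "effectiveDateTime"),
    "Condition": ("code",),
    "MedicationStatement": ("medicationCodeableConcept",),
    "AllergyIntolerance": ("code",),
    "MedicationRequest": ("medicationCodeableConcept", "dosage"),
}


def _validate_resource(resource: Any, path: str) -> FhirLiteDocument:
    if not isinstance(resource, dict):
        _fail(path, "resource must be an object")
    rtype = resource.get("resourceType")
    if rtype not in SUPPORTED_RESOURCE_TYPES:
        _fail(f"{path}.resourceType", f"unsupported resource type {rtype!r}")
    rid = resource.get("id")
    if not rid or not isinstance(rid, str):
        _fail(f"{path}.id", "resource needs a string id")
    for field in _REQUIRED_FIELDS.get(rtype, ()):
        if field not in resource:
            _fail(f"{path}.{field}", f"{rtype} requires {field}")
    _check_codings_and_quantities(resource, path)
    return FhirLiteDocument(resource_type=rtype, id=rid, payload=resource)


def read_bundle(json_text: str) -> list[FhirLiteDocument]:
    """Parse and validate a bundle; returns its entries in order.

    Malformed JSON raises :class:`BundleError` (parse), as do schema
    violations (with the offending JSON path) and dangling subject
    references.
    """
    try:
        root = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise BundleError(f"malformed JSON: {exc}") from exc
    if not isinstance(root, dict) or root.get("resourceType") != "Bundle":
        _fail("$.resourceType", "document root must be a Bundle")
    entries = root.get("entry", [])
    if not isinstance(entries, list):
        _fail("$.entry", "entry must be a list")
    docs: list[FhirLiteDocument] = []
    for i, entry in enumerate(entries):
        if not isinstance(entry, dict) or "resource" not in entry:
            _fail(f"$.entry[{i}]", "entry needs a resource")
        docs.append(_validate_resource(entry["resource"], f"$.entry[{i}].resource"))
    ids = {(d.resource_type, d.id) for d in docs}
    types_present = {d.resource_type for d in docs}
    for i, doc in enumerate(docs):
        ref = doc.payload.get("subject", {}).get("reference")
        if ref:
            rtype, _, rid = ref.partition("/")
            # a reference into this bundle must resolve; a reference to a
            # type the bundle does not carry is treated as external
            if rtype in types_present and (rtype, rid) not in ids:
                _fail(f"$.entry[{i}].resource.subject.reference",
                      f"dangling reference {ref!r}")
    return docs


# ---------------------------------------------------------------------------
# Writers: profile and observations
# ---------------------------------------------------------------------------


def _codeable(coding: Coding) -> dict[str, Any]:
    return {"coding": [{"system": coding.system, "code": coding.code,
                        "display": coding.display}]}


def _coding_from(cc: dict[str, Any]) -> Coding:
    c = cc["coding"][0]
    return Coding(system=c["system"], code=c["code"],
                  display=c.get("display", ""))


def _patient_resource(profile: PatientProfile) -> dict[str, Any]:
    return {
        "resourceType": "Patient",
        "id": profile.id,
        "gender": profile.sex.value,
        "communication": [{"language": profile.preferred_language}],
        "extension": {
            "age": profile.age,
            "pregnant": profile.pregnant,
            "lifestyle": profile.lifestyle.value,
            "education_level": profile.education_level.value,
            "food_preferences": list(profile.food_preferences),
            "exercise_preferences": [
                {"system": c.system, "code": c.code, "display": c.display}
                for c in profile.exercise_preferences
            ],
            "regimen_preference": profile.regimen_preference.value,
            "history_of_hypoglycemia": profile.history_of_hypoglycemia,
            "history_of_hyperglycemia": profile.history_of_hyperglycemia,
            "has_dka": profile.has_dka,
            "has_relative": profile.has_relative,
        },
    }


def observation_resource(
    record: ObservationRecord, subject_id: str, obs_id: str
) -> dict[str, Any]:
    return {
        "resourceType": "Observation",
        "id": obs_id,
        "status": "final",
        "code": _codeable(record.code),
        "subject": {"reference": f"Patient/{subject_id}"},
        "effectiveDateTime": record.timestamp.isoformat(),
        "valueQuantity": {"value": record.value.value, "unit": record.value.unit},
        "extension": {"slot": record.slot.value, "source": record.source.value},
    }


def _bundle(docs: Sequence[dict[str, Any]], bundle_id: str) -> str:
    root = {
        "resourceType": "Bundle",
        "id": bundle_id,
        "type": "collection",
        "entry": [{"resource": d} for d in docs],
    }
    return json.dumps(root, indent=2, sort_keys=True)


def write_patient_bundle(
    profile: PatientProfile,
    observations: Iterable[ObservationRecord] = (),
    timestamp: Optional[datetime] = None,
) -> str:
    """Profile -> Patient + Condition/MedicationStatement/AllergyIntolerance
    + anthropometric Observations (+ any extra observations), as a bundle."""
    ts = (timestamp or datetime(2000, 1, 1)).isoformat()
    docs: list[dict[str, Any]] = [_patient_resource(profile)]
    subject = {"reference": f"Patient/{profile.id}"}
    for i, cond in enumerate(profile.conditions):
        docs.append({"resourceType": "Condition", "id": f"cond-{i}",
                     "verificationStatus": "confirmed",
                     "subject": subject, "code": _codeable(cond)})
    for i, med in enumerate(profile.medications):
        docs.append({"resourceType": "MedicationStatement", "id": f"med-{i}",
                     "status": "active", "subject": subject,
                     "medicationCodeableConcept": _codeable(med)})
    for i, allergy in enumerate(profile.allergies):
        docs.append({"resourceType": "AllergyIntolerance", "id": f"allergy-{i}",
                     "subject": subject, "code": _codeable(allergy)})
    docs.append({
        "resourceType": "Observation", "id": "obs-weight", "status": "final",
        "code": {"coding": [{"system": LOINC, "code": WEIGHT_LOINC,
                             "display": "Body weight"}]},
        "subject": subject, "effectiveDateTime": ts,
        "valueQuantity": {"value": profile.weight, "unit": "kg"},
    })
    docs.append({
        "resourceType": "Observation", "id": "obs-height", "status": "final",
        "code": {"coding": [{"system": LOINC, "code": HEIGHT_LOINC,
                             "display": "Body height"}]},
        "subject": subject, "effectiveDateTime": ts,
        "valueQuantity": {"value": profile.height, "unit": "cm"},
    })
    for i, record in enumerate(observations):
        docs.append(observation_resource(record, profile.id, f"obs-{i}"))
    return _bundle(docs, f"patient-bundle-{profile.id}")


def write_observation_bundle(
    records: Iterable[ObservationRecord], subject_id: str
) -> str:
    docs = [observation_resource(r, subject_id, f"obs-{i}")
            for i, r in enumerate(records)]
    return _bundle(docs, f"observations-{subject_id}")


# ---------------------------------------------------------------------------
# Binding: documents -> domain objects
# ---------------------------------------------------------------------------


def bind_profile(docs: Sequence[FhirLiteDocument]) -> PatientProfile:
    """Map a document set onto a PatientProfile.

    Requires exactly one Patient. Weight and height come from the latest
    matching Observation (latest ``effectiveDateTime`` wins on ties in
    document order).
    """
    patients = [d for d in docs if d.resource_type == "Patient"]
    if len(patients) != 1:
        raise BundleError(
            f"bundle must contain exactly one Patient, found {len(patients)}"
        )
    patient = patients[0].payload
    ext = patient.get("extension", {})

    def latest(loinc: str) -> Optional[float]:
        best: Optional[tuple[str, float]] = None
        for d in docs:
            if d.resource_type != "Observation":
                continue
            coding = d.payload.get("code", {}).get("coding", [{}])[0]
            if coding.get("system") == LOINC and coding.get("code") == loinc:
                when = d.payload.get("effectiveDateTime", "")
                value = d.payload["valueQuantity"]["value"]
                if best is None or when >= best[0]:
                    best = (when, value)
        return None if best is None else best[1]

    weight = latest(WEIGHT_LOINC)
    height = latest(HEIGHT_LOINC)
    if weight is None or height is None:
        raise BundleError(
            "bundle must contain weight and height Observations "
            f"(LOINC {WEIGHT_LOINC}, {HEIGHT_LOINC})"
        )
    conditions = [_coding_from(d.payload["code"]) for d in docs
                  if d.resource_type == "Condition"]
    medications = [_coding_from(d.payload["medicationCodeableConcept"])
                   for d in docs if d.resource_type == "MedicationStatement"]
    allergies = [_coding_from(d.payload["code"]) for d in docs
                 if d.resource_type == "AllergyIntolerance"]
    language = "en"
    comm = patient.get("communication")
    if comm:
        language = comm[0].get("language", "en")
    try:
        return PatientProfile(
            id=patients[0].id,
            age=ext["age"],
            sex=patient.get("gender", "female"),
            pregnant=ext.get("pregnant", False),
            weight=weight,
            height=height,
            lifestyle=ext.get("lifestyle", "sedentary"),
            education_level=ext.get("education_level", "medium"),
            preferred_language=language,
            conditions=conditions,
            medications=medications,
            allergies=allergies,
            food_preferences=ext.get("food_preferences", []),
            exercise_preferences=[Coding(**c) for c in
                                  ext.get("exercise_preferences", [])],
            regimen_preference=ext.get("regimen_preference", "none"),
            history_of_hypoglycemia=ext.get("history_of_hypoglycemia", 0),
            history_of_hyperglycemia=ext.get("history_of_hyperglycemia", 0),
            has_dka=ext.get("has_dka", False),
            has_relative=ext.get("has_relative", False),
        )
    except (KeyError, ValueError) as exc:
        raise BundleError(f"cannot bind PatientProfile: {exc}") from exc


def observations_from_documents(
    docs: Sequence[FhirLiteDocument],
) -> list[ObservationRecord]:
    records = []
    for d in docs:
        if d.resource_type != "Observation":
            continue
        payload = d.payload
        ext = payload.get("extension", {})
        records.append(ObservationRecord(
            code=_coding_from(payload["code"]),
            value=Quantity(value=payload["valueQuantity"]["value"],
                           unit=payload["valueQuantity"]["unit"]),
            timestamp=datetime.fromisoformat(payload["effectiveDateTime"]),
            slot=ext.get("slot", "other"),
            source=ext.get("source", "sensor"),
        ))
    return records


def log_from_documents(docs: Sequence[FhirLiteDocument]) -> GlucoseLog:
    """Glucose Observations (with a slot extension) -> GlucoseLog."""
    entries = {}
    for record in observations_from_documents(docs):
        if record.code.code != GLUCOSE_LOINC or record.slot is Slot.other:
            continue
        entries[(record.timestamp.date(), record.slot)] = record.value
    return GlucoseLog(entries)


# ---------------------------------------------------------------------------
# Care-plan bundle
# ---------------------------------------------------------------------------


def _goal_resource(plan: CarePlan) -> dict[str, Any]:
    g = plan.goals
    payload: dict[str, Any] = {
        "resourceType": "Goal",
        "id": f"goal-{plan.patient_id}",
        "subject": {"reference": f"Patient/{plan.patient_id}"},
        "extension": {
            "hba1c_max_percent": g.hba1c_max,
            "premeal_bg_lowQuantity": {"value": g.premeal_bg_low.value,
                                       "unit": g.premeal_bg_low.unit},
            "premeal_bg_highQuantity": {"value": g.premeal_bg_high.value,
                                        "unit": g.premeal_bg_high.unit},
        },
    }
    ext = payload["extension"]
    if g.weight_goal is not None:
        ext["weight_goal_kg"] = g.weight_goal
    if g.bp_goal is not None:
        ext["bp_goal"] = g.bp_goal
    if g.bedtime_bg_low is not None and g.bedtime_bg_high is not None:
        ext["bedtime_bg_lowQuantity"] = {"value": g.bedtime_bg_low.value,
                                         "unit": g.bedtime_bg_low.unit}
        ext["bedtime_bg_highQuantity"] = {"value": g.bedtime_bg_high.value,
                                          "unit": g.bedtime_bg_high.unit}
    return payload


def _dose_resource(dose: InsulinDose, plan: CarePlan, i: int) -> dict[str, Any]:
    return {
        "resourceType": "MedicationRequest",
        "id": f"medreq-{i}",
        "subject": {"reference": f"Patient/{plan.patient_id}"},
        "medicationCodeableConcept": _codeable(dose.product.code),
        "dosage": {
            "doseQuantity": {"value": dose.units, "unit": "U"},
            "timing": dose.timing.value,
        },
        "extension": {
            "kind": dose.kind.value,
            "action_class": dose.product.action_class.value,
            "preference_rank": dose.product.preference_rank,
            "rounded_units": dose.rounded_units,
        },
    }


def _nutrition_resource(plan: CarePlan) -> dict[str, Any]:
    d = plan.diet
    return {
        "resourceType": "NutritionOrder",
        "id": f"diet-{plan.patient_id}",
        "subject": {"reference": f"Patient/{plan.patient_id}"},
        "dailyCalories": d.calories_per_day,
        "meal": [
            {"name": m.name, "share": m.share, "carbs_g": m.carbs_g,
             "calories": m.calories}
            for m in d.meals
        ],
        "excludeFoodModifier": list(d.forbidden_foods),
        "foodPreferenceModifier": list(d.recommended_food_groups),
        "extension": {
            "bmr": d.bmr,
            "activity_multiplier": d.activity_multiplier,
            "maintenance_calories": d.maintenance_calories,
            "ideal_weight_low": d.ideal_weight_low,
            "ideal_weight_high": d.ideal_weight_high,
            "weight_status": d.weight_status.value,
            "weight_goal": d.weight_goal,
            "adjustment_period_days": d.adjustment_period_days,
            "total_carbs_g": d.total_carbs_g,
        },
    }


def _exercise_resources(plan: CarePlan) -> list[dict[str, Any]]:
    docs = []
    for i, comp in enumerate(plan.exercise.components):
        docs.append({
            "resourceType": "ProcedureRequest",
            "id": f"exercise-{i}",
            "subject": {"reference": f"Patient/{plan.patient_id}"},
            "category": "exercise",
            "code": _codeable(comp.exercise),
            "extension": {
                "met": comp.met,
                "frequency_per_week": comp.frequency_per_week,
                "duration_min": comp.duration_min,
                "intensity": comp.intensity.value,
            },
        })
    return docs


def _course_resources(plan: CarePlan) -> list[dict[str, Any]]:
    return [{
        "resourceType": "ProcedureRequest",
        "id": f"course-{i}",
        "subject": {"reference": f"Patient/{plan.patient_id}"},
        "category": "education",
        "code": {"coding": [{"system": "COURSE", "code": course,
                             "display": course}]},
    } for i, course in enumerate(plan.education.courses)]


def write_careplan_bundle(plan: CarePlan) -> str:
    """Serialize a care plan to a FHIR-lite bundle.

    The bundle carries the CarePlan resource, its Goal, one
    MedicationRequest per planned dose, the NutritionOrder, one
    ProcedureRequest per exercise component and per course, and the
    Patient snapshot — enough to bind back an equivalent plan.
    """
    careplan_doc: dict[str, Any] = {
        "resourceType": "CarePlan",
        "id": f"careplan-{plan.patient_id}",
        "status": plan.status.value,
        "subject": {"reference": f"Patient/{plan.patient_id}"},
        "category": {"coding": [{"system": "SNOMEDCT", "code": "698360004",
                                 "display": "Diabetes self management plan"}]},
        "period": {"start": plan.created.isoformat(),
                   "days": plan.valid_days},
        "extension": {
            "is_current": plan.is_current,
            "regimen_kind": plan.regimen.kind.value,
            "tdd": plan.regimen.tdd,
            "f_factor": plan.regimen.f_factor,
            "exercise_allowed": plan.exercise.allowed,
            "exercise_fixed": plan.exercise.fixed,
            "exercise_forbidden_reasons": list(plan.exercise.forbidden_reasons),
            "exercise_forbidden_codes": sorted(plan.exercise.forbidden_exercises),
            "education_coordinator": plan.education.coordinator.value,
            "education_styles": sorted(s.value for s in plan.education.styles),
            "education_topics": sorted(t.value for t in plan.education.topics),
        },
    }
    docs = [careplan_doc, _goal_resource(plan)]
    docs += [_dose_resource(d, plan, i) for i, d in enumerate(plan.regimen.doses)]
    docs.append(_nutrition_resource(plan))
    docs += _exercise_resources(plan)
    docs += _course_resources(plan)
    patient_docs = json.loads(write_patient_bundle(plan.profile))
    docs += [e["resource"] for e in patient_docs["entry"]]
    return _bundle(docs, f"careplan-bundle-{plan.patient_id}")


def _quantity_from(obj: dict[str, Any]) -> Quantity:
    return Quantity(value=obj["value"], unit=obj["unit"])


def bind_careplan(docs: Sequence[FhirLiteDocument]) -> CarePlan:
    """Reconstruct a CarePlan from a bundle written by write_careplan_bundle."""
    from .core import GoalSet, RegimenKind

    def only(rtype: str) -> FhirLiteDocument:
        found = [d for d in docs if d.resource_type == rtype]
        if len(found) != 1:
            raise BundleError(
                f"bundle must contain exactly one {rtype}, found {len(found)}"
            )
        return found[0]

    cp = only("CarePlan").payload
    ext = cp["extension"]
    goal_ext = only("Goal").payload["extension"]
    goals = GoalSet(
        hba1c_max=goal_ext["hba1c_max_percent"],
        premeal_bg_low=_quantity_from(goal_ext["premeal_bg_lowQuantity"]),
        premeal_bg_high=_quantity_from(goal_ext["premeal_bg_highQuantity"]),
        weight_goal=goal_ext.get("weight_goal_kg"),
        bp_goal=goal_ext.get("bp_goal"),
        bedtime_bg_low=(_quantity_from(goal_ext["bedtime_bg_lowQuantity"])
                        if "bedtime_bg_lowQuantity" in goal_ext else None),
        bedtime_bg_high=(_quantity_from(goal_ext["bedtime_bg_highQuantity"])
                         if "bedtime_bg_highQuantity" in goal_ext else None),
    )
    doses = []
    for d in docs:
        if d.resource_type != "MedicationRequest":
            continue
        p = d.payload
        dext = p["extension"]
        doses.append(InsulinDose(
            product=InsulinProduct(
                code=_coding_from(p["medicationCodeableConcept"]),
                action_class=ActionClass(dext["action_class"]),
                preference_rank=dext["preference_rank"],
            ),
            units=p["dosage"]["doseQuantity"]["value"],
            timing=DoseTiming(p["dosage"]["timing"]),
            kind=DoseKind(dext["kind"]),
        ))
    regimen = InsulinRegimen(kind=RegimenKind(ext["regimen_kind"]),
                             tdd=ext["tdd"], f_factor=ext["f_factor"],
                             doses=doses)
    n = only("NutritionOrder").payload
    next_ = n["extension"]
    diet = DietPlan(
        bmr=next_["bmr"],
        activity_multiplier=next_["activity_multiplier"],
        maintenance_calories=next_["maintenance_calories"],
        ideal_weight_low=next_["ideal_weight_low"],
        ideal_weight_high=next_["ideal_weight_high"],
        weight_status=WeightStatus(next_["weight_status"]),
        weight_goal=next_["weight_goal"],
        adjustment_period_days=next_["adjustment_period_days"],
        calories_per_day=n["dailyCalories"],
        total_carbs_g=next_["total_carbs_g"],
        meals=[MealSpec(**m) for m in n["meal"]],
        forbidden_foods=list(n["excludeFoodModifier"]),
        recommended_food_groups=list(n["foodPreferenceModifier"]),
    )
    components = []
    courses = []
    for d in docs:
        if d.resource_type != "ProcedureRequest":
            continue
        p = d.payload
        if p.get("category") == "exercise":
            pext = p["extension"]
            components.append(ExerciseComponent(
                exercise=_coding_from(p["code"]),
                met=pext["met"],
                frequency_per_week=pext["frequency_per_week"],
                duration_min=pext["duration_min"],
                intensity=Intensity(pext["intensity"]),
            ))
        elif p.get("category") == "education":
            courses.append(p["code"]["coding"][0]["code"])
    exercise = ExercisePlan(
        allowed=ext["exercise_allowed"],
        forbidden_reasons=list(ext["exercise_forbidden_reasons"]),
        forbidden_exercises=set(ext["exercise_forbidden_codes"]),
        components=components,
        fixed=ext["exercise_fixed"],
    )
    education = EducationPlan(
        coordinator=Coordinator(ext["education_coordinator"]),
        styles={LearningStyle(s) for s in ext["education_styles"]},
        topics={Topic(t) for t in ext["education_topics"]},
        courses=courses,
    )
    profile = bind_profile(docs)
    return CarePlan(
        patient_id=profile.id,
        created=datetime.fromisoformat(cp["period"]["start"]),
        valid_days=cp["period"]["days"],
        is_current=ext["is_current"],
        status=PlanStatus(cp["status"]),
        goals=goals,
        regimen=regimen,
        diet=diet,
        exercise=exercise,
        education=education,
        profile=profile,
    )
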