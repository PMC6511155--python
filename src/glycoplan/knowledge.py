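"""Config-loaded treatment knowledge: catalogs and contraindication maps.

The knowledge base plays the role an ontology TBOX would play in a semantic
CDSS: which insulin products exist and in what preference order, which
drugs/diseases/foods/exercises conflict, the activity-level table, the
course catalog, and per-stratum goal defaults.

The shipped catalog is deliberately small and illustrative — correctness of
every downstream rule is defined *relative to the loaded knowledge base*,
not to a clinical drug registry. Deployments extend it through YAML or JSON
config documents; any section left out falls back to the shipped default.
"""

from __future__ import annotations

import copy
import enum
import json
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .core import AgeCategory, Coding, GoalSet, Lifestyle, PatientProfile
from .errors import ConfigError, NoSafeInsulinError


class ActionClass(str, enum.Enum):
    rapid = "rapid"
    short = "short"
    intermediate = "intermediate"
    long = "long"


class InsulinProduct(BaseModel):
    model_config = ConfigDict(frozen=True)

    code: Coding
    action_class: ActionClass
    preference_rank: int


class ExerciseEntry(BaseModel):
    """One compendium activity: MET value + display name."""

    model_config = ConfigDict(frozen=True)

    met: float
    display: str


class KnowledgeBase(BaseModel):
    insulin_catalog: list[InsulinProduct]
    drug_drug_contra: dict[str, set[str]]
    drug_disease_contra: dict[str, set[str]]
    drug_food_contra: dict[str, set[str]]
    disease_food_contra: dict[str, set[str]] = {}
    disease_exercise_contra: dict[str, set[str]]
    hyperglycemic_drugs: set[str]
    hypoglycemic_drugs: set[str]
    exercise_catalog: dict[str, ExerciseEntry]
    default_exercises: set[str]
    activity_levels: dict[Lifestyle, float]
    course_catalog: dict[str, list[str]]  # "topic/style" -> course ids
    learning_styles: dict[str, list[str]]  # "agecat/education" -> styles
    goal_defaults: dict[str, GoalSet]  # "agecat/pregnant" -> goals
    exercise_forbidden_conditions: set[str]
    pregnancy_exercise_contra: set[str]
    age_bands: dict[str, int]

    def products_of_class(self, action_class: ActionClass) -> list[InsulinProduct]:
        return sorted(
            (p for p in self.insulin_catalog if p.action_class is action_class),
            key=lambda p: p.preference_rank,
        )

    def goal_default(
        self, age_cat: AgeCategory, pregnant: bool, hypo_history: bool = False
    ) -> GoalSet:
        """Goal template for a demographic stratum.

        A history of hypoglycemia selects the stratum's ``.../hypo_history``
        override entry when one is configured (relaxed targets), else the
        base entry.
        """
        key = f"{age_cat.value}/{'pregnant' if pregnant else 'nonpregnant'}"
        if hypo_history and f"{key}/hypo_history" in self.goal_defaults:
            return self.goal_defaults[f"{key}/hypo_history"]
        if key in self.goal_defaults:
            return self.goal_defaults[key]
        raise ConfigError(f"goal_defaults.{key}: no default goal set configured")

    def to_config(self) -> dict[str, Any]:
        """Serialize back to the config-document form accepted by the loader."""
        return json.loads(self.model_dump_json())


# ---------------------------------------------------------------------------
# Shipped default catalog (illustrative, config-extensible)
# ---------------------------------------------------------------------------

SCT = "SNOMEDCT"
COMPENDIUM = "COMPENDIUM"

_mgdl = lambda v: {"value": v, "unit": "mg/dL"}  # noqa: E731

DEFAULT_KB_CONFIG: dict[str, Any] = {
    "insulin_catalog": [
        {"code": {"system": SCT, "code": "414518007", "display": "insulin detemir"},
         "action_class": "long", "preference_rank": 1},
        {"code": {"system": SCT, "code": "126212009", "display": "insulin glargine"},
         "action_class": "long", "preference_rank": 2},
        {"code": {"system": SCT, "code": "412453006", "display": "NPH insulin"},
         "action_class": "intermediate", "preference_rank": 1},
        {"code": {"system": SCT, "code": "325072002", "display": "regular insulin"},
         "action_class": "short", "preference_rank": 1},
        {"code": {"system": SCT, "code": "325064001", "display": "insulin aspart"},
         "action_class": "rapid", "preference_rank": 1},
        {"code": {"system": SCT, "code": "412210000", "display": "insulin lispro"},
         "action_class": "rapid", "preference_rank": 2},
    ],
    # Stored once per unordered pair; symmetry is closed at load time.
    # Detemir conflicts with testosterone, beta-blockers, decongestants and
    # hydrochlorothiazide.
    "drug_drug_contra": {
        "414518007": ["testosterone", "beta-blocker", "decongestant",
                      "hydrochlorothiazide"],
    },
    "drug_disease_contra": {
        # illustrative: detemir x severe hepatic impairment
        "414518007": ["197270009"],
    },
    "drug_food_contra": {
        "beta-blocker": ["grapefruit"],
        "warfarin": ["leafy greens (high vitamin K)"],
    },
    "disease_food_contra": {},
    "disease_exercise_contra": {
        # foot ulcers -> jogging; cataracts -> cycling;
        # severe nonproliferative retinopathy -> jumping/jarring/breath-holding
        "371087003": ["12020"],
        "193570009": ["01015"],
        "312903003": ["15552", "15551", "15550"],
    },
    "hyperglycemic_drugs": ["prednisone", "decongestant"],
    "hypoglycemic_drugs": ["sulfonylurea", "beta-blocker"],
    "exercise_catalog": {
        "12020": {"met": 7.0, "display": "jogging, general"},
        "01015": {"met": 7.5, "display": "bicycling, general"},
        "18310": {"met": 6.0, "display": "swimming, leisurely"},
        "17170": {"met": 3.5, "display": "walking, brisk"},
        "15552": {"met": 8.0, "display": "rope jumping, moderate"},
        "15551": {"met": 11.8, "display": "rope jumping, fast"},
        "15550": {"met": 12.3, "display": "jumping, vigorous"},
        "02054": {"met": 3.5, "display": "resistance training, light"},
    },
    "default_exercises": ["17170", "18310"],
    # Activity-level multipliers by lifestyle.
    "activity_levels": {
        "sedentary": 1.2,
        "lightly_active": 1.375,
        "moderately_active": 1.55,
        "very_active": 1.725,
        "extra_active": 1.9,
    },
    "course_catalog": {
        "insulin/reading": ["C-INS-R1-basics", "C-INS-R2-injection",
                            "C-INS-R3-storage"],
        "insulin/visual": ["C-INS-V1-basics", "C-INS-V2-injection"],
        "insulin/auditory": ["C-INS-A1-basics"],
        "insulin/games": ["C-INS-G1-basics"],
        "medications/reading": ["C-MED-R1-administration"],
        "medications/visual": ["C-MED-V1-administration"],
        "diet/reading": ["C-DIET-R1-carb-counting", "C-DIET-R2-weight"],
        "diet/visual": ["C-DIET-V1-carb-counting"],
        "diet/games": ["C-DIET-G1-carb-counting"],
        "diet/auditory": ["C-DIET-A1-carb-counting"],
        "monitoring/reading": ["C-MON-R1-pattern-mgmt", "C-MON-R2-isf-icr"],
        "monitoring/visual": ["C-MON-V1-pattern-mgmt"],
        "monitoring/games": ["C-MON-G1-bg-basics"],
        "monitoring/auditory": ["C-MON-A1-bg-basics"],
        "emergency/reading": ["C-EMG-R1-hypo-symptoms"],
        "emergency/visual": ["C-EMG-V1-hypo-symptoms"],
        "emergency/auditory": ["C-EMG-A1-hypo-symptoms"],
        "emergency/games": ["C-EMG-G1-hypo-symptoms"],
        "exercise/reading": ["C-EXE-R1-sport-selection"],
        "exercise/visual": ["C-EXE-V1-sport-selection"],
        "exercise/games": ["C-EXE-G1-sport-selection"],
        "complications/reading": ["C-CMP-R1-overview"],
        "complications/visual": ["C-CMP-V1-overview"],
        "complications/auditory": ["C-CMP-A1-overview"],
        "complications/games": ["C-CMP-G1-overview"],
    },
    # Learning-style table; printed anchor: highly educated adults get
    # visual + reading. Other strata are shipped defaults.
    "learning_styles": {
        "child/low": ["games", "visual"],
        "child/medium": ["games", "visual"],
        "child/high": ["games", "visual"],
        "adolescent/low": ["visual", "games"],
        "adolescent/medium": ["visual", "games"],
        "adolescent/high": ["visual", "reading"],
        "adult/low": ["visual", "auditory"],
        "adult/medium": ["visual", "case_studies"],
        "adult/high": ["visual", "reading"],
        "oldAdult/low": ["auditory", "visual"],
        "oldAdult/medium": ["visual", "auditory"],
        "oldAdult/high": ["reading", "visual"],
    },
    # Per-stratum goal defaults (kcal of the CPG family; the printed rule
    # covers only the pregnant-adult stratum, which is hard-wired in
    # insulin_planner.set_goals and bypasses this table).
    "goal_defaults": {
        "child/nonpregnant": {
            "hba1c_max": 7.5, "premeal_bg_low": _mgdl(90),
            "premeal_bg_high": _mgdl(130),
            "bedtime_bg_low": _mgdl(90), "bedtime_bg_high": _mgdl(150)},
        # relaxed targets for children with a hypoglycemia history
        "child/nonpregnant/hypo_history": {
            "hba1c_max": 8.0, "premeal_bg_low": _mgdl(100),
            "premeal_bg_high": _mgdl(140),
            "bedtime_bg_low": _mgdl(110), "bedtime_bg_high": _mgdl(160)},
        "adolescent/nonpregnant": {
            "hba1c_max": 7.5, "premeal_bg_low": _mgdl(90),
            "premeal_bg_high": _mgdl(130),
            "bedtime_bg_low": _mgdl(90), "bedtime_bg_high": _mgdl(150)},
        "adult/nonpregnant": {
            "hba1c_max": 7.0, "premeal_bg_low": _mgdl(80),
            "premeal_bg_high": _mgdl(130),
            "bedtime_bg_low": _mgdl(90), "bedtime_bg_high": _mgdl(150)},
        "adult/pregnant": {
            "hba1c_max": 6.5, "premeal_bg_low": _mgdl(90),
            "premeal_bg_high": _mgdl(100)},
        "adolescent/pregnant": {
            "hba1c_max": 6.5, "premeal_bg_low": _mgdl(90),
            "premeal_bg_high": _mgdl(100)},
        "oldAdult/pregnant": {
            "hba1c_max": 6.5, "premeal_bg_low": _mgdl(90),
            "premeal_bg_high": _mgdl(100)},
        "oldAdult/nonpregnant": {
            "hba1c_max": 7.5, "premeal_bg_low": _mgdl(90),
            "premeal_bg_high": _mgdl(150),
            "bedtime_bg_low": _mgdl(100), "bedtime_bg_high": _mgdl(180)},
    },
    # Exercise ban comorbidity list (applies in conjunction with age > 30):
    # hypertension, dyslipidemia, preproliferative retinopathy, nephropathy,
    # cigarette smoking.
    "exercise_forbidden_conditions": [
        "38341003", "370992007", "312903003", "90708001", "77176002",
    ],
    # Pregnancy-specific bans: preeclampsia, morbid obesity, placenta
    # previa, fetal anemia, chronic bronchitis.
    "pregnancy_exercise_contra": [
        "398254007", "238136002", "36026004", "276508000", "63480004",
    ],
    "age_bands": {"child": 12, "adolescent": 18, "adult": 55},
}

_REQUIRED_ACTIVITY_LEVELS = {1.2, 1.375, 1.55, 1.725, 1.9}


def _merge_defaults(config: Mapping[str, Any]) -> dict[str, Any]:
    merged = copy.deepcopy(DEFAULT_KB_CONFIG)
    for key, value in config.items():
        if key not in merged:
            raise ConfigError(f"{key}: unknown knowledge-base section")
        merged[key] = value
    return merged


def _symmetrize(pairs: dict[str, set[str]]) -> dict[str, set[str]]:
    closed: dict[str, set[str]] = {k: set(v) for k, v in pairs.items()}
    for a, others in list(closed.items()):
        for b in others:
            closed.setdefault(b, set()).add(a)
    return closed


def load_knowledge_base(
    source: Union[None, str, Path, Mapping[str, Any]] = None,
) -> KnowledgeBase:
    """Build a KnowledgeBase from a YAML/JSON path, a mapping, or defaults.

    Sections missing from the document fall back to the shipped defaults;
    an empty document therefore yields the all-defaults knowledge base.
    Schema violations raise :class:`ConfigError` naming the failing path.
    """
    if source is None:
        raw: Mapping[str, Any] = {}
    elif isinstance(source, Mapping):
        raw = source
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, Mapping):
            raise ConfigError("document root: expected a mapping")

    merged = _merge_defaults(raw)
    try:
        kb = KnowledgeBase.model_validate(merged)
    except ValidationError as exc:
        first = exc.errors()[0]
        path = ".".join(str(p) for p in first["loc"])
        raise ConfigError(f"{path}: {first['msg']}") from exc

    # invariant: exactly the five published activity multipliers
    values = set(kb.activity_levels.values())
    if len(kb.activity_levels) != 5 or values != _REQUIRED_ACTIVITY_LEVELS:
        raise ConfigError(
            "activity_levels: must contain exactly the five multipliers "
            f"{sorted(_REQUIRED_ACTIVITY_LEVELS)}"
        )

    # invariant: preference_rank unique within an action class
    for action_class in ActionClass:
        ranks = [p.preference_rank for p in kb.insulin_catalog
                 if p.action_class is action_class]
        if len(ranks) != len(set(ranks)):
            raise ConfigError(
                f"insulin_catalog: duplicate preference_rank within "
                f"action class {action_class.value!r}"
            )

    # invariant: drug-drug map is symmetric (close it here)
    kb = kb.model_copy(
        update={"drug_drug_contra": _symmetrize(kb.drug_drug_contra)}
    )
    return kb


def contradicted_insulins(
    profile: PatientProfile, kb: KnowledgeBase
) -> set[str]:
    """Insulin codes unsafe for this patient.

    An insulin is contradicted iff it is drug-drug contradicted with any
    current medication, or drug-disease contradicted with any current
    condition. Codes absent from the maps contribute nothing.
    """
    meds = profile.medication_codes()
    conditions = profile.condition_codes()
    out: set[str] = set()
    for product in kb.insulin_catalog:
        code = product.code.code
        if meds & kb.drug_drug_contra.get(code, set()):
            out.add(code)
        if conditions & kb.drug_disease_contra.get(code, set()):
            out.add(code)
    return out


def contradiction_reasons(
    profile: PatientProfile, kb: KnowledgeBase
) -> dict[str, str]:
    """Human-readable reason per contradicted insulin code."""
    meds = profile.medication_codes()
    conditions = profile.condition_codes()
    reasons: dict[str, str] = {}
    for product in kb.insulin_catalog:
        code = product.code.code
        drug_hits = sorted(meds & kb.drug_drug_contra.get(code, set()))
        disease_hits = sorted(conditions & kb.drug_disease_contra.get(code, set()))
        parts = []
        if drug_hits:
            parts.append(f"drug-drug with {', '.join(drug_hits)}")
        if disease_hits:
            parts.append(f"drug-disease with {', '.join(disease_hits)}")
        if parts:
            reasons[code] = "; ".join(parts)
    return reasons


def select_insulin(
    action_class: ActionClass,
    profile: PatientProfile,
    kb: KnowledgeBase,
    contraindicated: Optional[set[str]] = None,
) -> InsulinProduct:
    """Pick the preferred safe product of an action class.

    Returns the lowest preference_rank product not contradicted for the
    patient (e.g. glargine when detemir is ruled out). Raises
    :class:`NoSafeInsulinError`, carrying the reasons, if every product of
    the class is contradicted.
    """
    if contraindicated is None:
        contraindicated = contradicted_insulins(profile, kb)
    for product in kb.products_of_class(action_class):
        if product.code.code not in contraindicated:
            return product
    reasons = contradiction_reasons(profile, kb)
    class_reasons = {
        p.code.code: reasons.get(p.code.code, "contradicted")
        for p in kb.products_of_class(action_class)
    }
    raise NoSafeInsulinError(action_class.value, class_reasons)
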