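"""Deterministic synthetic patients, glucose logs, and fixture bundles.

Everything a test or demo needs is generated from a seeded scenario: no
downloads, no stored binaries. The generator emulates what the sensor
network and EHR would supply — heterogeneous demographics, multi-day
per-slot glucose logs with Gaussian sensor noise, and injectable
out-of-range patterns (a slot pushed outside the goal range on every day,
the situation pattern management must recover).

Two pinned fixtures are shipped in code: the three-day reference log with
a persistent fasting-hyperglycemia pattern, and the reference patient
whose weight (83 1/3 kg) back-derives from the worked bolus example's
TDD of 50 U so the whole advice pipeline reproduces it end to end.
"""

from __future__ import annotations

import hashlib
import json
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .core import (
    MGDL,
    Coding,
    ObservationRecord,
    ObservationSource,
    PatientProfile,
    Quantity,
    Slot,
)
from .errors import InputError
from .fhir import (
    GLUCOSE_LOINC,
    write_observation_bundle,
    write_patient_bundle,
)
from .knowledge import DEFAULT_KB_CONFIG, load_knowledge_base
from .monitor import LOG_SLOTS, GlucoseLog

__all__ = [
    "Scenario",
    "PatternInjection",
    "generate_patient",
    "generate_glucose_log",
    "generate_fixture_bundles",
    "reference_pattern_log",
    "worked_example_profile",
    "REFERENCE_LOG_VALUES",
]

GLUCOSE_CODING = Coding(system="LOINC", code=GLUCOSE_LOINC,
                        display="Glucose [Mass/volume] in Blood")


class PatternInjection(BaseModel):
    """Push one slot out of range on every generated day."""

    model_config = ConfigDict(frozen=True)

    slot: Slot
    direction: str  # "high" | "low"
    magnitude: float  # mg/dL shift applied to the slot baseline

    @field_validator("direction")
    @classmethod
    def _direction(cls, v: str) -> str:
        if v not in ("high", "low"):
            raise ValueError("direction must be 'high' or 'low'")
        return v


class Scenario(BaseModel):
    """Parameter ranges and noise model for one synthetic cohort."""

    model_config = ConfigDict(frozen=True)

    name: str = "default"
    seed: int = 0
    age_range: tuple[int, int] = (6, 80)
    weight_range_kg: tuple[float, float] = (20.0, 110.0)
    height_range_cm: tuple[float, float] = (110.0, 195.0)
    pregnant_fraction: float = 0.05
    #: proportions of stated regimen preferences (IIT, fixed_once,
    #: fixed_twice, none)
    regimen_mix: tuple[float, float, float, float] = (0.4, 0.1, 0.3, 0.2)
    pattern_injections: tuple[PatternInjection, ...] = ()
    noise_sd: float = 10.0  # mg/dL sensor noise

    @field_validator("noise_sd")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("noise_sd must be non-negative")
        return v

    @model_validator(mode="after")
    def _mix_sums_to_one(self) -> "Scenario":
        if abs(sum(self.regimen_mix) - 1.0) > 1e-9:
            raise ValueError("regimen_mix proportions must sum to 1")
        return self


def _rng(scenario: Scenario, *streams: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(scenario.seed, spawn_key=streams)
    )


_LIFESTYLES = ["sedentary", "lightly_active", "moderately_active",
               "very_active", "extra_active"]
_EDUCATION = ["low", "medium", "high"]
_REGIMENS = ["IIT", "fixed_once", "fixed_twice", "none"]


def generate_patient(scenario: Scenario, index: int) -> PatientProfile:
    """Draw one profile; the same (scenario, index) always yields the
    same profile, and every draw satisfies the profile invariants."""
    rng = _rng(scenario, 1, index)
    age = int(rng.integers(scenario.age_range[0], scenario.age_range[1] + 1))
    sex = "female" if rng.random() < 0.5 else "male"
    pregnant = bool(
        sex == "female" and 18 <= age <= 45
        and rng.random() < scenario.pregnant_fraction
    )
    # adults get full-range anthropometrics; children are scaled down
    lo_w, hi_w = scenario.weight_range_kg
    lo_h, hi_h = scenario.height_range_cm
    if age < 13:
        hi_w = min(hi_w, 60.0)
        hi_h = min(hi_h, 165.0)
    weight = float(np.round(rng.uniform(lo_w, hi_w), 1))
    height = float(np.round(rng.uniform(lo_h, hi_h), 1))
    regimen = str(rng.choice(_REGIMENS, p=scenario.regimen_mix))
    exercise_codes = sorted(DEFAULT_KB_CONFIG["exercise_catalog"])
    n_prefs = int(rng.integers(0, 3))
    prefs = [
        Coding(system="COMPENDIUM", code=str(c),
               display=DEFAULT_KB_CONFIG["exercise_catalog"][str(c)]["display"])
        for c in rng.choice(exercise_codes, size=n_prefs, replace=False)
    ]
    return PatientProfile(
        id=f"{scenario.name}-{index:04d}",
        age=age,
        sex=sex,
        pregnant=pregnant,
        weight=weight,
        height=height,
        lifestyle=str(rng.choice(_LIFESTYLES)),
        education_level=str(rng.choice(_EDUCATION)),
        regimen_preference=regimen,
        exercise_preferences=prefs,
        history_of_hypoglycemia=int(rng.integers(0, 3)),
        history_of_hyperglycemia=int(rng.integers(0, 3)),
        has_relative=bool(rng.random() < 0.7),
    )


def generate_glucose_log(
    profile: PatientProfile,
    goal: tuple[Quantity, Quantity],
    days: int,
    scenario: Scenario,
    start: date = date(2024, 5, 1),
) -> GlucoseLog:
    """Multi-day per-slot log: in-goal baselines plus Gaussian noise,
    with every pattern injection shifting its slot on all days.

    With |magnitude| > goal half-width + 3·noise_sd the injected slot is
    guaranteed out of range on the injected side (to ~3 sigma), so a
    three-day pattern is detectable by construction.
    """
    if days < 3:
        raise InputError(f"pattern-relevant logs need days >= 3, got {days}")
    rng = _rng(scenario, 2, _stable_hash(profile.id))
    low, high = goal
    mid = (low.value + high.value) / 2.0
    half_width = (high.value - low.value) / 2.0
    # fixed per-slot baselines inside the goal range
    baselines = {
        slot: mid + float(rng.uniform(-0.4, 0.4)) * half_width
        for slot in LOG_SLOTS
    }
    shifts: dict[Slot, float] = {}
    for injection in scenario.pattern_injections:
        sign = 1.0 if injection.direction == "high" else -1.0
        shifts[injection.slot] = sign * injection.magnitude
    entries = {}
    for offset in range(days):
        day = date.fromordinal(start.toordinal() + offset)
        for slot in LOG_SLOTS:
            value = (
                baselines[slot]
                + shifts.get(slot, 0.0)
                + float(rng.normal(0.0, scenario.noise_sd))
            )
            entries[(day, slot)] = Quantity(value=round(max(value, 1.0), 1),
                                            unit=low.unit)
    return GlucoseLog(entries)


def _stable_hash(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")


# ---------------------------------------------------------------------------
# Pinned fixtures
# ---------------------------------------------------------------------------

#: Three consecutive days of per-slot readings (mg/dL) with a persistent
#: fasting-hyperglycemia pattern: every before-breakfast value is above a
#: 70-140 goal, the other slots are in range except one isolated
#: before-dinner excursion that must NOT trigger a finding.
REFERENCE_LOG_VALUES: dict[str, dict[str, float]] = {
    "2019-05-05": {"before_breakfast": 320, "before_lunch": 104,
                   "before_dinner": 96, "before_bedtime": 86},
    "2019-05-06": {"before_breakfast": 296, "before_lunch": 123,
                   "before_dinner": 300, "before_bedtime": 136},
    "2019-05-07": {"before_breakfast": 341, "before_lunch": 197,
                   "before_dinner": 92, "before_bedtime": 111},
}


def reference_pattern_log() -> GlucoseLog:
    """The pinned three-day reference log."""
    entries = {}
    for day_str, slots in REFERENCE_LOG_VALUES.items():
        day = date.fromisoformat(day_str)
        for slot_name, value in slots.items():
            entries[(day, Slot(slot_name))] = Quantity(value=float(value),
                                                       unit=MGDL)
    return GlucoseLog(entries)


def worked_example_profile() -> PatientProfile:
    """The reference advice patient: weight 83 1/3 kg so the weight-based
    rule gives TDD = 50 U, an adult on IIT."""
    return PatientProfile(
        id="patient-x",
        age=35,
        sex="male",
        weight=250.0 / 3.0,  # TDD = 0.6 * W = 50 U
        height=178.0,
        lifestyle="lightly_active",
        regimen_preference="IIT",
    )


def _log_records(log: GlucoseLog) -> list[ObservationRecord]:
    records = []
    for (day, slot), value in sorted(log.entries.items()):
        hour = {Slot.before_breakfast: 7, Slot.before_lunch: 12,
                Slot.before_dinner: 18, Slot.before_bedtime: 22}[slot]
        records.append(ObservationRecord(
            code=GLUCOSE_CODING,
            value=value,
            timestamp=datetime(day.year, day.month, day.day, hour,
                               tzinfo=timezone.utc),
            slot=slot,
            source=ObservationSource.sensor,
        ))
    return records


def generate_fixture_bundles(
    out_dir: str | Path,
    scenario: Optional[Scenario] = None,
    n_patients: int = 5,
) -> dict[str, str]:
    """Write the fixture set and return a manifest of file -> sha256.

    Emits one patient bundle per cohort member, the pinned reference
    patient and log, a default knowledge-base config, and the manifest
    itself. Fully reproducible from the scenario seed.
    """
    scenario = scenario or Scenario()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    def write(name: str, text: str) -> None:
        path = out / name
        path.write_text(text)
        files[name] = hashlib.sha256(text.encode()).hexdigest()

    kb = load_knowledge_base()
    write("kb_default.json", json.dumps(kb.to_config(), indent=2,
                                        sort_keys=True))
    for i in range(n_patients):
        profile = generate_patient(scenario, i)
        write(f"patient_{i:04d}.json", write_patient_bundle(profile))
    write("patient_x.json", write_patient_bundle(worked_example_profile()))
    write("reference_log.json",
          write_observation_bundle(_log_records(reference_pattern_log()), "patient-x"))
    manifest = json.dumps(files, indent=2, sort_keys=True)
    (out / "manifest.json").write_text(manifest)
    files["manifest.json"] = hashlib.sha256(manifest.encode()).hexdigest()
    return files
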