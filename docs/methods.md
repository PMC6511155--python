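# Methods

This note documents the procedures glycoplan implements, the assumptions
behind them, the defaults and why they were chosen, and what the tests do
and do not demonstrate.

## Scope and stance

glycoplan encodes guideline-style T1D planning rules as deterministic
arithmetic over a coded patient profile and a configurable knowledge
base. It proposes; it does not decide: every care plan starts in `draft`
status and only a recorded approval marks it `approved`. Emergency
treatment is out of scope — dangerous readings (below 3.6 mmol/L or above
9.0 mmol/L) are only *flagged* by `classify_glucose_danger`. Premixed
insulins and between-meal snacks are likewise out of scope.

## Units

Glucose circulates as `mg/dL` or `mmol/L` (UCUM codes), converted at
18.0182 mg/dL per mmol/L (molar mass of glucose / 10). Arithmetic stays
in the unit supplied; cross-unit comparisons convert to mg/dL first. The
1800-rule (mg/dL) and 100-rule (mmol/L) sensitivity factors are not
exactly equivalent (1800/18.0182 ≈ 99.9); the resulting advice
discrepancy is below 0.05 U across the physiological range, which the
test suite asserts.

## Demographic bands

Age categories: child ≤ 12, adolescent 13–18, adult 19–55, oldAdult > 55.
The adult band (19–55) and the child anchor (< 10 falls inside child) are
rule-given; the adolescent/oldAdult cut-offs are this package's
convention, configurable through the knowledge base's `age_bands`
section.

## Insulin planning

- `TDD = 0.6 U/kg/day` for every regimen family, including once-daily
  fixed (nothing distinguishes its TDD rule, so the same equation is
  applied).
- Regimen: pregnancy or childhood forces basal-bolus (IIT); adults keep
  their stated preference; no preference defaults to IIT as the most
  flexible regimen.
- IIT basal fraction `f` defaults to 0.5; the selection criteria among
  {0.3, 0.4, 0.5, 0.6} are not clearly defined in the clinical
  literature, so no automatic selection is attempted — callers override
  explicitly. A two-shot basal option divides the basal dose equally
  morning/evening (no proportions are specified anywhere, so equality is
  the symmetric choice).
- Goals: the pregnant-adult stratum is rule-pinned (HbA1c < 6.5 %,
  pre-meal glucose 90–100 mg/dL). All other strata ship as an editable
  goal-defaults table in the knowledge base drawn from the same
  guideline family (e.g. non-pregnant adult: HbA1c < 7.0 %, pre-meal
  80–130 mg/dL); they are package defaults, not rule-derived values. A
  hypoglycemia history selects a relaxed per-stratum override when one is
  configured.
- Product selection walks the catalog of the required action class in
  `preference_rank` order and returns the first product that is neither
  drug-drug nor drug-disease contradicted; exhausting the class raises an
  error carrying the reasons. The shipped catalog and contradiction maps
  are deliberately small and illustrative — correctness is defined
  relative to the loaded knowledge base, not to a drug registry.
- Rounding: all dose arithmetic is exact; whole-unit rounding
  (`InsulinDose.rounded_units`) and 0.5 U advice rounding
  (`BolusAdvice.bd_rounded`) are presentation-layer only, and the exact
  values feed all chained computation.

## Diet planning

Harris-Benedict BMR with the revised coefficient sets (metric male
13.75/5.003/6.755/66.5; metric female 9.563/1.85/4.676/655.1; imperial
male 6.2/12.7/6.76/66; imperial female 4.35/4.7/4.7/655.1). The metric
and imperial sets are independent published fits and agree only to ~2 %,
which is asserted as a property bound, not an equality.

The daily carbohydrate budget `CpD/4` treats every planned calorie as
carbohydrate at 4 kcal/g. That deliberately ignores protein and fat
calories; it is implemented verbatim because the downstream bolus
arithmetic (carb counting against ICR) is defined on exactly this
quantity. Meal shares are 30/35/35 % and are applied to both carbs and
calories — the source procedure distributes carb grams by meal but also
speaks of per-meal calories, and a single share table is the only
consistent reading.

Weight goals: inside BMI 18.5–25 the goal is the current weight; below it
the goal is the lowest ideal weight, above it the highest — the nearest
healthy value, since only inequalities ("at least"/"at most") are
specified. The adjustment period `d` defaults to 90 days, matching the
plan's validity window; a period so short that the calorie reduction
drives `CpD ≤ 0` raises `PeriodTooShortError` rather than emitting an
unsafe plan.

## Exercise and education

The comorbidity exercise ban (hypertension, dyslipidemia,
preproliferative retinopathy, nephropathy, smoking) is applied
*conjunctively* with the age-over-30 trigger, reading the rule as one
conjunction rather than a list of independent bans; a 25-year-old with
hypertension therefore remains eligible. Pregnancy contraindications
(BMI < 12, preeclampsia, morbid obesity, placenta previa, fetal anemia,
chronic bronchitis) are a separate disjunct. Condition-specific exercise
exclusions (foot ulcers → jogging, cataracts → cycling, severe
nonproliferative retinopathy → jumping/jarring/breath-holding) live in
the knowledge base's disease-exercise map.

Recommended exercises are the patient's preferences minus the forbidden
set, falling back to a knowledge-base default set (walking, swimming) for
patients with no stated preference. The default prescription (3–5
sessions/week, 30 min, moderate intensity, lighter for old adults)
follows generic guideline practice and is config-overridable; it is a
package default, not a derived value.

Education: children and old adults with an available relative get the
relative as coordinator. The learning-style table anchors on "highly
educated adults → visual + reading" and "children → games + visual"; all
other strata are shipped defaults. Topics accumulate from regimen (IIT
adds monitoring), conditions (complications), hypo-/hyperglycemia history
(emergency), medications, and an active exercise plan. Course assignment
is a deterministic (topic, style) catalog join with first-occurrence
deduplication.

## Real-time advice

The correction-band table is anchored at the goal's upper bound: +1 unit
per started 50 mg/dL band above it, capped at +4; below 70 mg/dL the
planned dose drops by 1. The band between 70 mg/dL and the goal's lower
bound is undefined in the source table; glycoplan treats it as in-goal
(delta 0), which is the conservative reading. The printed table for goal
[100, 150] is the test fixture.

A negative bolus converts to carbohydrate as `(−BD)·ICR` grams — the carb
mass one unit's deficit covers. This is a derived rule: the source only
says "take some more carbs".

Exercise-only advice (no meal within 3 h) follows the stated rule
verbatim: underweight/normal patients eat `BC/4` grams *and* the
equivalent insulin units `(BC/4)/ICR` are **added** to the correction
dose N1. Adding insulin while adding carbs is arithmetically surprising,
but it is what the procedure states, and it is implemented as written
rather than rationalized; overweight patients get the units subtracted
and no carbs. Consequently the advice type's "carbs only when action is
eat_carbs" invariant holds for meal advice but is intentionally relaxed
on this one path.

## Pattern management

A finding requires all three same-slot values of a consecutive-3-day
window outside the goal on the same side. Longer logs scan every 3-day
window; findings are deduplicated per slot keeping the most recent
window. The slot→dose mapping is fixed (pre-lunch → breakfast bolus,
pre-dinner → lunch bolus, bedtime → dinner bolus, fasting → bedtime
basal). The adjustment fraction defaults to 0.10 ("at least 10 %") and is
validated to the stated 0.10–0.20 band; the same band is applied to bolus
and basal adjustments since nothing distinguishes them. Adjusting
non-IIT regimens is rejected. After an adjustment the regimen's TDD is
updated to the new dose sum while the plan-time basal fraction is kept as
provenance — the realised fraction legitimately drifts off the
{0.3, 0.4, 0.5, 0.6} planning grid.

Maintenance (`maintain_plan`) runs on the plan's validity cycle: achieved
HbA1c above the goal or weight off the weight goal (±0.5 kg) triggers a
full rebuild from the profile updated with the measured weight; ISF/ICR
implicitly recompute from the new TDD at the next advice call. Met goals
extend validity with unchanged doses. The superseded plan is archived
with `is_current = False`.

## FHIR-lite serialization

Only the profiled element subset is produced and validated: resources
carry `resourceType`/`id` and FHIR-compatible field names
(`valueQuantity`, `effectiveDateTime`, `medicationCodeableConcept`, …)
plus an `extension` object for planner-specific fields; statuses are
fixed (`Observation.status = "final"`,
`Condition.verificationStatus = "confirmed"`). Validation reports the
failing JSON path; every coding needs system + code, every quantity needs
value + unit. References into a bundle must resolve by id; references to
a resource type the bundle does not carry are treated as external.
Writers sort keys so bundles are diff-stable, and write → read → bind is
lossless for profiles and care plans (asserted over a synthetic cohort).

## Synthetic data

The generator draws demographics from configurable ranges (ages 6–80,
weights 20–110 kg scaled down for children, five lifestyles, the stated
regimen-preference mix) and builds per-slot glucose logs as in-goal
baselines plus Gaussian sensor noise (default sd 10 mg/dL — a round
figure for consumer CGM error; no physiologic glucose-insulin dynamics
are simulated). Pattern injections shift one slot by a fixed magnitude on
every day; with magnitude above goal half-width + 3·noise_sd the pattern
is detectable by construction, and the suite asserts ≥ 99 % recovery over
200 seeds plus exact cleanliness of noise-free uninjected logs. All
outputs are pure functions of (scenario, seed).

Two fixtures are pinned in code rather than generated: the three-day
reference log (12 values, one persistent fasting-high pattern, one
isolated excursion) and the reference advice patient whose 83⅓ kg weight
back-derives from the 50 U TDD of the worked bolus example so that the
pipeline reproduces ICR = 10, ISF = 36, N1 = 2.5, N2 = 6, BD = 8.5 end to
end.

Because the generator emulates only slot-structured noise around fixed
baselines, passing tests demonstrate the correctness of the *rules* on
realistic-looking inputs — not performance on real CGM traces, which have
meal/exercise dynamics, drift and dropout that this model does not
attempt.

## Numerical choices

- Dose splits are computed by subtraction (`ED = TDD − MD`) so the parts
  sum to TDD exactly in floating point.
- Advice rounding is half-away-from-zero to 0.5 U; plan doses round half
  up to whole units. Exact values are always retained.
- Thresholds are strict as stated: danger flags at < 3.6 / > 9.0 mmol/L;
  the 300-rule applies strictly below TDD = 10 U; exercise is permitted
  at exactly 80 and 250 mg/dL.
- Problem sizes in the test suite (10⁴ random TDDs, 1000 random logs for
  the brute-force cross-check, 200 seeded recovery logs, 20-patient
  round-trip cohort) keep the full suite under a few seconds while giving
  the property checks wide coverage.

## Known limitations

- The shipped knowledge base is illustrative, not a clinical registry;
  deployments must supply their own catalogs.
- Goal defaults for non-pregnant strata, the learning-style table beyond
  its two anchors, and the exercise prescription are package defaults.
- Carbohydrate budgeting ignores protein/fat macronutrients by design.
- The underweight exercise-only rule is implemented as stated even though
  its arithmetic is questionable (see above).
- No OWL/RDF representation, no terminology-server lookups, no FHIR
  server, and no emergency-treatment procedures.
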