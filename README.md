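# glycoplan

Rule-based clinical decision support for type 1 diabetes (T1D): build a
complete personalized care plan — insulin regimen, diet, exercise and
education — from a coded patient profile, then give real-time bolus /
carb / exercise advice and multi-day glucose pattern management from
sensor-style observations. Documents are exchanged as FHIR-lite JSON
bundles; all treatment knowledge (insulin catalog, contraindication maps,
MET table, course catalog, goal defaults) lives in a config-loadable
knowledge base.

It is aimed at health-informatics researchers and CDSS builders who need
a deterministic, testable reference implementation of guideline-style T1D
planning arithmetic — not at direct clinical use: every plan is a *draft*
proposal for a physician to approve.

## The arithmetic at the core

**Insulin.** Total daily dose from body weight, `TDD = 0.6 W` U/day.
The twice-daily fixed regimen splits it `MD = ⅔ TDD`, `ED = ⅓ TDD`, with
`MD_L = ⅔ MD` (intermediate-acting), `MD_S = ⅓ MD` (short-acting), and the
evening dose half/half. Basal-bolus therapy (IIT) takes `BA = f·TDD`
(f ∈ {0.3, 0.4, 0.5, 0.6}, default 0.5) and spreads `BO = (1−f)·TDD`
equally over three pre-meal boluses.

**Diet.** Harris-Benedict basal metabolic rate × the activity-level
multiplier (1.2 … 1.9) gives maintenance calories `MC`; the ideal-weight
range comes from BMI 18.5–25; a weight deficit/excess is converted at
7700 kcal/kg over an adjustment period `d` (default 90 days) to get daily
calories `CpD`; daily carbohydrate grams are `CpD/4`, distributed
30 % / 35 % / 35 % over breakfast / lunch / dinner.

**Real-time advice** (IIT only). Insulin sensitivity factor
`ISF = 1800/TDD` (mg/dL, or 100/TDD in mmol/L); insulin-to-carb ratio
`ICR = 500/TDD` (300/TDD when TDD < 10 U). For a meal with carbs `MC_g`
and current glucose `CBG` against pre-meal goal `PBG`:

    DBG = CBG − PBG,  N1 = DBG/ISF,  N2 = MC_g/ICR,  BD = N1 + N2

Positive `BD` → inject; zero → skip; negative → eat `(−BD)·ICR` grams of
carbs. Exercise within 3 h of the meal burns `BC = MET·weight·hours` kcal
and reduces the bolus by `(BC/4)/ICR` units; exercise is forbidden when
glucose is above 250 or below 80 mg/dL or with ketoacidosis.

**Pattern management.** Three consecutive days out of goal on the same
side in the same time slot adjust the responsible dose by 10–20 %: a
pre-lunch pattern moves the breakfast bolus, pre-dinner the lunch bolus,
bedtime the dinner bolus, and a fasting (pre-breakfast) pattern moves the
bedtime basal. Single excursions never trigger a change.

## Worked example

A 35-year-old, 83.3 kg adult on IIT (`glycoplan.synth.worked_example_profile()`):

```python
from glycoplan import build_care_plan, load_knowledge_base, advise_bolus, Quantity
from glycoplan.synth import worked_example_profile

kb = load_knowledge_base()                 # shipped default catalogs
plan = build_care_plan(worked_example_profile(), kb)
r = plan.regimen
print(r.kind.value, round(r.tdd, 1))       # IIT 50.0
for d in r.doses:
    print(d.timing.value, d.product.code.display, round(d.units, 2))

adv = advise_bolus(Quantity(value=210, unit="mg/dL"),
                   Quantity(value=120, unit="mg/dL"), 60, r.tdd)
print(adv.n1, adv.n2, adv.bd_rounded, adv.action.value)
```

prints

```
IIT 50.0
bedtime insulin detemir 25.0
before_breakfast insulin aspart 8.33
before_lunch insulin aspart 8.33
before_dinner insulin aspart 8.33
2.5 6.0 8.5 inject
```

i.e. a 50 U total daily dose split 25 U basal + 3 × 8.33 U boluses, and —
for a 60 g meal at glucose 210 mg/dL against a 120 mg/dL goal — a
correction of 2.5 U plus carb cover of 6 U: inject 8.5 U.

The same flows are available from the shell:

```sh
glycoplan synth --out fixtures --seed 1          # synthetic FHIR-lite bundles
glycoplan plan --in fixtures/patient_x.json --out plan.json
glycoplan advise --plan plan.json --cbg 210 --carbs 60
glycoplan monitor --plan plan.json --log fixtures/reference_log.json
```

## Layout

- `src/glycoplan/core.py` — shared types, glucose units, age bands
- `src/glycoplan/knowledge.py` — config-loaded catalogs and contraindication maps
- `src/glycoplan/insulin.py` — goals, regimen choice, TDD and dose splits
- `src/glycoplan/diet.py` — BMR, calories, ideal weight, meal distribution
- `src/glycoplan/lifestyle.py` — exercise and education sub-plans
- `src/glycoplan/monitor.py` — bolus advice and pattern management
- `src/glycoplan/careplan.py` — plan assembly, approval, maintenance
- `src/glycoplan/fhir.py` — FHIR-lite JSON bundles
- `src/glycoplan/synth.py` — seeded synthetic patients, logs and fixtures
- `src/glycoplan/cli.py` — `glycoplan plan|advise|monitor|synth`

See `docs/methods.md` for the model assumptions, parameter defaults, and
known limitations.
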