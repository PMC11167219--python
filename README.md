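# obesitydosing

Decision support and quality-improvement monitoring for weight-based
medication dosing in inpatients with obesity.

Most pediatric medications are dosed per kilogram of body weight, but in
patients with obesity the pharmacokinetically correct weight is often not
the actual body weight: depending on the drug's distribution and
clearance, an **ideal body weight** (IBW, estimated lean mass for height)
or an **adjusted body weight** (AdjBW, lean mass plus a fraction of the
excess) is recommended. This package implements the computable core of an
EHR-based dosing initiative around that problem, for pharmacists,
medication-safety teams and QI analysts:

* **Obesity identification.** BMI and BMI-percentile-for-age via the CDC
  LMS method — for a growth reference supplying the Box-Cox power *L*,
  median *M* and coefficient of variation *S* at each (sex, age) point,

  `z = ((BMI/M)^L − 1) / (L·S)` (`z = ln(BMI/M)/S` at L = 0), percentile = 100·Φ(z).

  Children 2 to <20 years are obese above the 95th percentile-for-age;
  adults (≥20 years) above an absolute BMI of 30 kg/m² (strict
  inequalities, configurable to inclusive).
* **Dosing weights.** Traub IBW `2.396·e^(0.01863·height_cm)` below
  152.4 cm (60 in), sex-specific Devine formula at or above;
  `AdjBW = IBW + 0.4·(actual − IBW)` with a configurable cofactor.
* **Formulary rules.** Seven high-risk IV drugs ship as defaults
  (acetaminophen, acyclovir, amikacin, dexmedetomidine, gentamicin,
  tobramycin, voriconazole) with their recommended dosing-weight kind,
  max single dose and per-kg guideline range; opt-out default weight
  selection mirrors the EHR behaviour.
* **Order auditing.** A retrospective rule engine judges each order
  appropriate/inappropriate/excluded: weight-based orders by dosing-weight
  kind; flat (mg) doses by back-calculated mg/kg against the recommended
  alternative weight, with a max-dose carve-out (a 1000 mg acetaminophen
  dose is appropriate whenever 1000 mg ≤ 15 mg/kg × AdjBW, i.e. AdjBW
  strictly above 66 kg); level-based aminoglycoside/voriconazole flat
  doses and patients off the CDC 2–20-year chart are excluded.
* **SPC monitoring.** Monthly p-charts with pooled centerlines and 3σ
  binomial limits `p̄ ± 3·√(p̄(1−p̄)/nᵢ)`, the 8-consecutive-point run
  rule, centerline re-phasing at confirmed shifts, Pareto decompositions,
  and unit-level funnel charts.
* **Synthetic cohorts.** A generator producing growth references,
  patients and order streams with planted ground truth, so the entire
  pipeline is testable end to end without any external data.

## Worked example

```python
from obesitydosing import (
    MedicationOrder, OrderDoseUnit, PatientAnthropometrics, Sex,
    body_weights, classify_obesity, default_formulary, evaluate_order,
    make_lms_fixture,
)

lms = make_lms_fixture()          # synthetic growth reference, ages 2-20 y
patient = PatientAnthropometrics(
    patient_id="demo", age_months=132, sex=Sex.FEMALE,
    height_cm=149.0, weight_kg=58.0,
)
assessment = classify_obesity(patient, lms)
weights = body_weights(patient)
print(f"BMI {assessment.bmi:.1f} kg/m2, percentile {assessment.bmi_percentile:.1f}, "
      f"obese={assessment.obese}")
print(f"ideal {weights.ideal_kg:.1f} kg ({weights.ibw_method.value}), "
      f"adjusted {weights.adjusted_kg:.1f} kg")

order = MedicationOrder(
    order_id="rx1", patient_id="demo", drug="acetaminophen",
    dose_amount=650.0, dose_unit=OrderDoseUnit.MG,
)
verdict = evaluate_order(order, patient, assessment, weights, default_formulary())
print(f"{order.drug} {order.dose_amount:.0f} mg -> {verdict.status.value} "
      f"({verdict.reason.value}, {verdict.computed_per_kg:.1f} mg/kg)")
```

prints

```
BMI 26.1 kg/m2, percentile 99.6, obese=True
ideal 38.5 kg (traub), adjusted 46.3 kg
acetaminophen 650 mg -> appropriate (flat_dose_in_range, 14.0 mg/kg)
```

The 11-year-old's BMI of 26.1 kg/m² sits at the 99.6th percentile-for-age
on this reference, so she meets obesity criteria; her Traub ideal weight
is 38.5 kg and adjusted weight 46.3 kg. The 650 mg flat acetaminophen dose
back-calculates to 14.0 mg/kg of *adjusted* weight — inside the 10–15
mg/kg guideline range — so the order is judged appropriate.

## Command line

```bash
obesity-dosing simulate --n-patients 400 --months 24 --seed 7 \
    --out-patients P.csv --out-orders O.csv --out-lms L.csv
obesity-dosing evaluate-orders --orders O.csv --patients P.csv --lms L.csv --out E.csv
obesity-dosing pchart --in subgroups.csv --phase-break 2022-01 --out chart.csv
obesity-dosing funnel --in units.csv --out funnel.csv
obesity-dosing run --config run.yaml     # full pipeline, writes a summary report
```

Production users point `--lms` at the published CDC growth-reference CSV
(columns `Sex`, `Agemos`, `L`, `M`, `S`); the synthetic fixture exists so
nothing in the test suite needs a download.

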