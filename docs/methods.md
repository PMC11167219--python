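# Methods

## Problem setting

Hospitals dosing weight-based medications need two computations that are
awkward to standardise: *who has obesity* (defined by BMI-percentile-for-age
in children but absolute BMI in adults) and *which weight to dose on*
(actual, ideal, or adjusted, per drug). This package reimplements that
computation as a library, together with the retrospective audit ("was the
recommended dosing weight used?") and the statistical process control
layer a QI team uses to monitor the audit proportion over time.

## Obesity classification

BMI percentiles use the LMS (lambda-mu-sigma) parameterisation of a
growth reference: at each sex and age, the reference supplies a Box-Cox
power `L`, median `M` (kg/m²) and coefficient of variation `S`, and a
measured BMI `x` maps to

    z = ((x/M)^L - 1) / (L*S)     (L != 0)
    z = ln(x/M) / S               (L = 0)

with percentile `100*Phi(z)`. The two forms agree in the `L -> 0` limit;
the implementation switches to the log form only at `L == 0` exactly,
which keeps the function continuous to well below 1e-6 for physiologic
inputs. L, M and S are interpolated linearly in age between adjacent
reference points (the convention used with the published CDC tables); no
extrapolation is performed — ages outside the covered interval raise an
error naming the interval.

Classification is age-split with half-open, lower-inclusive intervals on
age in integer months:

* 24 ≤ age < 240 months: obese iff percentile **> 95** (strict);
* age ≥ 240 months: obese iff BMI **> 30** kg/m² (strict);
* age < 24 months: out of scope, an error.

Strictness follows the initiative's stated criteria verbatim; because
growth-chart conventions elsewhere use ≥, both comparisons can be
switched to inclusive with `inclusive=True`. Comparisons are always made
on the unrounded double-precision value.

## Dosing weights

Ideal body weight below 152.4 cm (60 in) uses the Traub exponential
formula `IBW = 2.396 * exp(0.01863 * height_cm)`. At or above 152.4 cm
(the boundary inclusive — "less than 60 inches" delimits the Traub
branch) the sex-specific Devine adult formula applies: 50 kg (male) or
45.5 kg (female) plus 2.3 kg per inch over 60. Devine is the dominant
adult-practice convention and is the package default; any callable
`(sex, height_cm) -> kg` can be substituted. Adjusted body weight is
`IBW + c*(actual - IBW)` with cofactor `c = 0.4` by default (range
checked to [0, 1]); it is exactly linear in the cofactor and bounded by
[ideal, actual] whenever actual ≥ ideal.

## Formulary

A dosing rule records the recommended weight kind (ideal/adjusted/actual),
the maximum single dose (nullable), and a per-kg guideline range. The
packaged default covers the initiative's seven high-risk IV drugs.
The max doses and weight-kind recommendations are institutional; the
per-kg ranges are *package defaults* assembled from common pediatric
references (e.g. acetaminophen 10–15 mg/kg/dose) because the judging
institution's exact reference ranges are proprietary — every verdict
records the computed mg/kg so institutions can audit against their own
ranges, and the JSON formulary document makes all values overridable.
`level_monitored` is set for the three aminoglycosides **and**
voriconazole because the level-based exclusion rule (below) covers all
four. Drug names are lowercased and trimmed; there is no fuzzy matching —
an unknown drug is a hard "not governed" miss.

## Order evaluation

The decision cascade, applied in order:

1. **Growth-chart exclusion** — patients not plotted on the CDC
   2–20-year chart are excluded; children under 24 months fall under the
   same code since they cannot be plotted on that chart.
2. **Level-based exclusion** — flat (mg) doses of level-monitored drugs
   chosen from previous serum levels are excluded (titration to levels is
   valid practice that says nothing about weight-selection behaviour).
3. **Non-obese** — appropriate iff the order used actual weight or no
   dosing weight at all.
4. **Obese, weight-based dose** (mg/kg or mcg/kg/hr) — appropriate iff
   the dosing-weight *kind* matches the drug's recommendation. The kind,
   not the numeric value, is judged; the value is retained for audit.
5. **Obese, flat mg dose** — the dose is divided by the recommended
   alternative weight; appropriate iff the implied mg/kg lies within the
   guideline range, **or** the dose equals the drug's max dose and the
   implied mg/kg does not exceed the upper bound. The carve-out is stated
   in terms of the max dose, not a hard-coded weight, which reproduces
   the familiar consequence for acetaminophen: 1000 mg is appropriate
   exactly when AdjBW > 1000/15 ≈ 66.7 kg (strictly above 66 kg on an
   integer scan). When both the range test and the carve-out hold, the
   carve-out is the reported reason.

The cascade is exhaustive and exclusive — every order receives exactly
one of eight reason codes, and excluded orders never enter any
denominator. Batch evaluation is deterministic and order-independent,
drops non-formulary drugs with a logged count, reports unresolvable
patient ids as rejects, and satisfies the conservation identity
`orders in = evaluated + rejected + not governed`.

Rate-based dexmedetomidine orders are judged by weight kind only: no
rate-range check is applied because no rate bounds are part of the
recommendation. Safety-event rates are computed as events/reports rounded
half-up to six decimals.

## SPC

The p-chart centerline is the pooled proportion `pbar = sum(x)/sum(n)`
per phase — a weighted mean, not a mean of monthly proportions, which is
what makes the binomial limit formula `pbar ± 3*sqrt(pbar*(1-pbar)/n_i)`
coherent. Limits are clipped to [0, 1]; zero-order months are rejected
rather than plotted at n = 0. Two special-cause rules are active by
default: a point beyond its 3σ limits, and eight consecutive points
strictly on one side of the centerline. Points exactly on the centerline
break a run (the conservative choice); a run longer than eight yields one
signal, at its eighth point. Further run rules are deliberately not
enabled by default: the monitored chart evidences only these two.
Confirmed shifts are folded in by re-phasing — centerlines recomputed
independently before and after the shift index.

Measured behaviour of the run rule on in-control data (Monte-Carlo,
24-point series of Binomial(100, 0.5) subgroups, seeded): a false alarm in
roughly 4% of series. This rate is a property of run-length statistics
(the chance of an 8-run among 24 near-fair side-of-centerline indicators)
and is essentially independent of subgroup size; the regression test
asserts it stays below 8%.

The funnel chart compares unit-level proportions against the pooled
overall proportion with limits `p ± sigma*sqrt(p*(1-p)/n_i)`; sigma
defaults to 3 (configurable — published funnel plots vary between 2σ and
3σ). A unit exactly on a limit is in control; flagging requires being
strictly outside. No overdispersion correction is applied.

## Synthetic data

The generator is the package's study-conditions harness, not a realism
engine. Its guarantees:

* **Growth fixture** — L/M/S given as constants or smooth curves of age;
  the 95th-percentile BMI is therefore available in closed form at every
  age, giving an exact oracle for the classifier. The default curves are
  shaped like a school-age BMI reference (median rising from ~15.8 at
  2 years, S = 0.11, L = −1, females shifted −0.3 kg/m²).
* **Patients** — the obesity label is planted: a Bernoulli(prevalence)
  draw decides the side of the 95th percentile, the BMI z-score is
  sampled strictly on that side with a small safety margin, and weight is
  recovered through the same curves. Realized prevalence is a plain
  binomial fluctuation around the request. Heights follow a crude linear
  stature-for-age line spanning both the Traub and adult IBW branches.
  Default cohort: 400 patients, ages 24–216 months, even sex split,
  prevalence 0.5 (the pipeline needs both obese and non-obese patients
  well represented; prevalence conditions nothing downstream because
  appropriateness is planted per order).
* **Orders** — each order's appropriateness label is Bernoulli with a
  phase-specific probability (defaults 0.37 pre / 0.787 post, the
  initiative's observed regimes), and the order is *constructed* to
  satisfy or violate the evaluator's own cascade — weight-kind match or
  mismatch for weight-based doses, in-range or out-of-range back-computed
  mg/kg for flat doses. Every constructed order is re-checked through
  `evaluate_order`, so generation/evaluation consistency is exact by
  construction, which is what makes the SPC parameter-recovery test a
  calibrated oracle. Exclusions are injected (default 2%) as level-based
  flat doses of level-monitored drugs. The default drug mix follows the
  post-implementation order shares (acetaminophen 58.1%, dexmedetomidine
  28.8%, amikacin 5.7%, gentamicin 3.9%, acyclovir 2.5%, voriconazole
  1.0%).

What the generator does **not** emulate: correlated repeat orders within
an encounter, realistic order timing or length-of-stay, secular drift in
case mix, or measurement error in heights — so green tests demonstrate
algorithmic correctness and statistical calibration, not performance on
messy real EHR extracts.

## Problem sizes and numerical choices

The end-to-end recovery check uses 24 months × 100 orders/month over a
200-patient cohort — large enough that the 3-standard-error recovery
bands are ±0.042 (pre) and ±0.036 (post) while the whole suite runs in
seconds. The classifier-vs-closed-form check uses a 10,000-point
(sex × age × BMI) grid. Flat-dose boundary checks scan dense dose grids
plus the exact max-dose point, since the carve-out holds only at exact
equality with the max dose.

Ties and degenerate inputs: exact reference ages return the stored LMS
record verbatim; Pareto ties are broken lexicographically; a subgroup
proportion exactly on a control limit is in control; `cap_dose` is the
identity for rate-based drugs and rules without a max. Phase assignment
from month labels is half-open — a month equal to an intervention date
starts the new phase. All pipeline stages are seed-free; randomness lives
only in the generator, and generator outputs are bit-for-bit reproducible
under a fixed seed.

## Known limitations

* Per-kg guideline ranges are package defaults, not the judging
  institution's reference values; verdicts for flat doses shift if an
  institution's ranges differ.
* Dose-interval appropriateness, cumulative daily dose, renal/hepatic
  adjustment and therapeutic drug monitoring are out of scope.
* Per-kg orders written against a numerically correct but mislabeled
  weight are judged by the label (kind), with the numeric value kept for
  audit only.
* WHO and specialty growth charts are excluded upstream, not
  re-classified; body-surface-area dosing is unsupported.
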