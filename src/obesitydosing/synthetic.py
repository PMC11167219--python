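"""Synthetic growth references, patients and medication orders.

Everything the pipeline consumes can be generated here with known ground
truth, so every stage is testable without downloading a real growth
reference:

* :func:`make_lms_fixture` builds an LMS growth table from smooth L/M/S
  curves; because the curves are known, the 95th-percentile BMI cutoff at
  any age is available in closed form (``lms_inverse`` at z = Φ⁻¹(0.95)),
  giving an exact oracle for the obesity classifier.
* :func:`simulate_patients` draws a cohort with a *planted* obesity label:
  each patient's BMI z-score is sampled on the intended side of the 95th
  percentile and converted back to weight through the same LMS curves, so
  the classifier's verdict matches the label by construction and the
  realized prevalence is an ordinary binomial draw around the requested
  prevalence.
* :func:`simulate_orders` plants appropriateness labels per order at a
  phase-specific probability and constructs each order to satisfy (or
  violate) the evaluator's own decision cascade, with level-based
  exclusions injected at a configurable rate. The default drug mix follows
  the post-implementation share of orders in the source initiative
  (acetaminophen-dominated).

All outputs are reproducible bit-for-bit under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .anthropometry import (
    GrowthChart,
    LMSRecord,
    LMSTable,
    PatientAnthropometrics,
    Sex,
    WeightKind,
    body_weights,
    classify_obesity,
    interpolate_lms,
    lms_inverse,
)
from .errors import GenerationError
from .formulary import Formulary, RuleDoseUnit
from .order_eval import (
    MedicationOrder,
    OrderDoseUnit,
    Phase,
    Status,
    evaluate_order,
)

#: z-score of the 95th percentile of the standard normal.
Z95 = float(norm.ppf(0.95))

Curve = float | Callable[[float], float]


def _as_curve(v: Curve) -> Callable[[float], float]:
    return v if callable(v) else (lambda _age, _v=v: _v)


# ---------------------------------------------------------------------------
# LMS fixture
# ---------------------------------------------------------------------------

# Default smooth curves loosely shaped like a school-age BMI reference:
# median BMI rising slowly with age, moderate right skew.
def _default_M(age: float) -> float:
    return 15.8 + 0.028 * (age - 24.0)


DEFAULT_L: Curve = -1.0
DEFAULT_M: Curve = _default_M
DEFAULT_S: Curve = 0.11
#: Additive shift applied to M per sex (females run slightly lighter here).
DEFAULT_SEX_SHIFT = {Sex.MALE: 0.0, Sex.FEMALE: -0.3}


def make_lms_fixture(
    age_lo: float = 24.0,
    age_hi: float = 240.0,
    *,
    step: float = 6.0,
    L: Curve = DEFAULT_L,
    M: Curve = DEFAULT_M,
    S: Curve = DEFAULT_S,
    sex_shift: dict[Sex, float] | None = None,
    source_label: str = "synthetic LMS fixture",
) -> LMSTable:
    """Build a growth-reference table from smooth L/M/S curves.

    Each of ``L``, ``M``, ``S`` may be a constant or a callable of age in
    months; ``sex_shift`` adds a per-sex offset to M. The resulting table
    covers ``[age_lo, age_hi]`` at ``step``-month spacing (endpoints always
    included).
    """
    if age_hi <= age_lo or step <= 0:
        raise GenerationError("age range must be non-empty with positive step")
    fL, fM, fS = _as_curve(L), _as_curve(M), _as_curve(S)
    shift = DEFAULT_SEX_SHIFT if sex_shift is None else sex_shift
    ages = list(np.arange(age_lo, age_hi, step)) + [age_hi]
    records = []
    for sex in Sex:
        for age in ages:
            age = float(age)
            m = fM(age) + shift.get(sex, 0.0)
            s = fS(age)
            if m <= 0 or s <= 0:
                raise GenerationError(
                    f"LMS curves non-positive at age {age} ({sex.value}): M={m}, S={s}"
                )
            records.append(LMSRecord(sex=sex, age_months=float(age), L=fL(age), M=m, S=s))
    return LMSTable(records, source_label=source_label)


def p95_bmi(table: LMSTable, sex: Sex, age_months: float) -> float:
    """Closed-form 95th-percentile BMI cutoff at one (sex, age) point."""
    return lms_inverse(Z95, interpolate_lms(table, sex, age_months))


# ---------------------------------------------------------------------------
# Patient simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror a pediatric inpatient population: ages 2-18 years,
    roughly even sex split, and an obesity prevalence of 0.5 — the cohort
    is *conditioned* on the dosing workflow (only patients with obesity
    trigger alternative-weight rules, but non-obese patients must also be
    represented to exercise the actual-weight branch).
    """

    n_patients: int = 400
    age_range_months: tuple[int, int] = (24, 216)
    sex_ratio: float = 0.5  # fraction male
    obesity_prevalence: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.obesity_prevalence <= 1.0):
            raise GenerationError("obesity prevalence must lie in [0, 1]")
        if not (0.0 <= self.sex_ratio <= 1.0):
            raise GenerationError("sex ratio must lie in [0, 1]")
        if self.n_patients <= 0:
            raise GenerationError("n_patients must be positive")


def _height_for_age(age_months: float, rng: np.random.Generator) -> float:
    # crude stature-for-age line; spans both the Traub (<152.4 cm) and the
    # adult-formula branches across the default age range
    h = 80.0 + 0.48 * age_months + rng.normal(0.0, 4.0)
    return float(np.clip(h, 82.0, 185.0))


def simulate_patients(
    spec: CohortSpec,
    lms: LMSTable,
    *,
    inclusive: bool = False,
) -> list[PatientAnthropometrics]:
    """Draw a cohort with planted obesity labels.

    Each patient's obesity label is Bernoulli(prevalence); the BMI z-score
    is then drawn strictly on the matching side of the 95th percentile
    (with a small safety margin) and inverted through the growth curves to
    a weight. The classifier therefore agrees with the label exactly, and
    the realized prevalence fluctuates binomially around the request.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.age_range_months
    for sex in Sex:
        cov = lms.age_range(sex)
        if lo < cov[0] or hi > cov[1]:
            raise GenerationError(
                f"age range [{lo}, {hi}] outside LMS coverage {cov} for {sex.value}"
            )
    patients: list[PatientAnthropometrics] = []
    for i in range(spec.n_patients):
        sex = Sex.MALE if rng.random() < spec.sex_ratio else Sex.FEMALE
        age = int(rng.integers(lo, hi + 1))
        height = _height_for_age(age, rng)
        obese = bool(rng.random() < spec.obesity_prevalence)
        if obese:
            z = Z95 + 0.08 + abs(rng.normal(0.0, 0.6))
        else:
            z = Z95 - 0.08 - abs(rng.normal(0.0, 0.9))
        rec = interpolate_lms(lms, sex, float(age))
        if rec.L != 0.0 and 1.0 + rec.L * rec.S * z <= 0.0:
            raise GenerationError(
                f"z={z:.2f} not invertible under L={rec.L}, S={rec.S}"
            )
        bmi = lms_inverse(z, rec)
        weight = bmi * (height / 100.0) ** 2
        patient = PatientAnthropometrics(
            patient_id=f"P{i:05d}",
            age_months=age,
            sex=sex,
            height_cm=round(height, 1),
            weight_kg=round(weight, 2),
            growth_chart_id=GrowthChart.CDC_2_20,
        )
        # rounding can nudge a near-threshold draw across the cutoff;
        # re-check against the classifier and redraw deterministically
        got = classify_obesity(patient, lms, inclusive=inclusive).obese
        if got != obese:
            continue_weight = bmi * (height / 100.0) ** 2
            patient = PatientAnthropometrics(
                patient_id=patient.patient_id,
                age_months=age,
                sex=sex,
                height_cm=round(height, 1),
                weight_kg=continue_weight,
                growth_chart_id=GrowthChart.CDC_2_20,
            )
            got = classify_obesity(patient, lms, inclusive=inclusive).obese
            if got != obese:  # pragma: no cover - margins make this unreachable
                raise GenerationError("planted obesity label not realizable")
        patients.append(patient)
    return patients


# ---------------------------------------------------------------------------
# Order simulation
# ---------------------------------------------------------------------------

#: Drug mix following the post-implementation share of assessed orders.
DEFAULT_DRUG_MIX = {
    "acetaminophen": 0.581,
    "dexmedetomidine": 0.288,
    "amikacin": 0.057,
    "gentamicin": 0.039,
    "acyclovir": 0.025,
    "voriconazole": 0.010,
}

_DEPARTMENTS = ("ED", "PICU", "CTICU", "NICU", "Med-Surg", "Heme-Onc")


@dataclass(frozen=True)
class OrderSimSpec:
    """Parameters of a synthetic order stream.

    ``appropriateness_prob_by_phase`` gives the probability that a
    non-excluded order is constructed to be appropriate, per phase; months
    at or after ``intervention_month`` belong to the post phase.
    """

    months: tuple[str, ...]
    orders_per_month: int = 100
    drug_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_MIX)
    )
    appropriateness_prob_by_phase: dict[Phase, float] = field(
        default_factory=lambda: {Phase.PRE: 0.37, Phase.POST: 0.787}
    )
    exclusion_prob: float = 0.02
    intervention_month: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.drug_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise GenerationError(f"drug mix probabilities sum to {total}, not 1")
        if not (0.0 <= self.exclusion_prob < 1.0):
            raise GenerationError("exclusion probability must lie in [0, 1)")

    def phase_of(self, month: str) -> Phase:
        if self.intervention_month is not None and month >= self.intervention_month:
            return Phase.POST
        return Phase.PRE


def _mismatched_kind(recommended: WeightKind) -> WeightKind:
    for kind in (WeightKind.ACTUAL, WeightKind.IDEAL, WeightKind.ADJUSTED):
        if kind is not recommended:
            return kind
    raise AssertionError("unreachable")


def simulate_orders(
    patients: Sequence[PatientAnthropometrics],
    spec: OrderSimSpec,
    formulary: Formulary,
    lms: LMSTable,
    *,
    cofactor: float = 0.4,
    inclusive: bool = False,
) -> list[MedicationOrder]:
    """Generate an order stream with planted appropriateness labels.

    Every constructed order is re-checked with :func:`evaluate_order`, so
    generation and evaluation agree by construction. Injected exclusions
    are level-based flat doses of level-monitored drugs.
    """
    for drug in spec.drug_mix:
        if drug not in formulary:
            raise GenerationError(f"drug {drug!r} in drug_mix not in formulary")
    level_drugs = [r.drug for r in formulary if r.level_monitored]
    eligible = [
        p
        for p in patients
        if p.growth_chart_id is GrowthChart.CDC_2_20 and p.age_months >= 24
    ]
    if not eligible:
        raise GenerationError("no classifiable patients to order against")

    rng = np.random.default_rng(spec.seed)
    drugs = list(spec.drug_mix)
    probs = np.array([spec.drug_mix[d] for d in drugs])
    probs = probs / probs.sum()

    cache: dict[str, tuple] = {}

    def patient_state(p: PatientAnthropometrics):
        if p.patient_id not in cache:
            cache[p.patient_id] = (
                classify_obesity(p, lms, inclusive=inclusive),
                body_weights(p, cofactor=cofactor),
            )
        return cache[p.patient_id]

    orders: list[MedicationOrder] = []
    oid = 0
    for month in spec.months:
        phase = spec.phase_of(month)
        p_appropriate = spec.appropriateness_prob_by_phase[phase]
        for _ in range(spec.orders_per_month):
            oid += 1
            patient = eligible[int(rng.integers(len(eligible)))]
            department = _DEPARTMENTS[int(rng.integers(len(_DEPARTMENTS)))]
            common = dict(
                order_id=f"O{oid:06d}",
                patient_id=patient.patient_id,
                department=department,
                month=month,
                phase=phase,
            )
            assessment, weights = patient_state(patient)

            if spec.exclusion_prob > 0 and rng.random() < spec.exclusion_prob and level_drugs:
                drug = level_drugs[int(rng.integers(len(level_drugs)))]
                rule = formulary.lookup(drug)
                order = MedicationOrder(
                    drug=drug,
                    dose_amount=round(
                        rule.per_kg_low * weights.actual_kg, 1
                    ) or 1.0,
                    dose_unit=OrderDoseUnit.MG,
                    level_based=True,
                    **common,
                )
                expected = Status.EXCLUDED
            else:
                drug = drugs[int(rng.choice(len(drugs), p=probs))]
                rule = formulary.lookup(drug)
                appropriate = bool(rng.random() < p_appropriate)
                order = _construct_order(
                    common, rule, assessment, weights, appropriate, rng
                )
                expected = (
                    Status.APPROPRIATE if appropriate else Status.INAPPROPRIATE
                )

            got = evaluate_order(order, patient, assessment, weights, formulary)
            if got.status is not expected:  # pragma: no cover - by construction
                raise GenerationError(
                    f"constructed order {order.order_id} evaluated {got.status}, "
                    f"expected {expected}"
                )
            orders.append(order)
    return orders


def _construct_order(common, rule, assessment, weights, appropriate, rng):
    """Build one order that the evaluator will judge as requested."""
    recommended = rule.recommended_weight_kind
    obese = assessment.obese

    if rule.dose_unit is RuleDoseUnit.MCG_PER_KG_PER_HR:
        # rate-based infusion: judged purely by dosing-weight kind
        rate = float(rng.uniform(rule.per_kg_low, rule.per_kg_high))
        if obese:
            kind = recommended if appropriate else _mismatched_kind(recommended)
        else:
            kind = WeightKind.ACTUAL if appropriate else WeightKind.IDEAL
        return MedicationOrder(
            drug=rule.drug,
            dose_amount=round(rate, 2),
            dose_unit=OrderDoseUnit.MCG_PER_KG_PER_HR,
            weight_kind_used=kind,
            weight_used_kg=round(weights.weight_of_kind(kind), 2),
            **common,
        )

    if not obese and not appropriate:
        # a flat dose on a non-obese patient is always appropriate, so an
        # inappropriate order must be weight-based with the wrong kind
        per_kg = float(rng.uniform(rule.per_kg_low, rule.per_kg_high))
        return MedicationOrder(
            drug=rule.drug,
            dose_amount=round(per_kg, 2),
            dose_unit=OrderDoseUnit.MG_PER_KG,
            weight_kind_used=WeightKind.IDEAL,
            weight_used_kg=round(weights.ideal_kg, 2),
            **common,
        )

    weight_based = bool(rng.random() < 0.5)
    if weight_based:
        per_kg = float(rng.uniform(rule.per_kg_low, rule.per_kg_high))
        if obese:
            kind = recommended if appropriate else _mismatched_kind(recommended)
        else:
            kind = WeightKind.ACTUAL
        return MedicationOrder(
            drug=rule.drug,
            dose_amount=round(per_kg, 2),
            dose_unit=OrderDoseUnit.MG_PER_KG,
            weight_kind_used=kind,
            weight_used_kg=round(weights.weight_of_kind(kind), 2),
            **common,
        )

    # flat mg dose
    alt_w = weights.weight_of_kind(recommended if obese else WeightKind.ACTUAL)
    if appropriate:
        margin = 0.02 * (rule.per_kg_high - rule.per_kg_low)
        per_kg = float(
            rng.uniform(rule.per_kg_low + margin, rule.per_kg_high - margin)
        )
        dose = per_kg * alt_w
        if rule.max_dose_mg is not None and dose == rule.max_dose_mg:
            dose *= 0.999  # avoid coinciding with the max-dose carve-out point
    else:
        per_kg = 2.0 * rule.per_kg_high + float(rng.uniform(0.5, 2.0))
        dose = per_kg * alt_w
        if rule.max_dose_mg is not None and dose == rule.max_dose_mg:
            dose *= 1.01
    return MedicationOrder(
        drug=rule.drug,
        dose_amount=dose,
        dose_unit=OrderDoseUnit.MG,
        **common,
    )
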