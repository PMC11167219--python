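"""Retrospective appropriateness evaluation of medication orders.

Each order for a formulary-governed drug is judged against the dosing rules
for patients with obesity:

* orders are *excluded* when the patient is not plotted on the CDC
  2-20-year chart (including children under 2, who cannot be plotted on
  it), or when a flat (mg) dose of a level-monitored drug was chosen from
  previous serum drug levels;
* for non-obese patients, any order written against actual weight (or with
  no dosing weight at all) is appropriate;
* for obese patients, per-kg and rate-based orders are appropriate exactly
  when the dosing weight *kind* matches the drug's recommendation;
* flat mg doses for obese patients are back-calculated against the
  recommended alternative weight: the dose is appropriate when the implied
  mg/kg falls in the guideline range, or when the order is exactly the
  drug's maximum dose and the implied mg/kg does not exceed the guideline
  upper bound (the max-dose carve-out — e.g. 1000 mg acetaminophen is
  appropriate for any adjusted weight above 1000/15 ≈ 66.7 kg).

The cascade is exhaustive and exclusive: every order maps to exactly one
reason code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

from .anthropometry import (
    GrowthChart,
    LMSTable,
    MIN_CLASSIFIABLE_AGE_MONTHS,
    ObesityAssessment,
    BodyWeights,
    PatientAnthropometrics,
    WeightKind,
    body_weights,
    classify_obesity,
)
from .errors import DataIntegrityError, OutOfRangeError, UndefinedRateError
from .formulary import Formulary, normalize_drug_name
from .spc import SubgroupProportion

log = logging.getLogger(__name__)


class OrderDoseUnit(str, Enum):
    MG = "mg"                             # flat dose
    MG_PER_KG = "mg_per_kg"               # weight-based dose
    MCG_PER_KG_PER_HR = "mcg_per_kg_per_hr"  # weight-based infusion rate


class Phase(str, Enum):
    PRE = "pre"
    POST = "post"


class Status(str, Enum):
    APPROPRIATE = "appropriate"
    INAPPROPRIATE = "inappropriate"
    EXCLUDED = "excluded"


class Reason(str, Enum):
    WEIGHT_KIND_MATCH = "weight_kind_match"
    WEIGHT_KIND_MISMATCH = "weight_kind_mismatch"
    FLAT_DOSE_IN_RANGE = "flat_dose_in_range"
    FLAT_DOSE_OUT_OF_RANGE = "flat_dose_out_of_range"
    MAX_DOSE_RULE = "max_dose_rule"
    EXCLUDED_LEVEL_BASED = "excluded_level_based"
    EXCLUDED_GROWTH_CHART = "excluded_growth_chart"
    NOT_OBESE_ACTUAL_OK = "not_obese_actual_ok"


_EXCLUSION_REASONS = {Reason.EXCLUDED_LEVEL_BASED, Reason.EXCLUDED_GROWTH_CHART}


@dataclass(frozen=True)
class MedicationOrder:
    """One inpatient medication order as extracted from the EHR."""

    order_id: str
    patient_id: str
    drug: str
    dose_amount: float
    dose_unit: OrderDoseUnit
    weight_kind_used: WeightKind | None = None
    weight_used_kg: float | None = None
    department: str = "unknown"
    month: str = "0000-00"
    level_based: bool = False
    phase: Phase = Phase.PRE

    def __post_init__(self) -> None:
        if self.dose_amount <= 0:
            raise DataIntegrityError(
                f"order {self.order_id}: non-positive dose {self.dose_amount}"
            )
        if self.dose_unit is not OrderDoseUnit.MG and self.weight_kind_used is None:
            raise DataIntegrityError(
                f"order {self.order_id}: per-kg dose unit requires a dosing weight kind"
            )


@dataclass(frozen=True)
class OrderEvaluation:
    """Appropriateness verdict for one order, with grouping metadata."""

    order_id: str
    status: Status
    reason: Reason
    computed_per_kg: float | None = None
    # grouping metadata carried along for aggregation
    drug: str = ""
    department: str = ""
    month: str = ""
    phase: Phase = Phase.PRE
    age_band: str = ""

    def __post_init__(self) -> None:
        assert (self.status is Status.EXCLUDED) == (self.reason in _EXCLUSION_REASONS)


AGE_BANDS = ((24, "2-5y"), (72, "6-11y"), (144, "12-19y"), (240, "20y+"))


def age_band(age_months: int) -> str:
    """Coarse age grouping used for subgroup analyses."""
    label = "<2y"
    for lower, name in AGE_BANDS:
        if age_months >= lower:
            label = name
    return label


# ---------------------------------------------------------------------------
# Single-order evaluation
# ---------------------------------------------------------------------------


def evaluate_order(
    order: MedicationOrder,
    patient: PatientAnthropometrics,
    assessment: ObesityAssessment | None,
    weights: BodyWeights | None,
    formulary: Formulary,
) -> OrderEvaluation:
    """Judge one order via the decision cascade described in the module docs.

    ``assessment``/``weights`` may be None only when the patient is not
    classifiable (non-CDC growth chart or under 2 years old), in which case
    the order is excluded before they are consulted.
    """
    rule = formulary.lookup(order.drug)

    def verdict(status: Status, reason: Reason, per_kg: float | None = None):
        return OrderEvaluation(
            order_id=order.order_id,
            status=status,
            reason=reason,
            computed_per_kg=per_kg,
            drug=normalize_drug_name(order.drug),
            department=order.department,
            month=order.month,
            phase=order.phase,
            age_band=age_band(patient.age_months),
        )

    # (a) not plottable on the CDC 2-20y chart -> excluded
    if (
        patient.growth_chart_id is not GrowthChart.CDC_2_20
        or patient.age_months < MIN_CLASSIFIABLE_AGE_MONTHS
    ):
        return verdict(Status.EXCLUDED, Reason.EXCLUDED_GROWTH_CHART)

    # (b) flat dose of a level-monitored drug chosen from previous levels
    if (
        order.level_based
        and order.dose_unit is OrderDoseUnit.MG
        and rule.level_monitored
    ):
        return verdict(Status.EXCLUDED, Reason.EXCLUDED_LEVEL_BASED)

    if assessment is None or weights is None:
        raise DataIntegrityError(
            f"order {order.order_id}: classifiable patient requires an "
            "obesity assessment and computed weights"
        )

    # (c) non-obese patients need no alternative weight
    if not assessment.obese:
        if order.weight_kind_used in (WeightKind.ACTUAL, None):
            return verdict(Status.APPROPRIATE, Reason.NOT_OBESE_ACTUAL_OK)
        return verdict(Status.INAPPROPRIATE, Reason.WEIGHT_KIND_MISMATCH)

    # (d) obese, weight-based dose: judge by dosing-weight kind
    if order.dose_unit in (OrderDoseUnit.MG_PER_KG, OrderDoseUnit.MCG_PER_KG_PER_HR):
        if order.weight_kind_used is None:
            raise DataIntegrityError(
                f"order {order.order_id}: per-kg order without a dosing weight kind"
            )
        if order.weight_kind_used is rule.recommended_weight_kind:
            return verdict(Status.APPROPRIATE, Reason.WEIGHT_KIND_MATCH)
        return verdict(Status.INAPPROPRIATE, Reason.WEIGHT_KIND_MISMATCH)

    # (e) obese, flat mg dose: back-calculate against the recommended weight
    alt_weight = weights.weight_of_kind(rule.recommended_weight_kind)
    per_kg = order.dose_amount / alt_weight
    if (
        rule.max_dose_mg is not None
        and order.dose_amount == rule.max_dose_mg
        and per_kg <= rule.per_kg_high
    ):
        return verdict(Status.APPROPRIATE, Reason.MAX_DOSE_RULE, per_kg)
    if rule.per_kg_low <= per_kg <= rule.per_kg_high:
        return verdict(Status.APPROPRIATE, Reason.FLAT_DOSE_IN_RANGE, per_kg)
    return verdict(Status.INAPPROPRIATE, Reason.FLAT_DOSE_OUT_OF_RANGE, per_kg)


# ---------------------------------------------------------------------------
# Batch evaluation
# ---------------------------------------------------------------------------


@dataclass
class BatchResult:
    """Evaluations plus the bookkeeping needed for the conservation check:

    ``len(orders in) == len(evaluations) + len(rejects) + len(not_governed)``.
    """

    evaluations: list[OrderEvaluation]
    rejects: list[tuple[str, str]]        # (order_id, why)
    not_governed: list[str]               # order_ids for non-formulary drugs


def evaluate_batch(
    orders: Iterable[MedicationOrder],
    patients: Iterable[PatientAnthropometrics],
    formulary: Formulary,
    lms: LMSTable,
    *,
    cofactor: float = 0.4,
    inclusive: bool = False,
) -> BatchResult:
    """Evaluate a batch of orders; deterministic and order-independent.

    Orders for drugs outside the formulary are dropped with a logged count;
    orders whose patient cannot be resolved (or whose age falls outside the
    growth-reference coverage) are reported in ``rejects``, never silently
    dropped.
    """
    by_id = {p.patient_id: p for p in patients}
    cache: dict[str, tuple[ObesityAssessment | None, BodyWeights | None]] = {}
    evaluations: list[OrderEvaluation] = []
    rejects: list[tuple[str, str]] = []
    not_governed: list[str] = []

    for order in orders:
        if order.drug not in formulary:
            not_governed.append(order.order_id)
            continue
        patient = by_id.get(order.patient_id)
        if patient is None:
            rejects.append((order.order_id, f"unknown patient {order.patient_id!r}"))
            continue
        if patient.patient_id not in cache:
            if (
                patient.growth_chart_id is not GrowthChart.CDC_2_20
                or patient.age_months < MIN_CLASSIFIABLE_AGE_MONTHS
            ):
                cache[patient.patient_id] = (None, None)
            else:
                try:
                    assessment = classify_obesity(patient, lms, inclusive=inclusive)
                except OutOfRangeError as exc:
                    rejects.append((order.order_id, str(exc)))
                    continue
                cache[patient.patient_id] = (
                    assessment,
                    body_weights(patient, cofactor=cofactor),
                )
        assessment, weights = cache[patient.patient_id]
        evaluations.append(
            evaluate_order(order, patient, assessment, weights, formulary)
        )

    if not_governed:
        log.info("dropped %d orders for drugs outside the formulary", len(not_governed))
    return BatchResult(evaluations, rejects, not_governed)


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


class GroupKey(str, Enum):
    MONTH = "month"
    DEPARTMENT = "department"
    DRUG = "drug"
    AGE_BAND = "age_band"
    PHASE = "phase"


def _group_label(ev: OrderEvaluation, key: GroupKey) -> str:
    value = getattr(ev, key.value)
    return value.value if isinstance(value, Enum) else value


def aggregate_proportions(
    evaluations: Sequence[OrderEvaluation],
    key: GroupKey,
) -> list[SubgroupProportion]:
    """Appropriateness proportions per group; excluded orders never enter n.

    Groups are returned sorted by label; months sort chronologically under
    the ISO ``YYYY-MM`` convention.
    """
    counts: dict[str, list[int]] = {}
    for ev in evaluations:
        if ev.status is Status.EXCLUDED:
            continue
        label = _group_label(ev, key)
        n_succ = counts.setdefault(label, [0, 0])
        n_succ[0] += 1
        if ev.status is Status.APPROPRIATE:
            n_succ[1] += 1
    if not counts:
        log.warning("aggregate_proportions: no non-excluded evaluations")
        return []
    return [
        SubgroupProportion(label=label, n=n, successes=succ)
        for label, (n, succ) in sorted(counts.items())
    ]


def pareto_decomposition(
    evaluations: Sequence[OrderEvaluation],
    key: GroupKey,
) -> list[tuple[str, int, float]]:
    """Inappropriate-order counts per category, largest first.

    Returns ``(label, count, cumulative %)`` rows sorted by descending
    count with ties broken lexicographically; the cumulative percentage
    reaches 100 at the last row.
    """
    counts: dict[str, int] = {}
    for ev in evaluations:
        if ev.status is Status.INAPPROPRIATE:
            label = _group_label(ev, key)
            counts[label] = counts.get(label, 0) + 1
    if not counts:
        return []
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    total = sum(counts.values())
    rows: list[tuple[str, int, float]] = []
    running = 0
    for label, count in ordered:
        running += count
        rows.append((label, count, 100.0 * running / total))
    return rows


def event_rate(events: int, reports: int) -> float:
    """Safety-event rate events/reports, rounded half-up to 6 decimals."""
    if reports <= 0:
        raise UndefinedRateError("event rate undefined for zero reports")
    if events < 0 or events > reports:
        raise DataIntegrityError(
            f"events {events} must lie in [0, reports={reports}]"
        )
    rate = Decimal(events) / Decimal(reports)
    return float(rate.quantize(Decimal("0.000001"), rounding=ROUND_HALF_UP))
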