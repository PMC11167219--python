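"""Anthropometric computations for obesity-aware dosing.

This module turns raw height/weight/age/sex into the quantities the dosing
rules consume:

* BMI and BMI-percentile-for-age via the CDC LMS (lambda-mu-sigma) method,
  in which a growth reference supplies a Box-Cox power ``L``, median ``M``
  and coefficient of variation ``S`` at each (sex, age) point and a
  measurement ``x`` maps to the z-score ``((x/M)**L - 1) / (L*S)``
  (``log(x/M)/S`` in the ``L == 0`` limit);
* obesity classification with an age split: children (2 to <20 years) are
  obese above the 95th BMI-percentile-for-age, adults (>=20 years) above an
  absolute BMI of 30 — both strict inequalities by default;
* ideal body weight (Traub exponential formula below 152.4 cm, sex-specific
  Devine formula at or above) and adjusted body weight
  ``IBW + cofactor * (actual - IBW)`` with a default cofactor of 0.4.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Sequence

from scipy.stats import norm

from .errors import (
    InvalidMeasurementError,
    NotEligibleError,
    OutOfRangeError,
    ConfigurationError,
)

# ---------------------------------------------------------------------------
# Constants
# ---------------------------------------------------------------------------

#: Minimum age (months) for obesity classification; the initiative covers
#: patients two years and older.
MIN_CLASSIFIABLE_AGE_MONTHS = 24
#: Age (months) at which the adult absolute-BMI criterion replaces the
#: pediatric percentile criterion (20 years; lower bound inclusive).
ADULT_AGE_MONTHS = 240
#: Pediatric obesity cutoff: BMI-percentile-for-age must exceed this.
PEDIATRIC_PERCENTILE_CUTOFF = 95.0
#: Adult obesity cutoff: absolute BMI (kg/m^2) must exceed this.
ADULT_BMI_CUTOFF = 30.0

#: Traub ideal-body-weight formula, IBW = 2.396 * exp(0.01863 * height_cm),
#: applicable to children under 60 inches (152.4 cm).
TRAUB_COEF = 2.396
TRAUB_EXP = 0.01863
TRAUB_MAX_HEIGHT_CM = 152.4

#: Devine adult formula: base kg at 60 inches plus 2.3 kg per inch over.
DEVINE_BASE_KG = {"male": 50.0, "female": 45.5}
DEVINE_SLOPE_KG_PER_INCH = 2.3
CM_PER_INCH = 2.54

DEFAULT_ADJUSTMENT_COFACTOR = 0.4


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"


class GrowthChart(str, Enum):
    """Which growth chart the patient's height/weight are plotted on."""

    CDC_2_20 = "cdc_2_20"
    OTHER = "other"


class WeightKind(str, Enum):
    """Which body weight is entered into a per-kg dose calculation."""

    IDEAL = "ideal"
    ADJUSTED = "adjusted"
    ACTUAL = "actual"


class IBWMethod(str, Enum):
    TRAUB = "traub"
    TALL_FORMULA = "tall_formula"


class ObesityCriterion(str, Enum):
    PEDIATRIC_PERCENTILE = "pediatric_percentile"
    ADULT_ABSOLUTE_BMI = "adult_absolute_bmi"
    NOT_ASSESSED = "not_assessed"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatientAnthropometrics:
    """One patient's measurements plus growth-chart provenance."""

    patient_id: str
    age_months: int
    sex: Sex
    height_cm: float
    weight_kg: float
    growth_chart_id: GrowthChart = GrowthChart.CDC_2_20

    def __post_init__(self) -> None:
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise InvalidMeasurementError(
                f"patient {self.patient_id}: height and weight must be positive "
                f"(got height={self.height_cm} cm, weight={self.weight_kg} kg)"
            )
        if self.age_months < 0:
            raise InvalidMeasurementError(
                f"patient {self.patient_id}: negative age {self.age_months}"
            )


@dataclass(frozen=True)
class LMSRecord:
    """Growth-reference parameters at one (sex, age) point.

    ``L`` is the Box-Cox power, ``M`` the median of the measurement
    (BMI, kg/m^2) and ``S`` its coefficient of variation.
    """

    sex: Sex
    age_months: float
    L: float
    M: float
    S: float

    def __post_init__(self) -> None:
        if self.M <= 0 or self.S <= 0:
            raise InvalidMeasurementError(
                f"LMS record ({self.sex.value}, {self.age_months} mo): "
                f"M and S must be positive (M={self.M}, S={self.S})"
            )


class LMSTable:
    """An ordered growth reference: LMS records by sex and age in months.

    Within each sex, ages must be strictly increasing; interpolation is
    linear in each of L, M and S and never extrapolates.
    """

    def __init__(self, records: Sequence[LMSRecord], source_label: str = "unlabeled"):
        self.source_label = source_label
        self._by_sex: dict[Sex, list[LMSRecord]] = {s: [] for s in Sex}
        for rec in records:
            self._by_sex[rec.sex].append(rec)
        for sex, recs in self._by_sex.items():
            recs.sort(key=lambda r: r.age_months)
            ages = [r.age_months for r in recs]
            if any(b <= a for a, b in zip(ages, ages[1:])):
                raise InvalidMeasurementError(
                    f"LMS table {source_label!r}: duplicate or non-increasing "
                    f"ages for sex {sex.value}"
                )

    @property
    def records(self) -> list[LMSRecord]:
        return [r for s in Sex for r in self._by_sex[s]]

    def age_range(self, sex: Sex) -> tuple[float, float]:
        recs = self._by_sex[sex]
        if not recs:
            raise OutOfRangeError(f"LMS table has no records for sex {sex.value}")
        return recs[0].age_months, recs[-1].age_months

    def records_for(self, sex: Sex) -> list[LMSRecord]:
        return list(self._by_sex[sex])


@dataclass(frozen=True)
class ObesityAssessment:
    """Result of obesity classification for one patient."""

    bmi: float
    bmi_percentile: float | None
    obese: bool
    criterion: ObesityCriterion


@dataclass(frozen=True)
class BodyWeights:
    """Actual, ideal and adjusted weight for one patient."""

    actual_kg: float
    ideal_kg: float
    adjusted_kg: float
    ibw_method: IBWMethod
    adjustment_cofactor: float = DEFAULT_ADJUSTMENT_COFACTOR

    def weight_of_kind(self, kind: WeightKind) -> float:
        return {
            WeightKind.IDEAL: self.ideal_kg,
            WeightKind.ADJUSTED: self.adjusted_kg,
            WeightKind.ACTUAL: self.actual_kg,
        }[kind]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def compute_bmi(weight_kg: float, height_cm: float) -> float:
    """Body mass index, kg/m^2."""
    if weight_kg <= 0 or height_cm <= 0:
        raise InvalidMeasurementError(
            f"BMI requires positive inputs (weight={weight_kg}, height={height_cm})"
        )
    height_m = height_cm / 100.0
    return weight_kg / (height_m * height_m)


def lms_zscore(x: float, record: LMSRecord) -> float:
    """Z-score of measurement ``x`` under the Box-Cox LMS model.

    ``z = ((x/M)**L - 1) / (L*S)`` for ``L != 0``; the ``L -> 0`` limit
    ``z = log(x/M) / S`` is used when ``L == 0``.
    """
    if x <= 0:
        raise InvalidMeasurementError(f"LMS z-score requires x > 0 (got {x})")
    ratio = x / record.M
    if record.L == 0.0:
        return math.log(ratio) / record.S
    return (ratio**record.L - 1.0) / (record.L * record.S)


def lms_inverse(z: float, record: LMSRecord) -> float:
    """Measurement at z-score ``z``: the inverse of :func:`lms_zscore`."""
    if record.L == 0.0:
        return record.M * math.exp(record.S * z)
    return record.M * (1.0 + record.L * record.S * z) ** (1.0 / record.L)


def interpolate_lms(table: LMSTable, sex: Sex, age_months: float) -> LMSRecord:
    """LMS parameters at an arbitrary age, linear in each of L, M, S.

    Exact reference ages return the stored record verbatim; ages outside
    the covered interval raise :class:`OutOfRangeError`.
    """
    recs = table.records_for(sex)
    lo, hi = table.age_range(sex)
    if not (lo <= age_months <= hi):
        raise OutOfRangeError(
            f"age {age_months} mo outside LMS coverage [{lo}, {hi}] "
            f"for sex {sex.value}"
        )
    ages = [r.age_months for r in recs]
    i = bisect.bisect_left(ages, age_months)
    if i < len(ages) and ages[i] == age_months:
        return recs[i]
    left, right = recs[i - 1], recs[i]
    t = (age_months - left.age_months) / (right.age_months - left.age_months)
    return LMSRecord(
        sex=sex,
        age_months=age_months,
        L=left.L + t * (right.L - left.L),
        M=left.M + t * (right.M - left.M),
        S=left.S + t * (right.S - left.S),
    )


def bmi_percentile(patient: PatientAnthropometrics, table: LMSTable) -> float:
    """BMI-percentile-for-age in [0, 100] via the LMS z-score and normal CDF."""
    bmi = compute_bmi(patient.weight_kg, patient.height_cm)
    rec = interpolate_lms(table, patient.sex, float(patient.age_months))
    z = lms_zscore(bmi, rec)
    return 100.0 * float(norm.cdf(z))


def classify_obesity(
    patient: PatientAnthropometrics,
    table: LMSTable | None = None,
    *,
    inclusive: bool = False,
) -> ObesityAssessment:
    """Classify a patient as obese using the age-split criteria.

    Children (24 to <240 months) are obese when BMI-percentile-for-age
    exceeds the 95th percentile; adults (>=240 months) when absolute BMI
    exceeds 30 kg/m^2. Both comparisons are strict by default;
    ``inclusive=True`` switches to >= at both thresholds. An ``LMSTable``
    is required only for the pediatric branch.
    """
    if patient.age_months < MIN_CLASSIFIABLE_AGE_MONTHS:
        raise NotEligibleError(
            f"patient {patient.patient_id} is {patient.age_months} months old; "
            f"obesity classification covers ages >= {MIN_CLASSIFIABLE_AGE_MONTHS} months"
        )
    bmi = compute_bmi(patient.weight_kg, patient.height_cm)
    if patient.age_months >= ADULT_AGE_MONTHS:
        obese = bmi >= ADULT_BMI_CUTOFF if inclusive else bmi > ADULT_BMI_CUTOFF
        return ObesityAssessment(
            bmi=bmi,
            bmi_percentile=None,
            obese=obese,
            criterion=ObesityCriterion.ADULT_ABSOLUTE_BMI,
        )
    if table is None:
        raise OutOfRangeError(
            "pediatric obesity classification requires a growth-reference table"
        )
    pct = bmi_percentile(patient, table)
    obese = (
        pct >= PEDIATRIC_PERCENTILE_CUTOFF
        if inclusive
        else pct > PEDIATRIC_PERCENTILE_CUTOFF
    )
    return ObesityAssessment(
        bmi=bmi,
        bmi_percentile=pct,
        obese=obese,
        criterion=ObesityCriterion.PEDIATRIC_PERCENTILE,
    )


TallFormula = Callable[[Sex, float], float]


def _devine(sex: Sex, height_cm: float) -> float:
    inches_over_60 = height_cm / CM_PER_INCH - 60.0
    return DEVINE_BASE_KG[sex.value] + DEVINE_SLOPE_KG_PER_INCH * inches_over_60


def ideal_body_weight(
    patient: PatientAnthropometrics,
    tall_formula: TallFormula = _devine,
) -> tuple[float, IBWMethod]:
    """Ideal body weight in kg with the method used.

    Heights under 152.4 cm (60 in) use the Traub exponential formula
    ``2.396 * exp(0.01863 * height_cm)``; at or above 152.4 cm the
    sex-specific Devine adult formula applies (overridable via
    ``tall_formula``). The 152.4 cm boundary itself takes the tall branch.
    """
    h = patient.height_cm
    if h <= 0:
        raise InvalidMeasurementError(f"non-positive height {h}")
    if h < TRAUB_MAX_HEIGHT_CM:
        return TRAUB_COEF * math.exp(TRAUB_EXP * h), IBWMethod.TRAUB
    return tall_formula(patient.sex, h), IBWMethod.TALL_FORMULA


def adjusted_body_weight(
    actual_kg: float,
    ideal_kg: float,
    cofactor: float = DEFAULT_ADJUSTMENT_COFACTOR,
) -> float:
    """Adjusted body weight ``IBW + cofactor * (actual - IBW)``."""
    if actual_kg <= 0 or ideal_kg <= 0:
        raise InvalidMeasurementError(
            f"weights must be positive (actual={actual_kg}, ideal={ideal_kg})"
        )
    if not (0.0 <= cofactor <= 1.0):
        raise ConfigurationError(f"adjustment cofactor {cofactor} outside [0, 1]")
    return ideal_kg + cofactor * (actual_kg - ideal_kg)


def body_weights(
    patient: PatientAnthropometrics,
    cofactor: float = DEFAULT_ADJUSTMENT_COFACTOR,
    tall_formula: TallFormula = _devine,
) -> BodyWeights:
    """Compute the full actual/ideal/adjusted weight triple for a patient."""
    ideal, method = ideal_body_weight(patient, tall_formula)
    adjusted = adjusted_body_weight(patient.weight_kg, ideal, cofactor)
    return BodyWeights(
        actual_kg=patient.weight_kg,
        ideal_kg=ideal,
        adjusted_kg=adjusted,
        ibw_method=method,
        adjustment_cofactor=cofactor,
    )
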