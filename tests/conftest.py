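import pytest

from obesitydosing import (
    BodyWeights,
    IBWMethod,
    ObesityAssessment,
    ObesityCriterion,
    PatientAnthropometrics,
    Sex,
    default_formulary,
    make_lms_fixture,
)


@pytest.fixture(scope="session")
def lms():
    """Default synthetic growth reference, ages 24-240 months."""
    return make_lms_fixture()


@pytest.fixture(scope="session")
def flat_lms():
    """Analytically simple reference: L=1, M=20, S=0.1 at every age/sex.

    With L=1 the z-score is linear, z = (BMI - 20) / 2, so the
    95th-percentile BMI is 20 * (1 + 1.6449 * 0.1) ≈ 23.29 everywhere.
    """
    return make_lms_fixture(
        24, 240, step=12, L=1.0, M=20.0, S=0.1,
        sex_shift={Sex.MALE: 0.0, Sex.FEMALE: 0.0},
    )


@pytest.fixture(scope="session")
def formulary():
    return default_formulary()


def make_patient(
    age_months=120,
    sex=Sex.MALE,
    height_cm=130.0,
    weight_kg=40.0,
    **kwargs,
) -> PatientAnthropometrics:
    return PatientAnthropometrics(
        patient_id=kwargs.pop("patient_id", "p1"),
        age_months=age_months,
        sex=sex,
        height_cm=height_cm,
        weight_kg=weight_kg,
        **kwargs,
    )


def obese_assessment(bmi=28.0, percentile=98.0) -> ObesityAssessment:
    return ObesityAssessment(
        bmi=bmi, bmi_percentile=percentile, obese=True,
        criterion=ObesityCriterion.PEDIATRIC_PERCENTILE,
    )


def lean_assessment(bmi=18.0, percentile=50.0) -> ObesityAssessment:
    return ObesityAssessment(
        bmi=bmi, bmi_percentile=percentile, obese=False,
        criterion=ObesityCriterion.PEDIATRIC_PERCENTILE,
    )


def weights_of(actual=70.0, ideal=40.0, adjusted=52.0) -> BodyWeights:
    return BodyWeights(
        actual_kg=actual, ideal_kg=ideal, adjusted_kg=adjusted,
        ibw_method=IBWMethod.TRAUB,
    )
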