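"""Shared fixtures: a hand-enumerable cohort fixture and small synthetic
worlds (all generated at test time; nothing is read from disk)."""

from datetime import date

import pandas as pd
import pytest

from claimsbmi import GeneratorConfig, generate, identity_kernel

INDEX = pd.Timestamp("2017-06-01")  # ICD-10-CM era, incl. the 182-day lookback


def _d(offset: int) -> pd.Timestamp:
    return INDEX + pd.Timedelta(days=offset)


@pytest.fixture(scope="session")
def ten_patient_world():
    """Hand-built 10-patient fixture: one clean tier-3 member (p0), one
    violation of each tier-1 exclusion rule (p1-p7), one tier-1-only
    patient whose last preop code is nonspecific (p8), and one tier-2
    member whose postop proximate measurement falls outside the
    postoperative window (p9).

    Expected memberships: cohort1 = {0, 8, 9}, cohort2 = {0, 9},
    cohort3 = {0}.
    """
    patients = pd.DataFrame({
        "patient_id": range(10),
        "age": [45, 17, 45, 45, 45, 45, 45, 45, 45, 45],
        "sex": ["F"] * 10,
        "ehr_linked": [True] * 10,
    })
    enrollment = pd.DataFrame(
        [(p, _d(-100) if p == 3 else _d(-400), _d(400)) for p in range(10)],
        columns=["patient_id", "start", "end"])
    proc_rows = [(p, "SG", INDEX, "inpatient") for p in range(10)]
    proc_rows += [
        (2, "RYGB", INDEX, "inpatient"),          # conflicting same-day codes
        (4, "REVISION", _d(-50), "inpatient"),    # preop revisional operation
        (6, "OTHER", INDEX, "emergency"),         # ED encounter on index day
    ]
    procedures = pd.DataFrame(proc_rows,
                              columns=["patient_id", "op_type", "date", "setting"])
    dx_rows = [
        (0, "Z68.41", "ICD10CM", _d(-90)),
        (0, "Z68.42", "ICD10CM", _d(-10)),
        (0, "Z68.39", "ICD10CM", _d(200)),
        (5, "C16.9", "ICD10CM", _d(-30)),         # GI malignancy in lookback
        (7, "K25.9", "ICD10CM", _d(0)),           # ulcer on index day
        (8, "Z68.41", "ICD10CM", _d(-60)),
        (8, "E66.9", "ICD10CM", _d(-5)),          # nonspecific last preop code
        (9, "Z68.43", "ICD10CM", _d(-20)),
        (9, "Z68.41", "ICD10CM", _d(360)),        # postop code near window end
    ]
    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "code", "system", "date"])
    bmi_rows = [
        (0, 46.0, _d(-12)),
        (0, 36.5, _d(210)),
        (8, 42.0, _d(-58)),
        (9, 51.0, _d(-15)),
        (9, 40.5, _d(380)),   # within 30 d of the code but past day 365
    ]
    bmi = pd.DataFrame(bmi_rows, columns=["patient_id", "bmi", "date"])
    return {"patients": patients, "enrollment": enrollment,
            "procedures": procedures, "diagnoses": diagnoses, "bmi": bmi}


def perfect_coder_config(n: int, seed: int = 11, **overrides) -> GeneratorConfig:
    """Identity kernel, zero noise, full linkage, codes at every visit."""
    base = dict(n_patients=n, seed=seed, fidelity_kernel=identity_kernel(),
                upcode_at_35=0.0, ehr_noise_sd=0.0, p_ehr_linked=1.0,
                p_bmi_given_encounter=1.0,
                p_any_code_preop=1.0, p_granular_given_code_preop=1.0,
                p_any_code_postop=1.0, p_granular_given_code_postop=1.0)
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_perfect_world():
    return generate(perfect_coder_config(300))


@pytest.fixture(scope="session")
def small_default_world():
    return generate(GeneratorConfig(n_patients=400, seed=5, p_ehr_linked=1.0))
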