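"""Cohort eligibility rules, anchor selection, and nesting invariants."""

import itertools

import pandas as pd
import pytest

from claimsbmi import (
    WindowSpec,
    build_cohort1,
    build_cohort2,
    build_cohort3,
    find_proximate_bmi,
    generate,
    last_available_code,
)
from conftest import INDEX, _d, perfect_coder_config


def _cohorts(world, windows=WindowSpec()):
    c1, att = build_cohort1(world["patients"], world["enrollment"],
                            world["procedures"], world["diagnoses"], windows)
    c2 = build_cohort2(c1, world["diagnoses"], world["bmi"], windows)
    c3 = build_cohort3(c2, world["diagnoses"], world["bmi"], windows)
    return c1, c2, c3, att


def test_hand_fixture_memberships(ten_patient_world):
    c1, c2, c3, att = _cohorts(ten_patient_world)
    assert set(c1.patient_id) == {0, 8, 9}
    assert set(c2.patient_id) == {0, 9}
    assert set(c3.patient_id) == {0}
    for reason in ("age", "conflicting_procedures", "enrollment",
                   "preop_bariatric_or_revision", "preop_gi_malignancy",
                   "ed_on_index_day", "gi_ulcer_on_index_day"):
        assert att[reason] == 1, reason
    assert att["eligible"] == 3


def test_anchor_values_in_hand_fixture(ten_patient_world):
    _, c2, c3, _ = _cohorts(ten_patient_world)
    p0 = c2[c2.patient_id == 0].iloc[0]
    assert p0.preop_anchor_code == "Z68.42"          # later code wins
    assert p0.preop_anchor_date == _d(-10)
    assert p0.preop_anchor_bmi == 46.0               # measurement at -12 d
    p0c3 = c3.iloc[0]
    assert p0c3.postop_anchor_code == "Z68.39"
    assert p0c3.postop_anchor_bmi == 36.5


def test_postop_measurement_must_lie_in_window(ten_patient_world):
    """p9's postop code (day 360) has a measurement 20 days later — within
    the proximity bound but past day 365, so tier 3 is not reached; moving
    the measurement to day 350 admits the patient."""
    _, _, c3, _ = _cohorts(ten_patient_world)
    assert 9 not in set(c3.patient_id)
    moved = dict(ten_patient_world)
    bmi = moved["bmi"].copy()
    bmi.loc[(bmi.patient_id == 9) & (bmi.bmi == 40.5), "date"] = _d(350)
    moved["bmi"] = bmi
    _, _, c3b, _ = _cohorts(moved)
    assert 9 in set(c3b.patient_id)


def test_overlapping_enrollment_rejected(ten_patient_world):
    w = dict(ten_patient_world)
    extra = pd.DataFrame([(0, _d(-300), _d(100))],
                         columns=["patient_id", "start", "end"])
    w["enrollment"] = pd.concat([w["enrollment"], extra], ignore_index=True)
    with pytest.raises(ValueError, match="overlap"):
        build_cohort1(w["patients"], w["enrollment"], w["procedures"],
                      w["diagnoses"])


# ---------------------------------------------------------------------------
# anchor-selection primitives


def _dx(rows):
    return pd.DataFrame(rows, columns=["patient_id", "code", "system", "date"])


def test_last_available_code_max_date():
    dx = _dx([(1, "Z68.41", "ICD10CM", _d(-90)), (1, "Z68.42", "ICD10CM", _d(-10))])
    got = last_available_code(dx, (_d(-182), INDEX))
    assert got["code"] == "Z68.42"


def test_last_available_code_granular_only_filter():
    dx = _dx([(1, "E66.9", "ICD10CM", _d(-10))])
    assert last_available_code(dx, (_d(-182), INDEX), "granular_only") is None
    assert last_available_code(dx, (_d(-182), INDEX), "any_weight_code")["code"] == "E66.9"


def test_same_day_tie_highest_category_wins_any_order():
    """Deterministic tie rule, invariant to row order: granular beats
    nonspecific, then the higher category wins (brute-forced over all
    input orderings)."""
    rows = [(1, "Z68.41", "ICD10CM", _d(-10)),
            (1, "Z68.42", "ICD10CM", _d(-10)),
            (1, "E66.01", "ICD10CM", _d(-10)),
            (1, "Z68.39", "ICD10CM", _d(-40))]
    for perm in itertools.permutations(rows):
        got = last_available_code(_dx(list(perm)), (_d(-182), INDEX))
        assert got["code"] == "Z68.42"


def _bmi(rows):
    return pd.DataFrame(rows, columns=["patient_id", "bmi", "date"])


def test_proximate_bmi_min_distance():
    rec = _bmi([(1, 40.0, _d(-29)), (1, 41.0, _d(5))])
    assert find_proximate_bmi(INDEX, rec, 30)["bmi"] == 41.0


def test_proximate_bmi_outside_bound_absent():
    assert find_proximate_bmi(INDEX, _bmi([(1, 40.0, _d(31))]), 30) is None
    assert find_proximate_bmi(INDEX, _bmi([(1, 40.0, _d(30))]), 30) is not None


def test_proximate_bmi_equidistant_tie_takes_earlier():
    rec = _bmi([(1, 39.0, _d(-7)), (1, 41.0, _d(7))])
    assert find_proximate_bmi(INDEX, rec, 30)["bmi"] == 39.0


# ---------------------------------------------------------------------------
# invariants on generated worlds


@pytest.fixture(scope="module")
def generated(small_default_world):
    w = small_default_world
    c1, _ = build_cohort1(w.patients, w.enrollment, w.procedures, w.diagnoses)
    c2 = build_cohort2(c1, w.diagnoses, w.bmi)
    c3 = build_cohort3(c2, w.diagnoses, w.bmi)
    return w, c1, c2, c3


def test_nesting(generated):
    _, c1, c2, c3 = generated
    assert set(c3.patient_id) <= set(c2.patient_id) <= set(c1.patient_id)


def test_proximity_monotonicity(generated):
    w, c1, *_ = generated
    sizes2, sizes3 = [], []
    for prox in (5, 15, 30, 60):
        win = WindowSpec(proximity_days=prox)
        c2 = build_cohort2(c1, w.diagnoses, w.bmi, win)
        c3 = build_cohort3(c2, w.diagnoses, w.bmi, win)
        sizes2.append(set(c2.patient_id))
        sizes3.append(set(c3.patient_id))
    for a, b in zip(sizes2, sizes2[1:]):
        assert a <= b
    for a, b in zip(sizes3, sizes3[1:]):
        assert a <= b


def test_idempotence_under_restriction(generated):
    """Rebuilding from a world restricted to tier-1 members reproduces the
    same tiers 2 and 3."""
    w, c1, c2, c3 = generated
    keep = set(c1.patient_id)
    pats = w.patients[w.patients.patient_id.isin(keep)]
    enr = w.enrollment[w.enrollment.patient_id.isin(keep)]
    procs = w.procedures[w.procedures.patient_id.isin(keep)]
    dx = w.diagnoses[w.diagnoses.patient_id.isin(keep)]
    bmi = w.bmi[w.bmi.patient_id.isin(keep)]
    c1b, _ = build_cohort1(pats, enr, procs, dx)
    assert set(c1b.patient_id) == keep
    assert set(build_cohort2(c1b, dx, bmi).patient_id) == set(c2.patient_id)
    c2b = build_cohort2(c1b, dx, bmi)
    assert set(build_cohort3(c2b, dx, bmi).patient_id) == set(c3.patient_id)


def test_perfect_coder_cohort2_is_everyone_with_codes(small_perfect_world):
    """Full linkage + a granular code at every visit: tier 2 equals tier 1
    (every member has an index-day code with a same-day measurement)."""
    w = small_perfect_world
    c1, _ = build_cohort1(w.patients, w.enrollment, w.procedures, w.diagnoses)
    c2 = build_cohort2(c1, w.diagnoses, w.bmi)
    assert set(c2.patient_id) == set(c1.patient_id)
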