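"""The two claims-based algorithms and the EHR reference standard.

* **Severe-obesity classification**: a patient is claims-positive if *any*
  weight-related diagnosis code in the preoperative window indicates
  BMI >= 35 kg/m^2 (>= 40 in the sensitivity variant). The reference is
  any EHR BMI measurement >= the threshold in the same window.
* **BMI categorization**: the last available weight-related code in a
  window, mapped to the 10-level scale (or the coarsened 5-/4-level
  schemes). The reference category comes from the most proximate EHR
  measurement to that code (preoperative) or the last available in-window
  measurement (postoperative) — the asymmetry the validation design uses.

Patients with no reference data never enter validation denominators; they
are flagged, not counted as negatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .codes import (
    BmiCategory,
    CodeClass,
    CodeDictionary,
    Scheme,
    SCALES,
    categorize_bmi,
    coarsen,
    coarsen_level,
    default_dictionary,
)
from .cohorts import WindowSpec, classify_diagnoses, last_available_code

PHYSIOLOGIC_BMI = (10.0, 120.0)

_COARSE_OBESE = SCALES[Scheme.FOUR_LEVEL][3]  # >=30.0


@dataclass(frozen=True)
class AlgorithmConfig:
    """Published algorithm variants."""

    severe_threshold: int = 35              # 35 or 40 kg/m^2
    scheme: Scheme = Scheme.TEN_LEVEL
    include_nonspecific: bool = False
    windows: WindowSpec = field(default_factory=WindowSpec)

    def __post_init__(self) -> None:
        if self.severe_threshold not in (35, 40):
            raise ValueError("severe_threshold must be 35 or 40")
        Scheme(self.scheme)


def severe_obesity_claims(diagnoses: pd.DataFrame,
                          window: tuple[pd.Timestamp, pd.Timestamp],
                          config: AlgorithmConfig = AlgorithmConfig(),
                          dictionary: Optional[CodeDictionary] = None) -> bool:
    """Any-time semantics: one qualifying code anywhere in the window
    suffices; nonspecific codes never qualify under the base algorithm."""
    dictionary = dictionary or default_dictionary()
    if diagnoses.empty:
        return False
    dx = classify_diagnoses(diagnoses, dictionary)
    dx["date"] = pd.to_datetime(dx["date"])
    lo, hi = window
    dx = dx[(dx["date"] >= lo) & (dx["date"] <= hi)]
    qualifying = (dx["kind"] == CodeClass.GRANULAR.value) & \
        (dx["category"].map(lambda i: SCALES[Scheme.TEN_LEVEL][i].lower_bound
                            if i >= 0 else -1.0) >= config.severe_threshold)
    return bool(qualifying.any())


def severe_obesity_ehr(bmi_records: pd.DataFrame,
                       window: tuple[pd.Timestamp, pd.Timestamp],
                       threshold: float = 35.0) -> tuple[Optional[bool], str]:
    """Reference standard: any measurement >= threshold in the window.

    Returns (label, flag); an empty measurement set yields
    (None, "no_reference_data") rather than a negative label.
    """
    if bmi_records.empty:
        return None, "no_reference_data"
    rec = bmi_records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    lo, hi = window
    rec = rec[(rec["date"] >= lo) & (rec["date"] <= hi)]
    if rec.empty:
        return None, "no_reference_data"
    return bool((rec["bmi"] >= threshold).any()), ""


def bmi_category_ehr(value: float, scheme: Scheme = Scheme.TEN_LEVEL
                     ) -> tuple[Optional[BmiCategory], str]:
    """Bin one measurement; non-physiologic values are flagged and excluded
    from comparisons."""
    if not PHYSIOLOGIC_BMI[0] <= value <= PHYSIOLOGIC_BMI[1]:
        return None, "non_physiologic"
    return categorize_bmi(value, scheme), ""


def bmi_category_claims(diagnoses: pd.DataFrame,
                        window: tuple[pd.Timestamp, pd.Timestamp],
                        config: AlgorithmConfig = AlgorithmConfig(),
                        dictionary: Optional[CodeDictionary] = None,
                        ) -> tuple[Optional[BmiCategory], str]:
    """Last-available-code semantics; returns (category-or-None, flag).

    With ``include_nonspecific``, a nonspecific last code is assignable
    only under the four-level scheme (obese >= 30.0); under finer schemes
    it yields None with flag ``nonspecific_last_code`` since no principled
    level assignment exists.
    """
    dictionary = dictionary or default_dictionary()
    codes_filter = "with_nonspecific" if config.include_nonspecific else "granular_only"
    last = last_available_code(diagnoses, window, codes_filter, dictionary)
    if last is None:
        return None, "no_qualifying_code"
    if last["kind"] == CodeClass.NONSPECIFIC.value:
        if config.scheme == Scheme.FOUR_LEVEL:
            return _COARSE_OBESE, ""
        return None, "nonspecific_last_code"
    cat10 = SCALES[Scheme.TEN_LEVEL][int(last["category"])]
    return coarsen(cat10, config.scheme), ""


def build_classification_table(members: pd.DataFrame,
                               diagnoses: pd.DataFrame,
                               bmi: pd.DataFrame,
                               window_kind: str,
                               config: AlgorithmConfig = AlgorithmConfig(),
                               dictionary: Optional[CodeDictionary] = None,
                               ) -> pd.DataFrame:
    """Per-patient claims-vs-reference labels for one window — the single
    input to the metrics stage.

    Preoperative reference: the most proximate measurement to the last
    code (within the proximity bound); postoperative reference: the last
    available measurement in the window. Levels are indices within
    ``config.scheme``; -1 with a flag marks an unassignable side.
    """
    if window_kind not in ("preop", "postop"):
        raise ValueError("window_kind must be 'preop' or 'postop'")
    from .cohorts import _vector_last_code, _vector_proximate_bmi  # no cycle at runtime

    dictionary = dictionary or default_dictionary()
    windows = config.windows
    scale = SCALES[config.scheme]
    out = members.reset_index(drop=True).copy()
    out["index_date"] = pd.to_datetime(out["index_date"])
    if window_kind == "preop":
        lo = out["index_date"] - pd.Timedelta(days=windows.preop_days)
        hi = out["index_date"]
    else:
        lo = out["index_date"] + pd.Timedelta(days=1)
        hi = out["index_date"] + pd.Timedelta(days=windows.postop_days)

    dx = classify_diagnoses(diagnoses, dictionary)
    dx["date"] = pd.to_datetime(dx["date"])
    b = bmi.copy()
    if len(b):
        b["date"] = pd.to_datetime(b["date"])
    else:
        b = pd.DataFrame(columns=["patient_id", "bmi", "date"])

    # --- claims side: last available code under the configured filter
    codes_filter = "with_nonspecific" if config.include_nonspecific else "granular_only"
    last = _vector_last_code(out, dx, lo, hi, codes_filter)
    last = last.set_index("patient_id")
    kind = out["patient_id"].map(last["kind"])
    cat10 = out["patient_id"].map(last["category"])
    claims_level = np.full(len(out), -1, dtype=int)
    claims_flag = np.where(kind.isna(), "no_qualifying_code", "")
    gran_mask = (kind == CodeClass.GRANULAR.value).to_numpy()
    if gran_mask.any():
        lv10 = cat10[gran_mask].astype(int).to_numpy()
        claims_level[gran_mask] = [coarsen_level(v, config.scheme) for v in lv10]
    ns_mask = (kind == CodeClass.NONSPECIFIC.value).to_numpy()
    if ns_mask.any():
        if config.scheme == Scheme.FOUR_LEVEL:
            claims_level[ns_mask] = _COARSE_OBESE.level_index
        else:
            claims_flag = np.where(ns_mask, "nonspecific_last_code", claims_flag)

    # --- reference side
    ref_level = np.full(len(out), -1, dtype=int)
    ref_flag = np.full(len(out), "", dtype=object)
    ref_bmi = np.full(len(out), np.nan)
    if window_kind == "preop":
        anchors = pd.DataFrame({"patient_id": out["patient_id"],
                                "anchor_date": out["patient_id"].map(last["date"])})
        valid = anchors["anchor_date"].notna().to_numpy()
        prox = _vector_proximate_bmi(anchors[valid], b, lo[valid], hi[valid],
                                     windows.proximity_days) if valid.any() \
            else pd.DataFrame(columns=["patient_id", "bmi", "date"])
        prox = prox.set_index("patient_id")
        vals = out["patient_id"].map(prox["bmi"])
        ref_bmi = vals.to_numpy(dtype=float)
    else:
        need = pd.DataFrame({"patient_id": out["patient_id"],
                             "_lo": lo.to_numpy(), "_hi": hi.to_numpy()})
        m = b.merge(need, on="patient_id")
        m = m[(m["date"] >= m["_lo"]) & (m["date"] <= m["_hi"])]
        lastb = (m.sort_values(["patient_id", "date", "bmi"])
                 .groupby("patient_id").tail(1).set_index("patient_id"))
        vals = out["patient_id"].map(lastb["bmi"]) if len(lastb) else \
            pd.Series(np.nan, index=out.index)
        ref_bmi = vals.to_numpy(dtype=float)

    missing = np.isnan(ref_bmi)
    ref_flag[missing] = "no_reference_data"
    ok = ~missing
    nonphys = ok & ((ref_bmi < PHYSIOLOGIC_BMI[0]) | (ref_bmi > PHYSIOLOGIC_BMI[1]))
    ref_flag[nonphys] = "non_physiologic"
    ok &= ~nonphys
    if ok.any():
        edges = np.array([c.lower_bound for c in scale][1:])
        ref_level[ok] = np.searchsorted(edges, ref_bmi[ok], side="right")

    table = pd.DataFrame({
        "patient_id": out["patient_id"],
        "window": window_kind,
        "claims_level": claims_level,
        "claims_label": [scale[i].label if i >= 0 else "" for i in claims_level],
        "claims_flag": claims_flag,
        "ref_level": ref_level,
        "ref_label": [scale[i].label if i >= 0 else "" for i in ref_level],
        "ref_flag": ref_flag,
        "ref_bmi": ref_bmi,
    })

    if window_kind == "preop":
        thresh_level = 4 if config.severe_threshold == 35 else 5
        q = dx[(dx["kind"] == CodeClass.GRANULAR.value)
               & (dx["category"] >= thresh_level)]
        m = q.merge(pd.DataFrame({"patient_id": out["patient_id"],
                                  "_lo": lo.to_numpy(), "_hi": hi.to_numpy()}),
                    on="patient_id")
        m = m[(m["date"] >= m["_lo"]) & (m["date"] <= m["_hi"])]
        pos = set(m["patient_id"])
        table["severe_claims"] = out["patient_id"].isin(pos)
        mb = b.merge(pd.DataFrame({"patient_id": out["patient_id"],
                                   "_lo": lo.to_numpy(), "_hi": hi.to_numpy()}),
                     on="patient_id")
        mb = mb[(mb["date"] >= mb["_lo"]) & (mb["date"] <= mb["_hi"])]
        any_meas = set(mb["patient_id"])
        pos_ehr = set(mb.loc[mb["bmi"] >= config.severe_threshold, "patient_id"])
        table["severe_ehr"] = [
            (pid in pos_ehr) if pid in any_meas else None
            for pid in out["patient_id"]
        ]
    else:
        table["severe_claims"] = None
        table["severe_ehr"] = None
    return table
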