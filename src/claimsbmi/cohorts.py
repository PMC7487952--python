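"""Nested study-cohort construction around an index bariatric operation.

Three tiers, each a subset of the previous:

* **Cohort 1** — adults with a first qualifying operation (AGB, RYGB or SG)
  in the accrual window, continuously enrolled through the 182-day
  preoperative window, with the washout/index-day exclusions applied.
* **Cohort 2** — Cohort 1 members whose *last* preoperative weight-related
  diagnosis code is granular and has an EHR BMI measurement within
  ±``proximity_days`` of it (measurement inside the preoperative window).
* **Cohort 3** — Cohort 2 members satisfying the analogous condition in the
  postoperative window.

Temporal conventions: the preoperative window is ``[index - preop_days,
index]`` (index day included); the postoperative window is ``(index,
index + postop_days]``. Same-day code ties resolve granular-over-
nonspecific, then highest BMI category; equidistant proximity ties take
the earlier measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from typing import Optional

import pandas as pd

from .codes import CodeClass, CodeDictionary, CodingSystem, default_dictionary

INDEX_OPS = frozenset({"AGB", "RYGB", "SG"})
EXCLUSION_OPS = frozenset({"REVISION", "OTHER_BARIATRIC"})

# dotless code prefixes, per coding system
GI_MALIGNANCY_PREFIXES = frozenset(
    {f"{n}" for n in range(150, 160)} | {f"C{n}" for n in range(15, 27)}
)
GI_ULCER_PREFIXES = frozenset(
    {f"{n}" for n in range(531, 535)} | {f"K{n}" for n in range(25, 29)}
)


@dataclass(frozen=True)
class WindowSpec:
    """Fixed-day analysis windows anchored on the index operation."""

    preop_days: int = 182
    postop_days: int = 365
    proximity_days: int = 30

    def __post_init__(self) -> None:
        if self.preop_days <= 0 or self.postop_days <= 0:
            raise ValueError("window lengths must be positive")
        if self.proximity_days < 0:
            raise ValueError("proximity_days must be >= 0")

    def preop_bounds(self, index_date: pd.Timestamp) -> tuple[pd.Timestamp, pd.Timestamp]:
        index_date = pd.Timestamp(index_date)
        return index_date - pd.Timedelta(days=self.preop_days), index_date

    def postop_bounds(self, index_date: pd.Timestamp) -> tuple[pd.Timestamp, pd.Timestamp]:
        index_date = pd.Timestamp(index_date)
        return (index_date + pd.Timedelta(days=1),
                index_date + pd.Timedelta(days=self.postop_days))


def _norm_codes(codes: pd.Series) -> pd.Series:
    return codes.astype(str).str.upper().str.replace(".", "", regex=False)


def classify_diagnoses(diagnoses: pd.DataFrame,
                       dictionary: Optional[CodeDictionary] = None) -> pd.DataFrame:
    """Annotate a diagnoses table with ``kind`` (granular / nonspecific /
    not_weight_related) and the 10-level ``category`` index (-1 if none)."""
    dictionary = dictionary or default_dictionary()
    rows = []
    for e in dictionary.entries():
        cat = e.category10.level_index if e.category10 is not None else -1
        rows.append((e.code.replace(".", "").upper(), e.system.value,
                     e.granularity.value, cat))
    lut = pd.DataFrame(rows, columns=["_norm", "system", "kind", "category"])
    out = diagnoses.copy()
    out["_norm"] = _norm_codes(out["code"])
    out = out.merge(lut, on=["_norm", "system"], how="left")
    out["kind"] = out["kind"].fillna(CodeClass.NOT_WEIGHT_RELATED.value)
    out["category"] = out["category"].fillna(-1).astype(int)
    return out.drop(columns="_norm")


def _validate_enrollment(enrollment: pd.DataFrame) -> None:
    enr = enrollment.sort_values(["patient_id", "start"])
    prev_end = enr.groupby("patient_id")["end"].shift()
    if (enr["start"] <= prev_end).any():
        raise ValueError("overlapping enrollment spans")


def _covers(enrollment: pd.DataFrame, needs: pd.DataFrame,
            max_gap_days: int) -> pd.Series:
    """Boolean per row of ``needs`` (patient_id, win_start, win_end): is the
    interval covered by (gap-merged) enrollment spans?"""
    enr = enrollment.sort_values(["patient_id", "start"]).copy()
    gap = (enr["start"] - enr.groupby("patient_id")["end"].shift()).dt.days
    new_block = (gap.isna() | (gap - 1 > max_gap_days)).astype(int)
    enr["block"] = new_block.groupby(enr["patient_id"]).cumsum()
    spans = enr.groupby(["patient_id", "block"]).agg(start=("start", "min"),
                                                     end=("end", "max")).reset_index()
    m = needs.reset_index().merge(spans, on="patient_id", how="left")
    m["ok"] = (m["start"] <= m["win_start"]) & (m["end"] >= m["win_end"])
    return m.groupby("index")["ok"].any().reindex(needs.index, fill_value=False)


def build_cohort1(patients: pd.DataFrame,
                  enrollment: pd.DataFrame,
                  procedures: pd.DataFrame,
                  diagnoses: pd.DataFrame,
                  windows: WindowSpec = WindowSpec(),
                  accrual_start: date = date(2011, 1, 1),
                  accrual_end: date = date(2018, 6, 30),
                  max_gap_days: int = 0) -> tuple[pd.DataFrame, dict[str, int]]:
    """Tier-1 eligibility. Returns (members, attrition counts by reason).

    A patient's index operation is the first qualifying operation in the
    accrual window; exclusion reasons are assigned in a fixed rule order
    and each excluded patient carries the first reason that applied.
    """
    required = {"patient_id", "op_type", "date", "setting"}
    if not required <= set(procedures.columns):
        raise ValueError(f"procedures table needs columns {sorted(required)}")
    _validate_enrollment(enrollment)

    procs = procedures.copy()
    procs["date"] = pd.to_datetime(procs["date"])
    bar = procs[procs["op_type"].isin(INDEX_OPS)
                & (procs["date"] >= pd.Timestamp(accrual_start))
                & (procs["date"] <= pd.Timestamp(accrual_end))]
    if bar.empty:
        return _empty_members(), {"eligible": 0}
    index_dates = bar.groupby("patient_id")["date"].min().rename("index_date")
    cand = index_dates.reset_index().merge(patients, on="patient_id", how="left")

    same_day = bar.merge(index_dates, left_on=["patient_id", "date"],
                         right_on=["patient_id", "index_date"])
    n_types = same_day.groupby("patient_id")["op_type"].nunique()
    op_of = (same_day.sort_values(["patient_id", "op_type", "setting"])
             .groupby("patient_id").first())

    cand["win_start"] = cand["index_date"] - pd.Timedelta(days=windows.preop_days)
    cand["win_end"] = cand["index_date"]

    dx = classify_diagnoses(diagnoses) if len(diagnoses) else None
    norm = _norm_codes(diagnoses["code"]) if dx is not None else None

    def _dx_flag(prefixes, on_index_only: bool) -> pd.Series:
        if dx is None:
            return pd.Series(False, index=cand["patient_id"])
        pref = norm.str[:3].isin(prefixes)
        hits = diagnoses.loc[pref, ["patient_id", "date"]].copy()
        hits["date"] = pd.to_datetime(hits["date"])
        m = hits.merge(cand[["patient_id", "index_date", "win_start"]], on="patient_id")
        if on_index_only:
            m = m[m["date"] == m["index_date"]]
        else:
            m = m[(m["date"] >= m["win_start"]) & (m["date"] <= m["index_date"])]
        flagged = set(m["patient_id"])
        return pd.Series([p in flagged for p in cand["patient_id"]],
                         index=cand["patient_id"])

    pid = cand["patient_id"]
    conflicting = pid.map(n_types).fillna(0) > 1
    underage = cand["age"].fillna(0) < 18
    covered = _covers(enrollment, cand[["patient_id", "win_start", "win_end"]],
                      max_gap_days)
    covered.index = cand.index

    prior = procs[procs["op_type"].isin(INDEX_OPS | EXCLUSION_OPS)]
    m = prior.merge(cand[["patient_id", "index_date", "win_start"]], on="patient_id")
    m = m[(m["date"] >= m["win_start"]) & (m["date"] < m["index_date"])]
    prior_bariatric = pid.isin(set(m["patient_id"]))

    malignancy = _dx_flag(GI_MALIGNANCY_PREFIXES, on_index_only=False).to_numpy()
    ulcer = _dx_flag(GI_ULCER_PREFIXES, on_index_only=True).to_numpy()

    ed = procs[(procs["setting"] == "emergency")]
    m = ed.merge(cand[["patient_id", "index_date"]], on="patient_id")
    m = m[m["date"] == m["index_date"]]
    ed_index = pid.isin(set(m["patient_id"]))

    reasons = pd.Series("", index=cand.index)
    rule_order = [
        ("conflicting_procedures", conflicting.to_numpy()),
        ("age", underage.to_numpy()),
        ("enrollment", (~covered).to_numpy()),
        ("preop_bariatric_or_revision", prior_bariatric.to_numpy()),
        ("preop_gi_malignancy", malignancy),
        ("ed_on_index_day", ed_index.to_numpy()),
        ("gi_ulcer_on_index_day", ulcer),
    ]
    attrition = {"candidates": int(len(cand))}
    for name, mask in rule_order:
        newly = (reasons == "") & mask
        attrition[name] = int(newly.sum())
        reasons[newly] = name

    keep = reasons == ""
    members = cand.loc[keep, ["patient_id", "index_date", "age", "sex"]].copy()
    members["op_type"] = members["patient_id"].map(op_of["op_type"])
    members["setting"] = members["patient_id"].map(op_of["setting"])
    members["tier"] = 1
    attrition["eligible"] = int(keep.sum())
    members = members.reset_index(drop=True)
    return members, attrition


def _empty_members() -> pd.DataFrame:
    return pd.DataFrame(columns=["patient_id", "index_date", "age", "sex",
                                 "op_type", "setting", "tier"])


# ---------------------------------------------------------------------------
# anchor-selection primitives (single-patient versions used by callers/tests;
# the cohort builders use vectorised equivalents)


_FILTERS = {"granular_only": {CodeClass.GRANULAR.value},
            "any_weight_code": {CodeClass.GRANULAR.value, CodeClass.NONSPECIFIC.value},
            "with_nonspecific": {CodeClass.GRANULAR.value, CodeClass.NONSPECIFIC.value}}


def last_available_code(diagnoses: pd.DataFrame,
                        window: tuple[pd.Timestamp, pd.Timestamp],
                        codes_filter: str = "any_weight_code",
                        dictionary: Optional[CodeDictionary] = None,
                        ) -> Optional[pd.Series]:
    """The weight-related record with maximal service date in ``window``
    passing the granularity filter; None if there is none.

    Same-date ties: granular beats nonspecific, then highest category,
    then code string (deterministic).
    """
    if codes_filter not in _FILTERS:
        raise ValueError(f"unknown codes_filter {codes_filter!r}")
    if diagnoses.empty:
        return None
    dx = classify_diagnoses(diagnoses, dictionary)
    dx["date"] = pd.to_datetime(dx["date"])
    lo, hi = window
    dx = dx[(dx["date"] >= lo) & (dx["date"] <= hi)
            & dx["kind"].isin(_FILTERS[codes_filter])]
    if dx.empty:
        return None
    dx["_gran"] = (dx["kind"] == CodeClass.GRANULAR.value).astype(int)
    dx = dx.sort_values(["date", "_gran", "category", "code"])
    return dx.iloc[-1].drop("_gran")


def find_proximate_bmi(anchor_date: pd.Timestamp,
                       bmi_records: pd.DataFrame,
                       proximity_days: int = 30) -> Optional[pd.Series]:
    """The BMI measurement minimising |date - anchor| within the proximity
    bound; equidistant ties take the earlier measurement."""
    if bmi_records.empty:
        return None
    rec = bmi_records.copy()
    rec["date"] = pd.to_datetime(rec["date"])
    rec["_delta"] = (rec["date"] - pd.Timestamp(anchor_date)).dt.days
    rec = rec[rec["_delta"].abs() <= proximity_days]
    if rec.empty:
        return None
    rec = rec.sort_values(["date"]).sort_values("_delta", key=lambda s: s.abs(),
                                                kind="stable")
    return rec.iloc[0].drop("_delta")


def _vector_last_code(members: pd.DataFrame, dx: pd.DataFrame,
                      lo: pd.Series, hi: pd.Series,
                      codes_filter: str) -> pd.DataFrame:
    """Last qualifying code per member; dx must be pre-classified."""
    m = dx.merge(pd.DataFrame({"patient_id": members["patient_id"],
                               "_lo": lo.to_numpy(), "_hi": hi.to_numpy()}),
                 on="patient_id")
    m = m[(m["date"] >= m["_lo"]) & (m["date"] <= m["_hi"])
          & m["kind"].isin(_FILTERS[codes_filter])]
    if m.empty:
        return pd.DataFrame(columns=["patient_id", "code", "system", "date",
                                     "kind", "category"])
    m["_gran"] = (m["kind"] == "granular").astype(int)
    m = m.sort_values(["patient_id", "date", "_gran", "category", "code"])
    last = m.groupby("patient_id").tail(1)
    return last[["patient_id", "code", "system", "date", "kind", "category"]]


def _vector_proximate_bmi(anchors: pd.DataFrame, bmi: pd.DataFrame,
                          lo: pd.Series, hi: pd.Series,
                          proximity_days: int) -> pd.DataFrame:
    """Most proximate in-window measurement per anchor row
    (anchors: patient_id, anchor_date)."""
    need = pd.DataFrame({"patient_id": anchors["patient_id"],
                         "_anchor": anchors["anchor_date"].to_numpy(),
                         "_lo": lo.to_numpy(), "_hi": hi.to_numpy()})
    m = bmi.merge(need, on="patient_id")
    m = m[(m["date"] >= m["_lo"]) & (m["date"] <= m["_hi"])]
    m["_delta"] = (m["date"] - m["_anchor"]).dt.days
    m = m[m["_delta"].abs() <= proximity_days]
    if m.empty:
        return pd.DataFrame(columns=["patient_id", "bmi", "date"])
    m["_absd"] = m["_delta"].abs()
    m = m.sort_values(["patient_id", "_absd", "date"])
    best = m.groupby("patient_id").head(1)
    return best[["patient_id", "bmi", "date"]]


def _attach_anchor(members: pd.DataFrame, diagnoses: pd.DataFrame,
                   bmi: pd.DataFrame, windows: WindowSpec, which: str,
                   dictionary: Optional[CodeDictionary]) -> pd.DataFrame:
    """Shared cohort-2/3 logic: last any-weight code must be granular and
    have a proximate in-window measurement; anchors stored as columns
    prefixed ``{which}_``."""
    out = members.copy().reset_index(drop=True)
    if out.empty:
        for c in ("anchor_code", "anchor_date", "anchor_category",
                  "anchor_bmi", "anchor_bmi_date"):
            out[f"{which}_{c}"] = pd.Series(dtype=object)
        return out.iloc[0:0]
    if which == "preop":
        lo = out["index_date"] - pd.Timedelta(days=windows.preop_days)
        hi = out["index_date"]
    else:
        lo = out["index_date"] + pd.Timedelta(days=1)
        hi = out["index_date"] + pd.Timedelta(days=windows.postop_days)

    dx = classify_diagnoses(diagnoses, dictionary)
    dx = dx.copy()
    dx["date"] = pd.to_datetime(dx["date"])
    last = _vector_last_code(out, dx, lo, hi, "any_weight_code")
    last = last[last["kind"] == "granular"]
    last = last.rename(columns={"code": f"{which}_anchor_code",
                                "date": f"{which}_anchor_date",
                                "category": f"{which}_anchor_category"})
    out = out.merge(last[["patient_id", f"{which}_anchor_code",
                          f"{which}_anchor_date", f"{which}_anchor_category"]],
                    on="patient_id", how="inner")

    # window bounds realigned to the surviving members
    if which == "preop":
        lo = out["index_date"] - pd.Timedelta(days=windows.preop_days)
        hi = out["index_date"]
    else:
        lo = out["index_date"] + pd.Timedelta(days=1)
        hi = out["index_date"] + pd.Timedelta(days=windows.postop_days)
    b = bmi.copy()
    if len(b):
        b["date"] = pd.to_datetime(b["date"])
    anchors = pd.DataFrame({"patient_id": out["patient_id"],
                            "anchor_date": out[f"{which}_anchor_date"]})
    best = _vector_proximate_bmi(anchors, b, lo, hi, windows.proximity_days) \
        if len(b) else pd.DataFrame(columns=["patient_id", "bmi", "date"])
    best = best.rename(columns={"bmi": f"{which}_anchor_bmi",
                                "date": f"{which}_anchor_bmi_date"})
    out = out.merge(best, on="patient_id", how="inner")
    return out.reset_index(drop=True)


def build_cohort2(cohort1: pd.DataFrame, diagnoses: pd.DataFrame,
                  bmi: pd.DataFrame, windows: WindowSpec = WindowSpec(),
                  dictionary: Optional[CodeDictionary] = None) -> pd.DataFrame:
    """Tier 2: last preoperative weight code granular with a proximate
    preoperative EHR BMI measurement; anchors recorded."""
    out = _attach_anchor(cohort1, diagnoses, bmi, windows, "preop", dictionary)
    out["tier"] = 2
    return out


def build_cohort3(cohort2: pd.DataFrame, diagnoses: pd.DataFrame,
                  bmi: pd.DataFrame, windows: WindowSpec = WindowSpec(),
                  dictionary: Optional[CodeDictionary] = None) -> pd.DataFrame:
    """Tier 3: additionally, the last postoperative weight code is granular
    with a proximate measurement inside the postoperative window."""
    out = _attach_anchor(cohort2, diagnoses, bmi, windows, "postop", dictionary)
    out["tier"] = 3
    return out
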