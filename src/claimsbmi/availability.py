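"""Descriptive availability of weight-related diagnosis codes.

Each cohort member is assigned to exactly one of three mutually exclusive
classes per window — *granular* (>= 1 granular code in the window), else
*nonspecific-only*, else *none* — and tabulated overall and by operation
type, calendar year of the index operation, and ICD coding era (boundary
2015-10-01). Percentages are printed to one decimal with half-up rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

import pandas as pd

from .codes import CodeDictionary
from .cohorts import WindowSpec, classify_diagnoses

ERA_BOUNDARY = pd.Timestamp(date(2015, 10, 1))

CLASSES = ("granular", "nonspecific_only", "none")


def percent(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Half-up percentage to ``decimals`` places (the reporting convention
    throughout the package)."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    q = Decimal(1).scaleb(-decimals)
    val = (Decimal(numerator) * 100 / Decimal(denominator)).quantize(
        q, rounding=ROUND_HALF_UP)
    return float(val)


@dataclass(frozen=True)
class PresenceSummary:
    """Counts and printed percentages for one stratum."""

    stratum: dict
    n_granular: int
    n_nonspecific_only: int
    n_none: int

    @property
    def denominator(self) -> int:
        return self.n_granular + self.n_nonspecific_only + self.n_none

    @property
    def pct_granular(self) -> float:
        return percent(self.n_granular, self.denominator)

    @property
    def pct_nonspecific_only(self) -> float:
        return percent(self.n_nonspecific_only, self.denominator)

    @property
    def pct_none(self) -> float:
        return percent(self.n_none, self.denominator)

    @property
    def n_any_code(self) -> int:
        return self.n_granular + self.n_nonspecific_only

    def as_row(self) -> dict:
        row = dict(self.stratum)
        row.update(n=self.denominator,
                   n_granular=self.n_granular,
                   n_nonspecific_only=self.n_nonspecific_only,
                   n_none=self.n_none,
                   pct_granular=self.pct_granular,
                   pct_nonspecific_only=self.pct_nonspecific_only,
                   pct_none=self.pct_none)
        return row


def _presence_classes(members: pd.DataFrame, diagnoses: pd.DataFrame,
                      window_kind: str, windows: WindowSpec,
                      dictionary: Optional[CodeDictionary]) -> pd.Series:
    """Per-member class, indexed like ``members``."""
    if members.empty:
        return pd.Series(dtype=object)
    if window_kind == "preop":
        lo = members["index_date"] - pd.Timedelta(days=windows.preop_days)
        hi = members["index_date"]
    elif window_kind == "postop":
        lo = members["index_date"] + pd.Timedelta(days=1)
        hi = members["index_date"] + pd.Timedelta(days=windows.postop_days)
    else:
        raise ValueError("window_kind must be 'preop' or 'postop'")
    if diagnoses.empty:
        return pd.Series("none", index=members.index)
    dx = classify_diagnoses(diagnoses, dictionary)
    dx["date"] = pd.to_datetime(dx["date"])
    bounds = pd.DataFrame({"patient_id": members["patient_id"],
                           "_lo": lo.to_numpy(), "_hi": hi.to_numpy()})
    m = dx.merge(bounds, on="patient_id")
    m = m[(m["date"] >= m["_lo"]) & (m["date"] <= m["_hi"])]
    has_gran = set(m.loc[m["kind"] == "granular", "patient_id"])
    has_nonspec = set(m.loc[m["kind"] == "nonspecific", "patient_id"])

    def classify(pid):
        if pid in has_gran:
            return "granular"
        if pid in has_nonspec:
            return "nonspecific_only"
        return "none"

    return members["patient_id"].map(classify)


def code_presence(members: pd.DataFrame, diagnoses: pd.DataFrame,
                  window_kind: str = "preop",
                  windows: WindowSpec = WindowSpec(),
                  dictionary: Optional[CodeDictionary] = None,
                  stratum: Optional[dict] = None) -> PresenceSummary:
    """Overall presence summary for one window (empty cohort -> empty
    summary, not an error)."""
    cls = _presence_classes(members, diagnoses, window_kind, windows, dictionary)
    counts = cls.value_counts()
    return PresenceSummary(
        stratum=dict(stratum or {}, window=window_kind),
        n_granular=int(counts.get("granular", 0)),
        n_nonspecific_only=int(counts.get("nonspecific_only", 0)),
        n_none=int(counts.get("none", 0)),
    )


def stratified_presence(members: pd.DataFrame, diagnoses: pd.DataFrame,
                        window_kind: str = "preop",
                        strata: Sequence[str] = ("operation",),
                        windows: WindowSpec = WindowSpec(),
                        dictionary: Optional[CodeDictionary] = None,
                        ) -> list[PresenceSummary]:
    """One summary per stratum combination; stratum denominators partition
    the cohort. Strata: subset of {'operation', 'year', 'era'}."""
    valid = {"operation", "year", "era"}
    if not set(strata) <= valid:
        raise ValueError(f"strata must be a subset of {sorted(valid)}")
    mem = members.copy()
    mem["index_date"] = pd.to_datetime(mem["index_date"])
    keys = []
    for s in strata:
        if s == "operation":
            mem["_operation"] = mem["op_type"]
        elif s == "year":
            mem["_year"] = mem["index_date"].dt.year
        else:
            mem["_era"] = (mem["index_date"] >= ERA_BOUNDARY).map(
                {False: "ICD9CM", True: "ICD10CM"})
        keys.append(f"_{s}")
    out = []
    for vals, grp in mem.groupby(keys, sort=True):
        if not isinstance(vals, tuple):
            vals = (vals,)
        label = {s: v for s, v in zip(strata, vals)}
        out.append(code_presence(grp, diagnoses, window_kind, windows,
                                 dictionary, stratum=label))
    return out
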