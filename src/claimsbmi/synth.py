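"""Synthetic linked claims + EHR data with a controllable coding process.

Real validation studies of claims-based BMI phenotyping run against
proprietary linked warehouses; nothing downstream of this module ever sees
real data. The generator emulates the structure such studies rely on:

* one index bariatric operation per patient (AGB / RYGB / SG mix),
* a preoperative BMI distribution centered on the severe-obesity range,
* a linear first-year postoperative weight-loss trajectory,
* a claims *coding* process with configurable fidelity: at each encounter a
  weight-related diagnosis code may be emitted; granular codes draw their
  BMI category from a row-stochastic ``fidelity_kernel`` applied to the
  contemporaneous true category, with optional preoperative up-coding of
  the 30.0-34.9 category across the 35 kg/m^2 authorization threshold,
* the ICD-9-CM to ICD-10-CM switch on 2015-10-01,
* partial EHR linkage and Gaussian BMI measurement noise.

The latent truth (true BMI and category at every encounter) is retained so
tests can compare the emitted data against :func:`expected_agreement_matrix`,
the exact joint distribution of (coded category, measured category) implied
by the configuration.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator
from scipy import stats

from .codes import (
    CodeDictionary,
    CodingSystem,
    TEN_LEVELS,
    default_dictionary,
)

ICD10_SWITCH = date(2015, 10, 1)

N_LEVELS = 10
_EDGES = np.array([c.lower_bound for c in TEN_LEVELS] + [np.inf])  # len 11


class OpType(str, enum.Enum):
    AGB = "AGB"
    RYGB = "RYGB"
    SG = "SG"


def identity_kernel() -> tuple[tuple[float, ...], ...]:
    """Perfect coder: the coded category always equals the true category."""
    return tuple(tuple(np.eye(N_LEVELS)[i]) for i in range(N_LEVELS))


def tridiagonal_kernel(diag: float = 0.85) -> tuple[tuple[float, ...], ...]:
    """Adjacent-category error kernel: ``diag`` on the diagonal, the rest
    split evenly over the one or two adjacent categories."""
    if not 0.0 <= diag <= 1.0:
        raise ValueError("diag must be a probability")
    k = np.zeros((N_LEVELS, N_LEVELS))
    for i in range(N_LEVELS):
        k[i, i] = diag
        nbrs = [j for j in (i - 1, i + 1) if 0 <= j < N_LEVELS]
        for j in nbrs:
            k[i, j] = (1.0 - diag) / len(nbrs)
    return tuple(tuple(row) for row in k)


class GeneratorConfig(BaseModel):
    """All knobs of the synthetic world; defaults emulate the study
    conditions of a large US bariatric-surgery claims cohort (2011-2018)."""

    model_config = ConfigDict(frozen=True)

    n_patients: int = Field(ge=0)
    seed: int = 0
    accrual_start: date = date(2011, 1, 1)
    accrual_end: date = date(2018, 6, 30)
    op_mix: dict[OpType, float] = Field(
        default_factory=lambda: {OpType.AGB: 0.100, OpType.RYGB: 0.322, OpType.SG: 0.578}
    )
    # preoperative BMI, kg/m^2 (log-normal matched to mean/sd)
    preop_bmi_mean: float = Field(default=46.1, gt=0)
    preop_bmi_sd: float = Field(default=9.0, gt=0)
    # mean fractional BMI reduction at 1 year, per operation type
    postop_loss_fraction_by_op: dict[OpType, float] = Field(
        default_factory=lambda: {OpType.AGB: 0.15, OpType.RYGB: 0.30, OpType.SG: 0.25}
    )
    loss_fraction_sd: float = Field(default=0.05, ge=0)
    # per-encounter coding probabilities; the defaults are derived by
    # inverting the Poisson-encounter presence formula so that window-level
    # availability lands near the typical bariatric pattern (preop
    # granular/nonspecific-only/none ~ 93/5/2%, postop ~ 45/34/21%)
    p_any_code_preop: float = Field(default=0.53, ge=0, le=1)
    p_granular_given_code_preop: float = Field(default=0.70, ge=0, le=1)
    p_any_code_postop: float = Field(default=0.185, ge=0, le=1)
    p_granular_given_code_postop: float = Field(default=0.38, ge=0, le=1)
    fidelity_kernel: tuple[tuple[float, ...], ...] = Field(
        default_factory=tridiagonal_kernel
    )
    upcode_at_35: float = Field(default=0.60, ge=0, le=1)
    p_ehr_linked: float = Field(default=0.15, ge=0, le=1)
    # probability that a linked patient's encounter records a BMI vital;
    # < 1 makes the proximity restriction bind, as in real linked data
    p_bmi_given_encounter: float = Field(default=0.70, ge=0, le=1)
    ehr_noise_sd: float = Field(default=0.5, ge=0)
    # encounters per 30 days
    visit_rate_preop: float = Field(default=1.0, ge=0)
    visit_rate_postop: float = Field(default=0.7, ge=0)
    preop_horizon_days: int = Field(default=182, gt=0)
    postop_horizon_days: int = Field(default=365, gt=0)

    @field_validator("fidelity_kernel")
    @classmethod
    def _check_kernel(cls, v):
        arr = np.asarray(v, dtype=float)
        if arr.shape != (N_LEVELS, N_LEVELS):
            raise ValueError(f"fidelity_kernel must be {N_LEVELS}x{N_LEVELS}")
        if (arr < 0).any():
            raise ValueError("fidelity_kernel entries must be non-negative")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("fidelity_kernel rows must sum to 1")
        return v

    @model_validator(mode="after")
    def _check_mix(self):
        for name, mix in (("op_mix", self.op_mix),
                          ("postop_loss_fraction_by_op", self.postop_loss_fraction_by_op)):
            if set(mix) != set(OpType):
                raise ValueError(f"{name} must cover AGB, RYGB and SG")
        if not np.isclose(sum(self.op_mix.values()), 1.0, atol=1e-9):
            raise ValueError("op_mix must sum to 1")
        if any(p < 0 for p in self.op_mix.values()):
            raise ValueError("op_mix entries must be non-negative")
        if self.accrual_end < self.accrual_start:
            raise ValueError("accrual_end before accrual_start")
        return self

    def kernel_array(self) -> np.ndarray:
        return np.asarray(self.fidelity_kernel, dtype=float)

    def lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of ln(BMI) matched to the configured mean/sd."""
        m, s = self.preop_bmi_mean, self.preop_bmi_sd
        sigma2 = np.log1p((s / m) ** 2)
        return float(np.log(m) - sigma2 / 2.0), float(np.sqrt(sigma2))


@dataclass
class SyntheticWorld:
    """The five linked analysis tables plus the latent truth table."""

    patients: pd.DataFrame      # patient_id, age, sex, ehr_linked
    enrollment: pd.DataFrame    # patient_id, start, end
    procedures: pd.DataFrame    # patient_id, op_type, date, setting
    diagnoses: pd.DataFrame     # patient_id, code, system, date
    bmi: pd.DataFrame           # patient_id, bmi, date
    truth: pd.DataFrame         # patient_id, date, window, true_bmi,
                                # true_category, coded_category, code_kind
    config: Optional[GeneratorConfig] = field(default=None, repr=False)

    _TABLES = ("patients", "enrollment", "procedures", "diagnoses", "bmi", "truth")

    def to_csv(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False,
                                       date_format="%Y-%m-%d")

    @classmethod
    def from_csv(cls, indir) -> "SyntheticWorld":
        indir = Path(indir)
        date_cols = {"enrollment": ["start", "end"], "procedures": ["date"],
                     "diagnoses": ["date"], "bmi": ["date"], "truth": ["date"]}
        frames = {}
        for name in cls._TABLES:
            frames[name] = pd.read_csv(indir / f"{name}.csv",
                                       parse_dates=date_cols.get(name, []))
        return cls(**frames)


def _true_category(bmi: np.ndarray) -> np.ndarray:
    return np.clip(np.searchsorted(_EDGES[1:-1], bmi, side="right"), 0, N_LEVELS - 1)


def _empty_world(config: GeneratorConfig) -> SyntheticWorld:
    dt = "datetime64[ns]"
    return SyntheticWorld(
        patients=pd.DataFrame({"patient_id": pd.Series(dtype=int),
                               "age": pd.Series(dtype=int),
                               "sex": pd.Series(dtype=str),
                               "ehr_linked": pd.Series(dtype=bool)}),
        enrollment=pd.DataFrame({"patient_id": pd.Series(dtype=int),
                                 "start": pd.Series(dtype=dt),
                                 "end": pd.Series(dtype=dt)}),
        procedures=pd.DataFrame({"patient_id": pd.Series(dtype=int),
                                 "op_type": pd.Series(dtype=str),
                                 "date": pd.Series(dtype=dt),
                                 "setting": pd.Series(dtype=str)}),
        diagnoses=pd.DataFrame({"patient_id": pd.Series(dtype=int),
                                "code": pd.Series(dtype=str),
                                "system": pd.Series(dtype=str),
                                "date": pd.Series(dtype=dt)}),
        bmi=pd.DataFrame({"patient_id": pd.Series(dtype=int),
                          "bmi": pd.Series(dtype=float),
                          "date": pd.Series(dtype=dt)}),
        truth=pd.DataFrame({"patient_id": pd.Series(dtype=int),
                            "date": pd.Series(dtype=dt),
                            "window": pd.Series(dtype=str),
                            "true_bmi": pd.Series(dtype=float),
                            "true_category": pd.Series(dtype=int),
                            "coded_category": pd.Series(dtype=int),
                            "code_kind": pd.Series(dtype=str)}),
        config=config,
    )


def generate(config: GeneratorConfig,
             dictionary: Optional[CodeDictionary] = None) -> SyntheticWorld:
    """Draw one synthetic world.

    Reproducible for a fixed config (including seed); per-patient random
    substreams are spawned from the master seed so growing ``n_patients``
    leaves earlier patients unchanged.
    """
    dictionary = dictionary or default_dictionary()
    if config.n_patients == 0:
        return _empty_world(config)

    mu, sigma = config.lognormal_params()
    ops = list(OpType)
    mix = np.array([config.op_mix[o] for o in ops])
    mix = mix / mix.sum()
    loss_mean = {o: config.postop_loss_fraction_by_op[o] for o in ops}
    kernel_cum = np.cumsum(config.kernel_array(), axis=1)
    accrual_days = (config.accrual_end - config.accrual_start).days
    # all dates handled as integer days since the Unix epoch until the end
    epoch = date(1970, 1, 1)
    accrual_start_day = (config.accrual_start - epoch).days
    switch_day = (ICD10_SWITCH - epoch).days

    # (system, level) -> list of code strings; era-specific nonspecific pairs
    code_lists = {}
    for system in CodingSystem:
        for cat in TEN_LEVELS:
            code_lists[(system, cat.level_index)] = sorted(
                e.code for e in dictionary.codes_for_category(cat, system))
    nonspec = {(CodingSystem.ICD9CM, "unspecific"): "278.00",
               (CodingSystem.ICD9CM, "morbid"): "278.01",
               (CodingSystem.ICD10CM, "unspecific"): "E66.9",
               (CodingSystem.ICD10CM, "morbid"): "E66.01"}

    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)

    pat_rows, enr_rows, proc_rows = [], [], []
    dx_rows, bmi_rows, truth_rows = [], [], []

    for pid in range(config.n_patients):
        rng = np.random.default_rng(children[pid])
        age = int(np.clip(np.round(rng.normal(47.0, 12.3)), 18, 85))
        sex = "F" if rng.random() < 0.755 else "M"
        op = ops[rng.choice(len(ops), p=mix)]
        index_day = accrual_start_day + int(rng.integers(0, accrual_days + 1))
        setting = "inpatient" if rng.random() < 0.6 else "outpatient"
        linked = rng.random() < config.p_ehr_linked
        b0 = float(rng.lognormal(mu, sigma))
        loss = float(np.clip(rng.normal(loss_mean[op], config.loss_fraction_sd), 0.0, 0.6))

        pat_rows.append((pid, age, sex, linked))
        enr_rows.append((pid, index_day - config.preop_horizon_days - 30,
                         index_day + config.postop_horizon_days + 30))
        proc_rows.append((pid, op.value, index_day, setting))

        # encounter day offsets: negative = days before index, 0 = index day
        hp = config.preop_horizon_days
        n_pre = min(int(rng.poisson(config.visit_rate_preop * hp / 30.0)), hp)
        pre = -rng.choice(np.arange(1, hp + 1), size=n_pre, replace=False)
        hq = config.postop_horizon_days
        n_post = min(int(rng.poisson(config.visit_rate_postop * hq / 30.0)), hq)
        post = rng.choice(np.arange(1, hq + 1), size=n_post, replace=False)
        offsets = np.concatenate([np.sort(pre), [0], np.sort(post)]).astype(int)
        is_pre = offsets <= 0
        n_enc = offsets.size

        t = np.maximum(offsets, 0)
        true_bmi = b0 * (1.0 - loss * np.minimum(t, 365) / 365.0)
        true_cat = _true_category(true_bmi)
        days = index_day + offsets
        icd9 = days < switch_day

        # coding process
        p_any = np.where(is_pre, config.p_any_code_preop, config.p_any_code_postop)
        p_gran = np.where(is_pre, config.p_granular_given_code_preop,
                          config.p_granular_given_code_postop)
        has_code = rng.random(n_enc) < p_any
        granular = rng.random(n_enc) < p_gran
        u_kernel = rng.random(n_enc)
        coded = (u_kernel[:, None] >= kernel_cum[true_cat]).sum(axis=1)
        upcoded = (rng.random(n_enc) < config.upcode_at_35) & is_pre & (true_cat == 3)
        coded = np.where(upcoded, 4, coded)
        pick = rng.integers(0, 2 ** 31, size=n_enc)
        has_meas = linked & (rng.random(n_enc) < config.p_bmi_given_encounter)
        noise = rng.normal(0.0, 1.0, size=n_enc) * config.ehr_noise_sd

        for e in range(n_enc):
            window = "preop" if is_pre[e] else "postop"
            system = CodingSystem.ICD9CM if icd9[e] else CodingSystem.ICD10CM
            kind = "none"
            coded_cat = -1
            day = int(days[e])
            if has_code[e]:
                if granular[e]:
                    kind = "granular"
                    coded_cat = int(coded[e])
                    lst = code_lists[(system, coded_cat)]
                    code = lst[pick[e] % len(lst)]
                else:
                    kind = "nonspecific"
                    which = "morbid" if true_bmi[e] >= 35.0 else "unspecific"
                    code = nonspec[(system, which)]
                dx_rows.append((pid, code, system.value, day))
            if has_meas[e]:
                bmi_rows.append((pid, float(true_bmi[e] + noise[e]), day))
            truth_rows.append((pid, day, window, float(true_bmi[e]),
                               int(true_cat[e]), coded_cat, kind))

    def _frame(rows, columns, date_cols):
        df = pd.DataFrame(rows, columns=columns)
        for c in date_cols:
            df[c] = pd.to_datetime(df[c], unit="D")
        return df

    world = SyntheticWorld(
        patients=pd.DataFrame(pat_rows, columns=["patient_id", "age", "sex", "ehr_linked"]),
        enrollment=_frame(enr_rows, ["patient_id", "start", "end"], ["start", "end"]),
        procedures=_frame(proc_rows, ["patient_id", "op_type", "date", "setting"], ["date"]),
        diagnoses=_frame(dx_rows, ["patient_id", "code", "system", "date"], ["date"]),
        bmi=_frame(bmi_rows, ["patient_id", "bmi", "date"], ["date"]),
        truth=_frame(truth_rows, ["patient_id", "date", "window", "true_bmi",
                                  "true_category", "coded_category", "code_kind"], ["date"]),
        config=config,
    )
    return world


# ---------------------------------------------------------------------------
# analytic oracle


def _ref_probs(bmi: np.ndarray, noise_sd: float) -> np.ndarray:
    """P(measured category = j | true BMI), shape (n, 10)."""
    if noise_sd == 0:
        out = np.zeros((bmi.size, N_LEVELS))
        out[np.arange(bmi.size), _true_category(bmi)] = 1.0
        return out
    upper = stats.norm.cdf((_EDGES[1:][None, :] - bmi[:, None]) / noise_sd)
    lower = stats.norm.cdf((_EDGES[:-1][None, :] - bmi[:, None]) / noise_sd)
    return upper - lower


def _code_probs(true_cat: np.ndarray, kernel: np.ndarray,
                upcode: float, preop: bool) -> np.ndarray:
    """P(coded category = i | true category), shape (n, 10)."""
    rows = kernel[true_cat]
    if preop and upcode > 0:
        mask = true_cat == 3
        if mask.any():
            adj = rows[mask] * (1.0 - upcode)
            adj[:, 4] += upcode
            rows = rows.copy()
            rows[mask] = adj
    return rows


def expected_agreement_matrix(config: GeneratorConfig,
                              window: Literal["preop", "postop"]) -> np.ndarray:
    """Exact joint distribution P(coded category i, measured category j)
    at a random encounter in the window, conditional on a granular code and
    a BMI measurement being present.

    Computed by deterministic quantile-grid integration over the latent
    variables (baseline BMI; for the postoperative window also the
    operation type, the per-patient loss fraction and the encounter time),
    combined with the coding kernel, preoperative up-coding and the
    Gaussian measurement-noise model. Entries sum to 1.
    """
    if window not in ("preop", "postop"):
        raise ValueError("window must be 'preop' or 'postop'")
    mu, sigma = config.lognormal_params()
    kernel = config.kernel_array()
    lognorm = stats.lognorm(s=sigma, scale=np.exp(mu))

    joint = np.zeros((N_LEVELS, N_LEVELS))
    if window == "preop":
        nb = 100_000
        b = lognorm.ppf((np.arange(nb) + 0.5) / nb)
        w = np.full(nb, 1.0 / nb)
        code = _code_probs(_true_category(b), kernel, config.upcode_at_35, True)
        ref = _ref_probs(b, config.ehr_noise_sd)
        joint = np.einsum("n,ni,nj->ij", w, code, ref)
    else:
        nb, nl, nt = 1000, 16, 24
        b0 = lognorm.ppf((np.arange(nb) + 0.5) / nb)
        ql = (np.arange(nl) + 0.5) / nl
        # encounter times uniform over (0, horizon], loss plateau after day 365
        tt = (np.arange(nt) + 0.5) / nt * config.postop_horizon_days
        frac = np.minimum(tt, 365.0) / 365.0
        for op in OpType:
            p_op = config.op_mix[op]
            if p_op == 0:
                continue
            loss = np.clip(stats.norm.ppf(ql, loc=config.postop_loss_fraction_by_op[op],
                                          scale=config.loss_fraction_sd or 1e-12), 0.0, 0.6)
            b = (b0[:, None, None] * (1.0 - loss[None, :, None] * frac[None, None, :])).ravel()
            w = np.full(b.size, p_op / b.size)
            code = _code_probs(_true_category(b), kernel, config.upcode_at_35, False)
            ref = _ref_probs(b, config.ehr_noise_sd)
            joint += np.einsum("n,ni,nj->ij", w, code, ref)
    return joint / joint.sum()
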