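"""End-to-end orchestration: simulate/load -> cohorts -> classify ->
validate -> report.

Everything here is a thin sequencing layer over the other modules; the
run is fully determined by the configuration (including its seed), and a
manifest records the config hash, seed and row counts so reruns can be
checked byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import availability as avail
from .classify import AlgorithmConfig, build_classification_table
from .codes import SCALES, Scheme
from .cohorts import WindowSpec, build_cohort1, build_cohort2, build_cohort3
from .metrics import (
    AgreementTable,
    KappaResult,
    MetricResult,
    agreement_table,
    confusion_2x2,
    kappa_ci,
    per_level_metrics,
    suppress_small_cells,
)
from .synth import GeneratorConfig, SyntheticWorld, generate


@dataclass
class RunConfig:
    """One validation run; ``generator`` set => simulate mode, otherwise
    ``input_dir`` must point at the CSV tables."""

    generator: Optional[GeneratorConfig] = None
    input_dir: Optional[str] = None
    windows: WindowSpec = field(default_factory=WindowSpec)
    algorithm: AlgorithmConfig = field(default_factory=AlgorithmConfig)
    weight_scheme: str = "linear"
    ci_method: str = "asymptotic"
    n_boot: int = 2000
    seed: int = 0
    suppression_threshold: int = 10
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.generator is None and self.input_dir is None:
            raise ValueError("need either a generator config or an input_dir")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise FileNotFoundError(f"input_dir does not exist: {self.input_dir}")
        # the windows travel inside the algorithm config downstream
        self.algorithm = replace(self.algorithm, windows=self.windows)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.get("generator")
        win = WindowSpec(**raw.get("windows", {}))
        alg_raw = dict(raw.get("algorithm", {}))
        if "scheme" in alg_raw:
            alg_raw["scheme"] = Scheme(alg_raw["scheme"])
        alg = AlgorithmConfig(windows=win, **alg_raw)
        return cls(
            generator=GeneratorConfig(**gen) if gen else None,
            input_dir=raw.get("input_dir"),
            windows=win,
            algorithm=alg,
            weight_scheme=raw.get("weight_scheme", "linear"),
            ci_method=raw.get("ci_method", "asymptotic"),
            n_boot=raw.get("n_boot", 2000),
            seed=raw.get("seed", 0),
            suppression_threshold=raw.get("suppression_threshold", 10),
            out_dir=raw.get("out_dir"),
        )

    def config_hash(self) -> str:
        blob = {
            "generator": self.generator.model_dump(mode="json") if self.generator else None,
            "input_dir": self.input_dir,
            "windows": vars(self.windows),
            "algorithm": {"severe_threshold": self.algorithm.severe_threshold,
                          "scheme": self.algorithm.scheme.value,
                          "include_nonspecific": self.algorithm.include_nonspecific},
            "weight_scheme": self.weight_scheme,
            "ci_method": self.ci_method,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "suppression_threshold": self.suppression_threshold,
        }
        return hashlib.sha256(json.dumps(blob, sort_keys=True).encode()).hexdigest()


@dataclass
class WindowValidation:
    """Validation outputs for one window (preop or postop)."""

    window: str
    classification: pd.DataFrame
    table: Optional[AgreementTable]
    kappa: Optional[KappaResult]
    levels: list[MetricResult]
    severe: Optional[MetricResult] = None   # preop only

    @property
    def n_pairs(self) -> int:
        return self.table.n if self.table is not None else 0


@dataclass
class RunResult:
    config: RunConfig
    world: SyntheticWorld
    cohort1: pd.DataFrame
    cohort2: pd.DataFrame
    cohort3: pd.DataFrame
    attrition: dict
    preop: WindowValidation
    postop: WindowValidation
    availability_preop: avail.PresenceSummary
    availability_postop: avail.PresenceSummary
    availability_strata: pd.DataFrame
    report: str
    manifest: dict


def _validate_window(members: pd.DataFrame, world: SyntheticWorld,
                     window_kind: str, config: RunConfig) -> WindowValidation:
    alg = config.algorithm
    cls = build_classification_table(members, world.diagnoses, world.bmi,
                                     window_kind, alg)
    k = len(SCALES[alg.scheme])
    labels = [c.label for c in SCALES[alg.scheme]]
    ok = (cls["claims_level"] >= 0) & (cls["ref_level"] >= 0)
    table = kappa = None
    levels: list[MetricResult] = []
    if ok.any():
        table = agreement_table(cls.loc[ok, "claims_level"],
                                cls.loc[ok, "ref_level"], k, labels)
        kappa = kappa_ci(table, config.weight_scheme, method=config.ci_method,
                         n_boot=config.n_boot, seed=config.seed)
        levels = per_level_metrics(table)
    severe = None
    if window_kind == "preop" and len(cls):
        sv = cls[cls["severe_ehr"].notna()]
        if len(sv):
            severe = confusion_2x2(sv["severe_claims"].astype(bool),
                                   sv["severe_ehr"].astype(bool),
                                   label=f"BMI>={alg.severe_threshold}")
    return WindowValidation(window_kind, cls, table, kappa, levels, severe)


def _fmt_kappa(kr: Optional[KappaResult]) -> str:
    if kr is None or kr.kappa is None:
        return "NC"
    s = f"{kr.kappa:.2f}"
    if kr.ci_lower is not None:
        s += f" ({kr.ci_lower:.2f}, {kr.ci_upper:.2f})"
    return s


def render_report(preop: WindowValidation, postop: WindowValidation,
                  threshold: int, scheme: Scheme) -> str:
    """Human-readable validation report (per-level Se/Sp/PPV/NPV plus the
    weighted kappa for each window), with small-cell masking applied."""
    lines = [f"# BMI categorization algorithm validation ({scheme.value})", ""]
    lines.append(f"Preoperative pairs: {preop.n_pairs}; weighted kappa "
                 f"{_fmt_kappa(preop.kappa)}")
    lines.append(f"Postoperative pairs: {postop.n_pairs}; weighted kappa "
                 f"{_fmt_kappa(postop.kappa)}")
    lines.append("")
    header = ("| BMI category | Se (pre) | Sp (pre) | PPV (pre) | NPV (pre) "
              "| Se (post) | Sp (post) | PPV (post) | NPV (post) |")
    lines += [header, "|" + "---|" * 9]
    n_levels = max(len(preop.levels), len(postop.levels))
    for i in range(n_levels):
        pre = suppress_small_cells(preop.levels[i], threshold) \
            if i < len(preop.levels) else None
        post = suppress_small_cells(postop.levels[i], threshold) \
            if i < len(postop.levels) else None
        label = (pre or post)["label"]

        def cells(d):
            if d is None:
                return ["NC"] * 4
            return [d["sensitivity"], d["specificity"], d["ppv"], d["npv"]]

        lines.append("| " + " | ".join([label] + cells(pre) + cells(post)) + " |")
    if preop.severe is not None:
        d = suppress_small_cells(preop.severe, threshold)
        lines += ["", f"Severe obesity ({preop.severe.label}): "
                  f"Se {d['sensitivity']}, Sp {d['specificity']}, "
                  f"PPV {d['ppv']}, NPV {d['npv']} "
                  f"(TP={d['tp']}, FP={d['fp']}, TN={d['tn']}, FN={d['fn']})"]
    return "\n".join(lines) + "\n"


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full study pipeline; writes artifacts when ``out_dir``
    is set. Rerunning with the same config and seed reproduces every
    output byte."""
    if config.generator is not None:
        world = generate(config.generator)
        accrual = (config.generator.accrual_start, config.generator.accrual_end)
    else:
        world = SyntheticWorld.from_csv(config.input_dir)
        from datetime import date
        accrual = (date(2011, 1, 1), date(2018, 6, 30))

    cohort1, attrition = build_cohort1(world.patients, world.enrollment,
                                       world.procedures, world.diagnoses,
                                       config.windows, accrual[0], accrual[1])
    cohort2 = build_cohort2(cohort1, world.diagnoses, world.bmi, config.windows)
    cohort3 = build_cohort3(cohort2, world.diagnoses, world.bmi, config.windows)

    preop = _validate_window(cohort2, world, "preop", config)
    postop = _validate_window(cohort3, world, "postop", config)

    av_pre = avail.code_presence(cohort1, world.diagnoses, "preop", config.windows)
    av_post = avail.code_presence(cohort1, world.diagnoses, "postop", config.windows)
    strata_rows = []
    for kind in ("preop", "postop"):
        for s in ("operation", "year", "era"):
            if cohort1.empty:
                continue
            for summ in avail.stratified_presence(cohort1, world.diagnoses, kind,
                                                  (s,), config.windows):
                strata_rows.append(summ.as_row())
    strata = pd.DataFrame(strata_rows)

    report = render_report(preop, postop, config.suppression_threshold,
                           config.algorithm.scheme)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "rows": {
            "patients": int(len(world.patients)),
            "diagnoses": int(len(world.diagnoses)),
            "bmi": int(len(world.bmi)),
            "cohort1": int(len(cohort1)),
            "cohort2": int(len(cohort2)),
            "cohort3": int(len(cohort3)),
        },
        "attrition": attrition,
    }
    result = RunResult(config, world, cohort1, cohort2, cohort3, attrition,
                       preop, postop, av_pre, av_post, strata, report, manifest)
    if config.out_dir:
        _write_artifacts(result, Path(config.out_dir))
    return result


def _metric_rows(val: WindowValidation, threshold: int) -> list[dict]:
    rows = []
    for res in val.levels:
        masked = suppress_small_cells(res, threshold)
        rows.append({"window": val.window, "level": res.label,
                     "tp": res.tp, "fp": res.fp, "tn": res.tn, "fn": res.fn,
                     "sensitivity": res.sensitivity, "specificity": res.specificity,
                     "ppv": res.ppv, "npv": res.npv,
                     "sensitivity_masked": masked["sensitivity"],
                     "specificity_masked": masked["specificity"],
                     "ppv_masked": masked["ppv"], "npv_masked": masked["npv"]})
    return rows


def _write_artifacts(result: RunResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.world.to_csv(outdir / "world")
    for name in ("cohort1", "cohort2", "cohort3"):
        getattr(result, name).to_csv(outdir / f"{name}.csv", index=False)
    result.preop.classification.to_csv(outdir / "classification_preop.csv", index=False)
    result.postop.classification.to_csv(outdir / "classification_postop.csv", index=False)
    thr = result.config.suppression_threshold
    pd.DataFrame(_metric_rows(result.preop, thr)
                 + _metric_rows(result.postop, thr)
                 ).to_csv(outdir / "level_metrics.csv", index=False)
    kap_rows = []
    for val in (result.preop, result.postop):
        kr = val.kappa
        kap_rows.append({"window": val.window, "n_pairs": val.n_pairs,
                         "kappa": kr.kappa if kr else None,
                         "se": kr.se if kr else None,
                         "ci_lower": kr.ci_lower if kr else None,
                         "ci_upper": kr.ci_upper if kr else None,
                         "band": kr.band if kr else None})
    pd.DataFrame(kap_rows).to_csv(outdir / "kappa.csv", index=False)
    pd.DataFrame([result.availability_preop.as_row(),
                  result.availability_postop.as_row()]
                 ).to_csv(outdir / "availability.csv", index=False)
    result.availability_strata.to_csv(outdir / "availability_strata.csv", index=False)
    (outdir / "report.md").write_text(result.report)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2,
                                                     default=str))


SWEEP_AXES = ("proximity_days", "postop_window", "severe_threshold",
              "scheme", "include_nonspecific")


def sensitivity_sweep(config: RunConfig, axis: str,
                      values: Sequence) -> pd.DataFrame:
    """One full validation run per value of the axis; returns sample sizes
    and kappas (with CI) per value."""
    if axis not in SWEEP_AXES:
        raise ValueError(f"axis must be one of {SWEEP_AXES}")
    rows = []
    for v in values:
        win, alg = config.windows, config.algorithm
        if axis == "proximity_days":
            win = replace(win, proximity_days=int(v))
        elif axis == "postop_window":
            win = replace(win, postop_days=int(v))
        elif axis == "severe_threshold":
            alg = replace(alg, severe_threshold=int(v))
        elif axis == "scheme":
            alg = replace(alg, scheme=Scheme(v))
        else:
            alg = replace(alg, include_nonspecific=bool(v))
        sub = RunConfig(generator=config.generator, input_dir=config.input_dir,
                        windows=win, algorithm=replace(alg, windows=win),
                        weight_scheme=config.weight_scheme,
                        ci_method=config.ci_method, n_boot=config.n_boot,
                        seed=config.seed,
                        suppression_threshold=config.suppression_threshold)
        res = run_pipeline(sub)
        for val in (res.preop, res.postop):
            kr = val.kappa
            rows.append({"axis": axis, "value": v, "window": val.window,
                         "cohort2": len(res.cohort2), "cohort3": len(res.cohort3),
                         "n_pairs": val.n_pairs,
                         "kappa": kr.kappa if kr else None,
                         "ci_lower": kr.ci_lower if kr else None,
                         "ci_upper": kr.ci_upper if kr else None})
    return pd.DataFrame(rows)
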