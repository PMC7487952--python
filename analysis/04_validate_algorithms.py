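"""Validate the two claims-based algorithms against the EHR reference.

Severe-obesity classification (any code indicating BMI >= 35 kg/m^2
preoperatively) is scored with Se/Sp/PPV/NPV in cohort 2; the 10-level
BMI categorization is scored with per-level Se/Sp/PPV/NPV and the linear
weighted kappa in cohorts 2 (preop) and 3 (postop). Writes the metric
tables and a masked human-readable report.
"""

from pathlib import Path

from claimsbmi import GeneratorConfig, RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    cfg = RunConfig(generator=GeneratorConfig(n_patients=20_000, seed=20240901),
                    out_dir=str(ROOT / "validation"))
    res = run_pipeline(cfg)
    sv = res.preop.severe
    print(f"severe obesity (>=35): Se {100 * sv.sensitivity:.0f}%  "
          f"Sp {100 * sv.specificity:.0f}%  PPV {100 * sv.ppv:.0f}%  "
          f"NPV {100 * sv.npv:.0f}%  (n={sv.n})")
    for val in (res.preop, res.postop):
        kr = val.kappa
        print(f"{val.window}: weighted kappa {kr.kappa:.3f} "
              f"({kr.ci_lower:.3f}, {kr.ci_upper:.3f})  pairs={val.n_pairs}  "
              f"band={kr.band}")
    print(f"artifacts -> {ROOT / 'validation'}")
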