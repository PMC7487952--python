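"""Build the three nested study cohorts and report attrition.

Tier 1 applies the eligibility and washout rules around the index
operation; tiers 2 and 3 add the granular-anchor + proximate-measurement
requirements in the preoperative and postoperative windows. Writes the
cohort tables and the attrition log under results/.
"""

import json
from pathlib import Path

from claimsbmi import SyntheticWorld, build_cohort1, build_cohort2, build_cohort3

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    world = SyntheticWorld.from_csv(ROOT / "world")
    c1, attrition = build_cohort1(world.patients, world.enrollment,
                                  world.procedures, world.diagnoses)
    c2 = build_cohort2(c1, world.diagnoses, world.bmi)
    c3 = build_cohort3(c2, world.diagnoses, world.bmi)
    for name, df in (("cohort1", c1), ("cohort2", c2), ("cohort3", c3)):
        df.to_csv(ROOT / f"{name}.csv", index=False)
    (ROOT / "attrition.json").write_text(json.dumps(attrition, indent=2))
    print(f"cohort1={len(c1)}  cohort2={len(c2)}  cohort3={len(c3)}")
    print("attrition:", attrition)
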