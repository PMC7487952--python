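"""Tabulate weight-code availability before and after the operation.

For cohort 1, classifies each patient as having granular codes,
nonspecific codes only, or none, in each window, overall and stratified
by operation type, calendar year and ICD coding era.
"""

import pandas as pd
from pathlib import Path

from claimsbmi import SyntheticWorld, code_presence, stratified_presence

ROOT = Path(__file__).resolve().parent.parent / "results"

if __name__ == "__main__":
    world = SyntheticWorld.from_csv(ROOT / "world")
    c1 = pd.read_csv(ROOT / "cohort1.csv", parse_dates=["index_date"])
    rows = []
    for window in ("preop", "postop"):
        s = code_presence(c1, world.diagnoses, window)
        rows.append(s.as_row())
        print(f"{window}: granular {s.pct_granular}%  nonspecific-only "
              f"{s.pct_nonspecific_only}%  none {s.pct_none}%  (n={s.denominator})")
        for stratum in ("operation", "year", "era"):
            rows += [x.as_row() for x in
                     stratified_presence(c1, world.diagnoses, window, (stratum,))]
    pd.DataFrame(rows).to_csv(ROOT / "availability.csv", index=False)
    print(f"wrote {ROOT / 'availability.csv'}")
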