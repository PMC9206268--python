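#!/usr/bin/env python
"""Cross-system agreement: consistency ICC between CoP and LD parameters.

One ICC(3,1) with 95% CI per (age group, condition, parameter); writes
results/icc.csv and summarizes the dissociation between position-type
measures (distance, area: high agreement) and velocity measures (low
agreement, lowest in the older group).
"""

from pathlib import Path

import pandas as pd

from swaylab.agreement import icc_table, icc_to_frame

ROOT = Path(__file__).resolve().parents[1]


def main():
    params = pd.read_csv(ROOT / "results" / "parameters.csv")
    frame = icc_to_frame(icc_table(params))
    frame.to_csv(ROOT / "results" / "icc.csv", index=False)

    print(f"{len(frame)} ICC rows -> results/icc.csv\n")
    kind = frame.parameter.map(
        lambda p: "velocity" if p.startswith("velocity") else "position/area"
    )
    summary = frame.assign(kind=kind).groupby(["group", "kind"]).icc.agg(["min", "median", "max"])
    print("ICC by group and measure type:")
    print(summary.round(2).to_string())
    print("\nband counts:")
    print(frame.groupby(["group", "band"]).size().to_string())


if __name__ == "__main__":
    main()
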