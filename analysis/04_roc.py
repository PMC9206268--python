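#!/usr/bin/env python
"""ROC analysis: how well does each parameter separate the age groups?

One AUC + Youden cutpoint per (system, condition, parameter); writes
results/roc.csv and prints the per-condition ranking for the tracker (LD),
where the ML mean velocity is expected to lead in narrow stance.
"""

from pathlib import Path

import pandas as pd

from swaylab.discrimination import roc_table, roc_to_frame

ROOT = Path(__file__).resolve().parents[1]


def main():
    params = pd.read_csv(ROOT / "results" / "parameters.csv")
    frame = roc_to_frame(roc_table(params))
    frame.to_csv(ROOT / "results" / "roc.csv", index=False)

    print(f"{len(frame)} ROC rows -> results/roc.csv")
    for (stance, vision), cell in frame[frame.system == "LD"].groupby(
        ["stance", "vision"], sort=False
    ):
        top = cell.loc[cell.auc.idxmax()]
        print(f"LD {stance:>6}-{vision}: best AUC {top.auc:.2f} ({top.band}) "
              f"for {top.parameter}, cut {top.cut_point:.2f}, "
              f"sens {top.sensitivity:.2f} / spec {top.specificity:.2f}")


if __name__ == "__main__":
    main()
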