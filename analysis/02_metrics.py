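#!/usr/bin/env python
"""Compute the five sway parameters for every trial and average the two
repeats per condition.

Reads the simulated cohort written by 01_simulate.py back through the CSV
IO path (validation, unit normalization), applies the 5-Hz zero-phase
low-pass filter and per-trial demeaning, and writes the averaged parameter
table to results/parameters.csv.
"""

from pathlib import Path

import pandas as pd

from swaylab.study_pipeline import parameter_table
from swaylab.sway_io import (
    Stance,
    System,
    Vision,
    assemble_cohort,
    read_manifest,
    read_trial_csv,
)

ROOT = Path(__file__).resolve().parents[1]


def load_cohort(base: Path):
    subjects = read_manifest(base / "manifest.csv")
    trials = []
    for path in sorted((base / "trials").glob("*.csv")):
        sid, system, cond, rep = path.stem.rsplit("_", 3)
        stance_s, vision_s = cond.split("-")
        trials.append(
            read_trial_csv(
                path, System(system), subject_id=sid,
                stance=Stance.WIDE if stance_s == "W" else Stance.NARROW,
                vision=Vision(vision_s), repeat_index=int(rep[1:]),
            )
        )
    return assemble_cohort(subjects, trials)


def main():
    cohort = load_cohort(ROOT / "scratch" / "cohort")
    assert cohort.is_complete, "run 01_simulate.py first"
    params = parameter_table(cohort)
    out = ROOT / "results" / "parameters.csv"
    params.to_csv(out, index=False)

    print(f"{len(params)} condition-averaged rows -> {out}")
    med = params.groupby(["system", "stance", "vision"], sort=False)[
        ["velocity_ml", "distance_ap", "area_ce"]
    ].median().round(2)
    print("median parameters by condition:")
    print(med.to_string())


if __name__ == "__main__":
    main()
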