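#!/usr/bin/env python
"""Simulate the study cohort: 27 younger + 27 older adults, four stance
conditions, two repeats, recorded simultaneously by the pressure platform
(CoP) and the lumbar tracker (LD) at 100 Hz for 2 minutes.

Writes the cohort manifest and per-trial CSVs (sway_io dialect) under
scratch/cohort/, and the manifest alone under results/. Downstream scripts
re-read the trial files through the normal IO path, exercising the full
pipeline exactly as it would run on real exports.

Usage: python analysis/01_simulate.py [--seed 1] [--duration 120]
"""

import argparse
from pathlib import Path

import pandas as pd

from swaylab.sway_io import write_trial_csv
from swaylab.synthetic_sway import SimulationConfig, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--duration", type=float, default=120.0)
    args = ap.parse_args()

    cfg = SimulationConfig(seed=args.seed, duration_s=args.duration)
    cohort = simulate_cohort(cfg)

    out = ROOT / "scratch" / "cohort"
    (out / "trials").mkdir(parents=True, exist_ok=True)
    manifest = pd.DataFrame(
        [
            {"subject_id": s.subject_id, "sex": s.sex.value, "age": s.age,
             "height_cm": s.height_cm, "weight_kg": s.weight_kg}
            for s in cohort.subjects
        ]
    )
    manifest.to_csv(out / "manifest.csv", index=False)
    (ROOT / "results").mkdir(exist_ok=True)
    manifest.to_csv(ROOT / "results" / "manifest.csv", index=False)
    for key, trial in cohort.trials.items():
        name = f"{key.subject_id}_{key.system.value}_{key.condition}_r{key.repeat_index}.csv"
        write_trial_csv(trial, out / "trials" / name)

    ages = manifest.age
    print(f"cohort: {len(cohort.subjects)} subjects ({cfg.n_per_group}/group), "
          f"{len(cohort.trials)} trials of {cfg.duration_s:g} s at {cfg.fs:g} Hz")
    print(f"ages {ages.min():.0f}-{ages.max():.0f}; trials written to {out}")


if __name__ == "__main__":
    main()
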