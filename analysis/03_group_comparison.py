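#!/usr/bin/env python
"""Compare every sway parameter between the age groups.

Demographics table (sex chi-square, t tests for age/height/weight/BMI) and
the 40 per-cell younger-vs-older comparisons routed through the
Shapiro-Wilk normality gate (t test if both groups normal, Mann-Whitney U
otherwise). Writes results/demographics.csv and results/group_comparison.csv.
"""

from pathlib import Path

import pandas as pd

from swaylab.inferential_stats import compare_all_parameters, comparisons_to_frame
from swaylab.study_pipeline import demographics_table
from swaylab.sway_io import read_manifest

ROOT = Path(__file__).resolve().parents[1]


def main():
    params = pd.read_csv(ROOT / "results" / "parameters.csv")
    subjects = read_manifest(ROOT / "scratch" / "cohort" / "manifest.csv")

    demo = demographics_table(subjects)
    demo.to_csv(ROOT / "results" / "demographics.csv", index=False)

    comps = compare_all_parameters(params)
    frame = comparisons_to_frame(comps)
    frame.to_csv(ROOT / "results" / "group_comparison.csv", index=False)

    n_sig = int((frame.p_value < 0.05).sum())
    n_mw = int((frame.test_used == "MANN_WHITNEY").sum())
    print(f"{len(frame)} comparisons ({n_mw} routed to Mann-Whitney); "
          f"{n_sig} significant at 0.05 (no multiplicity correction)")
    print("\nmost discriminative cells (smallest p):")
    cols = ["system", "stance", "vision", "parameter", "test_used", "p_value"]
    print(frame.nsmallest(5, "p_value")[cols].to_string(index=False))


if __name__ == "__main__":
    main()
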