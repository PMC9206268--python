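"""End-to-end study orchestration.

``run_study`` takes either a simulation config or an assembled cohort and
executes the full chain: zero-phase low-pass filtering and demeaning of
every trial, computation of the five sway parameters, averaging of the two
repeats per condition, then the three reporting stages — demographics with
group tests, per-cell younger/older comparisons through the normality gate,
ROC/Youden discrimination, and cross-system consistency ICC. The report
carries a provenance block (config hash, seed, package version, filter
settings) sufficient to regenerate it bit-for-bit on simulated input.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, is_dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from swaylab.agreement import IccResult, icc_table, icc_to_frame
from swaylab.discrimination import RocResult, roc_table, roc_to_frame
from swaylab.inferential_stats import (
    GroupComparison,
    chi_square_2x2,
    compare_all_parameters,
    comparisons_to_frame,
    welch_or_student_t,
)
from swaylab.preprocess import DEFAULT_FILTER, FilterSpec, filtfilt_lowpass
from swaylab.sway_io import CONDITIONS, CohortTable, Group, Sex, Subject, System, TrialKey
from swaylab.sway_metrics import SwayParameters, compute_batch
from swaylab.synthetic_sway import SimulationConfig, simulate_cohort


class IncompleteCohortError(ValueError):
    pass


def parameter_table(
    cohort: CohortTable,
    filter_spec: FilterSpec = DEFAULT_FILTER,
    origin: str = "trial_mean",
) -> pd.DataFrame:
    """Averaged per-condition sway parameters for every subject and system.

    Each trial is filtered and demeaned, the five metrics computed, and the
    two repeats of each (subject, system, condition) averaged. Missing
    repeats fall back to the single available trial; fully missing cells
    yield NaN rows so downstream stages can drop them listwise.

    Filtering and metric computation are batched across trials of equal
    length (numerically identical to the per-trial path).
    """
    keys = list(cohort.trials)
    # batch trials by (fs, length) so one filtfilt call covers many trials
    batches: dict[tuple[float, int], list[TrialKey]] = {}
    for k in keys:
        t = cohort.trials[k]
        batches.setdefault((t.fs, t.n_samples), []).append(k)

    per_trial: dict[TrialKey, dict[str, float]] = {}
    for (fs, n), ks in batches.items():
        ml = np.stack([cohort.trials[k].ml for k in ks])
        ap = np.stack([cohort.trials[k].ap for k in ks])
        series = np.concatenate([ml, ap])
        filtered = filtfilt_lowpass(series, fs, filter_spec)
        ml_f, ap_f = filtered[: len(ks)], filtered[len(ks):]
        if origin == "trial_mean":
            ml_f = ml_f - ml_f.mean(axis=1, keepdims=True)
            ap_f = ap_f - ap_f.mean(axis=1, keepdims=True)
        metrics = compute_batch(ml_f, ap_f, fs)
        for i, k in enumerate(ks):
            per_trial[k] = {name: float(metrics[name][i]) for name in SwayParameters.NAMES}

    rows = []
    for subject in cohort.subjects:
        for system in System:
            for stance, vision in CONDITIONS:
                reps = [
                    per_trial.get(TrialKey(subject.subject_id, system, stance, vision, r))
                    for r in (1, 2)
                ]
                reps = [r for r in reps if r is not None]
                row: dict[str, Any] = {
                    "subject_id": subject.subject_id,
                    "group": subject.group.value,
                    "system": system.value,
                    "stance": stance.value,
                    "vision": vision.value,
                    "n_trials": len(reps),
                }
                for name in SwayParameters.NAMES:
                    row[name] = (
                        float(np.mean([r[name] for r in reps])) if reps else np.nan
                    )
                rows.append(row)
    return pd.DataFrame(rows)


def demographics_table(subjects: list[Subject]) -> pd.DataFrame:
    """Group descriptives with between-group tests: sex by Pearson χ²,
    continuous variables by the pooled t test."""
    younger = [s for s in subjects if s.group is Group.YOUNGER]
    older = [s for s in subjects if s.group is Group.OLDER]
    if len(younger) < 2 or len(older) < 2:
        raise IncompleteCohortError("need at least 2 subjects per group for demographics")

    rows = []
    m_y = sum(1 for s in younger if s.sex is Sex.M)
    m_o = sum(1 for s in older if s.sex is Sex.M)
    table = [[m_y, len(younger) - m_y], [m_o, len(older) - m_o]]
    try:
        _, p_sex = chi_square_2x2(table)
    except ValueError:
        p_sex = np.nan
    rows.append(
        {
            "variable": "male_n",
            "younger": m_y,
            "older": m_o,
            "younger_pct": 100.0 * m_y / len(younger),
            "older_pct": 100.0 * m_o / len(older),
            "p_value": p_sex,
            "test": "CHI_SQUARE",
        }
    )
    for var, get in (
        ("age_years", lambda s: s.age),
        ("height_cm", lambda s: s.height_cm),
        ("weight_kg", lambda s: s.weight_kg),
        ("bmi", lambda s: s.bmi),
    ):
        y = np.array([get(s) for s in younger])
        o = np.array([get(s) for s in older])
        _, _, p = welch_or_student_t(y, o, variant="student")
        rows.append(
            {
                "variable": var,
                "younger_mean": y.mean(),
                "younger_sd": y.std(ddof=1),
                "younger_min": y.min(),
                "younger_max": y.max(),
                "older_mean": o.mean(),
                "older_sd": o.std(ddof=1),
                "older_min": o.min(),
                "older_max": o.max(),
                "p_value": p,
                "test": "T_TEST",
            }
        )
    return pd.DataFrame(rows)


@dataclass
class StudyReport:
    demographics: pd.DataFrame
    parameters: pd.DataFrame
    comparisons: list[GroupComparison]
    roc: list[RocResult]
    icc: list[IccResult]
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def comparison_frame(self) -> pd.DataFrame:
        return comparisons_to_frame(self.comparisons)

    @property
    def roc_frame(self) -> pd.DataFrame:
        return roc_to_frame(self.roc)

    @property
    def icc_frame(self) -> pd.DataFrame:
        return icc_to_frame(self.icc)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.demographics.to_csv(out / "demographics.csv", index=False)
        self.parameters.to_csv(out / "parameters.csv", index=False)
        self.comparison_frame.to_csv(out / "group_comparison.csv", index=False)
        self.roc_frame.to_csv(out / "roc.csv", index=False)
        self.icc_frame.to_csv(out / "icc.csv", index=False)
        payload = {
            "provenance": self.provenance,
            "demographics": self.demographics.to_dict(orient="records"),
            "group_comparison": self.comparison_frame.to_dict(orient="records"),
            "roc": self.roc_frame.to_dict(orient="records"),
            "icc": self.icc_frame.to_dict(orient="records"),
        }
        with open(out / "report.json", "w") as fh:
            json.dump(payload, fh, indent=2, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if is_dataclass(obj):
        return asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _config_hash(cfg: SimulationConfig | None, filter_spec: FilterSpec) -> str:
    blob = json.dumps(
        {
            "simulate": asdict(cfg) if cfg is not None else None,
            "filter": asdict(filter_spec),
        },
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_study(
    source: SimulationConfig | CohortTable,
    filter_spec: FilterSpec = DEFAULT_FILTER,
    origin: str = "trial_mean",
    allow_incomplete: bool = False,
) -> StudyReport:
    """Execute the full analysis on a simulated or assembled cohort."""
    from swaylab import __version__

    sim_cfg = source if isinstance(source, SimulationConfig) else None
    cohort = simulate_cohort(source) if sim_cfg is not None else source
    missing = cohort.missing_cells()
    if missing and not allow_incomplete:
        raise IncompleteCohortError(
            f"cohort is missing {len(missing)} trial cells "
            f"(first: {missing[0]}); pass allow_incomplete=True to proceed listwise"
        )
    params = parameter_table(cohort, filter_spec, origin)
    report = StudyReport(
        demographics=demographics_table(cohort.subjects),
        parameters=params,
        comparisons=compare_all_parameters(params.dropna()),
        roc=roc_table(params),
        icc=icc_table(params),
        provenance={
            "software": f"swaylab {__version__}",
            "seed": sim_cfg.seed if sim_cfg is not None else None,
            "simulated": sim_cfg is not None,
            "n_subjects": len(cohort.subjects),
            "n_trials": len(cohort.trials),
            "missing_cells": len(missing),
            "filter": asdict(filter_spec),
            "origin": origin,
            "config_hash": _config_hash(sim_cfg, filter_spec),
        },
    )
    return report
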