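import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

from swaylab.cli import main as cli_main
from swaylab.preprocess import demean, lowpass_zero_phase
from swaylab.study_pipeline import (
    IncompleteCohortError,
    demographics_table,
    parameter_table,
    run_study,
)
from swaylab.sway_io import CohortTable, Subject
from swaylab.sway_metrics import compute_all


def _subjects(n_y=27, n_o=27, males_y=9, males_o=11):
    subs = []
    rng = np.random.default_rng(1)
    for i in range(n_y):
        subs.append(Subject(f"Y{i}", "M" if i < males_y else "F",
                            float(rng.integers(22, 54)), 164.0 + i % 5, 58.0 + i % 7))
    for i in range(n_o):
        subs.append(Subject(f"O{i}", "M" if i < males_o else "F",
                            float(rng.integers(55, 83)), 163.0 + i % 5, 62.0 + i % 7))
    return subs


class TestDemographicsTable:
    def test_study_sex_counts_reproduce_chi_square_p(self):
        table = demographics_table(_subjects())
        sex = table[table.variable == "male_n"].iloc[0]
        assert sex.younger == 9 and sex.older == 11
        assert sex.p_value == pytest.approx(0.573, abs=5e-4)

    def test_age_separation_significant(self):
        table = demographics_table(_subjects())
        age = table[table.variable == "age_years"].iloc[0]
        assert age.p_value < 0.001

    def test_mirrored_groups_give_unit_p(self):
        # same sex split and identical height/weight distributions
        subs = [Subject(f"Y{i}", "M" if i % 2 else "F", 30.0 + i, 160.0 + i, 55.0 + i)
                for i in range(4)]
        subs += [Subject(f"O{i}", "M" if i % 2 else "F", 60.0 + i, 160.0 + i, 55.0 + i)
                 for i in range(4)]
        table = demographics_table(subs)
        assert table[table.variable == "male_n"].iloc[0].p_value == pytest.approx(1.0)
        for var in ("height_cm", "weight_kg", "bmi"):
            assert table[table.variable == var].iloc[0].p_value == pytest.approx(1.0)

    def test_needs_two_per_group(self):
        with pytest.raises(IncompleteCohortError):
            demographics_table([Subject("Y1", "F", 30, 160, 55),
                                Subject("O1", "F", 60, 160, 55)])


class TestParameterTable:
    def test_batched_pipeline_matches_per_trial_path(self, small_cohort):
        params = parameter_table(small_cohort)
        key = next(iter(small_cohort.trials))
        rep1 = compute_all(demean(lowpass_zero_phase(small_cohort.trials[key])))
        other = small_cohort.trials[replace(key, repeat_index=3 - key.repeat_index)]
        rep2 = compute_all(demean(lowpass_zero_phase(other)))
        row = params[
            (params.subject_id == key.subject_id) & (params.system == key.system.value)
            & (params.stance == key.stance.value) & (params.vision == key.vision.value)
        ].iloc[0]
        for name in ("distance_ml", "velocity_ap", "area_ce"):
            expected = (getattr(rep1, name) + getattr(rep2, name)) / 2
            assert row[name] == pytest.approx(expected, rel=1e-9)

    def test_row_shape(self, small_params, small_cohort):
        assert len(small_params) == len(small_cohort.subjects) * 8
        assert small_params.n_trials.eq(2).all()


class TestRunStudy:
    def test_report_row_counts(self, small_config):
        report = run_study(small_config)
        assert len(report.roc) == 40
        assert len(report.icc) == 40
        assert len(report.comparisons) == 40

    def test_determinism_byte_identical_reports(self, tmp_path, small_config):
        run_study(small_config).write(tmp_path / "a")
        run_study(small_config).write(tmp_path / "b")
        for name in ("demographics.csv", "parameters.csv", "group_comparison.csv",
                     "roc.csv", "icc.csv", "report.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_provenance_records_settings(self, small_config):
        prov = run_study(small_config).provenance
        assert prov["seed"] == small_config.seed
        assert prov["simulated"] and prov["missing_cells"] == 0
        assert prov["filter"]["cutoff_hz"] == 5.0

    def test_incomplete_cohort_requires_flag(self, small_cohort):
        partial = CohortTable(subjects=small_cohort.subjects,
                              trials=dict(list(small_cohort.trials.items())[:-1]))
        with pytest.raises(IncompleteCohortError):
            run_study(partial)
        report = run_study(partial, allow_incomplete=True)
        assert report.provenance["missing_cells"] == 1


SMALL_YAML = """
io:
  expected_fs: 50.0
simulate:
  duration_s: 6.0
  fs: 50.0
"""


class TestCli:
    def _config(self, tmp_path):
        p = tmp_path / "config.yaml"
        p.write_text(SMALL_YAML)
        return str(p)

    def test_simulate_metrics_roundtrip(self, tmp_path):
        runner = CliRunner()
        out = tmp_path / "sim"
        res = runner.invoke(cli_main, [
            "--config", self._config(tmp_path),
            "simulate", "--seed", "3", "--n-per-group", "2", "--out-dir", str(out),
        ], catch_exceptions=False)
        assert res.exit_code == 0
        assert (out / "manifest.csv").exists()
        assert len(list((out / "trials").glob("*.csv"))) == 64

        res = runner.invoke(cli_main, [
            "--config", self._config(tmp_path),
            "metrics", "--manifest", str(out / "manifest.csv"),
            "--trials-dir", str(out / "trials"), "--out-dir", str(tmp_path / "m"),
        ], catch_exceptions=False)
        assert res.exit_code == 0
        params = pd.read_csv(tmp_path / "m" / "parameters.csv")
        assert len(params) == 4 * 8
        assert params.n_trials.eq(2).all()

    def test_run_study_simulated(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "--config", self._config(tmp_path),
            "run-study", "--simulate", "--seed", "7", "--n-per-group", "3",
            "--out-dir", str(tmp_path / "rep"),
        ], catch_exceptions=False)
        assert res.exit_code == 0
        report = json.loads((tmp_path / "rep" / "report.json").read_text())
        assert len(report["roc"]) == 40
        assert report["provenance"]["seed"] == 7

    def test_missing_seed_is_validation_failure(self, tmp_path):
        runner = CliRunner()
        res = runner.invoke(cli_main, [
            "run-study", "--simulate", "--out-dir", str(tmp_path / "rep"),
        ])
        assert res.exit_code == 2
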