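"""Reading, validation and normalization of sway recordings.

A *trial* is one two-minute bivariate position series — medial–lateral (ML)
and anterior–posterior (AP) — recorded at 100 Hz by one of two systems: the
pressure platform's center of pressure (``COP``) or the lumbar tracker's
displacement (``LD``). Trials arrive as plain CSV, one row per sample, with
a time column and the two position columns; the dialect (column mapping and
source unit) is configuration, not convention, because vendor exports vary.

Canonical internal units are millimetres for position (hence mm/s and mm²
downstream). Trials with missing samples, irregular timestamps, or a
sampling rate inconsistent with the declared one are rejected outright —
no imputation or resampling is attempted.
"""

from __future__ import annotations

import csv
import enum

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class System(str, enum.Enum):
    COP = "COP"
    LD = "LD"


class Stance(str, enum.Enum):
    WIDE = "WIDE"
    NARROW = "NARROW"


class Vision(str, enum.Enum):
    EO = "EO"
    EC = "EC"


class Group(str, enum.Enum):
    YOUNGER = "YOUNGER"
    OLDER = "OLDER"


class Sex(str, enum.Enum):
    M = "M"
    F = "F"


#: The four stance conditions in increasing order of task difficulty.
CONDITIONS: tuple[tuple[Stance, Vision], ...] = (
    (Stance.WIDE, Vision.EO),
    (Stance.WIDE, Vision.EC),
    (Stance.NARROW, Vision.EO),
    (Stance.NARROW, Vision.EC),
)

#: Age threshold (years) separating the younger and older groups.
OLDER_AGE_CUTOFF = 55.0


class MalformedInputError(ValueError):
    """Structural problem in an input file (timestamps, columns, values)."""


class RejectedTrialError(ValueError):
    """Trial fails a validity rule (e.g. missing samples) and is discarded."""


@dataclass(frozen=True)
class TrialKey:
    subject_id: str
    system: System
    stance: Stance
    vision: Vision
    repeat_index: int

    @property
    def condition(self) -> str:
        return condition_label(self.stance, self.vision)


def condition_label(stance: Stance, vision: Vision) -> str:
    return f"{'W' if stance is Stance.WIDE else 'N'}-{vision.value}"


@dataclass
class SwayTrial:
    """One bivariate sway recording from one system.

    ``ml`` and ``ap`` are position series in millimetres; ``fs`` is the
    sampling rate in Hz. The series are equal-length with no missing values.
    """

    subject_id: str
    system: System
    stance: Stance
    vision: Vision
    repeat_index: int
    fs: float
    ml: np.ndarray
    ap: np.ndarray

    def __post_init__(self) -> None:
        self.ml = np.asarray(self.ml, dtype=float)
        self.ap = np.asarray(self.ap, dtype=float)
        if self.ml.ndim != 1 or self.ap.ndim != 1:
            raise MalformedInputError("ml and ap must be 1-D series")
        if len(self.ml) != len(self.ap):
            raise MalformedInputError(
                f"ml and ap lengths differ ({len(self.ml)} vs {len(self.ap)})"
            )
        if len(self.ml) < 2:
            raise MalformedInputError("a trial needs at least 2 samples")
        if np.isnan(self.ml).any() or np.isnan(self.ap).any():
            raise RejectedTrialError(
                f"trial {self.key} contains missing values; trials with gaps are rejected"
            )
        if not self.fs > 0:
            raise MalformedInputError(f"fs must be positive, got {self.fs}")
        if self.repeat_index not in (1, 2):
            raise MalformedInputError(f"repeat_index must be 1 or 2, got {self.repeat_index}")

    @property
    def key(self) -> TrialKey:
        return TrialKey(self.subject_id, self.system, self.stance, self.vision, self.repeat_index)

    @property
    def n_samples(self) -> int:
        return len(self.ml)

    @property
    def duration_s(self) -> float:
        return (self.n_samples - 1) / self.fs

    def replace_series(self, ml: np.ndarray, ap: np.ndarray) -> "SwayTrial":
        return SwayTrial(
            subject_id=self.subject_id,
            system=self.system,
            stance=self.stance,
            vision=self.vision,
            repeat_index=self.repeat_index,
            fs=self.fs,
            ml=ml,
            ap=ap,
        )


@dataclass
class Subject:
    subject_id: str
    sex: Sex
    age: float
    height_cm: float
    weight_kg: float

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise MalformedInputError(f"subject {self.subject_id}: age must be positive")
        if self.height_cm <= 0 or self.weight_kg <= 0:
            raise MalformedInputError(
                f"subject {self.subject_id}: height and weight must be positive"
            )
        self.sex = Sex(self.sex)

    @property
    def bmi(self) -> float:
        # always recomputed; never trusted from file
        return self.weight_kg / (self.height_cm / 100.0) ** 2

    @property
    def group(self) -> Group:
        return Group.OLDER if self.age >= OLDER_AGE_CUTOFF else Group.YOUNGER


@dataclass
class CohortTable:
    """Subjects plus their trials, keyed by (subject, system, condition, repeat).

    A complete cohort has 2 systems × 4 conditions × 2 repeats = 16 trials
    per subject.
    """

    subjects: list[Subject]
    trials: dict[TrialKey, SwayTrial] = field(default_factory=dict)

    def subject(self, subject_id: str) -> Subject:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)

    def missing_cells(self) -> list[TrialKey]:
        """All (subject, system, condition, repeat) cells without a trial."""
        missing = []
        for s in self.subjects:
            for system in System:
                for stance, vision in CONDITIONS:
                    for rep in (1, 2):
                        k = TrialKey(s.subject_id, system, stance, vision, rep)
                        if k not in self.trials:
                            missing.append(k)
        return missing

    @property
    def is_complete(self) -> bool:
        return not self.missing_cells()

    def group_subjects(self, group: Group) -> list[Subject]:
        return [s for s in self.subjects if s.group is group]


@dataclass
class TrialDialect:
    """CSV layout of a trial export.

    ``unit`` is the source position unit (``"mm"`` or ``"m"``); metre exports
    (typical for tracker logs) are converted to mm on read. Columns may be
    named (strings) or positional (integers).
    """

    time_col: str | int = "time_s"
    ml_col: str | int = "ml"
    ap_col: str | int = "ap"
    unit: str = "mm"
    expected_fs: float = 100.0
    fs_tolerance: float = 0.01  # relative tolerance on inferred vs declared fs

    def __post_init__(self) -> None:
        if self.unit not in ("mm", "m"):
            raise MalformedInputError(f"unsupported unit {self.unit!r}; use 'mm' or 'm'")

    @property
    def scale_to_mm(self) -> float:
        return 1000.0 if self.unit == "m" else 1.0


def _resolve(df: pd.DataFrame, col: str | int, what: str) -> pd.Series:
    if isinstance(col, int):
        if col >= df.shape[1]:
            raise MalformedInputError(f"{what} column index {col} out of range")
        return df.iloc[:, col]
    if col not in df.columns:
        raise MalformedInputError(f"{what} column {col!r} not found (columns: {list(df.columns)})")
    return df[col]


def infer_fs(time_s: np.ndarray) -> float:
    """Sampling rate from the median time step.

    Raises on duplicate or non-monotone timestamps, and on irregular
    sampling (any step deviating from the median step by more than 1%).
    """
    steps = np.diff(time_s)
    bad = np.where(steps <= 0)[0]
    if bad.size:
        i = int(bad[0])
        kind = "duplicate" if steps[i] == 0 else "non-monotone"
        raise MalformedInputError(f"{kind} timestamp at row {i + 2} (t={time_s[i + 1]:g})")
    med = float(np.median(steps))
    irregular = np.where(np.abs(steps - med) > 0.01 * med)[0]
    if irregular.size:
        i = int(irregular[0])
        raise MalformedInputError(
            f"irregular sampling at row {i + 2}: step {steps[i]:g}s vs median {med:g}s"
        )
    return 1.0 / med


def read_trial_csv(
    path: str | Path,
    system: System,
    *,
    subject_id: str,
    stance: Stance,
    vision: Vision,
    repeat_index: int,
    dialect: TrialDialect | None = None,
) -> SwayTrial:
    """Read one trial CSV into a :class:`SwayTrial` in canonical units (mm).

    The sampling rate is inferred from the time column and must agree with
    the dialect's declared rate within its relative tolerance.
    """
    dialect = dialect or TrialDialect()
    path = Path(path)
    header = None if isinstance(dialect.time_col, int) else 0
    try:
        df = pd.read_csv(path, header=header)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MalformedInputError(f"{path}: cannot parse CSV ({exc})") from exc
    if df.shape[0] < 2:
        raise MalformedInputError(f"{path}: need at least 2 samples, got {df.shape[0]}")

    t = _resolve(df, dialect.time_col, "time").to_numpy(dtype=float)
    ml = _resolve(df, dialect.ml_col, "ML").to_numpy(dtype=float)
    ap = _resolve(df, dialect.ap_col, "AP").to_numpy(dtype=float)

    if np.isnan(t).any():
        raise MalformedInputError(f"{path}: missing timestamp at row {int(np.isnan(t).argmax()) + 2}")
    if np.isnan(ml).any() or np.isnan(ap).any():
        raise RejectedTrialError(f"{path}: missing position sample; trial rejected")

    fs = infer_fs(t)
    if abs(fs - dialect.expected_fs) > dialect.fs_tolerance * dialect.expected_fs:
        raise RejectedTrialError(
            f"{path}: inferred fs {fs:.3f} Hz differs from declared "
            f"{dialect.expected_fs:g} Hz by more than {dialect.fs_tolerance:.0%}"
        )

    return SwayTrial(
        subject_id=subject_id,
        system=system,
        stance=stance,
        vision=vision,
        repeat_index=repeat_index,
        fs=dialect.expected_fs,
        ml=ml * dialect.scale_to_mm,
        ap=ap * dialect.scale_to_mm,
    )


def write_trial_csv(trial: SwayTrial, path: str | Path, dialect: TrialDialect | None = None) -> None:
    """Write a trial back to CSV in the given dialect (default: mm, named columns)."""
    dialect = dialect or TrialDialect(expected_fs=trial.fs)
    scale = 1.0 / dialect.scale_to_mm
    t = np.arange(trial.n_samples) / trial.fs
    cols = {
        str(dialect.time_col): t,
        str(dialect.ml_col): trial.ml * scale,
        str(dialect.ap_col): trial.ap * scale,
    }
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6f")


def read_manifest(path: str | Path) -> list[Subject]:
    """Read the cohort manifest CSV (subject_id, sex, age, height_cm, weight_kg)."""
    path = Path(path)
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        required = {"subject_id", "sex", "age", "height_cm", "weight_kg"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise MalformedInputError(
                f"{path}: manifest must have columns {sorted(required)}, got {reader.fieldnames}"
            )
        subjects = []
        seen: set[str] = set()
        for i, row in enumerate(reader, start=2):
            sid = row["subject_id"].strip()
            if sid in seen:
                raise MalformedInputError(f"{path}: duplicate subject_id {sid!r} at row {i}")
            seen.add(sid)
            subjects.append(
                Subject(
                    subject_id=sid,
                    sex=Sex(row["sex"].strip().upper()),
                    age=float(row["age"]),
                    height_cm=float(row["height_cm"]),
                    weight_kg=float(row["weight_kg"]),
                )
            )
    return subjects


def assemble_cohort(subjects: Sequence[Subject], trials: Iterable[SwayTrial]) -> CohortTable:
    """Key trials by (subject, system, condition, repeat) into a cohort.

    Every trial's subject must appear in ``subjects``; an orphan trial is an
    error naming the offending subject id. Completeness is reported, not
    enforced: query :meth:`CohortTable.missing_cells`.
    """
    known = {s.subject_id for s in subjects}
    table = CohortTable(subjects=list(subjects))
    for trial in trials:
        if trial.subject_id not in known:
            raise MalformedInputError(
                f"trial references unknown subject {trial.subject_id!r}"
            )
        k = trial.key
        if k in table.trials:
            raise MalformedInputError(f"duplicate trial for {k}")
        table.trials[k] = trial
    return table
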