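"""Seeded synthetic dual-system sway cohorts.

The study protocol this emulates: two groups of adults (younger < 55 y,
older ≥ 55 y), four bipedal stance conditions (wide/narrow base × eyes
open/closed), two 2-minute trials per condition, recorded simultaneously at
100 Hz by a pressure platform (CoP) and a lumbar tracker (LD).

Generative model, per subject, axis (ML/AP), condition and repeat:

* a *shared slow component* — zero-phase-low-pass-shaped Gaussian noise
  (default bandwidth 0.3 Hz) — represents center-of-mass drift seen by both
  systems. Its amplitude scales with a per-axis base amplitude, a
  condition multiplier, an age-group multiplier, and a per-subject
  lognormal frailty shared across systems.
* the LD signal is the shared slow component (fraction ``lf_share`` of its
  variance) plus independent slow noise, plus a small band-limited
  *high-frequency regulatory component* (default 0.5–5 Hz).
* the CoP signal is the shared slow component plus a larger high-frequency
  component (``cop_hf_gain`` × the LD one): fast ankle-level corrections
  register at the plate, not at the lumbar level.

High-frequency amplitude scales with an age-group activity multiplier that
is larger in ML than AP (older adults' frontal-plane control requires more
regulatory activity) and with a per-subject, *per-system* lognormal
activity factor. Because the two systems' activity factors are independent
while the slow frailty is shared, distance/area measures agree well across
systems but velocity measures — dominated by the high-frequency content —
do not, and least of all in the older group. Group separation is likewise
strongest for velocity-ML. These are the qualitative patterns the
downstream ROC and ICC stages are expected to recover.

Everything is reproducible bit-for-bit from the master seed: every
(subject, condition, repeat) gets its own counter-based substream, so a
cohort can be partially regenerated without disturbing other trials.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
from scipy import signal

from swaylab.preprocess import FilterSpec, filtfilt_lowpass
from swaylab.sway_io import (
    CONDITIONS,
    CohortTable,
    Group,
    Sex,
    Stance,
    Subject,
    SwayTrial,
    System,
    Vision,
    condition_label,
)

CONDITION_ORDER = ("W-EO", "W-EC", "N-EO", "N-EC")


def _default_condition_mults() -> dict[str, dict[str, float]]:
    # ML grows more than AP when the base of support narrows.
    return {
        "ml": {"W-EO": 1.0, "W-EC": 1.25, "N-EO": 1.9, "N-EC": 2.5},
        "ap": {"W-EO": 1.0, "W-EC": 1.3, "N-EO": 1.45, "N-EC": 1.8},
    }


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    Amplitudes are in millimetres. ``group_*_mult`` apply to OLDER subjects
    only; the null (no-group-effect) model sets them all to 1.
    """

    seed: int = 0
    n_per_group: int = 27
    fs: float = 100.0
    duration_s: float = 120.0
    latent_cutoff_hz: float = 0.3
    base_amp_mm: dict[str, float] = field(default_factory=lambda: {"ml": 2.5, "ap": 3.5})
    hf_band_hz: tuple[float, float] = (0.5, 5.0)
    ld_hf_amp_mm: dict[str, float] = field(default_factory=lambda: {"ml": 0.12, "ap": 0.12})
    cop_hf_gain: float = 3.0
    group_amp_mult: float = 1.35
    group_hf_mult: dict[str, float] = field(default_factory=lambda: {"ml": 2.2, "ap": 1.5})
    condition_mults: dict[str, dict[str, float]] = field(default_factory=_default_condition_mults)
    lf_share: float = 0.9
    subject_amp_sigma: float = 0.35
    subject_act_sigma: float = 0.30

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")
        if not (0.0 < self.lf_share <= 1.0):
            raise ValueError("lf_share must be in (0, 1]")
        if not (0 < self.hf_band_hz[0] < self.hf_band_hz[1] < self.fs / 2):
            raise ValueError("hf_band_hz must satisfy 0 < lo < hi < Nyquist")
        if self.latent_cutoff_hz <= 0 or self.latent_cutoff_hz >= self.fs / 2:
            raise ValueError("latent_cutoff_hz must be in (0, Nyquist)")
        for name, val in [
            ("group_amp_mult", self.group_amp_mult),
            ("cop_hf_gain", self.cop_hf_gain),
            *[(f"group_hf_mult[{k}]", v) for k, v in self.group_hf_mult.items()],
            *[(f"base_amp_mm[{k}]", v) for k, v in self.base_amp_mm.items()],
            *[(f"ld_hf_amp_mm[{k}]", v) for k, v in self.ld_hf_amp_mm.items()],
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        for axis in ("ml", "ap"):
            mults = [self.condition_mults[axis][c] for c in CONDITION_ORDER]
            if any(m <= 0 for m in mults):
                raise ValueError(f"condition_mults[{axis}] must be positive")
            if any(b < a for a, b in zip(mults, mults[1:])):
                raise ValueError(
                    f"condition_mults[{axis}] must be non-decreasing across {CONDITION_ORDER}"
                )
        for cond in ("N-EO", "N-EC"):
            if self.condition_mults["ml"][cond] < self.condition_mults["ap"][cond]:
                raise ValueError(
                    "narrow-stance ML condition multipliers must be >= the AP ones"
                )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    def null(self) -> "SimulationConfig":
        """A copy with all age-group effects switched off."""
        return replace(
            self,
            group_amp_mult=1.0,
            group_hf_mult={"ml": 1.0, "ap": 1.0},
        )


# ---------------------------------------------------------------------------
# noise shaping

_GAIN_CACHE: dict[tuple, float] = {}


def _lowpass_gain(cutoff_hz: float, fs: float) -> float:
    """Std of zero-phase-low-passed unit white noise (for normalization)."""
    key = ("lp", cutoff_hz, fs)
    if key not in _GAIN_CACHE:
        sos = signal.butter(2, cutoff_hz, btype="low", fs=fs, output="sos")
        f, h = signal.sosfreqz(sos, worN=1 << 17, fs=fs)
        power = np.abs(h) ** 4  # forward-backward pass squares the magnitude
        _GAIN_CACHE[key] = float(np.sqrt(np.trapezoid(power, f) / (fs / 2)))
    return _GAIN_CACHE[key]


_SOS_BP_CACHE: dict[tuple, np.ndarray] = {}


def _bandpass_sos(band: tuple[float, float], fs: float):
    key = (band, fs)
    if key not in _SOS_BP_CACHE:
        _SOS_BP_CACHE[key] = signal.butter(2, band, btype="band", fs=fs, output="sos")
    return _SOS_BP_CACHE[key]


def _bandpass_gain(band: tuple[float, float], fs: float) -> float:
    key = ("bp", band, fs)
    if key not in _GAIN_CACHE:
        sos = _bandpass_sos(band, fs)
        f, h = signal.sosfreqz(sos, worN=1 << 17, fs=fs)
        power = np.abs(h) ** 4
        _GAIN_CACHE[key] = float(np.sqrt(np.trapezoid(power, f) / (fs / 2)))
    return _GAIN_CACHE[key]


def _shape_slow(white: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Low-pass shape white noise rows to unit-variance slow processes."""
    spec = FilterSpec(order=4, cutoff_hz=cfg.latent_cutoff_hz)
    return filtfilt_lowpass(white, cfg.fs, spec) / _lowpass_gain(cfg.latent_cutoff_hz, cfg.fs)


def _shape_hf(white: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Band-pass shape white noise rows to unit-variance regulatory processes."""
    sos = _bandpass_sos(cfg.hf_band_hz, cfg.fs)
    n = white.shape[-1]
    padlen = min(n - 1, 600)
    shaped = signal.sosfiltfilt(sos, white, axis=-1, padtype="even", padlen=padlen)
    return shaped / _bandpass_gain(cfg.hf_band_hz, cfg.fs)


# ---------------------------------------------------------------------------
# substreams

_SYS_CODE = {System.COP: 1, System.LD: 2}
_COND_CODE = {c: i for i, c in enumerate(CONDITION_ORDER)}


def _sid_int(subject_id: str) -> int:
    return zlib.crc32(subject_id.encode())


def _trial_rng(cfg: SimulationConfig, subject_id: str, stance, vision, repeat_index: int):
    cond = _COND_CODE[condition_label(stance, vision)]
    ss = np.random.SeedSequence([cfg.seed, 1, _sid_int(subject_id), cond, repeat_index])
    return np.random.default_rng(ss)


def _subject_rng(cfg: SimulationConfig, subject_id: str):
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, 2, _sid_int(subject_id)]))


def _cohort_rng(cfg: SimulationConfig):
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))


@dataclass(frozen=True)
class _SubjectFactors:
    frailty: float
    act_cop: float
    act_ld: float


def _subject_factors(cfg: SimulationConfig, subject_id: str) -> _SubjectFactors:
    rng = _subject_rng(cfg, subject_id)
    z = rng.standard_normal(3)
    return _SubjectFactors(
        frailty=float(np.exp(cfg.subject_amp_sigma * z[0])),
        act_cop=float(np.exp(cfg.subject_act_sigma * z[1])),
        act_ld=float(np.exp(cfg.subject_act_sigma * z[2])),
    )


# ---------------------------------------------------------------------------
# trial synthesis

def _pair_from_noise(
    subject: Subject,
    stance: Stance,
    vision: Vision,
    repeat_index: int,
    cfg: SimulationConfig,
    slow_unit: np.ndarray,  # (4, N): latent ml, latent ap, ld-extra ml, ld-extra ap
    hf_unit: np.ndarray,  # (4, N): ld hf ml, ld hf ap, cop hf ml, cop hf ap
    factors: _SubjectFactors,
) -> tuple[SwayTrial, SwayTrial]:
    older = subject.group is Group.OLDER
    cond = condition_label(stance, vision)
    cop = {}
    ld = {}
    for j, axis in enumerate(("ml", "ap")):
        cmult = cfg.condition_mults[axis][cond]
        amp = cfg.base_amp_mm[axis] * cmult * factors.frailty
        hf_amp = cfg.ld_hf_amp_mm[axis] * cmult
        if older:
            amp *= cfg.group_amp_mult
            hf_amp *= cfg.group_hf_mult[axis]
        latent = slow_unit[j]
        extra = slow_unit[2 + j]
        slow_ld = np.sqrt(cfg.lf_share) * latent + np.sqrt(1.0 - cfg.lf_share) * extra
        ld[axis] = amp * slow_ld + hf_amp * factors.act_ld * hf_unit[j]
        cop[axis] = amp * latent + cfg.cop_hf_gain * hf_amp * factors.act_cop * hf_unit[2 + j]
    meta = dict(
        subject_id=subject.subject_id,
        stance=stance,
        vision=vision,
        repeat_index=repeat_index,
        fs=cfg.fs,
    )
    return (
        SwayTrial(system=System.COP, ml=cop["ml"], ap=cop["ap"], **meta),
        SwayTrial(system=System.LD, ml=ld["ml"], ap=ld["ap"], **meta),
    )


def simulate_trial_pair(
    subject: Subject,
    stance: Stance,
    vision: Vision,
    repeat_index: int,
    config: SimulationConfig,
) -> tuple[SwayTrial, SwayTrial]:
    """Simultaneous CoP and LD recordings for one trial of one subject.

    Deterministic in (config.seed, subject_id, condition, repeat): the same
    cell regenerates identically regardless of what else is simulated.
    """
    rng = _trial_rng(config, subject.subject_id, stance, vision, repeat_index)
    white = rng.standard_normal((8, config.n_samples))
    slow_unit = _shape_slow(white[:4], config)
    hf_unit = _shape_hf(white[4:], config)
    factors = _subject_factors(config, subject.subject_id)
    return _pair_from_noise(
        subject, stance, vision, repeat_index, config, slow_unit, hf_unit, factors
    )


def _simulate_subjects(cfg: SimulationConfig) -> list[Subject]:
    rng = _cohort_rng(cfg)
    subjects = []
    for group, (lo, hi) in ((Group.YOUNGER, (22, 53)), (Group.OLDER, (55, 82))):
        for i in range(cfg.n_per_group):
            sid = f"{'Y' if group is Group.YOUNGER else 'O'}{i + 1:03d}"
            age = int(rng.integers(lo, hi + 1))
            sex = Sex.M if rng.random() < 0.37 else Sex.F
            height = float(np.clip(rng.normal(164.0, 7.3), 149.0, 180.0))
            mean_w = 58.0 if group is Group.YOUNGER else 62.8
            weight = float(np.clip(rng.normal(mean_w, 11.0), 44.0, 93.0))
            subjects.append(
                Subject(
                    subject_id=sid,
                    sex=sex,
                    age=float(age),
                    height_cm=round(height, 1),
                    weight_kg=round(weight, 1),
                )
            )
    return subjects


def _iter_cells(subject: Subject) -> Iterator[tuple[Stance, Vision, int]]:
    for stance, vision in CONDITIONS:
        for rep in (1, 2):
            yield stance, vision, rep


def simulate_cohort(config: SimulationConfig, subjects: list[Subject] | None = None) -> CohortTable:
    """A complete cohort: ``n_per_group`` subjects per group, 16 trials each.

    Noise shaping is batched per subject (one filter call per band over all
    of the subject's trials), which is numerically identical to calling
    :func:`simulate_trial_pair` cell by cell.
    """
    if subjects is None:
        subjects = _simulate_subjects(config)
    cohort = CohortTable(subjects=subjects)
    n = config.n_samples
    for subject in subjects:
        cells = list(_iter_cells(subject))
        white = np.empty((len(cells) * 8, n))
        for i, (stance, vision, rep) in enumerate(cells):
            rng = _trial_rng(config, subject.subject_id, stance, vision, rep)
            white[i * 8 : (i + 1) * 8] = rng.standard_normal((8, n))
        rows = white.reshape(len(cells), 8, n)
        slow_unit = _shape_slow(rows[:, :4].reshape(-1, n), config).reshape(len(cells), 4, n)
        hf_unit = _shape_hf(rows[:, 4:].reshape(-1, n), config).reshape(len(cells), 4, n)
        factors = _subject_factors(config, subject.subject_id)
        for i, (stance, vision, rep) in enumerate(cells):
            cop, ld = _pair_from_noise(
                subject, stance, vision, rep, config, slow_unit[i], hf_unit[i], factors
            )
            cohort.trials[cop.key] = cop
            cohort.trials[ld.key] = ld
    return cohort
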