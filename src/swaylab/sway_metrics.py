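"""The five stabilogram summary measures.

For a preprocessed (filtered, demeaned) bivariate trial x[n] (ML), y[n]
(AP), n = 0..N-1 sampled at fs:

* mean distance per axis: (1/N) Σ |x[n]| — the average absolute deviation
  from the sway origin; an effectiveness-of-control measure.
* mean velocity per axis: Σ |x[n+1] − x[n]| / T with T = (N−1)/fs — sway
  path length per unit time; an amount-of-regulatory-activity measure.
* AREA-CE: the area of the 95% bivariate confidence ellipse,
  2π · F(α=0.05; 2, N−2) · sqrt(s_x² s_y² − s_xy²), with unbiased sample
  (co)variances and the exact F quantile (not the large-N constant 3.00).

All five are nonnegative, invariant to time reversal and (after demeaning)
to translation, and scale as c (distances, velocities) or c² (area) under
position scaling by c > 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from swaylab.sway_io import SwayTrial


@dataclass
class SwayParameters:
    """The five scalar sway measures for one trial or one averaged condition."""

    distance_ml: float
    distance_ap: float
    velocity_ml: float
    velocity_ap: float
    area_ce: float
    n_samples: int
    duration_s: float
    key: tuple | None = None  # (subject_id, system, stance, vision)

    #: Canonical parameter order used throughout reports.
    NAMES = ("distance_ml", "distance_ap", "velocity_ml", "velocity_ap", "area_ce")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.NAMES}


def mean_distance(series: np.ndarray) -> float:
    """Mean absolute deviation of a (zero-mean) position series, in mm."""
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("mean_distance needs at least 2 samples")
    return float(np.mean(np.abs(series)))


def mean_velocity(series: np.ndarray, fs: float) -> float:
    """Path length per unit time along one axis, in mm/s.

    T = (N−1)/fs: a path of N points has N−1 segments.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 2:
        raise ValueError("mean_velocity needs at least 2 samples")
    total_path = float(np.sum(np.abs(np.diff(series))))
    return total_path * fs / (series.size - 1)


def confidence_ellipse_area(ml: np.ndarray, ap: np.ndarray, level: float = 0.95) -> float:
    """Area (mm²) of the ``level`` bivariate confidence ellipse of the sway cloud.

    The ellipse {z : zᵀ S⁻¹ z ≤ 2·F} with S the unbiased sample covariance
    and F the upper-(1−level) quantile of F(2, N−2) has area
    2π·F·sqrt(det S). A degenerate (collinear or constant) trajectory has
    zero determinant and hence zero area; tiny negative determinants from
    rounding are clamped to 0.
    """
    ml = np.asarray(ml, dtype=float)
    ap = np.asarray(ap, dtype=float)
    if ml.size != ap.size:
        raise ValueError("ml and ap must have equal length")
    n = ml.size
    if n < 3:
        raise ValueError("confidence_ellipse_area needs at least 3 samples")
    s_ml = np.var(ml, ddof=1)
    s_ap = np.var(ap, ddof=1)
    s_cross = np.cov(ml, ap, ddof=1)[0, 1]
    det = s_ml * s_ap - s_cross**2
    if det < 0:
        det = 0.0
    f_quant = stats.f.isf(1.0 - level, 2, n - 2)
    return float(2.0 * np.pi * f_quant * np.sqrt(det))


def ellipse_coverage(ml: np.ndarray, ap: np.ndarray, level: float = 0.95) -> float:
    """Fraction of points inside the fitted ``level`` confidence ellipse."""
    ml = np.asarray(ml, dtype=float) - np.mean(ml)
    ap = np.asarray(ap, dtype=float) - np.mean(ap)
    n = ml.size
    cov = np.cov(ml, ap, ddof=1)
    inv = np.linalg.inv(cov)
    q = inv[0, 0] * ml**2 + 2 * inv[0, 1] * ml * ap + inv[1, 1] * ap**2
    f_quant = stats.f.isf(1.0 - level, 2, n - 2)
    return float(np.mean(q <= 2.0 * f_quant))


def compute_all(trial: SwayTrial) -> SwayParameters:
    """Bundle the five measures for one preprocessed trial."""
    return SwayParameters(
        distance_ml=mean_distance(trial.ml),
        distance_ap=mean_distance(trial.ap),
        velocity_ml=mean_velocity(trial.ml, trial.fs),
        velocity_ap=mean_velocity(trial.ap, trial.fs),
        area_ce=confidence_ellipse_area(trial.ml, trial.ap),
        n_samples=trial.n_samples,
        duration_s=trial.duration_s,
        key=(trial.subject_id, trial.system, trial.stance, trial.vision),
    )


def compute_batch(ml: np.ndarray, ap: np.ndarray, fs: float, level: float = 0.95) -> dict[str, np.ndarray]:
    """Vectorized metrics for many trials at once (rows = trials).

    Returns arrays keyed by parameter name; exactly equivalent to calling
    the scalar operations row by row (tested), but orders of magnitude
    faster for simulation studies.
    """
    ml = np.atleast_2d(np.asarray(ml, dtype=float))
    ap = np.atleast_2d(np.asarray(ap, dtype=float))
    if ml.shape != ap.shape:
        raise ValueError("ml and ap batches must have the same shape")
    n = ml.shape[1]
    if n < 3:
        raise ValueError("batched metrics need at least 3 samples per trial")
    t = (n - 1) / fs

    mlc = ml - ml.mean(axis=1, keepdims=True)
    apc = ap - ap.mean(axis=1, keepdims=True)
    s_ml = np.sum(mlc**2, axis=1) / (n - 1)
    s_ap = np.sum(apc**2, axis=1) / (n - 1)
    s_cross = np.sum(mlc * apc, axis=1) / (n - 1)
    det = np.clip(s_ml * s_ap - s_cross**2, 0.0, None)
    f_quant = stats.f.isf(1.0 - level, 2, n - 2)

    return {
        "distance_ml": np.mean(np.abs(ml), axis=1),
        "distance_ap": np.mean(np.abs(ap), axis=1),
        "velocity_ml": np.sum(np.abs(np.diff(ml, axis=1)), axis=1) / t,
        "velocity_ap": np.sum(np.abs(np.diff(ap, axis=1)), axis=1) / t,
        "area_ce": 2.0 * np.pi * f_quant * np.sqrt(det),
    }
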