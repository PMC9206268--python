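"""Cross-system agreement via the consistency intraclass correlation.

Each subject contributes one averaged parameter value per system (CoP and
LD), giving an n×2 table per condition and age group. Agreement is the
single-measure two-way mixed-effects consistency ICC — ICC(3,1) in the
Shrout–Fleiss taxonomy — which is insensitive to a fixed additive offset
between the two measurement systems (their origins are physically
different), but penalizes subject-ordering disagreement.

From the two-way ANOVA decomposition with n subjects and k = 2 systems:

    ICC(3,1) = (MS_R − MS_E) / (MS_R + (k−1)·MS_E)

with MS_R the between-subjects and MS_E the residual mean square. The 95%
CI uses the F-interval (McGraw–Wong) method with F = MS_R/MS_E on
(n−1, (n−1)(k−1)) degrees of freedom, which also gives the p-value for
H₀: ICC = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from swaylab.sway_io import Group, System
from swaylab.sway_metrics import SwayParameters


class UndefinedIccError(ValueError):
    pass


@dataclass
class IccResult:
    group: str
    stance: str
    vision: str
    parameter: str
    icc: float
    ci_low: float
    ci_high: float
    f_stat: float
    p_value: float
    band: str
    n: int

    @property
    def stars(self) -> str:
        if self.p_value <= 0.001:
            return "***"
        if self.p_value <= 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def _anova_two_way(data: np.ndarray) -> tuple[float, float, float]:
    """(MS_R, MS_C, MS_E) for an n×k complete two-way layout."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((data - grand) ** 2))
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    return ms_r, ms_c, ms_e


def icc_consistency(
    paired: np.ndarray | Sequence[Sequence[float]],
    ci_level: float = 0.95,
    **meta,
) -> IccResult:
    """ICC(3,1) with F-method CI and p-value for an n×2 paired table.

    Rows are subjects, columns the two systems. Raises
    :class:`UndefinedIccError` when the between-subject variance is zero
    (the subject ordering carries no information to agree on).
    """
    data = np.asarray(paired, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError("paired must be an n×2 table")
    if np.isnan(data).any():
        raise ValueError("paired table must be complete (drop incomplete pairs first)")
    n, k = data.shape
    if n < 3:
        raise ValueError(f"ICC needs at least 3 complete pairs, got {n}")
    ms_r, _, ms_e = _anova_two_way(data)
    scale = max(float(np.var(data)), 1.0)
    if ms_r <= 1e-12 * scale:
        raise UndefinedIccError("zero between-subject variance; ICC undefined")

    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    df1, df2 = n - 1, (n - 1) * (k - 1)
    if ms_e == 0.0:
        f_stat, p = np.inf, 0.0
        lo = hi = 1.0
    else:
        f_stat = ms_r / ms_e
        p = float(stats.f.sf(f_stat, df1, df2))
        alpha = 1.0 - ci_level
        f_l = f_stat / stats.f.isf(alpha / 2.0, df1, df2)
        f_u = f_stat * stats.f.isf(alpha / 2.0, df2, df1)
        lo = (f_l - 1.0) / (f_l + k - 1.0)
        hi = (f_u - 1.0) / (f_u + k - 1.0)
    defaults = dict(group="", stance="", vision="", parameter="")
    defaults.update(meta)
    return IccResult(
        icc=float(icc),
        ci_low=float(lo),
        ci_high=float(hi),
        f_stat=float(f_stat),
        p_value=p,
        band=icc_band(float(icc)),
        n=n,
        **defaults,
    )


def icc_band(icc: float) -> str:
    """Interpretation: < 0.5 POOR, [0.5, 0.75) MODERATE, [0.75, 0.9] GOOD,
    (0.9, 1] EXCELLENT (0.9 exactly counts as GOOD)."""
    if icc > 1.0:
        raise ValueError(f"ICC cannot exceed 1, got {icc}")
    if icc > 0.9:
        return "EXCELLENT"
    if icc >= 0.75:
        return "GOOD"
    if icc >= 0.5:
        return "MODERATE"
    return "POOR"


def icc_table(params: pd.DataFrame) -> list[IccResult]:
    """One ICC row per (age group, condition, parameter) — 40 rows for a
    complete cohort. Incomplete CoP/LD pairs are dropped listwise per cell."""
    out = []
    for group in (Group.YOUNGER, Group.OLDER):
        sub = params[params["group"] == group.value]
        for (stance, vision), cell in sub.groupby(["stance", "vision"], sort=False):
            wide = cell.pivot_table(
                index="subject_id", columns="system", values=list(SwayParameters.NAMES),
                sort=False,
            )
            for name in SwayParameters.NAMES:
                pair = wide[name][[System.COP.value, System.LD.value]].dropna()
                out.append(
                    icc_consistency(
                        pair.to_numpy(),
                        group=group.value,
                        stance=stance,
                        vision=vision,
                        parameter=name,
                    )
                )
    return out


def icc_to_frame(results: list[IccResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "group": r.group,
                "stance": r.stance,
                "vision": r.vision,
                "parameter": r.parameter,
                "icc": r.icc,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "f_stat": r.f_stat,
                "p_value": r.p_value,
                "stars": r.stars,
                "band": r.band,
                "n": r.n,
            }
            for r in results
        ]
    )
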