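"""ROC analysis of age-group discrimination.

Each sway parameter is treated as a continuous marker for membership in
the OLDER group, with the orientation fixed as "higher value ⇒ older"
(all five measures are hypothesized larger in older adults). The empirical
AUC is the probability that a random older value exceeds a random younger
value, ties counting one half; an AUC below 0.5 is reported as-is with an
orientation warning rather than silently flipped, so a reversed effect
stays visible.

The operating cutpoint is chosen by Youden's index J = sensitivity +
specificity − 1 over candidate thresholds placed midway between consecutive
distinct pooled values (plus ±∞), with the classification rule
"value ≥ c → OLDER". Ties in J are broken in favour of higher sensitivity,
then the smaller cutpoint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from swaylab.inferential_stats import _normal_approx_p
from swaylab.sway_io import Group
from swaylab.sway_metrics import SwayParameters

AUC_BANDS = ("FAIL", "POOR", "FAIR", "GOOD", "EXCELLENT")


@dataclass
class RocResult:
    system: str
    stance: str
    vision: str
    parameter: str
    auc: float
    auc_p: float
    cutpoint: float
    sensitivity: float
    specificity: float
    youden_j: float
    band: str
    n_younger: int
    n_older: int
    orientation_warning: bool = False
    flagged: bool = False  # incomplete input for this cell


def empirical_auc(younger: Sequence[float], older: Sequence[float]) -> tuple[float, float]:
    """Empirical AUC (older = positive class) and its p-value vs AUC = 0.5.

    AUC = (#pairs older > younger + ½·ties) / (n_y · n_o); the p-value uses
    the Mann–Whitney normal approximation through the U–AUC duality.
    """
    y = np.asarray(younger, dtype=float)
    o = np.asarray(older, dtype=float)
    if y.size == 0 or o.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([o, y])
    if np.ptp(pooled) == 0:
        return 0.5, 1.0
    ranks = stats.rankdata(pooled)
    u_older = float(ranks[: o.size].sum()) - o.size * (o.size + 1) / 2.0
    auc = u_older / (o.size * y.size)
    p = _normal_approx_p(ranks, o.size, u_older)
    return float(auc), float(p)


def youden_cutpoint(
    younger: Sequence[float], older: Sequence[float]
) -> tuple[float, float, float, float]:
    """Best Youden cutpoint; returns (cutpoint, sensitivity, specificity, J).

    Classification rule: value ≥ c → OLDER. Candidates are midpoints
    between consecutive sorted distinct pooled values, plus −∞ and +∞.
    """
    y = np.asarray(younger, dtype=float)
    o = np.asarray(older, dtype=float)
    if y.size == 0 or o.size == 0:
        raise ValueError("both groups must be nonempty")
    distinct = np.unique(np.concatenate([y, o]))
    candidates = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    best = None
    for c in candidates:
        sens = float(np.mean(o >= c))
        spec = float(np.mean(y < c))
        j = sens + spec - 1.0
        key = (j, sens, -c)  # maximize J, then sensitivity, then prefer smaller c
        if best is None or key > best[0]:
            best = (key, (float(c), sens, spec, j))
    return best[1]


def auc_band(auc: float) -> str:
    """Interpretation band: [0.5,0.6) FAIL, [0.6,0.7) POOR, [0.7,0.8) FAIR,
    [0.8,0.9) GOOD, [0.9,1.0] EXCELLENT. Below 0.5 is FAIL (reversed marker)."""
    if not (0.0 <= auc <= 1.0):
        raise ValueError(f"AUC must be in [0, 1], got {auc}")
    if auc < 0.6:
        return "FAIL"
    if auc < 0.7:
        return "POOR"
    if auc < 0.8:
        return "FAIR"
    if auc < 0.9:
        return "GOOD"
    return "EXCELLENT"


def roc_analysis(
    younger: Sequence[float], older: Sequence[float], **meta
) -> RocResult:
    auc, p = empirical_auc(younger, older)
    cut, sens, spec, j = youden_cutpoint(younger, older)
    return RocResult(
        auc=auc,
        auc_p=p,
        cutpoint=cut,
        sensitivity=sens,
        specificity=spec,
        youden_j=j,
        band=auc_band(auc),
        n_younger=len(younger),
        n_older=len(older),
        orientation_warning=auc < 0.5,
        **meta,
    )


def roc_table(params: pd.DataFrame) -> list[RocResult]:
    """One ROC row per (system, condition, parameter) — 40 rows for a
    complete two-system cohort. Cells with missing subjects are computed on
    the available pairs and flagged."""
    expected_n = params.groupby(["system", "stance", "vision"]).size().max()
    out = []
    for (system, stance, vision), cell in params.groupby(
        ["system", "stance", "vision"], sort=False
    ):
        for name in SwayParameters.NAMES:
            sub = cell[["group", name]].dropna()
            y = sub.loc[sub["group"] == Group.YOUNGER.value, name].to_numpy()
            o = sub.loc[sub["group"] == Group.OLDER.value, name].to_numpy()
            res = roc_analysis(
                y, o, system=system, stance=stance, vision=vision, parameter=name
            )
            res.flagged = len(sub) < expected_n
            out.append(res)
    return out


def roc_to_frame(results: list[RocResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "system": r.system,
                "stance": r.stance,
                "vision": r.vision,
                "parameter": r.parameter,
                "auc": r.auc,
                "p_value": r.auc_p,
                "cut_point": r.cutpoint,
                "sensitivity": r.sensitivity,
                "specificity": r.specificity,
                "youden_j": r.youden_j,
                "band": r.band,
                "n_younger": r.n_younger,
                "n_older": r.n_older,
                "flagged": r.flagged,
            }
            for r in results
        ]
    )
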