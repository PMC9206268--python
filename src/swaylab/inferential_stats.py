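"""Group-comparison statistics.

The comparison layer mirrors conventional posturography reporting: per
parameter and condition, normality of each group is gated with the
Shapiro–Wilk test at α = 0.05; if either group fails, the two groups are
compared with the Mann–Whitney U test, otherwise with the independent t
test. Medians and interquartile ranges are always reported. No
multiple-testing correction is applied across the 40 comparisons; the
report records how many tests were run.

The Mann–Whitney implementation enumerates the exact null distribution
(all labelings of the pooled sample, ties included) when the smaller group
has at most 8 observations, and otherwise uses the normal approximation
with tie and continuity corrections. scipy's implementation is used as an
independent cross-check in the test suite, not here.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from swaylab.sway_io import Group
from swaylab.sway_metrics import SwayParameters

EXACT_MW_MAX_N = 8
SIGNIFICANCE_LEVELS = (0.05, 0.01, 0.001)


class DegenerateDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# normality

def shapiro_wilk(sample: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W and p (Royston's approximation, via scipy)."""
    x = np.asarray(sample, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ValueError(f"Shapiro–Wilk requires 3 <= n <= 5000, got n={x.size}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("Shapiro–Wilk is undefined for a zero-variance sample")
    w, p = stats.shapiro(x)
    return float(w), float(p)


# ---------------------------------------------------------------------------
# Mann–Whitney U

@dataclass(frozen=True)
class MannWhitneyResult:
    u: float  # U statistic of group A (pairs with a > b, ties half)
    p: float  # two-sided
    method: str  # "exact" or "normal_approx"
    degenerate: bool = False

    def __iter__(self):
        return iter((self.u, self.p))


def _u_from_ranks(rank_sum_a: float, n_a: int) -> float:
    return rank_sum_a - n_a * (n_a + 1) / 2.0


def _exact_two_sided_p(pooled_ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Enumerate U over all C(n, n_a) labelings of the pooled ranks."""
    n = len(pooled_ranks)
    n_b = n - n_a
    mean_u = n_a * n_b / 2.0
    count_le = 0
    count_ge = 0
    total = 0
    eps = 1e-9
    for idx in itertools.combinations(range(n), n_a):
        u = _u_from_ranks(float(pooled_ranks[list(idx)].sum()), n_a)
        total += 1
        if u <= u_obs + eps:
            count_le += 1
        if u >= u_obs - eps:
            count_ge += 1
    # two-sided: double the smaller tail (point mass included), capped at 1
    return min(1.0, 2.0 * min(count_le, count_ge) / total)


def _normal_approx_p(pooled_ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    n = len(pooled_ranks)
    n_b = n - n_a
    mean_u = n_a * n_b / 2.0
    _, tie_counts = np.unique(pooled_ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return 1.0
    # continuity correction: shrink the deviation from the mean by 0.5
    z = (abs(u_obs - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    return float(2.0 * stats.norm.sf(z))


def mann_whitney(group_a: Sequence[float], group_b: Sequence[float]) -> MannWhitneyResult:
    """Two-sided Mann–Whitney U test.

    U is the number of (a, b) pairs with a > b, ties counting one half.
    Exact enumeration when min(n_a, n_b) <= 8; tie- and continuity-corrected
    normal approximation otherwise. Completely overlapping degenerate data
    (all values identical) gives p = 1 with ``degenerate=True``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return MannWhitneyResult(u=a.size * b.size / 2.0, p=1.0, method="degenerate", degenerate=True)
    ranks = stats.rankdata(pooled)
    u = _u_from_ranks(float(ranks[: a.size].sum()), a.size)
    if min(a.size, b.size) <= EXACT_MW_MAX_N and math.comb(a.size + b.size, a.size) <= 500_000:
        p = _exact_two_sided_p(ranks, a.size, u)
        method = "exact"
    else:
        p = _normal_approx_p(ranks, a.size, u)
        method = "normal_approx"
    return MannWhitneyResult(u=u, p=p, method=method)


# ---------------------------------------------------------------------------
# t tests

def welch_or_student_t(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variant: str = "welch",
) -> tuple[float, float, float]:
    """Two-sided independent t test; returns (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if np.ptp(np.concatenate([a, b])) == 0:
        raise DegenerateDataError("zero variance in both groups; t test undefined")
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    equal_var = variant == "student"
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = a.size + b.size - 2
    else:
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def t_test_from_summary(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int,
    variant: str = "student",
) -> tuple[float, float, float]:
    """t test from printed summary statistics (mean, SD, n) per group.

    Defaults to the pooled (Student) form, the convention for demographic
    tables; returns (t, df, p).
    """
    res = stats.ttest_ind_from_stats(
        mean_a, sd_a, n_a, mean_b, sd_b, n_b, equal_var=(variant == "student")
    )
    if variant == "student":
        df = n_a + n_b - 2
    else:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def chi_square_2x2(table: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Pearson χ² (df = 1, no continuity correction) on a 2×2 count table."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be nonnegative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateDataError("χ² is undefined with a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# effect size and power arithmetic

def cohens_d_pooled(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Pooled Cohen's d for equal group sizes: |Δ| / sqrt((s_a² + s_b²)/2)."""
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    return abs(mean_b - mean_a) / math.sqrt((sd_a**2 + sd_b**2) / 2.0)


def two_sample_t_power(n_per_group: int, d: float, alpha: float = 0.05, tails: int = 2) -> float:
    """Power of the equal-n two-sample t test via the noncentral t distribution."""
    df = 2 * n_per_group - 2
    nc = d * math.sqrt(n_per_group / 2.0)
    if tails == 2:
        tc = stats.t.isf(alpha / 2.0, df)
        return float(stats.nct.sf(tc, df, nc) + stats.nct.cdf(-tc, df, nc))
    tc = stats.t.isf(alpha, df)
    return float(stats.nct.sf(tc, df, nc))


def required_n_per_group(
    d: float, alpha: float = 0.05, power: float = 0.90, tails: int = 2
) -> int:
    """Smallest equal group size whose two-sample t-test power reaches ``power``."""
    if d <= 0:
        raise ValueError("effect size must be positive")
    if not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    n = 2
    if two_sample_t_power(n, d, alpha, tails) >= power:
        return n
    hi = 4
    while two_sample_t_power(hi, d, alpha, tails) < power:
        hi *= 2
        if hi > 10_000_000:
            raise ValueError("required sample size exceeds search bound")
    lo = hi // 2
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if two_sample_t_power(mid, d, alpha, tails) >= power:
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# per-cell routing over the cohort parameter table

@dataclass
class GroupComparison:
    system: str
    stance: str
    vision: str
    parameter: str
    n_younger: int
    n_older: int
    median_younger: float
    iqr_younger: tuple[float, float]
    median_older: float
    iqr_older: tuple[float, float]
    test_used: str  # T_TEST | MANN_WHITNEY
    statistic: float
    p_value: float
    mean_younger: float | None = None
    sd_younger: float | None = None
    mean_older: float | None = None
    sd_older: float | None = None
    degenerate: bool = False
    significant: dict[float, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.significant:
            self.significant = {a: self.p_value < a for a in SIGNIFICANCE_LEVELS}

    @property
    def stars(self) -> str:
        if self.p_value <= 0.001:
            return "***"
        if self.p_value <= 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def _iqr(x: np.ndarray) -> tuple[float, float]:
    # linear-interpolation ("type 7") quartiles
    return (float(np.percentile(x, 25)), float(np.percentile(x, 75)))


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    try:
        _, p = shapiro_wilk(x)
    except (ValueError, DegenerateDataError):
        return False
    return p > alpha


def compare_groups(
    younger: Sequence[float],
    older: Sequence[float],
    normality_alpha: float = 0.05,
    t_variant: str = "welch",
) -> tuple[str, float, float, bool]:
    """Route one comparison through the normality gate.

    Returns (test_used, statistic, p, degenerate). Both groups normal by
    Shapiro–Wilk → independent t test; otherwise Mann–Whitney U.
    """
    y = np.asarray(younger, dtype=float)
    o = np.asarray(older, dtype=float)
    if np.ptp(np.concatenate([y, o])) == 0:
        return "MANN_WHITNEY", y.size * o.size / 2.0, 1.0, True
    if _is_normal(y, normality_alpha) and _is_normal(o, normality_alpha):
        t, _, p = welch_or_student_t(y, o, variant=t_variant)
        return "T_TEST", t, p, False
    res = mann_whitney(y, o)
    return "MANN_WHITNEY", res.u, res.p, res.degenerate


def compare_all_parameters(
    params: pd.DataFrame,
    normality_alpha: float = 0.05,
    t_variant: str = "welch",
) -> list[GroupComparison]:
    """One routed younger-vs-older comparison per (system, condition, parameter).

    ``params`` is the tidy averaged-parameter table with columns
    (subject_id, group, system, stance, vision, <five parameters>).
    """
    out = []
    for (system, stance, vision), cell in params.groupby(
        ["system", "stance", "vision"], sort=False
    ):
        for name in SwayParameters.NAMES:
            y = cell.loc[cell["group"] == Group.YOUNGER.value, name].dropna().to_numpy()
            o = cell.loc[cell["group"] == Group.OLDER.value, name].dropna().to_numpy()
            if y.size == 0 or o.size == 0:
                raise ValueError(f"empty group in cell ({system}, {stance}, {vision}, {name})")
            test_used, statistic, p, degenerate = compare_groups(
                y, o, normality_alpha=normality_alpha, t_variant=t_variant
            )
            gc = GroupComparison(
                system=system,
                stance=stance,
                vision=vision,
                parameter=name,
                n_younger=y.size,
                n_older=o.size,
                median_younger=float(np.median(y)),
                iqr_younger=_iqr(y),
                median_older=float(np.median(o)),
                iqr_older=_iqr(o),
                test_used=test_used,
                statistic=statistic,
                p_value=p,
                degenerate=degenerate,
            )
            if test_used == "T_TEST":
                gc.mean_younger = float(y.mean())
                gc.sd_younger = float(y.std(ddof=1))
                gc.mean_older = float(o.mean())
                gc.sd_older = float(o.std(ddof=1))
            out.append(gc)
    return out


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        rows.append(
            {
                "system": c.system,
                "stance": c.stance,
                "vision": c.vision,
                "parameter": c.parameter,
                "n_younger": c.n_younger,
                "n_older": c.n_older,
                "median_younger": c.median_younger,
                "q1_younger": c.iqr_younger[0],
                "q3_younger": c.iqr_younger[1],
                "median_older": c.median_older,
                "q1_older": c.iqr_older[0],
                "q3_older": c.iqr_older[1],
                "test_used": c.test_used,
                "statistic": c.statistic,
                "p_value": c.p_value,
                "stars": c.stars,
                "degenerate": c.degenerate,
            }
        )
    return pd.DataFrame(rows)
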