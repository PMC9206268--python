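import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from swaylab.inferential_stats import (
    DegenerateDataError,
    chi_square_2x2,
    cohens_d_pooled,
    compare_all_parameters,
    compare_groups,
    mann_whitney,
    required_n_per_group,
    shapiro_wilk,
    t_test_from_summary,
    two_sample_t_power,
    welch_or_student_t,
)

# reported summary statistics of the velocity-ML reference used for the
# power analysis: younger 11.4 +/- 4.7 mm/s, older 18.0 +/- 9.9 mm/s
VEL_ML_SUMMARY = (11.4, 4.7, 18.0, 9.9)


def mw_exhaustive_worst_discrepancy(min_n: int, max_n: int) -> float:
    """Worst |exact − approx| two-sided Mann–Whitney p over every tie-free
    shape with min_n ≤ n_a ≤ n_b ≤ max_n, at every achievable U.

    The exact p comes from the full null distribution of the rank sum
    (independent of the package's exact path).
    """
    import itertools

    from swaylab.inferential_stats import _normal_approx_p

    worst = 0.0
    for na in range(min_n, max_n + 1):
        for nb in range(na, max_n + 1):
            n = na + nb
            ranks = np.arange(1, n + 1, dtype=float)
            us = np.array(
                [sum(c) for c in itertools.combinations(range(1, n + 1), na)], dtype=float
            ) - na * (na + 1) / 2
            vals, counts = np.unique(us, return_counts=True)
            total = counts.sum()
            cdf = np.cumsum(counts)
            sf = np.cumsum(counts[::-1])[::-1]
            for i, u in enumerate(vals):
                exact = min(1.0, 2.0 * min(cdf[i], sf[i]) / total)
                approx = _normal_approx_p(ranks, na, float(u))
                worst = max(worst, abs(exact - approx))
    return worst


class TestShapiroWilk:
    def test_three_point_sample_is_perfectly_linear(self):
        w, _ = shapiro_wilk([1, 2, 3])
        assert w == pytest.approx(1.0, abs=1e-9)

    def test_type_one_error_calibration(self):
        rng = np.random.default_rng(42)
        keep = sum(shapiro_wilk(rng.standard_normal(50))[1] > 0.05 for _ in range(300))
        assert keep / 300 >= 0.92

    def test_power_against_lognormal(self):
        rng = np.random.default_rng(43)
        reject = sum(
            shapiro_wilk(np.exp(rng.standard_normal(50)))[1] < 0.05 for _ in range(300)
        )
        assert reject / 300 > 0.95

    @pytest.mark.parametrize("n", [2, 5001])
    def test_sample_size_limits(self, n):
        with pytest.raises(ValueError):
            shapiro_wilk(np.arange(n, dtype=float))

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            shapiro_wilk([3.0, 3.0, 3.0, 3.0])


class TestMannWhitney:
    def test_enumeration_example_small(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res.u == 0
        assert res.p == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_identical_samples_degenerate(self):
        res = mann_whitney([2, 2, 2], [2, 2, 2])
        assert res.p == 1.0
        assert res.degenerate

    def test_enumeration_example_separated(self):
        res = mann_whitney([1, 2, 3, 4, 5], [6, 7, 8, 9, 10])
        assert res.u == 0
        assert res.p == pytest.approx(2 / 252)

    @given(
        st.integers(2, 7), st.integers(2, 7),
        st.randoms(use_true_random=False),
    )
    def test_exact_agrees_with_scipy_on_tie_free_data(self, na, nb, rnd):
        vals = list(range(na + nb))
        rnd.shuffle(vals)
        a, b = vals[:na], vals[na:]
        ours = mann_whitney(a, b)
        ref = stats.mannwhitneyu(a, b, method="exact")
        # scipy reports U of the first sample with the a > b convention
        assert ours.u == pytest.approx(float(ref.statistic))
        assert ours.p == pytest.approx(float(ref.pvalue), abs=1e-12)

    def test_normal_approx_accuracy_by_shape(self):
        """The normal approximation is coarse for the tiniest groups and
        tightens as the smaller group grows; exhaustive tie-free check over
        every achievable U value."""
        assert mw_exhaustive_worst_discrepancy(min_n=5, max_n=8) <= 0.02
        assert mw_exhaustive_worst_discrepancy(min_n=2, max_n=4) <= 0.09

    def test_exact_path_matches_distribution_oracle_with_ties(self):
        from swaylab.inferential_stats import _exact_two_sided_p
        import itertools

        rng = np.random.default_rng(7)
        for _ in range(20):
            na, nb = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            pooled = rng.integers(0, 4, size=na + nb).astype(float)
            if np.ptp(pooled) == 0:
                pooled[0] += 1
            ranks = stats.rankdata(pooled)
            u = float(ranks[:na].sum()) - na * (na + 1) / 2
            # oracle: full U distribution over labelings of the tied ranks
            us = np.array(
                [sum(ranks[list(c)]) for c in itertools.combinations(range(na + nb), na)]
            ) - na * (na + 1) / 2
            exact = min(1.0, 2 * min(np.mean(us <= u + 1e-9), np.mean(us >= u - 1e-9)))
            assert _exact_two_sided_p(ranks, na, u) == pytest.approx(exact, abs=1e-12)

    def test_u_complement_identity(self, rng):
        a, b = rng.normal(size=12), rng.normal(size=9)
        assert mann_whitney(a, b).u + mann_whitney(b, a).u == pytest.approx(12 * 9)


class TestTTests:
    def test_equal_groups_give_unit_p(self):
        t, _, p = welch_or_student_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    def test_age_summary_comparison_is_highly_significant(self):
        t, df, p = t_test_from_summary(31.7, 9.9, 27, 63.8, 7.1, 27)
        assert df == 52
        assert p < 0.001

    def test_separated_samples(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(10, 1, 10)
        _, _, p = welch_or_student_t(a, b)
        assert p < 1e-6

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            welch_or_student_t([1.0, 1.0], [1.0, 1.0])


class TestChiSquare:
    def test_study_sex_distribution(self):
        chi2, p = chi_square_2x2([[9, 18], [11, 16]])
        assert chi2 == pytest.approx(0.318, abs=5e-4)
        assert p == pytest.approx(0.573, abs=5e-4)

    def test_balanced_table(self):
        chi2, p = chi_square_2x2([[10, 10], [10, 10]])
        assert chi2 == 0.0 and p == 1.0

    def test_perfect_association(self):
        _, p = chi_square_2x2([[20, 0], [0, 20]])
        assert p < 1e-8

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateDataError):
            chi_square_2x2([[0, 0], [5, 5]])


class TestEffectSizeArithmetic:
    def test_reference_velocity_effect_size(self):
        assert cohens_d_pooled(*VEL_ML_SUMMARY) == pytest.approx(0.85, abs=5e-3)

    def test_equal_means_give_zero(self):
        assert cohens_d_pooled(3.0, 1.0, 3.0, 2.0) == 0.0

    def test_unit_case(self):
        assert cohens_d_pooled(0, 1, 1, 1) == pytest.approx(1.0)


class TestRequiredN:
    def test_reference_power_analysis(self):
        d = cohens_d_pooled(*VEL_ML_SUMMARY)  # 0.85170, the unrounded value
        n = required_n_per_group(d, alpha=0.05, power=0.90)
        assert n == 30
        assert two_sample_t_power(n, d) >= 0.90
        assert two_sample_t_power(n - 1, d) < 0.90

    def test_lower_power_needs_fewer(self):
        assert required_n_per_group(0.85, alpha=0.05, power=0.80) == 23

    def test_huge_effect_saturates_at_minimum(self):
        assert required_n_per_group(10.0) == 2

    @pytest.mark.parametrize("d1,d2", [(0.3, 0.5), (0.5, 0.9)])
    def test_monotone_in_effect_size(self, d1, d2):
        assert required_n_per_group(d1) >= required_n_per_group(d2)

    def test_monotone_in_power_and_alpha(self):
        assert required_n_per_group(0.5, power=0.95) >= required_n_per_group(0.5, power=0.80)
        assert required_n_per_group(0.5, alpha=0.01) >= required_n_per_group(0.5, alpha=0.10)


class TestCompareAllParameters:
    def _table(self, rng, n=8, constant_col=False):
        rows = []
        for grp in ("YOUNGER", "OLDER"):
            for i in range(n):
                rows.append(
                    {
                        "subject_id": f"{grp[0]}{i}",
                        "group": grp,
                        "system": "COP",
                        "stance": "WIDE",
                        "vision": "EO",
                        "distance_ml": 1.0 if constant_col else rng.normal(),
                        "distance_ap": rng.normal(),
                        "velocity_ml": rng.lognormal(),
                        "velocity_ap": rng.lognormal(),
                        "area_ce": rng.lognormal(),
                    }
                )
        return pd.DataFrame(rows)

    def test_one_row_per_cell_parameter(self, rng):
        out = compare_all_parameters(self._table(rng))
        assert len(out) == 5
        assert {c.parameter for c in out} == {
            "distance_ml", "distance_ap", "velocity_ml", "velocity_ap", "area_ce"
        }
        for c in out:
            assert 0 <= c.p_value <= 1
            assert c.significant[0.05] == (c.p_value < 0.05)

    def test_constant_column_flags_degenerate_without_crashing(self, rng):
        out = compare_all_parameters(self._table(rng, constant_col=True))
        dml = next(c for c in out if c.parameter == "distance_ml")
        assert dml.degenerate and dml.p_value == 1.0

    def test_normality_gate_routes_tests(self, rng):
        # clearly normal on both sides -> t test; grossly lognormal -> MW
        normal = compare_groups(rng.normal(size=60), rng.normal(size=60))
        skewed = compare_groups(np.exp(rng.normal(size=60) * 2), np.exp(rng.normal(size=60) * 2))
        assert normal[0] == "T_TEST"
        assert skewed[0] == "MANN_WHITNEY"
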