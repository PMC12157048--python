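"""Unit and property tests for the agreement and reliability statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from usfold import (
    bland_altman,
    cv_percent,
    icc_consistency,
    lins_ccc,
    multiple_regression_power,
    paired_comparison,
    regression_with_covariates,
    required_n_multiple_regression,
    tem_percent,
)
from usfold.agreement import CCCClass, R2Class, classify_ccc, classify_r2
from usfold.exceptions import (
    CollinearityError,
    DegenerateInputError,
    InvalidInputError,
)

paired_floats = st.lists(
    st.floats(min_value=-100, max_value=100, allow_nan=False), min_size=3, max_size=30
)


class TestPairedComparison:
    def test_identical_sequences(self):
        res = paired_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (res.mean_diff, res.t_stat, res.p_value) == (0.0, 0.0, 1.0)
        assert res.degenerate

    def test_constant_nonzero_difference_is_flagged_degenerate(self):
        res = paired_comparison([2.0, 3.0, 5.0], [1.0, 2.0, 4.0])
        assert res.degenerate
        assert math.isinf(res.t_stat) and res.t_stat > 0
        assert res.p_value == 0.0

    def test_hand_computed_example(self):
        res = paired_comparison([2, 4, 6], [1, 1, 3])
        assert res.mean_diff == pytest.approx(7 / 3, abs=1e-4)
        assert res.t_stat == pytest.approx(3.500, abs=1e-3)
        assert res.p_value == pytest.approx(0.0728, abs=5e-4)
        half = stats.t.ppf(0.975, 2) * (res.mean_diff / res.t_stat)
        assert res.ci_low == pytest.approx(res.mean_diff - half)
        assert res.ci_high == pytest.approx(res.mean_diff + half)

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(InvalidInputError):
            paired_comparison([1, 2, 3], [1, 2])
        with pytest.raises(InvalidInputError):
            paired_comparison([1, 2], [1, 2])


class TestBlandAltman:
    def test_constant_offset_collapses_limits(self):
        res = bland_altman([2.0, 3.0, 5.0], [1.0, 2.0, 4.0])
        assert res.bias == 1.0
        assert res.loa_lower == res.loa_upper == 1.0
        assert res.trend_r is None and res.trend_flag is not None

    def test_hand_computed_example(self):
        res = bland_altman([11, 11, 15], [10, 12, 14])
        assert res.bias == pytest.approx(1 / 3, abs=1e-4)
        assert res.sd_diff == pytest.approx(1.1547, abs=1e-4)
        assert res.loa_lower == pytest.approx(-1.930, abs=1e-3)
        assert res.loa_upper == pytest.approx(2.597, abs=1e-3)

    def test_proportional_bias_gives_unit_trend(self):
        ref = np.array([5.0, 10.0, 15.0])
        res = bland_altman(1.2 * ref, ref)
        assert res.trend_r == pytest.approx(1.0)

    @given(paired_floats, paired_floats)
    def test_loa_width_and_antisymmetry(self, a, b):
        n = min(len(a), len(b))
        a, b = a[:n], b[:n]
        fwd = bland_altman(a, b)
        rev = bland_altman(b, a)
        assert fwd.loa_upper - fwd.loa_lower == pytest.approx(2 * 1.96 * fwd.sd_diff, abs=1e-9)
        assert fwd.loa_lower <= fwd.bias <= fwd.loa_upper
        assert fwd.bias == pytest.approx(-rev.bias, abs=1e-9)
        assert fwd.bias == pytest.approx(paired_comparison(a, b).mean_diff, abs=1e-12)


class TestLinsCCC:
    def test_identity_is_almost_perfect(self):
        ccc, klass = lins_ccc([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ccc == pytest.approx(1.0)
        assert klass is CCCClass.ALMOST_PERFECT

    def test_closed_form_shift_example(self):
        ccc, klass = lins_ccc([2, 3, 4], [1, 2, 3])
        assert ccc == pytest.approx(4 / 7, abs=1e-10)
        assert klass is CCCClass.POOR

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            lins_ccc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_equals_pearson_under_equal_moments(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = x[::-1].copy()  # same mean and variance, different pairing
        ccc, _ = lins_ccc(y, x)
        assert ccc == pytest.approx(float(np.corrcoef(x, y)[0, 1]), abs=1e-10)

    def test_bounded_by_pearson_and_symmetric(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = rng.integers(3, 15)
            x = rng.normal(size=n)
            y = rng.normal(loc=rng.normal(), size=n) + 0.5 * x
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            ccc, _ = lins_ccc(x, y)
            r = float(np.corrcoef(x, y)[0, 1])
            assert abs(ccc) <= abs(r) + 1e-12
            assert ccc == pytest.approx(lins_ccc(y, x)[0], abs=1e-12)


class TestClassificationBands:
    @pytest.mark.parametrize("value, expected", [
        (0.8999, CCCClass.POOR),
        (0.90, CCCClass.MODERATE),      # 0.90–0.95 closed on the left
        (0.95, CCCClass.MODERATE),      # ...and on the right
        (0.9501, CCCClass.SUBSTANTIAL),
        (0.99, CCCClass.SUBSTANTIAL),   # "to 0.99" closed on the right
        (0.9901, CCCClass.ALMOST_PERFECT),
        (0.33, CCCClass.POOR),
    ])
    def test_ccc_boundaries(self, value, expected):
        assert classify_ccc(value) is expected

    @pytest.mark.parametrize("value, expected", [
        (0.2499, R2Class.BELOW_WEAK),
        (0.25, R2Class.WEAK),
        (0.4999, R2Class.WEAK),
        (0.50, R2Class.MODERATE),
        (0.7499, R2Class.MODERATE),
        (0.75, R2Class.SUBSTANTIAL),
        (1.0, R2Class.SUBSTANTIAL),
    ])
    def test_r2_boundaries(self, value, expected):
        assert classify_r2(value) is expected


def ols_normal_equations(y, X):
    """Independent from-scratch oracle: solve X'X b = X'y directly."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    return beta, 1.0 - sse / sst, math.sqrt(sse / (len(y) - X.shape[1]))


class TestRegressionWithCovariates:
    def test_exact_linear_dependence(self):
        x = np.arange(1.0, 11.0)
        rep = regression_with_covariates(3.0 + 2.0 * x, x)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.r2_class is R2Class.SUBSTANTIAL
        assert rep.coefficients["raw_us"] == pytest.approx(2.0)

    def test_constant_dependent_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            regression_with_covariates([5.0] * 6, np.arange(6.0))

    def test_toy_slope_and_r2(self):
        """Six-point toy fit; expectations from hand normal equations
        (slope = 34.6/17.5, r² = 1 − SSE/SST)."""
        x = [1, 2, 3, 4, 5, 6]
        y = [2.1, 3.9, 6.2, 7.8, 10.1, 11.9]
        rep = regression_with_covariates(y, x)
        assert rep.coefficients["raw_us"] == pytest.approx(34.6 / 17.5, abs=1e-6)
        assert rep.r2 > 0.998

    def test_matches_normal_equations_with_covariates(self):
        rng = np.random.default_rng(5)
        sites = np.array(["triceps", "abdominal", "thigh"])
        for _ in range(100):
            n = int(rng.integers(6, 13))
            x = rng.uniform(2, 20, n)
            site = sites[rng.integers(0, 3, n)]
            gender = np.where(rng.integers(0, 2, n) == 0, "M", "F")
            y = 1.5 * x + rng.normal(size=n)
            X = np.column_stack([
                np.ones(n), x,
                (site == "abdominal").astype(float), (site == "thigh").astype(float),
                (gender == "F").astype(float),
            ])
            if np.linalg.matrix_rank(X) < X.shape[1] or np.std(y) == 0:
                continue
            rep = regression_with_covariates(y, x, site=site, gender=gender,
                                             include={"site", "gender"})
            beta, r2, see = ols_normal_equations(y, X)
            assert np.allclose(list(rep.coefficients.values()), beta, rtol=1e-8)
            assert rep.r2 == pytest.approx(r2, rel=1e-8)
            assert rep.see == pytest.approx(see, rel=1e-8)

    def test_rank_deficiency_names_columns(self):
        with pytest.raises(CollinearityError, match="raw_us"):
            regression_with_covariates([1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0])


class TestPrecisionStatistics:
    def test_cv_percent(self):
        assert cv_percent([7.0, 7.0, 7.0]) == 0.0
        assert cv_percent([98, 100, 102]) == pytest.approx(2.0)
        with pytest.raises(InvalidInputError, match="mean"):
            cv_percent([-1.0, 1.0])

    def test_tem_percent(self):
        assert tem_percent([5.0, 6.0], [5.0, 6.0]) == 0.0
        assert tem_percent([10, 20], [12, 18]) == pytest.approx(9.428, abs=1e-3)
        assert tem_percent([10.0], [10.0]) == 0.0
        with pytest.raises(InvalidInputError):
            tem_percent([1, 2], [1, 2, 3])

    def test_icc_identity_and_shift_invariance(self):
        t1 = [1.0, 2.0, 3.0, 4.0]
        assert icc_consistency(t1, t1) == pytest.approx(1.0)
        assert icc_consistency(t1, [x + 5.0 for x in t1]) == pytest.approx(1.0)

    def test_icc_against_anova_oracle(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        t1 = [1.0, 2.0, 3.0, 4.0]
        t2 = [1.1, 1.9, 3.2, 3.8]
        long = pd.DataFrame({
            "subject": list(range(4)) * 2,
            "rater": ["a"] * 4 + ["b"] * 4,
            "score": t1 + t2,
        })
        table = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                         ratings="score")
        by_type = table.set_index("Type")["ICC"]
        # consistency, single measures: labelled ICC3 or ICC(C,1) by version
        key = "ICC3" if "ICC3" in by_type.index else "ICC(C,1)"
        expected = float(by_type[key])
        assert icc_consistency(t1, t2) == pytest.approx(expected, rel=1e-8)

    def test_icc_degenerate_between_subject_variance(self):
        with pytest.raises(DegenerateInputError):
            icc_consistency([2.0, 2.0, 2.0], [3.0, 3.0, 3.0])


class TestRequiredN:
    def test_study_power_analysis(self):
        assert required_n_multiple_regression(0.3, 0.05, 0.8, 2) == 36

    def test_small_effect_size(self):
        assert required_n_multiple_regression(0.15, 0.05, 0.8, 2) == 68

    def test_returned_n_brackets_the_target(self):
        for f2, power, p in [(0.3, 0.8, 2), (0.15, 0.8, 2), (0.35, 0.9, 3)]:
            n = required_n_multiple_regression(f2, 0.05, power, p)
            assert multiple_regression_power(n, f2, 0.05, p) >= power
            assert multiple_regression_power(n - 1, f2, 0.05, p) < power

    def test_monotonicity(self):
        base = required_n_multiple_regression(0.3, 0.05, 0.8, 2)
        assert required_n_multiple_regression(0.5, 0.05, 0.8, 2) <= base
        assert required_n_multiple_regression(0.3, 0.10, 0.8, 2) <= base
        assert required_n_multiple_regression(0.3, 0.05, 0.95, 2) >= base

    @pytest.mark.parametrize("kwargs", [
        dict(f2=0.0, alpha=0.05, power=0.8, n_predictors=2),
        dict(f2=0.3, alpha=1.5, power=0.8, n_predictors=2),
        dict(f2=0.3, alpha=0.05, power=0.0, n_predictors=2),
        dict(f2=0.3, alpha=0.05, power=0.8, n_predictors=0),
    ])
    def test_invalid_parameters(self, kwargs):
        with pytest.raises(InvalidInputError):
            required_n_multiple_regression(**kwargs)
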