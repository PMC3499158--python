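"""Outlier-detection suite: thresholds, robust normal, boxplot, log-IQR,
Huber regression — each against an independent oracle where one exists."""

import numpy as np
import pytest
from scipy import stats as sps

from flowqa.outliers import (
    between_group_outliers,
    outlier_cutoff,
    outlier_norm,
    qoutlier,
    residual_outliers,
    robust_regression,
)


def brute_quartiles(values):
    """Order-statistic interpolation at h = (n-1)p + 1, coded from scratch."""
    v = sorted(values)
    n = len(v)
    out = []
    for p in (0.25, 0.75):
        h = (n - 1) * p + 1
        k = int(np.floor(h))
        frac = h - k
        lo = v[k - 1]
        hi = v[min(k, n - 1)]
        out.append(lo + frac * (hi - lo))
    return out


def brute_iqr_flags(values, k=1.5):
    q1, q3 = brute_quartiles(values)
    iqr = q3 - q1
    if iqr == 0:
        return [False] * len(values)
    return [v < q1 - k * iqr or v > q3 + k * iqr for v in values]


class TestCutoff:
    def test_rbc_lysis_style_lower_bound(self):
        res = outlier_cutoff([0.95, 0.79, 0.85], lBound=0.8)
        np.testing.assert_array_equal(res.flags, [False, True, False])

    def test_value_at_bound_not_flagged(self):
        res = outlier_cutoff([0.8, 0.8000001], lBound=0.8)
        assert not res.flags[0]

    def test_upper_bound_and_scores(self):
        res = outlier_cutoff([1.0, 5.0], uBound=2.0)
        np.testing.assert_array_equal(res.flags, [False, True])
        assert res.scores[1] == pytest.approx(3.0)

    def test_bound_order_and_missing_bounds(self):
        with pytest.raises(ValueError):
            outlier_cutoff([1.0], lBound=2.0, uBound=1.0)
        with pytest.raises(ValueError):
            outlier_cutoff([1.0])


class TestNorm:
    def test_separated_point_flagged(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, 1, 20)
        loc = np.median(vals)
        scale = 1.4826 * np.median(np.abs(vals - loc))
        vals = np.append(vals, loc + 10 * scale)
        res = outlier_norm(vals, z_cutoff=3)
        assert res.flags[-1] and res.flags[:-1].sum() == 0

    def test_alpha_equivalent_to_z3(self):
        # alpha = 0.0027 two-sided -> z cutoff = Phi^-1(1 - alpha/2) ~ 3.0
        rng = np.random.default_rng(1)
        vals = rng.normal(0, 1, 200)
        a = outlier_norm(vals, alpha=0.0027)
        b = outlier_norm(vals, z_cutoff=3.0)
        assert abs(a.cutoffs["z_cutoff"] - 3.0) < 1e-3
        np.testing.assert_array_equal(a.flags, b.flags)

    def test_all_equal_values_zero_flags(self):
        res = outlier_norm([5.0] * 10)
        assert res.n_flagged == 0

    def test_one_sided_tests(self):
        vals = np.array([0.0] * 10 + [8.0, -8.0])
        up = outlier_norm(vals + np.arange(12) * 1e-6, sides="upper")
        lo = outlier_norm(vals + np.arange(12) * 1e-6, sides="lower")
        assert up.flags[10] and not up.flags[11]
        assert lo.flags[11] and not lo.flags[10]

    def test_minimum_group_size(self):
        with pytest.raises(ValueError, match=">= 3"):
            outlier_norm([1.0, 2.0])

    def test_false_positive_calibration_ungrouped(self):
        """z=3 on 1e5 null draws flags 0.27% +- 3 binomial sd."""
        rng = np.random.default_rng(42)
        n = 100_000
        flagged = outlier_norm(rng.normal(0, 1, n), z_cutoff=3).n_flagged
        p = 2 * sps.norm.sf(3)
        tol = 3 * np.sqrt(n * p * (1 - p))
        assert abs(flagged - n * p) <= tol

    def test_false_positive_calibration_grouped(self):
        """Grouped (100 x 1000), the median/MAD noise inflates the rate by
        ~20% over the known-sigma nominal (Jensen effect of the 1/MAD
        standardization); the rate stays inside the derived [0.2%, 0.45%]."""
        rng = np.random.default_rng(42)
        draws = rng.normal(0, 1, (100, 1000))
        flagged = sum(outlier_norm(g, z_cutoff=3).n_flagged for g in draws)
        assert 0.002 <= flagged / 100_000 <= 0.0045


class TestQoutlier:
    def test_single_extreme_flagged(self):
        vals = list(range(1, 10)) + [100]
        res = qoutlier(vals)
        np.testing.assert_array_equal(res.flags, brute_iqr_flags(vals))
        assert res.flags[-1] and res.flags[:-1].sum() == 0

    def test_zero_iqr_no_flags(self):
        assert qoutlier([2.0, 2.0, 2.0, 2.0]).n_flagged == 0

    def test_agreement_with_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(1000):
            n = int(rng.integers(4, 201))
            vals = rng.standard_t(df=3, size=n) * rng.uniform(0.1, 10)
            np.testing.assert_array_equal(qoutlier(vals).flags,
                                          brute_iqr_flags(vals))

    def test_permutation_and_scale_equivariance(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, 60)
        base = qoutlier(vals).flags
        perm = rng.permutation(60)
        np.testing.assert_array_equal(qoutlier(vals[perm]).flags, base[perm])
        np.testing.assert_array_equal(qoutlier(3.7 * vals + 11).flags, base)
        np.testing.assert_array_equal(outlier_norm(2 * vals - 5).flags,
                                      outlier_norm(vals).flags)


class TestBetweenGroup:
    def test_inflated_spread_group_flagged(self):
        rng = np.random.default_rng(5)
        groups = {f"g{i}": rng.normal(0, 1, 30) for i in range(20)}
        groups["bad"] = rng.normal(0, 10, 30)
        res = between_group_outliers(groups)
        flagged = {k for k, v in res.items() if v["flagged"]}
        assert flagged == {"bad"}

    def test_identical_spread_no_flags(self):
        groups = {f"g{i}": np.array([0.0, 1.0, 2.0]) for i in range(10)}
        res = between_group_outliers(groups)
        assert not any(v["flagged"] for v in res.values())

    def test_low_variance_never_flagged(self):
        rng = np.random.default_rng(6)
        groups = {f"g{i}": rng.normal(0, 1, 30) for i in range(15)}
        groups["tight"] = rng.normal(0, 1e-4, 30)
        res = between_group_outliers(groups)
        assert not res["tight"]["flagged"]

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        groups = {f"g{i}": rng.normal(0, 1 + (i == 3) * 9, 20) for i in range(12)}
        a = between_group_outliers(dict(sorted(groups.items())))
        b = between_group_outliers(dict(sorted(groups.items(), reverse=True)))
        assert {k: v["flagged"] for k, v in a.items()} == \
               {k: v["flagged"] for k, v in b.items()}

    def test_fewer_than_three_groups_no_calls(self):
        assert between_group_outliers({"a": [1, 2], "b": [1, 2, 3]}) == {}

    def test_zero_iqr_groups_admitted_and_never_flagged(self):
        """A minority of zero-spread groups must not break the log-IQR call
        (epsilon keeps the log finite); they sit far in the lower tail of
        the one-sided upper test and are never flagged themselves."""
        rng = np.random.default_rng(12)
        groups = {f"g{i}": rng.normal(0, 1, 20) for i in range(10)}
        groups["flat1"] = np.array([2.0, 2.0, 2.0])
        groups["flat2"] = np.array([7.0, 7.0, 7.0])
        groups["wide"] = rng.normal(0, 10, 20)
        res = between_group_outliers(groups)
        flagged = {k for k, v in res.items() if v["flagged"]}
        assert flagged == {"wide"}


class TestRobustRegression:
    def test_noiseless_line_recovered(self):
        x = np.arange(10, dtype=float)
        y = 2 * x + 1
        fit = robust_regression(x, y)
        assert fit.slope == pytest.approx(2.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert residual_outliers(fit, x, y).n_flagged == 0

    def test_offset_points_flagged_slope_preserved(self):
        rng = np.random.default_rng(8)
        x = np.linspace(0, 10, 100)
        y = x + rng.normal(0, 0.1, 100)
        bad = [5, 20, 40, 60, 90]
        y[bad] += 10
        fit = robust_regression(x, y)
        res = residual_outliers(fit, x, y)
        assert set(np.flatnonzero(res.flags)) == set(bad)
        # slope within 3 standard errors of truth for clean data of sd 0.1
        se = 0.1 / (np.std(x) * np.sqrt(100))
        assert abs(fit.slope - 1.0) < 3 * se

    def test_huge_c_matches_ols_closed_form(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 5, 40)
        y = 1.5 * x - 2 + rng.normal(0, 0.5, 40)
        fit = robust_regression(x, y, c=1e12)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        assert fit.slope == pytest.approx(beta[1], abs=1e-8)

    def test_matches_statsmodels_rlm(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(10)
        x = np.linspace(0, 20, 60)
        y = 0.7 * x + 3 + rng.normal(0, 1, 60)
        y[::13] += 8
        fit = robust_regression(x, y)
        X = sm.add_constant(x)
        ref = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(scale_est="mad")
        assert fit.intercept == pytest.approx(ref.params[0], abs=5e-3)
        assert fit.slope == pytest.approx(ref.params[1], abs=5e-3)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            robust_regression([1.0] * 5, [1, 2, 3, 4, 5])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            robust_regression([1, 2, 3], [1, 2, 3])


def test_sensitivity_on_separated_synthetic_outliers():
    """>= 6 robust-sd separated contamination: sensitivity >= 0.95, FPR <= 0.01."""
    rng = np.random.default_rng(11)
    tp = fn = fp = tn = 0
    for _ in range(200):
        n = 40
        vals = rng.normal(10, 2, n)
        k = 3
        idx = rng.choice(n, k, replace=False)
        vals[idx] = 10 + rng.choice([-1, 1], k) * 2 * rng.uniform(6.5, 9, k)
        flags = outlier_norm(vals, z_cutoff=3).flags
        truth = np.zeros(n, dtype=bool)
        truth[idx] = True
        tp += int((flags & truth).sum())
        fn += int((~flags & truth).sum())
        fp += int((flags & ~truth).sum())
        tn += int((~flags & ~truth).sum())
    assert tp / (tp + fn) >= 0.95
    assert fp / (fp + tn) <= 0.01
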