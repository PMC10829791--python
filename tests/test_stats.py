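"""Normality-gated cohort statistics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from batkinetics.stats import (
    bonferroni,
    correlate,
    group_compare,
    is_normal,
    multivariable_fit,
    paired_compare,
    sample_size_two_t,
    summarize,
)


class TestSummarize:
    def test_closed_form_mean_sd(self):
        s = summarize([1, 2, 3, 4, 5])
        assert s["kind"] == "mean_sd"
        assert s["mean"] == pytest.approx(3.0)
        assert s["sd"] == pytest.approx(1.5811, abs=1e-4)

    def test_gate_selects_mean_for_normal_and_median_for_lognormal(self):
        rng = np.random.default_rng(7)
        normal = rng.normal(10, 2, 100)
        skewed = rng.lognormal(0, 1.2, 100)
        assert summarize(normal)["kind"] == "mean_sd"
        s = summarize(skewed)
        assert s["kind"] == "median_iqr"
        assert s["q1"] <= s["median"] <= s["q3"]


class TestGroupCompare:
    def test_mann_whitney_exact_matches_enumeration(self):
        """Complete separation of {1,2,3} vs {4,5,6}: U=0, two-sided p=2/20."""
        res = group_compare(
            [1, 2, 3, 4, 5, 6], ["a"] * 3 + ["b"] * 3, method="mann_whitney"
        )
        assert min(res.statistic, 9 - res.statistic) == 0
        # enumeration of all C(6,3)=20 group assignments
        count_extreme = 0
        for combo in itertools.combinations(range(6), 3):
            u = sum(1 for i in combo for j in set(range(6)) - set(combo) if i > j)
            if min(u, 9 - u) <= 0:
                count_extreme += 1
        assert res.p_value == pytest.approx(count_extreme / 20)
        assert res.p_value == pytest.approx(0.1)

    def test_identical_values_degenerate(self):
        res = group_compare([5.0] * 8, ["a"] * 4 + ["b"] * 4)
        assert res.p_value == 1.0 and res.degenerate

    def test_equal_groups_statistic_at_null_center(self):
        x = np.arange(1.0, 11.0)
        res = group_compare(
            np.concatenate([x, x]), ["a"] * 10 + ["b"] * 10, method="mann_whitney"
        )
        assert res.statistic == pytest.approx(50.0)  # n1*n2/2

    def test_gate_picks_mann_whitney_for_skewed_groups(self):
        rng = np.random.default_rng(21)
        a = rng.lognormal(0, 1.5, 30)
        b = rng.lognormal(0, 1.5, 30)
        res = group_compare(np.concatenate([a, b]), ["a"] * 30 + ["b"] * 30)
        assert res.method == "mann_whitney"


class TestPairedCompare:
    def test_equal_samples_give_p_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_compare(a, a)
        assert res.p_value == 1.0 and res.degenerate

    def test_constant_shift_is_flagged_exact(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_compare(a + 1.0, a)
        assert res.p_value == 0.0 and res.degenerate
        assert any("constant shift" in n for n in res.notes)

    def test_rejection_rate_matches_paired_t_power(self):
        """Known delta/sigma = 1 at n=14: closed-form noncentral-t power."""
        from scipy import stats as sps

        n, delta = 14, 1.0
        df = n - 1
        ncp = delta * np.sqrt(n)
        tcrit = sps.t.ppf(0.975, df)
        power = sps.nct.sf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp)
        rng = np.random.default_rng(17)
        nsim = 800
        rejections = 0
        for _ in range(nsim):
            d = rng.normal(delta, 1.0, n)
            res = paired_compare(d, np.zeros(n))
            if res.p_value < 0.05:
                rejections += 1
        se = np.sqrt(power * (1 - power) / nsim)
        assert rejections / nsim == pytest.approx(power, abs=4 * se)


class TestBonferroni:
    def test_examples_and_cap(self):
        assert bonferroni([0.01], 3)[0] == pytest.approx(0.03)
        assert bonferroni([0.5], 3)[0] == 1.0

    def test_monotone_never_decreases_and_idempotent_when_capped(self):
        rng = np.random.default_rng(3)
        p = np.sort(rng.uniform(0, 1, 50))
        adj = bonferroni(p, 10)
        assert np.all(adj >= p)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(bonferroni(adj[adj >= 1.0], 10) == 1.0)


class TestCorrelate:
    def test_perfect_linear_and_rank_invariance(self):
        x = np.linspace(1, 10, 20)
        assert correlate(x, x, method="pearson")["estimate"] == pytest.approx(1.0)
        y = np.exp(x)  # monotone nonlinear
        rho = correlate(x, y, method="spearman")
        r = correlate(x, y, method="pearson")
        assert rho["estimate"] == pytest.approx(1.0)
        assert r["estimate"] < 1.0

    def test_bivariate_normal_recovery(self):
        rng = np.random.default_rng(3)
        rho = 0.6
        est = []
        for _ in range(1000):
            z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=25)
            est.append(correlate(z[:, 0], z[:, 1], method="pearson")["estimate"])
        assert np.mean(est) == pytest.approx(rho, abs=0.03)


class TestMultivariableFit:
    def test_exact_linear_relationship(self):
        x = np.linspace(1, 10, 30)
        res = multivariable_fit(2 * x, pd.DataFrame({"x": x}))
        assert res.coefficients["x"] == pytest.approx(2.0)
        assert res.standardized_betas["x"] == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_orthogonal_predictors_match_univariate_slopes(self):
        rng = np.random.default_rng(9)
        n = 64
        x1 = np.tile([-1.0, 1.0], n // 2)
        x2 = np.repeat([-1.0, 1.0], n // 2)
        y = 1.5 * x1 - 0.7 * x2 + rng.normal(0, 0.3, n)
        res = multivariable_fit(y, pd.DataFrame({"x1": x1, "x2": x2}))
        # closed-form OLS slope per predictor (orthogonal, centered design)
        for name, x in [("x1", x1), ("x2", x2)]:
            slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
            assert res.coefficients[name] == pytest.approx(slope, abs=1e-10)

    def test_standardized_betas_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 40)
        z = rng.normal(0, 1, 40)
        y = x + 0.5 * z + rng.normal(0, 0.2, 40)
        a = multivariable_fit(y, pd.DataFrame({"x": x, "z": z}))
        b = multivariable_fit(y, pd.DataFrame({"x": 100 * x + 7, "z": 0.01 * z - 3}))
        assert a.standardized_betas["x"] == pytest.approx(b.standardized_betas["x"], rel=1e-10)
        assert a.standardized_betas["z"] == pytest.approx(b.standardized_betas["z"], rel=1e-10)

    def test_singular_design_names_offender(self):
        x = np.linspace(0, 1, 20)
        with pytest.raises(ValueError, match="x_dup"):
            multivariable_fit(x, pd.DataFrame({"x": x, "x_dup": 2 * x}))

    def test_log_transform_rejects_nonpositive(self):
        with pytest.raises(ValueError, match="log-transform"):
            multivariable_fit(
                np.ones(10),
                pd.DataFrame({"x": np.linspace(-1, 1, 10)}),
                log_flags={"x": True},
            )


class TestSampleSize:
    def test_unit_effect_size_needs_17_per_group(self):
        assert sample_size_two_t(0.0, 1.0, 1.0, 1.0, power=0.8, alpha=0.05) == 17

    def test_matches_statsmodels_power_solver(self):
        from statsmodels.stats.power import TTestIndPower

        for d in (0.5, 0.8, 1.2):
            n = sample_size_two_t(0.0, 1.0, d, 1.0, power=0.8, alpha=0.05)
            n_sm = TTestIndPower().solve_power(effect_size=d, power=0.8, alpha=0.05)
            assert n == int(np.ceil(n_sm))

    def test_empirical_power_at_returned_n(self):
        mean1, sd1, mean2, sd2 = 0.0, 1.0, 1.0, 1.0
        n = sample_size_two_t(mean1, sd1, mean2, sd2, power=0.8, alpha=0.05)
        from scipy import stats as sps

        rng = np.random.default_rng(19)
        rejections = 0
        nsim = 5000
        for _ in range(nsim):
            a = rng.normal(mean1, sd1, n)
            b = rng.normal(mean2, sd2, n)
            if sps.ttest_ind(a, b).pvalue < 0.05:
                rejections += 1
        assert rejections / nsim >= 0.8 - 0.02

    def test_zero_effect_is_an_error(self):
        with pytest.raises(ValueError, match="zero effect"):
            sample_size_two_t(1.0, 1.0, 1.0, 2.0)


class TestGate:
    def test_gate_is_deterministic(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        assert all(is_normal(x) == is_normal(x.copy()) for _ in range(3))
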