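"""Reliability statistics: ICC, Spearman-Brown, CV, RMS, ANOVA, agreement,
normality."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import tendonmetrics as tm
from tendonmetrics.stats import MeasurementMatrix


def matrix(values, days=None):
    values = np.asarray(values, dtype=float)
    if days is None:
        days = (1,) * values.shape[1]
    return MeasurementMatrix(values=values, trial_days=days)


def brute_force_icc_a1(x):
    """Independent variance-components oracle: explicit two-way sums of
    squares computed cell by cell."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_err = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(n)
        for j in range(k)
    )
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_columns_give_perfect_agreement(self):
        x = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert tm.icc_a1(matrix(x)) == pytest.approx(1.0)

    def test_small_grid_matches_brute_force_oracle(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0], [7.0, 8.0]])
        assert tm.icc_a1(matrix(x)) == pytest.approx(brute_force_icc_a1(x), abs=1e-12)

    def test_oracle_equivalence_on_random_grids(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            n = rng.integers(3, 9)
            k = rng.integers(2, 7)
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 4), (n, k))
            x += rng.normal(0, 2, (n, 1))  # subject effects
            assert tm.icc_a1(matrix(x)) == pytest.approx(
                brute_force_icc_a1(x), abs=1e-10
            )

    def test_agrees_with_pingouin_icc2(self):
        """Cross-check against an independent published implementation
        (ICC2 = two-way random, absolute agreement, single measures)."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, (8, 4)) + rng.normal(0, 2, (8, 1))
        df = pd.DataFrame(x).reset_index().melt(
            id_vars="index", var_name="rater", value_name="y"
        )
        ref = pingouin.intraclass_corr(
            data=df, targets="index", raters="rater", ratings="y"
        )
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(ref.loc[mask, "ICC"].iloc[0])
        assert tm.icc_a1(matrix(x)) == pytest.approx(icc2, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(tm.StatsError):
            tm.icc_a1(matrix(np.full((4, 3), 2.0)))
        with pytest.raises(tm.StatsError):
            tm.icc_a1(matrix(np.array([[1.0, np.nan], [2.0, 3.0]])))


class TestSpearmanBrown:
    def test_published_icc_examples(self):
        """Overall single-trial reliabilities of 0.67 and 0.76 require 4-5
        and 2-3 averaged trials for 0.9 reliability: k = 9(1-r)/r."""
        sb = tm.spearman_brown_trials(0.67, 0.9)
        assert sb.k_exact == pytest.approx(9 * 0.33 / 0.67, abs=1e-12)
        assert sb.k_exact == pytest.approx(4.433, abs=5e-4)
        assert (sb.floor, sb.ceil) == (4, 5)
        sb = tm.spearman_brown_trials(0.76, 0.9)
        assert sb.k_exact == pytest.approx(2.842, abs=5e-4)
        assert (sb.floor, sb.ceil) == (2, 3)

    def test_fixed_point(self):
        assert tm.spearman_brown_trials(0.9, 0.9).k_exact == pytest.approx(1.0)

    def test_domain_errors(self):
        for r in (0.0, 1.0, -0.2, 1.4):
            with pytest.raises(tm.StatsError):
                tm.spearman_brown_trials(r)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.floats(0.05, 0.95), st.floats(0.05, 0.95),
        st.floats(0.05, 0.9), st.floats(0.05, 0.9),
    )
    def test_monotonicity(self, r1, r2, t1, t2):
        """k decreases with single-trial reliability and increases with the
        target."""
        lo_r, hi_r = sorted({r1, r2})if r1 != r2 else (r1, r1 + 0.01)
        assert (
            tm.spearman_brown_trials(hi_r, t1).k_exact
            <= tm.spearman_brown_trials(lo_r, t1).k_exact
        )
        lo_t, hi_t = sorted({t1, t2}) if t1 != t2 else (t1, t1 + 0.05)
        assert (
            tm.spearman_brown_trials(r1, lo_t).k_exact
            <= tm.spearman_brown_trials(r1, hi_t).k_exact
        )


class TestCV:
    def test_identical_trials_zero(self):
        x = np.array([[3.0, 3.0, 3.0], [7.0, 7.0, 7.0]])
        assert tm.cv_percent(matrix(x)) == pytest.approx(0.0)

    def test_hand_computation(self):
        """Trials (100, 110): 100 * sd / mean = 100 * 7.0711 / 105 = 6.734%."""
        x = np.array([[100.0, 110.0], [100.0, 110.0]])
        assert tm.cv_percent(matrix(x)) == pytest.approx(6.734, abs=1e-3)

    def test_negative_mean_uses_absolute_value(self):
        x = np.array([[-100.0, -110.0], [-100.0, -110.0]])
        assert tm.cv_percent(matrix(x)) == pytest.approx(6.734, abs=1e-3)

    def test_zero_mean_rejected(self):
        with pytest.raises(tm.StatsError):
            tm.cv_percent(matrix(np.array([[-1.0, 1.0], [2.0, 3.0]])))


class TestRMS:
    def test_identical_trials_zero(self):
        x = np.tile(np.array([[4.0], [9.0]]), (1, 4))
        m = matrix(x, days=(1, 1, 2, 2))
        for scope in ("day1", "day2", "between_day", "overall"):
            assert tm.rms_difference(m, scope) == pytest.approx(0.0)

    def test_hand_computation_two_pairs(self):
        """Pairs (1,2) and (3,5): sqrt((1 + 4)/2) = 1.581."""
        m = matrix(np.array([[1.0, 2.0]]), days=(1, 1))
        m2 = matrix(np.array([[3.0, 5.0]]), days=(1, 1))
        d1 = tm.rms_difference(m, "day1") ** 2
        d2 = tm.rms_difference(m2, "day1") ** 2
        assert np.sqrt((d1 + d2) / 2) == pytest.approx(1.581, abs=1e-3)

    def test_between_day_zero_for_equal_day_means(self):
        x = np.array([[1.0, 3.0, 0.0, 4.0], [5.0, 7.0, 6.0, 6.0]])
        m = matrix(x, days=(1, 1, 2, 2))
        assert tm.rms_difference(m, "between_day") == pytest.approx(0.0)

    def test_overall_pools_all_pairs(self):
        x = np.array([[1.0, 2.0, 4.0]])
        m = matrix(x, days=(1, 1, 2))
        expected = np.sqrt(np.mean([1.0, 9.0, 4.0]))
        assert tm.rms_difference(m, "overall") == pytest.approx(expected)


class TestRmAnova:
    @staticmethod
    def brute_force_table(y):
        """Independent oracle: sums of squares from explicit marginal-mean
        loops on a subjects x days x trials cube."""
        n, a, b = y.shape
        g = y.mean()
        sub = y.mean(axis=(1, 2))
        day = y.mean(axis=(0, 2))
        tri = y.mean(axis=(0, 1))
        ss = {}
        ss["day"] = n * b * sum((day[j] - g) ** 2 for j in range(a))
        ss["trial"] = n * a * sum((tri[k] - g) ** 2 for k in range(b))
        ss["dt"] = n * sum(
            (y[:, j, k].mean() - day[j] - tri[k] + g) ** 2
            for j in range(a) for k in range(b)
        )
        ss["sd"] = b * sum(
            (y[i, j].mean() - sub[i] - day[j] + g) ** 2
            for i in range(n) for j in range(a)
        )
        ss["st"] = a * sum(
            (y[i, :, k].mean() - sub[i] - tri[k] + g) ** 2
            for i in range(n) for k in range(b)
        )
        ss_tot = ((y - g) ** 2).sum()
        ss_sub = a * b * sum((sub[i] - g) ** 2 for i in range(n))
        ss["res"] = ss_tot - ss_sub - sum(
            ss[k] for k in ("day", "trial", "dt", "sd", "st")
        )
        f_day = (ss["day"] / (a - 1)) / (ss["sd"] / ((a - 1) * (n - 1)))
        f_tri = (ss["trial"] / (b - 1)) / (ss["st"] / ((b - 1) * (n - 1)))
        f_dt = (ss["dt"] / ((a - 1) * (b - 1))) / (
            ss["res"] / ((a - 1) * (b - 1) * (n - 1))
        )
        return f_day, f_tri, f_dt

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        y = rng.normal(0, 1, (5, 2, 4)) + rng.normal(0, 2, (5, 1, 1))
        m = matrix(y.reshape(5, 8), days=(1, 1, 1, 1, 2, 2, 2, 2))
        table = tm.rm_anova_trial_day(m).set_index("effect")
        f_day, f_tri, f_dt = self.brute_force_table(y)
        assert table.loc["day", "F"] == pytest.approx(f_day, abs=1e-10)
        assert table.loc["trial", "F"] == pytest.approx(f_tri, abs=1e-10)
        assert table.loc["day x trial", "F"] == pytest.approx(f_dt, abs=1e-10)

    def test_forced_day_effect_detected(self):
        rng = np.random.default_rng(5)
        y = rng.normal(0, 0.01, (6, 8)) + rng.normal(0, 1, (6, 1))
        y[:, 4:] += 10.0
        m = matrix(y, days=(1, 1, 1, 1, 2, 2, 2, 2))
        table = tm.rm_anova_trial_day(m).set_index("effect")
        assert table.loc["day", "F"] > 1e3
        assert table.loc["day", "p"] < 1e-6

    def test_type_one_error_calibrated_under_null(self):
        """With subject effects only, the day-effect p-value is uniform:
        rejections at alpha = 0.05 stay inside the binomial 99% interval
        over 500 simulated designs."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_sims = 500
        for _ in range(n_sims):
            y = rng.normal(0, 1, (11, 8)) + rng.normal(0, 2, (11, 1))
            m = matrix(y, days=(1, 1, 1, 1, 2, 2, 2, 2))
            table = tm.rm_anova_trial_day(m).set_index("effect")
            rejections += table.loc["day", "p"] < 0.05
        # binomial(500, 0.05): 99% interval roughly [13, 38]
        assert 13 <= rejections <= 38

    def test_zero_residual_variance_rejected(self):
        with pytest.raises(tm.StatsError):
            tm.rm_anova_trial_day(
                matrix(np.tile([[1.0], [2.0]], (1, 4)), days=(1, 1, 2, 2))
            )


class TestGroupComparison:
    def test_identical_groups_no_significance(self):
        groups = {g: np.full(5, 3.0) for g in ("a", "b", "c")}
        res = tm.group_comparison(groups)
        assert res.anova_f == pytest.approx(0.0)
        assert (res.pairwise["p_bonferroni"] == 1.0).all()

    def test_two_groups_no_multiplicity_penalty(self):
        rng = np.random.default_rng(0)
        res = tm.group_comparison(
            {"a": rng.normal(0, 1, 10), "b": rng.normal(5, 1, 10)}
        )
        assert len(res.pairwise) == 1
        assert res.pairwise["p_bonferroni"].iloc[0] == pytest.approx(
            res.pairwise["p_raw"].iloc[0]
        )

    def test_separated_cohort_distributions_detected(self):
        """Groups drawn at published cohort stiffness distributions
        (96.3 +- 11.7, 73.9 +- 18.3, 49.4 +- 11.5 kN/strain; n = 8/11/8):
        the one-way ANOVA flags the group effect in essentially every
        replicate, and the all-pairs Bonferroni rejection rate matches the
        analytic power of the design (noncentral-t per pair)."""
        from scipy import stats as sps

        def pair_power(mu1, sd1, n1, mu2, sd2, n2, alpha):
            sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
            ncp = (mu1 - mu2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            df = n1 + n2 - 2
            tc = sps.t.ppf(1 - alpha / 2, df)
            return sps.nct.sf(tc, df, ncp) + sps.nct.cdf(-tc, df, ncp)

        design = {"athletes": (96.3, 11.7, 8), "young": (73.9, 18.3, 11),
                "older": (49.4, 11.5, 8)}
        alpha = 0.05 / 3
        import itertools as it
        p_all = np.prod([
            pair_power(*design[a], *design[b], alpha)
            for a, b in it.combinations(design, 2)
        ])

        rng = np.random.default_rng(12)
        n_rep = 200
        anova_hits = all_pair_hits = 0
        for _ in range(n_rep):
            groups = {g: rng.normal(mu, sd, n) for g, (mu, sd, n) in design.items()}
            res = tm.group_comparison(groups)
            anova_hits += res.anova_p < 0.05
            all_pair_hits += bool((res.pairwise["p_bonferroni"] < 0.05).all())
        assert anova_hits >= 0.98 * n_rep
        # binomial 99.7% band around the analytic all-pairs power
        se = np.sqrt(p_all * (1 - p_all) / n_rep)
        assert abs(all_pair_hits / n_rep - p_all) < 3.5 * se

    def test_small_group_rejected(self):
        with pytest.raises(tm.StatsError):
            tm.group_comparison({"a": [1.0], "b": [1.0, 2.0]})


class TestMethodAgreement:
    def test_identity_and_offset(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = tm.method_agreement(a, a)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.rms == pytest.approx(0.0)
        res = tm.method_agreement(a, a + 0.5)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.rms == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(tm.StatsError):
            tm.method_agreement([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLilliefors:
    def test_gaussian_samples_rarely_rejected(self):
        rng = np.random.default_rng(7)
        passes = 0
        for i in range(100):
            x = rng.normal(3.0, 2.0, 50)
            _, p = tm.lilliefors_normality(x, n_sims=2000, seed=i)
            passes += p > 0.05
        assert passes >= 90

    def test_bimodal_sample_rejected(self):
        x = np.concatenate([np.full(50, -5.0), np.full(50, 5.0)])
        x += np.random.default_rng(1).normal(0, 0.3, 100)
        _, p = tm.lilliefors_normality(x, seed=0)
        assert p < 0.01

    def test_agrees_with_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.diagnostic")
        rng = np.random.default_rng(14)
        x = rng.normal(0, 1, 40) + 0.4 * rng.normal(0, 1, 40) ** 2
        d_obs, p = tm.lilliefors_normality(x, n_sims=20000, seed=0)
        d_ref, p_ref = statsmodels.lilliefors(x)
        assert d_obs == pytest.approx(d_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=0.05)

    def test_tiny_sample_rejected(self):
        with pytest.raises(tm.StatsError):
            tm.lilliefors_normality([1.0, 2.0, 3.0])
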