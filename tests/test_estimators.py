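import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import optimize

from mrkit import egger, ivw, penalized_weighted_median, wald_ratio, wald_ratios, weighted_median
from mrkit.estimators import _penalized_weights, _weighted_lsq, _weighted_median_rows


# ---------------------------------------------------------------- oracles

def ivw_normal_equations(beta_exposure, beta_outcome, se_outcome):
    """Zero-intercept weighted least squares solved from the normal equations:
    slope = sum(w x y) / sum(w x^2), var = 1 / sum(w x^2), w = se_outcome^-2."""
    x = np.asarray(beta_exposure, float)
    y = np.asarray(beta_outcome, float)
    w = np.asarray(se_outcome, float) ** -2.0
    slope = np.sum(w * x * y) / np.sum(w * x * x)
    return slope, np.sqrt(1.0 / np.sum(w * x * x))


def weighted_quantile_oracle(values, weights, q=0.5, tol=1e-12):
    """Independent weighted-quantile evaluation: build the piecewise-linear
    weighted CDF through the standardized cumulative weights and invert it at
    q by bisection on a dense value grid."""
    order = np.argsort(values)
    v = np.asarray(values, float)[order]
    w = np.asarray(weights, float)[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if q <= s[0]:
        return v[0]
    if q >= s[-1]:
        return v[-1]

    def cdf(x):
        return np.interp(x, v, s)

    lo, hi = v[0], v[-1]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if cdf(mid) < q:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def ratios_frame(ratio, se):
    se = np.asarray(se, float)
    return pd.DataFrame({"rsid": [f"rs{i}" for i in range(len(se))],
                         "ratio": ratio, "se_ratio": se, "weight": se ** -2.0})


# ---------------------------------------------------------------- Wald ratio

class TestWaldRatio:
    def test_zero_numerator_gives_zero_ratio(self):
        ratio, se = wald_ratio(0.0, 0.01, 0.1)
        assert ratio == 0.0 and se == pytest.approx(0.1)

    def test_strong_instrument_example(self):
        # SLC2A9-strength denominator: first- and second-order SEs agree <1%
        ratio, se = wald_ratio(0.0236, 0.01, 0.236, 0.0034)
        assert ratio == pytest.approx(0.1)
        assert se == pytest.approx(0.042373, abs=5e-7)
        _, se2 = wald_ratio(0.0236, 0.01, 0.236, 0.0034, second_order=True)
        assert abs(se2 - se) / se < 0.01
        assert se2 > se

    def test_linearity_in_outcome(self):
        r1, s1 = wald_ratio(0.02, 0.01, 0.1)
        r2, s2 = wald_ratio(0.04, 0.02, 0.1)
        assert (r2, s2) == (2 * r1, 2 * s1)

    def test_zero_denominator_excluded_from_table(self, caplog):
        df = pd.DataFrame({"rsid": ["a", "b"], "beta_exposure": [0.0, 0.1],
                           "se_exposure": [0.01] * 2, "beta_outcome": [0.01] * 2,
                           "se_outcome": [0.02] * 2})
        with caplog.at_level("WARNING", logger="mrkit"):
            out = wald_ratios(df)
        assert list(out["rsid"]) == ["b"]
        assert "beta_exposure = 0" in caplog.text

    def test_weight_is_inverse_variance(self, random_harmonized):
        out = wald_ratios(random_harmonized())
        np.testing.assert_allclose(out["weight"], out["se_ratio"] ** -2, rtol=1e-15)


# ---------------------------------------------------------------- IVW

class TestIvw:
    def test_single_snp_reduces_to_its_ratio(self):
        res = ivw(ratios_frame([0.3], [0.1]))
        assert res.estimate == pytest.approx(0.3)
        assert res.se == pytest.approx(0.1)
        assert res.n_snps == 1

    def test_two_identical_ratios_halve_the_variance(self):
        res = ivw(ratios_frame([0.2, 0.2], [0.1, 0.1]))
        assert res.estimate == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1 / np.sqrt(2))

    def test_matches_normal_equations_oracle(self, random_harmonized):
        df = random_harmonized(n=31, true_effect=0.05)
        res = ivw(wald_ratios(df))
        slope, se = ivw_normal_equations(df["beta_exposure"], df["beta_outcome"],
                                         df["se_outcome"])
        assert res.estimate == pytest.approx(slope, rel=1e-11)
        assert res.se == pytest.approx(se, rel=1e-11)

    def test_matches_statsmodels_wls_through_origin(self, random_harmonized):
        import statsmodels.api as sm
        df = random_harmonized(n=25, true_effect=-0.1, seed=4)
        fit = sm.WLS(df["beta_outcome"], df[["beta_exposure"]],
                     weights=df["se_outcome"] ** -2.0).fit()
        res = ivw(wald_ratios(df))
        assert res.estimate == pytest.approx(fit.params.iloc[0], rel=1e-11)

    def test_order_invariance_and_duplication(self, random_harmonized):
        ratios = wald_ratios(random_harmonized(n=20))
        base = ivw(ratios)
        shuffled = ivw(ratios.sample(frac=1, random_state=0))
        assert shuffled.estimate == pytest.approx(base.estimate, rel=1e-14)
        doubled = ivw(pd.concat([ratios, ratios], ignore_index=True))
        assert doubled.estimate == pytest.approx(base.estimate, rel=1e-14)
        assert doubled.se == pytest.approx(base.se / np.sqrt(2), rel=1e-12)

    def test_random_effects_only_inflates_se(self, random_harmonized):
        ratios = wald_ratios(random_harmonized(n=31, true_effect=0.3, seed=9))
        fe, re = ivw(ratios, "fixed"), ivw(ratios, "random")
        assert re.estimate == fe.estimate
        assert re.se >= fe.se

    def test_empty_input_is_hard_error(self):
        with pytest.raises(ValueError):
            ivw(ratios_frame([], []))

    def test_result_reporting_scale(self):
        res = ivw(ratios_frame([0.1, 0.2, 0.3], [0.1, 0.1, 0.1]))
        assert res.odds_ratio == pytest.approx(np.exp(res.estimate))
        assert res.ci_low < res.estimate < res.ci_high
        assert res.ci_high - res.estimate == pytest.approx(1.959964 * res.se)


# ---------------------------------------------------------------- MR-Egger

class TestEgger:
    def test_two_snps_is_hard_error(self, random_harmonized):
        with pytest.raises(ValueError, match="at least 3"):
            egger(random_harmonized(n=2))

    def test_noiseless_line_recovered_exactly(self):
        x = np.array([0.05, 0.1, 0.15, 0.2, 0.25])
        df = pd.DataFrame({"rsid": list("abcde"), "beta_exposure": x,
                           "se_exposure": 0.003, "beta_outcome": 0.01 + 0.2 * x,
                           "se_outcome": [0.01, 0.02, 0.015, 0.01, 0.03]})
        res = egger(df)
        assert res.estimate == pytest.approx(0.2, rel=1e-11)
        assert res.extras["intercept"] == pytest.approx(0.01, rel=1e-11)

    def test_matches_statsmodels_wls(self, random_harmonized):
        import statsmodels.api as sm
        df = random_harmonized(n=31, true_effect=0.1, seed=12)
        w = df["se_outcome"] ** -2.0
        fit = sm.WLS(df["beta_outcome"], sm.add_constant(df["beta_exposure"]),
                     weights=w).fit()
        res = egger(df)
        assert res.extras["intercept"] == pytest.approx(fit.params.iloc[0], rel=1e-10)
        assert res.estimate == pytest.approx(fit.params.iloc[1], rel=1e-10)
        # our SEs equal statsmodels' model-based SEs up to the overdispersion
        # convention: statsmodels scales by sigma, we scale by max(1, sigma)
        _, _, sigma = _weighted_lsq(df["beta_exposure"].to_numpy(),
                                    df["beta_outcome"].to_numpy(),
                                    w.to_numpy(), intercept=True)
        assert sigma == pytest.approx(np.sqrt(fit.scale), rel=1e-10)
        expected_se = fit.bse.iloc[1] / sigma * max(1.0, sigma)
        assert res.se == pytest.approx(expected_se, rel=1e-10)

    def test_zero_intercept_fit_reproduces_ivw(self, random_harmonized):
        """Shared-code consistency: forcing the intercept to zero in the same
        weighted regression gives exactly the IVW estimate."""
        df = random_harmonized(n=31)
        coef, se_raw, _ = _weighted_lsq(
            df["beta_exposure"].to_numpy(), df["beta_outcome"].to_numpy(),
            df["se_outcome"].to_numpy() ** -2.0, intercept=False)
        res = ivw(wald_ratios(df))
        assert coef[0] == pytest.approx(res.estimate, rel=1e-12)
        assert se_raw[0] == pytest.approx(res.se, rel=1e-12)

    def test_requires_orientation(self, random_harmonized):
        df = random_harmonized(n=10)
        df.loc[0, "beta_exposure"] *= -1
        with pytest.raises(ValueError, match="orient"):
            egger(df)

    def test_identical_exposure_betas_unidentified(self):
        df = pd.DataFrame({"rsid": list("abc"), "beta_exposure": [0.1] * 3,
                           "se_exposure": 0.003, "beta_outcome": [0.1, 0.2, 0.3],
                           "se_outcome": 0.02})
        with pytest.raises(ValueError, match="unidentified"):
            egger(df)


# ---------------------------------------------------------------- weighted median / PWM

class TestWeightedMedian:
    def test_equal_weights_simple_median(self):
        assert weighted_median(np.array([1., 2, 3, 4, 5]), np.ones(5)) == 3.0

    @given(st.integers(1, 12))
    def test_equal_weights_odd_n_equals_sample_median(self, half):
        n = 2 * half + 1
        rng = np.random.default_rng(n)
        v = rng.normal(size=n)
        assert weighted_median(v, np.ones(n)) == pytest.approx(np.median(v), rel=1e-12)

    def test_four_unequal_weights_match_grid_scan_oracle(self):
        v = np.array([0.1, -0.3, 0.25, 0.05])
        w = np.array([1.0, 0.5, 2.0, 3.0])
        assert weighted_median(v, w) == pytest.approx(
            weighted_quantile_oracle(v, w), abs=1e-8)

    @given(st.integers(3, 40), st.integers(0, 10_000))
    def test_matches_oracle_for_random_inputs(self, n, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=n)
        w = rng.uniform(0.1, 5.0, size=n)
        assert weighted_median(v, w) == pytest.approx(
            weighted_quantile_oracle(v, w), abs=1e-8)

    def test_row_version_agrees_with_scalar_version(self, rng):
        v = rng.normal(size=(50, 17))
        w = rng.uniform(0.1, 3.0, size=(50, 17))
        rows = _weighted_median_rows(v, w)
        for i in range(50):
            assert rows[i] == pytest.approx(weighted_median(v[i], w[i]), rel=1e-12)


class TestPenalizedWeightedMedian:
    def test_penalization_inactive_for_identical_ratios(self):
        b = np.full(5, 0.2)
        w = np.array([1., 2, 3, 4, 5])
        np.testing.assert_allclose(_penalized_weights(b, w), w)

    def test_outlier_weight_is_crushed(self):
        b = np.array([0.1, 0.11, 0.09, 0.1, 5.0])
        w = np.full(5, 400.0)  # se 0.05 each
        pw = _penalized_weights(b, w)
        assert pw[-1] < 1e-6 * w[-1]
        np.testing.assert_allclose(pw[:4], w[:4], rtol=1e-6)

    def test_point_estimate_matches_oracle_and_is_deterministic(self, rng):
        b = rng.normal(0.1, 0.2, 15)
        se = rng.uniform(0.05, 0.3, 15)
        ratios = ratios_frame(b, se)
        res1 = penalized_weighted_median(ratios, n_boot=200, seed=1)
        res2 = penalized_weighted_median(ratios, n_boot=500, seed=99)
        assert res1.estimate == res2.estimate  # point estimate ignores bootstrap
        pw = _penalized_weights(b, se ** -2.0)
        assert res1.estimate == pytest.approx(
            weighted_quantile_oracle(b, pw), abs=1e-8)

    def test_bootstrap_se_reproducible_given_seed(self, rng):
        ratios = ratios_frame(rng.normal(0, 0.2, 10), rng.uniform(0.05, 0.2, 10))
        a = penalized_weighted_median(ratios, n_boot=500, seed=7)
        b = penalized_weighted_median(ratios, n_boot=500, seed=7)
        assert a.se == b.se
        assert a.extras["seed"] == 7 and a.extras["n_boot"] == 500

    def test_small_bootstrap_warns(self):
        ratios = ratios_frame([0.1, 0.2, 0.3], [0.1, 0.1, 0.1])
        with pytest.warns(UserWarning, match="n_boot"):
            penalized_weighted_median(ratios, n_boot=50, seed=0)

    def test_fewer_than_three_snps_is_hard_error(self):
        with pytest.raises(ValueError, match=">= 3"):
            penalized_weighted_median(ratios_frame([0.1, 0.2], [0.1, 0.1]))


# ---------------------------------------------------------------- shared properties

class TestEquivariance:
    @given(st.sampled_from([0.25, 0.5, 2.0, 4.0]))
    def test_exposure_rescaling_divides_all_estimates(self, c):
        """Multiplying every exposure beta and SE by c > 0 (a change of
        exposure units) divides every causal estimate by c."""
        df = pd.DataFrame({
            "rsid": [f"rs{i}" for i in range(12)],
            "beta_exposure": np.linspace(0.03, 0.25, 12),
            "se_exposure": 0.004,
            "beta_outcome": np.linspace(0.03, 0.25, 12) * 0.2
                            + np.sin(np.arange(12)) * 0.01,
            "se_outcome": np.linspace(0.01, 0.03, 12),
        })
        scaled = df.assign(beta_exposure=df["beta_exposure"] * c,
                           se_exposure=df["se_exposure"] * c)
        for estimate in (
                lambda d: ivw(wald_ratios(d)).estimate,
                lambda d: egger(d).estimate,
                lambda d: penalized_weighted_median(
                    wald_ratios(d), n_boot=100, seed=3).estimate):
            assert estimate(scaled) == pytest.approx(estimate(df) / c, rel=1e-9)
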