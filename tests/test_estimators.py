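import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from tsmr.estimators import (
    InsufficientInstrumentsError,
    Z95,
    cochran_q,
    ivw,
    median_estimator,
    mr_egger,
    presso_global,
    to_odds_ratio,
    wald_ratio,
)

from conftest import mk_inst, mk_instruments


def _random_instruments(rng, k, beta=0.2, gamma_sd=0.1, se_g=0.01, se_a=0.01, delta=None):
    gamma = rng.normal(0, gamma_sd, k)
    gamma = np.where(np.abs(gamma) < 0.02, 0.02 * np.sign(gamma) + (gamma == 0) * 0.02, gamma)
    alpha = beta * gamma + (0.0 if delta is None else delta) + rng.normal(0, se_a, k)
    ghat = gamma + rng.normal(0, se_g, k)
    return mk_instruments(ghat, np.full(k, se_g), alpha, np.full(k, se_a))


class TestWaldRatio:
    def test_direct_division(self):
        res = wald_ratio(mk_inst(0.1, 0.01, 0.02, 0.01))
        assert res.beta == pytest.approx(0.2)
        assert res.se == pytest.approx(0.1)
        assert res.method == "wald_ratio" and res.n_snp == 1

    def test_sign_follows_gamma(self):
        res = wald_ratio(mk_inst(-0.1, 0.01, 0.02, 0.01))
        assert res.beta == pytest.approx(-0.2)
        assert res.se == pytest.approx(0.1)

    def test_zero_gamma_undefined(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(mk_inst(0.0, 0.01, 0.02, 0.01))

    def test_second_order_se_matches_monte_carlo(self, rng):
        # Monte-Carlo oracle: 1e6 draws of the ratio's sampling distribution
        g, se_g, a, se_a = 0.1, 0.005, 0.02, 0.01
        draws = rng.normal(a, se_a, 1_000_000) / rng.normal(g, se_g, 1_000_000)
        mc_se = float(np.std(draws))
        res = wald_ratio(mk_inst(g, se_g, a, se_a), second_order=True)
        assert res.se == pytest.approx(mc_se, rel=0.02)


class TestIVW:
    def test_degenerate_consensus(self):
        r = 0.3
        inst = [mk_inst(g, 0.01, r * g, 0.01, variant_id=f"rs{i}")
                for i, g in enumerate([0.1, 0.2, 0.15])]
        res = ivw(inst)
        assert res.beta == pytest.approx(r, abs=1e-12)
        het = cochran_q(inst, res.beta)
        assert het.Q == pytest.approx(0.0, abs=1e-18)

    def test_three_instrument_normal_equations_oracle(self):
        inst = [
            mk_inst(0.10, 0.01, 0.020, 0.010, "rs1"),
            mk_inst(0.20, 0.01, 0.050, 0.010, "rs2"),
            mk_inst(0.15, 0.01, 0.030, 0.010, "rs3"),
        ]
        g = np.array([0.10, 0.20, 0.15])
        a = np.array([0.020, 0.050, 0.030])
        w = 1.0 / 0.010**2
        # weighted least squares through the origin, solved by the normal
        # equation beta = (g' W a) / (g' W g)
        expected = (g * w * a).sum() / (g * w * g).sum()
        res = ivw(inst)
        assert res.beta == pytest.approx(expected, abs=1e-10)
        assert res.se == pytest.approx(1.0 / np.sqrt((g**2 * w).sum()), abs=1e-12)

    def test_matches_statsmodels_wls_through_origin(self, rng):
        import statsmodels.api as sm

        for trial in range(20):
            inst = _random_instruments(rng, k=int(rng.integers(3, 30)))
            g = np.array([i.gamma for i in inst])
            a = np.array([i.alpha for i in inst])
            se_a = np.array([i.se_alpha for i in inst])
            fit = sm.WLS(a, g, weights=1.0 / se_a**2).fit()
            assert ivw(inst).beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_fixed_and_mre_share_point_estimate(self, rng):
        inst = _random_instruments(rng, 15, delta=rng.normal(0, 0.05, 15))
        fixed = ivw(inst, "fixed")
        mre = ivw(inst, "multiplicative_random_effects")
        assert fixed.beta == mre.beta
        assert mre.se >= fixed.se  # inflation bounded below by 1

    def test_requires_two_instruments(self):
        with pytest.raises(InsufficientInstrumentsError, match="wald"):
            ivw([mk_inst(0.1, 0.01, 0.02, 0.01)])


class TestEgger:
    def test_exact_linear_data_recovered(self):
        c, b = 0.03, 0.25
        gammas = [0.05, 0.1, 0.15, 0.2, 0.3]
        inst = [mk_inst(g, 0.01, c + b * g, 0.01, f"rs{i}") for i, g in enumerate(gammas)]
        res = mr_egger(inst)
        assert res.beta == pytest.approx(b, abs=1e-10)
        assert res.intercept == pytest.approx(c, abs=1e-10)

    def test_orientation_invariance(self, rng):
        inst = _random_instruments(rng, 12)
        flipped = [
            mk_inst(-i.gamma, i.se_gamma, -i.alpha, i.se_alpha, i.variant_id)
            if j % 3 == 0 else i
            for j, i in enumerate(inst)
        ]
        a, b = mr_egger(inst), mr_egger(flipped)
        assert b.beta == pytest.approx(a.beta, rel=1e-12)
        assert b.intercept == pytest.approx(a.intercept, rel=1e-12)

    def test_matches_weighted_normal_equations_oracle(self, rng):
        # independently coded WLS-with-intercept on 20 random instruments
        inst = _random_instruments(rng, 20, delta=rng.normal(0.02, 0.03, 20))
        g = np.abs(np.array([i.gamma for i in inst]))
        a = np.array([i.alpha for i in inst]) * np.sign([i.gamma for i in inst])
        w = 1.0 / np.array([i.se_alpha for i in inst]) ** 2
        sw, swx, swy = w.sum(), (w * g).sum(), (w * a).sum()
        swxx, swxy = (w * g * g).sum(), (w * g * a).sum()
        det = sw * swxx - swx**2
        slope = (sw * swxy - swx * swy) / det
        intercept = (swxx * swy - swx * swxy) / det
        resid = a - intercept - slope * g
        scale = max(1.0, (w * resid**2).sum() / (len(inst) - 2))
        se_slope = np.sqrt(scale * sw / det)
        se_int = np.sqrt(scale * swxx / det)
        res = mr_egger(inst)
        assert res.beta == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.se == pytest.approx(se_slope, abs=1e-10)
        assert res.intercept_se == pytest.approx(se_int, abs=1e-10)

    def test_matches_statsmodels_coefficients(self, rng):
        import statsmodels.api as sm

        inst = _random_instruments(rng, 15)
        g = np.abs(np.array([i.gamma for i in inst]))
        a = np.array([i.alpha for i in inst]) * np.sign([i.gamma for i in inst])
        se_a = np.array([i.se_alpha for i in inst])
        X = sm.add_constant(g)
        fit = sm.WLS(a, X, weights=1.0 / se_a**2).fit()
        res = mr_egger(inst)
        assert res.intercept == pytest.approx(fit.params[0], abs=1e-10)
        assert res.beta == pytest.approx(fit.params[1], abs=1e-10)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger([mk_inst(0.1, 0.01, 0.02, 0.01, "a"),
                      mk_inst(0.2, 0.01, 0.05, 0.01, "b")])


def _scan_weighted_median(ratios, weights):
    """Brute-force cumulative-weight scan with interpolation."""
    order = np.argsort(ratios)
    r = np.array(ratios)[order]
    w = np.array(weights)[order] / np.sum(weights)
    cum = 0.0
    mids = []
    for wi in w:
        mids.append(cum + wi / 2)
        cum += wi
    mids = np.array(mids)
    if 0.5 <= mids[0]:
        return r[0]
    if 0.5 >= mids[-1]:
        return r[-1]
    for i in range(len(r) - 1):
        if mids[i] <= 0.5 <= mids[i + 1]:
            return r[i] + (r[i + 1] - r[i]) * (0.5 - mids[i]) / (mids[i + 1] - mids[i])
    raise AssertionError("unreachable")


class TestMedianEstimators:
    def test_simple_median_of_three(self):
        inst = [mk_inst(1.0, 0.01, r, 0.01, f"rs{i}") for i, r in enumerate([0.1, 0.2, 0.9])]
        res = median_estimator(inst, "simple", n_boot=10, seed=1)
        assert res.beta == pytest.approx(0.2)
        assert res.method == "simple_median"

    def test_weighted_median_matches_scan_oracle(self, rng):
        for _ in range(10):
            k = 5
            inst = _random_instruments(rng, k)
            g = np.array([i.gamma for i in inst])
            a = np.array([i.alpha for i in inst])
            se_a = np.array([i.se_alpha for i in inst])
            expected = _scan_weighted_median(a / g, g**2 / se_a**2)
            res = median_estimator(inst, "inverse_variance", n_boot=10, seed=2)
            assert res.beta == pytest.approx(expected, abs=1e-12)

    def test_majority_weight_instrument_dominates(self):
        # one instrument carries > 50% of the weight: the estimate stays in
        # the interpolation neighbourhood of its ratio
        inst = [
            mk_inst(1.0, 0.01, 0.1, 0.10, "a"),   # w = 100
            mk_inst(1.0, 0.01, 0.5, 0.01, "b"),   # w = 10000 (> 50%)
            mk_inst(1.0, 0.01, 0.9, 0.10, "c"),   # w = 100
        ]
        res = median_estimator(inst, "inverse_variance", n_boot=10, seed=3)
        assert 0.1 < res.beta <= 0.9
        assert res.beta == pytest.approx(0.5, abs=0.02)

    def test_bootstrap_reproducible_under_seed(self, rng):
        inst = _random_instruments(rng, 8)
        a = median_estimator(inst, "inverse_variance", n_boot=200, seed=42)
        b = median_estimator(inst, "inverse_variance", n_boot=200, seed=42)
        assert a.beta == b.beta and a.se == b.se and a.seed == 42

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            median_estimator([mk_inst(0.1, 0.01, 0.02, 0.01, "a"),
                              mk_inst(0.2, 0.01, 0.05, 0.01, "b")],
                             "simple", seed=1)


class TestCochranQ:
    def test_identical_ratios_no_heterogeneity(self):
        inst = [mk_inst(g, 0.01, 0.4 * g, 0.01, f"rs{i}")
                for i, g in enumerate([0.1, 0.2, 0.3])]
        het = cochran_q(inst, ivw(inst).beta)
        assert het.Q == pytest.approx(0.0, abs=1e-18)
        assert het.pvalue == pytest.approx(1.0)
        assert het.df == 2

    def test_order_invariant(self, rng):
        inst = _random_instruments(rng, 10, delta=rng.normal(0, 0.05, 10))
        beta = ivw(inst).beta
        q1 = cochran_q(inst, beta).Q
        q2 = cochran_q(list(reversed(inst)), beta).Q
        assert q1 == pytest.approx(q2, rel=1e-12)

    def test_term_by_term_summation_oracle(self, rng):
        inst = _random_instruments(rng, 12, delta=rng.normal(0, 0.03, 12))
        beta = ivw(inst).beta
        expected = sum(
            (i.gamma**2 / i.se_alpha**2) * (i.alpha / i.gamma - beta) ** 2 for i in inst
        )
        het = cochran_q(inst, beta)
        assert het.Q == pytest.approx(expected, rel=1e-12)
        assert het.pvalue == pytest.approx(float(sps.chi2.sf(expected, len(inst) - 1)))


class TestPresso:
    def test_planted_outlier_flagged_top(self, rng):
        # moderate pleiotropic offset on one SNP: large against its own SE
        # but too small to drag the leave-one-out fits of the others
        k = 20
        gamma = np.linspace(0.05, 0.2, k)
        alpha = 0.2 * gamma + rng.normal(0, 0.01, k)
        alpha[4] += 0.12
        inst = mk_instruments(gamma, np.full(k, 0.005), alpha, np.full(k, 0.01))
        res = presso_global(inst, n_sim=500, seed=9)
        assert res.global_p < 0.01
        assert res.outlier_flags[4]
        assert np.argmin(res.outlier_p) == 4
        assert res.outlier_flags.sum() == 1

    def test_bit_identical_under_seed(self, rng):
        inst = _random_instruments(rng, 6)
        a = presso_global(inst, n_sim=300, seed=5)
        b = presso_global(inst, n_sim=300, seed=5)
        assert a.rss_observed == b.rss_observed
        assert a.global_p == b.global_p
        assert np.array_equal(a.outlier_p, b.outlier_p)

    def test_requires_four_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            presso_global([mk_inst(0.1, 0.01, 0.02, 0.01, str(i)) for i in range(3)],
                          seed=1)


class TestOddsRatioConversion:
    def test_null_beta_gives_unit_or(self):
        res = to_odds_ratio(wald_ratio(mk_inst(0.1, 0.01, 0.0, 0.01)))
        assert res.or_ == pytest.approx(1.0)
        assert res.or_low < 1.0 < res.or_high

    def test_log_two_maps_to_or_two(self):
        res = wald_ratio(mk_inst(1.0, 0.001, np.log(2), 1e-9))
        assert res.or_ == pytest.approx(2.0)

    @given(beta=st.floats(min_value=-2, max_value=2),
           se=st.floats(min_value=1e-6, max_value=1.0))
    @settings(deadline=None, derandomize=True, max_examples=60)
    def test_or_bounds_are_exp_of_beta_bounds(self, beta, se):
        res = wald_ratio(mk_inst(1.0, 0.01, beta, se))
        assert res.or_ == pytest.approx(np.exp(res.beta), rel=1e-12)
        assert res.or_low == pytest.approx(np.exp(res.beta - Z95 * res.se), rel=1e-12)
        assert res.or_high == pytest.approx(np.exp(res.beta + Z95 * res.se), rel=1e-12)
        assert res.or_low <= res.or_ <= res.or_high
        assert 0 < res.pvalue <= 1

    def test_monotone_in_beta(self):
        lo = wald_ratio(mk_inst(1.0, 0.01, 0.1, 0.01))
        hi = wald_ratio(mk_inst(1.0, 0.01, 0.2, 0.01))
        assert hi.or_ > lo.or_
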