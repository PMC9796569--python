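"""Compound-Poisson amplitude mixture, fitting and Monte-Carlo KS."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from rodspr.spr_stats import (
    AmplitudeModelParams,
    AmplitudeSample,
    FitError,
    build_polynomial_template,
    eq1_cdf,
    eq1_density,
    estimate_ensemble_amplitudes,
    estimate_trial_amplitude,
    fit_amplitude_histogram,
    ks_statistic,
    monte_carlo_ks_pvalue,
    poisson_k_max,
    sample_eq1,
)
from rodspr.trace import ResponseTrace

P_REF = AmplitudeModelParams(sigma0=0.2, m=1.0, sigma1=0.2, a=1.0)


def brute_force_density(r, p, k_terms=100):
    """Independent oracle: direct series summation in extended precision."""
    total = np.longdouble(0.0)
    for k in range(k_terms + 1):
        w = np.longdouble(math.exp(-p.m)) * np.longdouble(p.m) ** k / math.factorial(k)
        v = np.longdouble(p.sigma0**2 + k * p.sigma1**2)
        total += w * np.exp(-np.longdouble((r - k * p.a) ** 2) / (2 * v)) / np.sqrt(
            2 * np.longdouble(math.pi) * v
        )
    return float(total)


class TestDensity:
    def test_no_light_reduces_to_background_gaussian(self):
        p = AmplitudeModelParams(sigma0=1.0, m=0.0, sigma1=0.2, a=1.0)
        assert eq1_density(0.0, p) == pytest.approx(1 / math.sqrt(2 * math.pi), rel=1e-12)

    def test_symmetric_when_mean_amplitude_zero(self):
        p = AmplitudeModelParams(sigma0=0.3, m=0.7, sigma1=0.1, a=0.0)
        r = np.linspace(0.1, 2.0, 7)
        assert np.allclose(eq1_density(r, p), eq1_density(-r, p), rtol=1e-12)

    def test_matches_brute_force_summation(self):
        for r in (-0.3, 0.0, 0.5, 1.0, 2.3):
            assert eq1_density(r, P_REF) == pytest.approx(
                brute_force_density(r, P_REF), abs=1e-10
            )

    @pytest.mark.parametrize(
        "p",
        [
            P_REF,
            AmplitudeModelParams(0.1, 0.3, 0.05, 0.6),
            AmplitudeModelParams(0.5, 2.5, 0.4, 1.5),
            AmplitudeModelParams(0.2, 0.0, 0.0, 1.0),
        ],
    )
    def test_density_normalized(self, p):
        lo = -10 * p.sigma0
        hi = p.m * p.a + 10 * math.sqrt(p.variance) + 10
        val, err = integrate.quad(lambda r: eq1_density(r, p), lo, hi, limit=200)
        assert val == pytest.approx(1.0, abs=1e-5)

    def test_truncation_respects_tail_bound(self):
        for m in (0.1, 1.0, 5.0, 20.0):
            k_max = poisson_k_max(m)
            assert stats.poisson.sf(k_max, m) < 1e-6

    def test_cdf_matches_quadrature(self):
        p = P_REF
        for r in (-0.5, 0.2, 1.1):
            q = integrate.quad(lambda x: eq1_density(x, p), -12, r, limit=400)[0]
            assert eq1_cdf(r, p) == pytest.approx(q, abs=1e-8)


class TestSampler:
    def test_no_light_sample_sd_is_sigma0(self):
        p = AmplitudeModelParams(sigma0=0.37, m=0.0, sigma1=0.2, a=1.0)
        x = sample_eq1(p, 50_000, 0)
        assert x.std() == pytest.approx(0.37, rel=0.02)

    def test_moments_match_compound_poisson_formulas(self):
        """Mean m*a and variance sigma0^2 + m(a^2 + sigma1^2), within 3
        Monte-Carlo standard errors at n = 100,000."""
        p = P_REF
        n = 100_000
        x = sample_eq1(p, n, 1)
        se_mean = x.std(ddof=1) / math.sqrt(n)
        assert abs(x.mean() - p.mean) < 3 * se_mean
        var = x.var(ddof=1)
        se_var = var * math.sqrt(2.0 / (n - 1)) * 1.6  # kurtosis allowance
        assert abs(var - p.variance) < 3 * se_var

    def test_reproducible_per_seed(self):
        p = P_REF
        assert np.array_equal(sample_eq1(p, 100, 7), sample_eq1(p, 100, 7))
        assert not np.array_equal(sample_eq1(p, 100, 7), sample_eq1(p, 100, 8))

    def test_empirical_distribution_converges_to_density(self):
        p = P_REF
        d = [
            ks_statistic(sample_eq1(p, n, 2), p)
            for n in (500, 5_000, 50_000)
        ]
        assert d[0] > d[1] > d[2]
        assert d[2] < 0.01


class TestHistogramFit:
    @pytest.mark.parametrize("method", ["mle", "binned"])
    def test_parameter_recovery(self, method):
        """Median of 20 replicate fits (n = 500 draws from sigma0=0.2,
        m=0.8, sigma1=0.2, a=0.7) recovers each parameter within 15%."""
        truth = AmplitudeModelParams(0.2, 0.8, 0.2, 0.7)
        rng = np.random.default_rng(10)
        est = []
        for _ in range(20):
            x = sample_eq1(truth, 500, rng)
            p, _ = fit_amplitude_histogram(AmplitudeSample(x), method=method,
                                           n_restarts=1)
            est.append([p.sigma0, p.m, p.sigma1, p.a])
        med = np.median(est, axis=0)
        for got, want in zip(med, [0.2, 0.8, 0.2, 0.7]):
            assert got == pytest.approx(want, rel=0.15)

    def test_fitted_m_increases_with_flash_strength(self):
        rng = np.random.default_rng(11)
        ms = []
        for m_true in (0.4, 0.8, 1.6):
            truth = AmplitudeModelParams(0.2, m_true, 0.15, 0.7)
            x = sample_eq1(truth, 2_000, rng)
            p, _ = fit_amplitude_histogram(AmplitudeSample(x), n_restarts=1)
            ms.append(p.m)
        assert ms[0] < ms[1] < ms[2]

    def test_degenerate_sample_raises(self):
        with pytest.raises(FitError):
            fit_amplitude_histogram(AmplitudeSample(np.full(50, 0.3)))


class TestTrialAmplitude:
    def _mean_trace(self):
        t = np.arange(-500.0, 5000.0, 2.5)
        shape = np.where(t > 0, (t / 1000.0) ** 3 * np.exp(3 - 3 * t / 1000.0), 0.0)
        return ResponseTrace(t, 0.8 * shape / shape.max())

    def test_scaled_template_recovers_scale(self):
        mean = self._mean_trace()
        trial = ResponseTrace(mean.t, 0.75 * mean.r)
        a = estimate_trial_amplitude(trial, mean)
        # amplitude = 0.75 x (template peak x mean peak) = 0.75 x 0.8
        assert a == pytest.approx(0.75 * 0.8, rel=0.02)

    def test_pure_noise_amplitude_zero_mean(self):
        mean = self._mean_trace()
        rng = np.random.default_rng(12)
        amps = [
            estimate_trial_amplitude(
                ResponseTrace(mean.t, rng.normal(0, 0.1, len(mean.t))), mean
            )
            for _ in range(200)
        ]
        se = np.std(amps) / math.sqrt(len(amps))
        assert abs(np.mean(amps)) < 3 * se

    def test_template_is_smooth_polynomial_of_degree_7(self):
        mean = self._mean_trace()
        t_w, tmpl, peak = build_polynomial_template(mean)
        assert peak == pytest.approx(0.8, rel=1e-6)
        # a 7th-degree polynomial has at most 6 extrema
        sign_changes = np.sum(np.diff(np.sign(np.diff(tmpl))) != 0)
        assert sign_changes <= 6

    def test_short_trial_window_raises(self):
        mean = self._mean_trace()
        short = ResponseTrace(mean.t[:100], mean.r[:100])
        with pytest.raises(FitError):
            estimate_trial_amplitude(short, mean)


class TestKS:
    def test_model_quantiles_give_minimal_statistic(self):
        p = P_REF
        n = 200
        q = np.array([stats.norm.ppf((i + 0.5) / n) for i in range(n)])
        # transform uniform quantiles through the mixture CDF inverse by
        # root-finding on eq1_cdf
        from scipy.optimize import brentq

        u = (np.arange(n) + 0.5) / n
        x = np.array([brentq(lambda r: eq1_cdf(r, p) - ui, -5, 30) for ui in u])
        assert ks_statistic(x, p) <= 1.0 / n + 1e-9

    def test_gross_shift_detected(self):
        p = P_REF
        x = sample_eq1(p, 200, 3) + 5 * p.sigma0 + 5
        assert ks_statistic(x, p) > 0.9

    def test_matches_brute_force_double_loop(self):
        p = P_REF
        x = sample_eq1(p, 50, 4)
        xs = np.sort(x)
        cdf = np.array([eq1_cdf(v, p) for v in xs])
        d_brute = 0.0
        n = len(xs)
        for i in range(n):
            d_brute = max(d_brute, abs((i + 1) / n - cdf[i]), abs(i / n - cdf[i]))
        assert ks_statistic(x, p) == pytest.approx(d_brute, abs=1e-12)


class TestMonteCarloKS:
    def test_same_seed_same_pvalue(self):
        p = P_REF
        x = sample_eq1(p, 60, 5)
        a = monte_carlo_ks_pvalue(x, p, n_mc=2000, seed=9)
        b = monte_carlo_ks_pvalue(x, p, n_mc=2000, seed=9)
        assert a.p_value == b.p_value
        assert a.statistic == b.statistic

    def test_bimodal_data_strongly_rejected(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(-3, 0.05, 30), rng.normal(8, 0.05, 30)])
        res = monte_carlo_ks_pvalue(x, P_REF, n_mc=2000, seed=1)
        assert res.p_value < 0.01
        assert res.significant_disagreement

    def test_three_independent_runs_agree_within_mc_error(self):
        p = P_REF
        x = sample_eq1(p, 60, 13)
        ps = [
            monte_carlo_ks_pvalue(x, p, n_mc=4000, seed=s).p_value
            for s in (1, 2, 3)
        ]
        se = math.sqrt(0.25 / 4000)  # worst-case binomial SE
        assert max(ps) - min(ps) < 6 * se

    def test_type_one_error_calibrated(self):
        """Data drawn from the model itself, parameters held fixed (not
        re-fit): rejection rate at p < 0.05 is 5% +/- 2% over 300 independent
        datasets."""
        p = P_REF
        rng = np.random.default_rng(20)
        rejections = 0
        n_sets = 300
        for i in range(n_sets):
            x = sample_eq1(p, 60, rng)
            res = monte_carlo_ks_pvalue(x, p, n_mc=1000, seed=int(rng.integers(2**31)))
            rejections += res.p_value < 0.05
        rate = rejections / n_sets
        assert 0.03 <= rate <= 0.07
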