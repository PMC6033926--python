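"""Shifted exponential and shifted ex-Gaussian laws.

The ex-Gaussian implementation is cross-checked against an independent
route throughout: scipy's exponnorm family (same law, different
parameterisation and evaluation) and Monte-Carlo construction of
exponential-plus-normal sums.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from rutsync.distributions import ShiftedExGaussian, ShiftedExponential


def _exponnorm_oracle(d: ShiftedExGaussian):
    return stats.exponnorm(1.0 / (d.rate * d.gestation_sd), loc=d.location, scale=d.gestation_sd)


class TestShiftedExponential:
    @pytest.mark.parametrize(
        "rate, shift, x, expected",
        [
            (0.5, 2.0, 1.0, 0.0),               # below the support
            (0.5, 2.0, 2.0, 0.5),               # density at the shift equals the rate
            (0.1, 5.0, 15.0, 0.1 * np.exp(-1)), # direct evaluation one mean past the shift
        ],
    )
    def test_pdf_pointwise(self, rate, shift, x, expected):
        assert ShiftedExponential(rate, shift).pdf(x) == pytest.approx(expected, abs=1e-12)

    def test_support_and_moments(self):
        d = ShiftedExponential(0.1, 5.71)
        assert d.quantile(0.0) == 5.71
        assert d.mean == pytest.approx(15.71)
        assert d.sd == pytest.approx(10.0)
        assert d.quantile(0.8) - d.quantile(0.0) == pytest.approx(np.log(5) / 0.1, rel=1e-12)

    @pytest.mark.parametrize("bad", [dict(rate=0.0), dict(rate=-1.0), dict(rate=1.0, shift=-0.1)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ShiftedExponential(**{"shift": 0.0, **bad})

    def test_quantile_domain_error(self):
        d = ShiftedExponential(0.1)
        with pytest.raises(ValueError):
            d.quantile(1.2)
        with pytest.raises(ValueError):
            d.quantile(-0.01)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        rate=st.floats(1e-3, 50.0),
        shift=st.floats(0.0, 100.0),
    )
    def test_cdf_quantile_round_trip(self, rate, shift):
        d = ShiftedExponential(rate, shift)
        u = np.linspace(0.0, 0.999, 100)
        np.testing.assert_allclose(d.cdf(d.quantile(u)), u, atol=1e-10)

    def test_sampling_matches_moments(self, rng):
        d = ShiftedExponential(0.1, 5.71)
        x = d.sample(1_000_000, rng)
        assert np.all(x >= d.shift)
        se = d.sd / np.sqrt(x.size)
        assert abs(x.mean() - 15.71) < 3 * se

    def test_translation_shifts_quantiles_only(self):
        base = ShiftedExponential(0.25, 3.0)
        moved = ShiftedExponential(0.25, 3.0 + 7.5)
        u = np.linspace(0, 0.99, 50)
        np.testing.assert_allclose(moved.quantile(u), base.quantile(u) + 7.5, rtol=1e-12)
        assert moved.var == base.var


class TestShiftedExGaussian:
    @pytest.mark.parametrize(
        "params",
        [
            dict(rate=0.1025, shift=0.0, gestation_mean=258.0, gestation_sd=5.74),
            dict(rate=0.03, shift=4.03, gestation_mean=258.0, gestation_sd=5.74),
            dict(rate=2.0, shift=1.0, gestation_mean=10.0, gestation_sd=0.3),
            dict(rate=0.5, shift=0.0, gestation_mean=0.0, gestation_sd=20.0),
        ],
    )
    def test_pdf_cdf_quantile_match_exponnorm(self, params):
        d = ShiftedExGaussian(**params)
        o = _exponnorm_oracle(d)
        b = np.linspace(d.location - 6 * d.gestation_sd, d.location + 12 / d.rate, 200)
        np.testing.assert_allclose(d.pdf(b), o.pdf(b), rtol=1e-9, atol=1e-300)
        np.testing.assert_allclose(d.cdf(b), o.cdf(b), atol=1e-10)
        u = np.linspace(0.01, 0.99, 25)
        np.testing.assert_allclose(d.quantile(u), o.ppf(u), atol=1e-6)

    def test_density_integrates_to_one(self, calving_law):
        # split at the mode: the density is a narrow peak on an infinite line
        left, _ = integrate.quad(calving_law.pdf, -np.inf, calving_law.location, limit=200)
        right, _ = integrate.quad(calving_law.pdf, calving_law.location, np.inf, limit=200)
        assert abs(left + right - 1.0) < 1e-6

    def test_no_overflow_for_large_rate_sigma_squared(self):
        # naive erfc evaluation overflows when rate*sd^2 is large
        d = ShiftedExGaussian(rate=50.0, shift=0.0, gestation_mean=0.0, gestation_sd=30.0)
        b = np.linspace(-200, 200, 101)
        vals = d.pdf(b)
        assert np.all(np.isfinite(vals)) and np.all(vals >= 0)
        val, _ = integrate.quad(d.pdf, -400, 400, limit=400)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_gestation_limit_is_shifted_exponential(self):
        lam, tau, mu = 0.5, 2.0, 7.0
        d = ShiftedExGaussian(lam, tau, mu, 1e-4)
        e = ShiftedExponential(lam, tau + mu)
        b = tau + mu + 1.0
        assert d.pdf(b) == pytest.approx(e.pdf(b), rel=1e-4)

    def test_variance_identity(self):
        d = ShiftedExGaussian(0.1025, 0.0, 258.0, 5.74)
        assert d.var == pytest.approx(1 / 0.1025**2 + 5.74**2, rel=1e-12)
        # location parameters have no effect on the spread
        d2 = ShiftedExGaussian(0.1025, 40.0, 100.0, 5.74)
        assert d2.var == d.var

    def test_construction_sampling_matches_closed_form(self, calving_law, rng):
        x = calving_law.sample(1_000_000, rng)
        se_mean = calving_law.sd / np.sqrt(x.size)
        assert abs(x.mean() - calving_law.mean) < 3 * se_mean
        # variance of B = M + G matches Var(M) + Var(G) within MC error
        m4 = stats.moment(x, 4)
        se_var = np.sqrt((m4 - calving_law.var**2) / x.size)
        assert abs(x.var() - calving_law.var) < 3 * se_var
        # distribution check: bin frequencies against CDF increments
        edges = calving_law.quantile(np.linspace(0.02, 0.98, 13))
        freq, _ = np.histogram(x, bins=edges)
        prob = np.diff(calving_law.cdf(edges))
        se = np.sqrt(prob * (1 - prob) / x.size)
        assert np.all(np.abs(freq / x.size - prob) < 5 * se)

    def test_pdf_equals_numerical_convolution(self):
        # trapezoid convolution of the exponential and normal densities
        lam, tau, mu, sd = 0.1025, 5.71, 258.0, 5.74
        d = ShiftedExGaussian(lam, tau, mu, sd)
        e = ShiftedExponential(lam, tau)
        xs = np.arange(tau, tau + 160.0 / lam, 0.01)
        fm = e.pdf(xs)
        bs = np.linspace(d.location - 5 * sd, d.location + 10 / lam, 60)
        for b in bs:
            conv = np.trapezoid(fm * stats.norm.pdf(b - xs, loc=mu, scale=sd), xs)
            assert abs(conv - d.pdf(b)) < 1e-6

    def test_cdf_quantile_round_trip(self):
        d = ShiftedExGaussian(0.1, 3.0, 250.0, 6.0)
        u = np.linspace(0.001, 0.999, 100)
        np.testing.assert_allclose(d.cdf(d.quantile(u)), u, atol=1e-8)

    def test_translation_invariance(self):
        a = ShiftedExGaussian(0.2, 1.0, 50.0, 4.0)
        b = ShiftedExGaussian(0.2, 1.0 + 13.25, 50.0, 4.0)
        u = np.linspace(0.05, 0.95, 10)
        np.testing.assert_allclose(b.quantile(u), a.quantile(u) + 13.25, atol=1e-6)
        assert a.var == b.var

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ShiftedExGaussian(0.0, 0.0, 258.0, 5.74)
        with pytest.raises(ValueError):
            ShiftedExGaussian(0.1, 0.0, 258.0, 0.0)
        with pytest.raises(ValueError):
            ShiftedExGaussian(0.1, -1.0, 258.0, 5.74)
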