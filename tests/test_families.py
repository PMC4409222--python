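"""Densities, samplers and scale-factor conditionals of the N/I families."""

import numpy as np
import pytest
from scipy import integrate, stats

from nide.families import (LocationScale, NIFamilySpec, conditional_scale_draw,
                           marginal_pdf, mixing_density, sample_nid)

from conftest import quadrature_cdf

SPECS = {
    "normal": NIFamilySpec.normal(),
    "t": NIFamilySpec.t(4.0),
    "slash": NIFamilySpec.slash(2.0),
    "contaminated_normal": NIFamilySpec.contaminated_normal(0.1, 0.25),
    "laplace": NIFamilySpec.laplace(1.0),
}


class TestSpecValidation:
    @pytest.mark.parametrize("family,shape", [
        ("t", (-1.0,)), ("slash", (0.0,)), ("laplace", (-2.0,)),
        ("contaminated_normal", (0.5,)), ("contaminated_normal", (1.5, 0.5)),
        ("normal", (1.0,)), ("nonsense", ()),
    ])
    def test_invalid_shapes_rejected(self, family, shape):
        with pytest.raises(ValueError):
            NIFamilySpec(family, shape)

    def test_aliases_resolve(self):
        assert NIFamilySpec("cn", (0.1, 0.2)).family == "contaminated_normal"
        assert NIFamilySpec("lap", (1.0,)).family == "laplace"

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            LocationScale(0.0, -1.0)


class TestMixingDensity:
    def test_slash_v1_is_uniform(self):
        assert mixing_density(0.5, NIFamilySpec.slash(1.0)) == pytest.approx(1.0)

    def test_cn_point_masses(self):
        spec = SPECS["contaminated_normal"]
        assert mixing_density(0.25, spec) == pytest.approx(0.1)
        assert mixing_density(1.0, spec) == pytest.approx(0.9)
        assert mixing_density(0.5, spec) == 0.0

    def test_t_mixing_is_gamma(self):
        # v=4: u ~ Gamma(2, rate 2), density at 1 is 2^2 * 1 * e^-2 / 1!
        assert mixing_density(1.0, SPECS["t"]) == pytest.approx(4.0 * np.exp(-2.0))

    def test_nonpositive_u_rejected(self):
        with pytest.raises(ValueError):
            mixing_density(0.0, SPECS["t"])

    @pytest.mark.parametrize("spec", [
        NIFamilySpec.t(1.0), NIFamilySpec.t(8.0), NIFamilySpec.slash(0.5),
        NIFamilySpec.slash(3.0), NIFamilySpec.laplace(0.5),
        NIFamilySpec.laplace(4.0)])
    def test_continuous_mixing_integrates_to_one(self, spec):
        val, _ = integrate.quad(lambda u: mixing_density(u, spec), 0, np.inf,
                                limit=300)
        assert val == pytest.approx(1.0, abs=1e-6)


class TestMarginalPdf:
    def test_standard_normal_at_mode(self):
        loc = LocationScale(0.0, 1.0)
        assert marginal_pdf(0.0, loc, SPECS["normal"]) == \
            pytest.approx(1.0 / np.sqrt(2 * np.pi))

    def test_cn_is_two_component_mixture(self):
        loc = LocationScale(0.0, 1.0)
        expected = 0.1 * stats.norm.pdf(0, 0, 2.0) + 0.9 * stats.norm.pdf(0, 0, 1.0)
        assert marginal_pdf(0.0, loc, SPECS["contaminated_normal"]) == \
            pytest.approx(expected)

    def test_slash_matches_bruteforce_quadrature(self):
        # independent oracle: dense trapezoid over the (0,1) mixing support
        u = np.linspace(1e-9, 1.0, 400001)
        oracle = np.trapezoid(np.sqrt(u / (2 * np.pi)) * np.exp(-u / 2.0)
                              * 2.0 * u, u)
        got = marginal_pdf(1.0, LocationScale(0.0, 1.0), SPECS["slash"])
        assert got == pytest.approx(oracle, rel=1e-5)

    @pytest.mark.parametrize("spec", [
        NIFamilySpec.normal(), NIFamilySpec.t(2.0), NIFamilySpec.t(4.0),
        NIFamilySpec.t(30.0), NIFamilySpec.slash(1.0), NIFamilySpec.slash(2.0),
        NIFamilySpec.slash(4.0), NIFamilySpec.contaminated_normal(0.1, 0.1),
        NIFamilySpec.contaminated_normal(0.1, 0.25),
        NIFamilySpec.contaminated_normal(0.5, 0.5), NIFamilySpec.laplace(0.5),
        NIFamilySpec.laplace(1.0), NIFamilySpec.laplace(3.0)])
    def test_integrates_to_one(self, spec):
        # full-line integral via y = mu + tan(theta): the substitution keeps
        # the integrand bounded even for polynomial tails (t small df, slash)
        loc = LocationScale(1.5, 2.0)

        def g(theta):
            t = np.tan(theta)
            return marginal_pdf(loc.mu + t, loc, spec) * (1.0 + t * t)

        val, _ = integrate.quad(g, -np.pi / 2, np.pi / 2, limit=400,
                                points=[0.0])
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("name", ["t", "slash", "contaminated_normal",
                                      "laplace"])
    def test_heavier_tails_than_normal(self, name):
        loc = LocationScale(0.0, 1.0)
        y = 10.0 * np.sqrt(loc.sigma)
        ratio = marginal_pdf(y, loc, SPECS[name]) / stats.norm.pdf(y, 0, 1)
        assert ratio > 1.0

    def test_t_large_df_approaches_normal(self):
        loc = LocationScale(0.5, 2.0)
        y = np.linspace(loc.mu - 5 * np.sqrt(2.0), loc.mu + 5 * np.sqrt(2.0), 501)
        diff = np.abs(marginal_pdf(y, loc, NIFamilySpec.t(1e4))
                      - marginal_pdf(y, loc, SPECS["normal"]))
        assert diff.max() < 1e-4


class TestSampleNid:
    def test_normal_sample_mean(self, rng):
        y = sample_nid(LocationScale(14.0, 1.0), SPECS["normal"], 10 ** 5, rng)
        assert abs(y.mean() - 14.0) < 3.0 / np.sqrt(10 ** 5)

    def test_t_sample_matches_t_cdf(self, rng):
        y = sample_nid(LocationScale(0.0, 1.0), NIFamilySpec.t(2.0), 10 ** 5, rng)
        # 1% critical value of the one-sample KS statistic
        assert stats.kstest(y, stats.t(2).cdf).pvalue > 0.01

    def test_cn_contamination_fraction(self, rng):
        spec = NIFamilySpec.contaminated_normal(0.1, 0.25)
        _, u = sample_nid(LocationScale(0.0, 1.0), spec, 10 ** 5, rng,
                          return_u=True)
        frac = (u == 0.25).mean()
        assert abs(frac - 0.1) < 3 * np.sqrt(0.1 * 0.9 / 10 ** 5)

    @pytest.mark.parametrize("name", sorted(SPECS))
    def test_deterministic_given_seed(self, name):
        a = sample_nid(LocationScale(0.0, 1.0), SPECS[name], 100,
                       np.random.default_rng(5))
        b = sample_nid(LocationScale(0.0, 1.0), SPECS[name], 100,
                       np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_laplace_sample_matches_laplace_cdf(self, rng):
        y = sample_nid(LocationScale(0.0, 1.0), NIFamilySpec.laplace(1.0),
                       10 ** 5, rng)
        b = np.sqrt(1.0 / 2.0)
        assert stats.kstest(y, stats.laplace(scale=b).cdf).pvalue > 0.01


class TestConditionalScaleDraw:
    def test_t_zero_residual_is_gamma(self, rng):
        # kernel collapses to u^{1/2} * prior => Gamma((v+1)/2, v/2)
        d = conditional_scale_draw(0.0, 1.0, NIFamilySpec.t(4.0), rng,
                                   size=10 ** 5)
        assert stats.kstest(d, stats.gamma(2.5, scale=0.5).cdf).pvalue > 0.01

    def test_cn_two_point_weight(self, rng):
        spec = NIFamilySpec.contaminated_normal(0.1, 0.25)
        d = conditional_scale_draw(0.0, 1.0, spec, rng, size=10 ** 5)
        # P(u=gamma) = lam*sqrt(gam) / (lam*sqrt(gam) + 1 - lam) = 1/19
        frac = (d == 0.25).mean()
        p = 1.0 / 19.0
        assert abs(frac - p) < 4 * np.sqrt(p * (1 - p) / 10 ** 5)

    def test_zero_residual_degenerate_cases_exact(self, rng):
        # slash: kernel u^{v+1/2-1} on (0,1) => Beta(v+1/2, 1)
        d = conditional_scale_draw(0.0, 2.0, SPECS["slash"], rng, size=10 ** 5)
        assert stats.kstest(d, stats.beta(2.5, 1.0).cdf).pvalue > 0.01
        # laplace: kernel u^{-3/2} e^{-v/u} => inverse gamma(1/2, v)
        d = conditional_scale_draw(0.0, 1.0, SPECS["laplace"], rng, size=10 ** 5)
        assert stats.kstest(d, stats.invgamma(0.5, scale=1.0).cdf).pvalue > 0.01

    @pytest.mark.parametrize("name,e,tau", [
        ("t", 1.5, 0.8), ("slash", 0.7, 2.0), ("laplace", 1.2, 1.0)])
    def test_matches_quadrature_normalised_kernel(self, name, e, tau, rng):
        spec = SPECS[name]

        def log_kernel(u):
            with np.errstate(divide="ignore"):
                return (0.5 * np.log(u) - 0.5 * u * tau * e ** 2
                        + np.log(mixing_density(u, spec)))

        hi = 1.0 if name == "slash" else 60.0
        cdf = quadrature_cdf(log_kernel, 1e-9, hi)
        d = conditional_scale_draw(e, tau, spec, rng, size=10 ** 5)
        assert stats.ks_1samp(d, cdf).pvalue > 0.01

    def test_normal_family_returns_unit_scale(self, rng):
        d = conditional_scale_draw(3.0, 1.0, SPECS["normal"], rng, size=10)
        np.testing.assert_array_equal(d, np.ones(10))

    def test_invalid_tau_rejected(self, rng):
        with pytest.raises(ValueError):
            conditional_scale_draw(1.0, 0.0, SPECS["t"], rng)
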