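"""Diameter (truncated GEV) and orientation (truncated exponential) laws:
fitting, sampling, and summary statistics."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from axonrve.errors import DomainError, FitError, InputError, ParameterError
from axonrve.histology import (
    DiameterDistribution,
    HistologySummary,
    OrientationDistribution,
    fit_diameter_model,
    fit_orientation_model,
    sample_diameters,
    sample_orientation,
    sample_orientations,
    summarize_measurements,
)

from conftest import CONTROL_SUMMARY, CONTROL_TRUNCATION


class TestGevDensity:
    def test_gumbel_value_at_location(self):
        """xi = 0 at y = nu: pdf = exp(-1)/omega (t = 1)."""
        d = DiameterDistribution(xi=0.0, nu=0.8, omega=0.25, d_min=0.1, d_max=3.0)
        assert d.pdf(0.8) == pytest.approx(math.exp(-1.0) / 0.25, rel=1e-12)

    def test_cdf_limits_at_support_ends(self):
        d = DiameterDistribution(xi=0.2, nu=0.8, omega=0.2, d_min=0.1, d_max=3.0)
        lo, _ = d.support()
        assert d.cdf(lo) == pytest.approx(0.0, abs=1e-12)
        assert d.cdf(1e6) == pytest.approx(1.0, abs=1e-12)

    def test_pdf_outside_support_rejected(self):
        d = DiameterDistribution(xi=0.5, nu=1.0, omega=0.2, d_min=0.1, d_max=3.0)
        lo, _ = d.support()
        with pytest.raises(DomainError):
            d.pdf(lo - 0.01)

    @pytest.mark.parametrize("xi", [-0.3, 0.0, 0.25])
    def test_cdf_increment_matches_quadrature_of_pdf(self, xi):
        d = DiameterDistribution(xi=xi, nu=0.85, omega=0.22, d_min=0.3, d_max=2.0)
        a, b = 0.5, 1.4
        quad, _ = integrate.quad(d.pdf, a, b, epsabs=1e-12, epsrel=1e-12)
        assert d.cdf(b) - d.cdf(a) == pytest.approx(quad, abs=1e-8)

    def test_shape_continuity_at_xi_zero(self):
        """pdf is continuous across the xi = 0 branch switch."""
        y = np.linspace(0.5, 1.3, 9)
        base = DiameterDistribution(0.0, 0.85, 0.22, 0.3, 2.0).pdf(y)
        for xi in (1e-8, -1e-8):
            near = DiameterDistribution(xi, 0.85, 0.22, 0.3, 2.0).pdf(y)
            assert np.max(np.abs(near - base) / base) < 1e-6


class TestDiameterFit:
    def test_control_summary_is_reproduced(self, control_diameters):
        """Truncated model matches the measured control-group mean/variance/
        median within 1%; large-sample mean ~ 0.8646 um."""
        m, v, md = control_diameters.truncated_moments()
        assert m == pytest.approx(CONTROL_SUMMARY.mean, rel=0.01)
        assert v == pytest.approx(CONTROL_SUMMARY.variance, rel=0.01)
        assert md == pytest.approx(CONTROL_SUMMARY.median, rel=0.01)
        x = control_diameters.sample(100_000, 11)
        assert x.mean() == pytest.approx(0.8646, rel=0.01)

    def test_round_trip_recovers_known_parameters(self):
        """fit(sample stats of a known GEV) recovers (xi, nu, omega) ~ 5%."""
        truth = DiameterDistribution(xi=0.1, nu=0.8, omega=0.2, d_min=0.05, d_max=5.0)
        m, v, md = truth.truncated_moments()
        summary = HistologySummary(
            n_axons=10**6, mean=m, sd=math.sqrt(v), median=md, variance=v,
            value_range=truth.d_max - truth.d_min,
        )
        got = fit_diameter_model(summary, (truth.d_min, truth.d_max))
        assert got.xi == pytest.approx(truth.xi, abs=0.05 * max(1.0, abs(truth.xi)))
        assert got.nu == pytest.approx(truth.nu, rel=0.05)
        assert got.omega == pytest.approx(truth.omega, rel=0.05)

    def test_zero_variance_rejected(self):
        s = HistologySummary(10, 0.8, 0.0, 0.8, 0.0, 0.0)
        with pytest.raises(FitError):
            fit_diameter_model(s, (0.4, 1.6))

    def test_median_outside_range_rejected(self):
        s = HistologySummary(10, 0.8, 0.2, 2.5, 0.04, 1.0)
        with pytest.raises(FitError):
            fit_diameter_model(s, (0.4, 1.6))


class TestDiameterSampling:
    def test_empty_draw(self, control_diameters):
        assert len(sample_diameters(control_diameters, 0, 1)) == 0

    def test_all_samples_within_truncation(self, control_diameters):
        x = sample_diameters(control_diameters, 100_000, 2)
        assert x.min() >= CONTROL_TRUNCATION[0]
        assert x.max() <= CONTROL_TRUNCATION[1]

    @pytest.mark.parametrize("n", [10_000, 100_000])
    def test_ecdf_converges_to_model_cdf(self, control_diameters, n):
        """KS distance below the 2/sqrt(n) envelope (and < 0.01 at 1e5)."""
        x = np.sort(sample_diameters(control_diameters, n, 3))
        ecdf = np.arange(1, n + 1) / n
        model = control_diameters.truncated_cdf(x)
        ks = np.max(np.abs(ecdf - model))
        assert ks < 2.0 / math.sqrt(n)
        if n >= 100_000:
            assert ks < 0.01


class TestOrientation:
    def test_cdf_at_zero_vanishes(self):
        for kappa in (0.05, 0.2, 1.0):
            assert OrientationDistribution(kappa, 60.0).cdf(0.0) == 0.0

    def test_rate_from_range_closed_form(self):
        d = fit_orientation_model(31.0, cap_quantile=0.99)
        assert d.kappa == pytest.approx(-math.log(0.01) / 31.0, rel=1e-12)
        assert d.cdf(31.0) == pytest.approx(0.99, rel=1e-12)

    def test_cdf_strictly_increasing(self):
        d = fit_orientation_model(31.0)
        y = np.linspace(0.0, 31.0, 200)
        assert np.all(np.diff(d.cdf(y)) > 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ParameterError):
            fit_orientation_model(-5.0)
        with pytest.raises(ParameterError):
            OrientationDistribution(kappa=0.0, theta_max=30.0)

    def test_sampled_angles_truncated_and_unit_vectors(self, control_orientations):
        theta, phi, p = sample_orientations(control_orientations, 20_000, 5)
        assert theta.min() >= 0.0
        assert theta.max() <= control_orientations.theta_max
        assert np.allclose(np.linalg.norm(p, axis=1), 1.0, atol=1e-12)

    def test_azimuth_uniform_mean(self, control_orientations):
        n = 100_000
        _, phi, _ = sample_orientations(control_orientations, n, 6)
        se = 360.0 / math.sqrt(12.0 * n)
        assert abs(phi.mean() - 180.0) < 3.0 * se

    def test_single_draw_convention(self, control_orientations):
        v = sample_orientation(control_orientations, 7)
        th, ph = math.radians(v.theta), math.radians(v.phi)
        expected = (math.cos(th), math.sin(th) * math.sin(ph), math.sin(th) * math.cos(ph))
        assert np.allclose(v.p, expected, atol=1e-12)

    def test_theta_distribution_matches_truncated_exponential(self, control_orientations):
        theta = control_orientations.sample_theta(50_000, 8)
        cap = control_orientations.cdf(control_orientations.theta_max)
        ref = control_orientations.cdf(np.sort(theta)) / cap
        ecdf = np.arange(1, len(theta) + 1) / len(theta)
        assert np.max(np.abs(ecdf - ref)) < 2.0 / math.sqrt(len(theta))


class TestSummaries:
    def test_constant_sample(self):
        s = summarize_measurements([0.8] * 10)
        assert s.variance == 0.0
        assert s.value_range == 0.0
        assert s.median == 0.8

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            summarize_measurements([])

    def test_matches_independent_streaming_statistics(self):
        """Welford's streaming algorithm as a second implementation."""
        rng = np.random.default_rng(9)
        x = rng.gamma(4.0, 0.2, size=501)
        mean, m2 = 0.0, 0.0
        for k, v in enumerate(x, start=1):
            delta = v - mean
            mean += delta / k
            m2 += delta * (v - mean)
        var = m2 / (len(x) - 1)
        s = summarize_measurements(x)
        assert s.mean == pytest.approx(mean, rel=1e-12)
        assert s.variance == pytest.approx(var, rel=1e-10)
        assert s.sd == pytest.approx(math.sqrt(var), rel=1e-10)
        assert s.median == pytest.approx(float(np.median(x)), rel=1e-12)

    def test_synthetic_control_sample_mean(self, control_diameters):
        """n = 115 draws from the fitted model: mean within 3 SE of 0.8646."""
        x = control_diameters.sample(115, 10)
        se = CONTROL_SUMMARY.sd / math.sqrt(115)
        assert abs(x.mean() - 0.8646) < 3.0 * se
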