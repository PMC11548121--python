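"""HG model, tabulated phase functions, samplers and suspension spectra."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import kstest

import collitrans as ct
from collitrans.scattering import DEPENDENT_SCATTERING_THRESHOLD


class TestHenyeyGreenstein:
    @pytest.mark.parametrize("g", [0.0, 0.5, 0.9, -0.3])
    def test_pdf_normalised_over_solid_angle(self, g):
        val, _ = quad(lambda th: 2 * np.pi * ct.hg_pdf(th, g) * np.sin(th),
                      0, np.pi, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_isotropic_sampling_uniform(self, rng):
        mu = ct.hg_sample(0.0, rng, 200_000)
        assert kstest(mu, "uniform", args=(-1, 2)).pvalue > 1e-3

    @pytest.mark.parametrize("g", [0.5, 0.9, 0.99, 0.999])
    def test_moment_recovery(self, g, rng):
        n = 10**6
        mu = ct.hg_sample(g, rng, n)
        se = mu.std(ddof=1) / np.sqrt(n)
        assert abs(mu.mean() - g) < 4 * se

    def test_cone_fraction_closed_form_value(self):
        # hand evaluation of the HG CDF
        assert ct.hg_cone_fraction(0.999, 4.95e-4) == pytest.approx(0.1038, abs=2e-4)

    @pytest.mark.parametrize("g,theta_c", [
        (0.9, 0.01), (0.5, 0.3), (0.0, 0.1), (-0.4, 1.0), (0.99, 1e-3),
    ])
    def test_cone_fraction_matches_quadrature(self, g, theta_c):
        num, _ = quad(lambda th: 2 * np.pi * ct.hg_pdf(th, g) * np.sin(th),
                      0, theta_c, limit=500)
        assert ct.hg_cone_fraction(g, theta_c) == pytest.approx(num, abs=1e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ct.InvalidInputError):
            ct.hg_pdf(0.1, 1.0)
        with pytest.raises(ct.InvalidInputError):
            ct.hg_cone_fraction(0.5, 4.0)


class TestTabulatedPhaseFunctions:
    def test_normalisation_and_anisotropy_bookkeeping(self):
        theta = np.linspace(0, np.pi, 4001)
        pf = ct.PhaseFunction.tabulated(theta, ct.hg_pdf(theta, 0.7))
        assert 2 * np.pi * np.trapezoid(pf.p * np.sin(theta), theta) == \
            pytest.approx(1.0, abs=1e-6)
        assert pf.g == pytest.approx(0.7, abs=1e-4)

    def test_unnormalised_table_rejected_without_renormalise(self):
        theta = np.linspace(0, np.pi, 101)
        with pytest.raises(ct.InvalidInputError):
            ct.PhaseFunction.tabulated(theta, np.ones_like(theta),
                                       renormalize=False)

    def test_two_point_isotropic_table_samples_uniform(self, rng):
        pf = ct.PhaseFunction.tabulated(np.linspace(0, np.pi, 721),
                                        np.full(721, 1 / (4 * np.pi)))
        mu = ct.sample_tabulated(pf, rng, 100_000)
        assert kstest(mu, "uniform", args=(-1, 2)).pvalue > 1e-3

    def test_tabulated_hg_matches_exact_sampler_moments(self, rng):
        g = 0.9
        theta = np.concatenate([np.geomspace(1e-5, 0.3, 2000),
                                np.linspace(0.3, np.pi, 2000)[1:]])
        pf = ct.PhaseFunction.tabulated(theta, ct.hg_pdf(theta, g))
        n = 10**6
        mu_tab = ct.sample_tabulated(pf, rng, n)
        se = mu_tab.std(ddof=1) / np.sqrt(n)
        assert abs(mu_tab.mean() - g) < 4 * se

    def test_mie_table_sampled_anisotropy(self, mie_phase_1um, rng):
        n = 10**6
        mu = ct.sample_tabulated(mie_phase_1um, rng, n)
        se = mu.std(ddof=1) / np.sqrt(n)
        assert abs(mu.mean() - mie_phase_1um.g) < 4 * se

    def test_sampling_requires_tabulated_kind(self, rng):
        with pytest.raises(ct.InvalidInputError):
            ct.sample_tabulated(ct.PhaseFunction.hg(0.5), rng)


class TestMiePhaseTable:
    def test_table_anisotropy_matches_series_g(self, mie_phase_1um):
        series_g = ct.mie_single(np.pi * 1.0e3 * 1.33 / 600.0, 1.586 / 1.33).g
        assert mie_phase_1um.g == pytest.approx(series_g, abs=1e-3)

    def test_rayleigh_shape_in_small_sphere_limit(self):
        theta = np.linspace(0, np.pi, 721)
        pf = ct.phase_function_table(0.01, 1.5, theta)
        shape = 1 + np.cos(theta) ** 2
        ratio = pf.p / shape
        assert np.allclose(ratio, ratio[0], rtol=1e-3)

    def test_forward_lobe_width_is_diffractive(self):
        # 100 um spheres at 600 nm in water: the forward lobe's first zero
        # sits at the Airy angle 1.22*pi/x
        x = np.pi * 100e3 * 1.33 / 600.0
        pf = ct.phase_function_table(x, 1.586 / 1.33)
        airy = 1.22 * np.pi / x
        sel = (pf.theta > 0.5 * airy) & (pf.theta < 1.5 * airy)
        theta_min = pf.theta[sel][np.argmin(pf.p[sel])]
        assert theta_min == pytest.approx(airy, rel=0.15)
        # and that lobe dominates: half the scattered power within ~the lobe
        assert pf.cone_fraction(airy) > 0.3


class TestSuspensionSpectra:
    def test_zero_concentration_zero_mus(self):
        susp = ct.SphereSuspension(diameter_um=2.0, volume_fraction=0.0)
        wl = np.array([500.0, 800.0])
        assert np.allclose(ct.scattering_coefficient_spectrum(susp, wl), 0.0)

    def test_linear_in_concentration(self):
        wl = np.linspace(400, 1000, 7)
        susp = ct.SphereSuspension(diameter_um=2.002, sd_um=0.012,
                                   volume_fraction=1e-3)
        mus1 = ct.scattering_coefficient_spectrum(susp, wl)
        mus2 = ct.scattering_coefficient_spectrum(
            susp.replace(volume_fraction=2e-3), wl)
        assert np.allclose(mus2, 2 * mus1, rtol=1e-12)

    def test_monodisperse_equals_vanishing_polydispersity(self):
        wl = np.linspace(400, 1000, 5)
        susp = ct.SphereSuspension(diameter_um=3.917, volume_fraction=1e-3)
        mono = ct.scattering_coefficient_spectrum(susp, wl)
        tiny = ct.scattering_coefficient_spectrum(
            susp.replace(sd_um=1e-6), wl)
        assert np.allclose(tiny, mono, rtol=1e-6)

    def test_dependent_scattering_warning(self):
        with pytest.warns(UserWarning, match="dependent"):
            ct.SphereSuspension(diameter_um=2.0,
                                volume_fraction=DEPENDENT_SCATTERING_THRESHOLD + 0.01)

    def test_dispersive_medium_index_accepted(self):
        table = (np.array([300.0, 2200.0]), np.array([1.34, 1.32]))
        susp = ct.SphereSuspension(diameter_um=1.0, n_medium=table,
                                   volume_fraction=1e-3)
        mus = ct.scattering_coefficient_spectrum(susp, np.array([600.0]))
        assert mus[0] > 0

    def test_invalid_suspension(self):
        with pytest.raises(ct.InvalidInputError):
            ct.SphereSuspension(diameter_um=-1.0)
        with pytest.raises(ct.InvalidInputError):
            ct.SphereSuspension(diameter_um=1.0, sd_um=-0.1)
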