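"""Spectrum I/O, masked interpolation and the evaluation pipeline."""

import numpy as np
import pytest

import collitrans as ct
from collitrans.multireflection import cuvette_total_transmission


class TestSpectrumIO:
    def test_write_read_roundtrip_preserves_values_and_mask(self, tmp_path):
        wl = np.arange(500.0, 520.0)
        vals = np.sin(wl / 10.0) + 2.0
        mask = np.ones(wl.size, bool)
        mask[5:8] = False
        s = ct.Spectrum(wl, vals, mask)
        path = tmp_path / "s.csv"
        ct.write_spectrum(s, path)
        back = ct.read_spectrum(path)
        assert np.array_equal(back.wavelength_nm, wl)
        assert np.array_equal(back.mask, mask)
        assert np.allclose(back.values[mask], vals[mask])

    def test_descending_grid_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("wavelength_nm,value\n500,1.0\n499,1.1\n")
        with pytest.raises(ct.SpectrumParseError, match="line 3"):
            ct.read_spectrum(path)

    def test_nan_rows_become_mask(self, tmp_path):
        path = tmp_path / "nan.csv"
        path.write_text("wavelength_nm,value\n500,1.0\n501,nan\n502,1.2\n")
        s = ct.read_spectrum(path)
        assert list(s.mask) == [True, False, True]

    def test_headerless_file_accepted(self, tmp_path):
        path = tmp_path / "plain.csv"
        path.write_text("500,1.0\n501,1.1\n502,1.2\n")
        s = ct.read_spectrum(path)
        assert len(s) == 3 and s.values[0] == 1.0

    def test_constructor_validation(self):
        with pytest.raises(ct.InvalidInputError):
            ct.Spectrum(np.array([2.0, 1.0]), np.array([0.0, 0.0]))


class TestInterpolateMasked:
    def test_unmasked_is_identity(self):
        s = ct.Spectrum(np.arange(5.0), np.arange(5.0) ** 2)
        out = ct.interpolate_masked(s)
        assert np.allclose(out.values, s.values)

    def test_single_gap_between_equal_neighbours(self):
        vals = np.array([2.0, np.nan, 2.0])
        out = ct.interpolate_masked(ct.Spectrum(np.arange(3.0), vals))
        assert out.values[1] == pytest.approx(2.0)
        assert out.mask.all()

    def test_linear_ramp_restored_exactly(self):
        wl = np.arange(10.0)
        vals = 3.0 * wl + 1.0
        masked = vals.copy()
        masked[3:7] = np.nan
        out = ct.interpolate_masked(ct.Spectrum(wl, masked))
        assert np.allclose(out.values, vals)

    def test_edge_gaps_stay_masked(self):
        vals = np.array([np.nan, 1.0, np.nan, 3.0, np.nan])
        out = ct.interpolate_masked(ct.Spectrum(np.arange(5.0), vals))
        assert list(out.mask) == [False, True, True, True, False]
        assert out.values[2] == pytest.approx(2.0)

    def test_fully_masked_is_an_error(self):
        s = ct.Spectrum(np.arange(3.0), np.full(3, np.nan))
        with pytest.raises(ct.InvalidInputError):
            ct.interpolate_masked(s)


class TestExtinctionSpectrum:
    def test_sample_equal_reference_gives_zero(self, quartz_water_cuvette):
        wl = np.arange(500.0, 510.0)
        s = ct.Spectrum(wl, np.full(wl.size, 0.8))
        mu = ct.extinction_spectrum(s, s.copy(), quartz_water_cuvette)
        assert np.allclose(mu.values[mu.mask], 0.0, atol=1e-12)

    def test_grid_mismatch_is_explicit(self, quartz_water_cuvette):
        a = ct.Spectrum(np.arange(500.0, 510.0), np.ones(10))
        b = ct.Spectrum(np.arange(501.0, 511.0), np.ones(10))
        with pytest.raises(ct.GridMismatchError):
            ct.extinction_spectrum(a, b, quartz_water_cuvette)

    def test_synthetic_fixture_roundtrip(self, small_fixture, small_fixture_spec):
        mu = ct.extinction_spectrum(small_fixture.sample,
                                    small_fixture.reference,
                                    small_fixture_spec.cuvette)
        assert mu.mask.all()
        assert np.allclose(mu.values, small_fixture.mus_true.values, atol=1e-10)

    def test_saturated_band_masked_not_fabricated(self, quartz_water_cuvette):
        wl = np.arange(500.0, 505.0)
        ref = ct.Spectrum(wl, np.ones(wl.size))
        vals = np.full(wl.size, 0.5)
        vals[2] = 1.5                       # impossible transmission
        mu = ct.extinction_spectrum(ct.Spectrum(wl, vals), ref,
                                    quartz_water_cuvette)
        assert not mu.mask[2]
        assert mu.mask[[0, 1, 3, 4]].all()

    def test_naive_flag_reproduces_uncorrected_bias(self, quartz_water_cuvette):
        spec = quartz_water_cuvette
        mua = 0.001
        wl = np.arange(500.0, 503.0)
        tm = np.full(wl.size, np.exp(-mua * spec.path_length_mm))
        t_ratio = np.asarray(cuvette_total_transmission(spec, tm)) / \
            np.asarray(cuvette_total_transmission(spec, 1.0))
        sample = ct.Spectrum(wl, t_ratio)
        ref = ct.Spectrum(wl, np.ones(wl.size))
        corrected = ct.extinction_spectrum(sample, ref, spec)
        naive = ct.extinction_spectrum(sample, ref, spec, naive=True)
        assert np.allclose(corrected.values, mua, rtol=1e-9)
        expected_bias = ct.neglect_multireflection_error(spec, [mua])[0]
        got_bias = (naive.values[0] - mua) / mua
        assert got_bias == pytest.approx(expected_bias, rel=1e-6)

    def test_concentration_equivariance(self, small_fixture_spec):
        base = small_fixture_spec
        doubled = ct.FixtureSpec(
            suspension=base.suspension.replace(
                volume_fraction=2 * base.suspension.volume_fraction),
            cuvette=base.cuvette, wavelength_nm=base.wavelength_nm,
            noise_sd=0.0, masked_intervals_nm=(), seed=base.seed)
        f1 = ct.generate_measurement_pair(base)
        f2 = ct.generate_measurement_pair(doubled)
        mu1 = ct.extinction_spectrum(f1.sample, f1.reference, base.cuvette)
        mu2 = ct.extinction_spectrum(f2.sample, f2.reference, base.cuvette)
        assert np.allclose(mu2.values, 2 * mu1.values, rtol=1e-9)


class TestCompareToMie:
    def test_identical_spectra_zero_error(self, small_fixture, small_fixture_spec):
        report = ct.compare_to_mie(small_fixture.mus_true,
                                   small_fixture_spec.suspension)
        assert report.mean_abs_rel_error < 1e-12
        assert report.max_abs_rel_error < 1e-12

    def test_constant_offset_reported_exactly(self, small_fixture,
                                              small_fixture_spec):
        biased = ct.Spectrum(small_fixture.mus_true.wavelength_nm,
                             1.01 * small_fixture.mus_true.values)
        report = ct.compare_to_mie(biased, small_fixture_spec.suspension)
        assert report.mean_abs_rel_error == pytest.approx(0.01, rel=1e-9)
        assert report.mean_abs_rel_error <= report.max_abs_rel_error

    def test_pipeline_roundtrip_through_evaluation(self, small_fixture,
                                                   small_fixture_spec):
        mu = ct.extinction_spectrum(small_fixture.sample,
                                    small_fixture.reference,
                                    small_fixture_spec.cuvette)
        report = ct.compare_to_mie(mu, small_fixture_spec.suspension)
        assert report.mean_abs_rel_error < 1e-10

    def test_summary_mentions_both_statistics(self, small_fixture,
                                              small_fixture_spec):
        report = ct.compare_to_mie(small_fixture.mus_true,
                                   small_fixture_spec.suspension)
        text = report.summary()
        assert "mean" in text and "max" in text
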