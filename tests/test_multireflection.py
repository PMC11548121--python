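"""Slab/cuvette multireflection optics: series closed forms and inversion."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import collitrans as ct
from collitrans.multireflection import (cuvette_total_transmission,
                                        naive_extinction,
                                        neglect_error_small_absorption_limit)


def series_transmission(TI, TM, terms=50):
    """Partial sums of the reflection-order series (independent oracle)."""
    j = np.arange(terms)
    return TI**2 * np.sum(TM ** (2 * j + 1) * (1 - TI) ** (2 * j))


def series_reflection(TI, TM, terms=50):
    j = np.arange(terms)
    return (1 - TI) + TI**2 * np.sum(TM ** (2 * j + 2) * (1 - TI) ** (2 * j + 1))


class TestInterfaceTransmission:
    @pytest.mark.parametrize("n1,n2,expected", [
        (1.0, 1.0, 1.0),
        (1.0, 1.5, 0.96),
        (1.5, 1.0, 0.96),           # symmetric: same from either side
        (1.33, 1.586, 0.9922926534),
    ])
    def test_fresnel_values(self, n1, n2, expected):
        assert ct.interface_transmission(n1, n2) == pytest.approx(expected, abs=1e-9)

    @given(st.floats(1.0, 3.0), st.floats(1.0, 3.0))
    def test_symmetry_and_range(self, n1, n2):
        t = ct.interface_transmission(n1, n2)
        assert t == ct.interface_transmission(n2, n1)
        assert 0 < t <= 1

    def test_rejects_nonpositive_index(self):
        with pytest.raises(ct.InvalidInputError):
            ct.interface_transmission(-1.0, 1.5)
        with pytest.raises(ct.InvalidInputError):
            ct.InterfacePair(1.0, 0.0)


class TestSlabTotals:
    @pytest.mark.parametrize("TI,TM,expected", [
        (1.0, 0.5, 0.5),                  # no interfaces
        (0.96, 1.0, 0.9230769230769231),  # transparent medium
        (0.96, 0.0, 0.0),                 # opaque medium
    ])
    def test_transmission_examples(self, TI, TM, expected):
        assert ct.slab_total_transmission(TI, TM) == pytest.approx(expected, abs=1e-12)

    def test_reflection_examples(self):
        assert ct.slab_total_reflection(1.0, 0.3) == 0.0
        # energy conservation at TM=1 fixes Rtot exactly
        assert ct.slab_total_reflection(0.96, 1.0) == pytest.approx(
            1.0 - ct.slab_total_transmission(0.96, 1.0), abs=1e-12)

    @given(st.floats(0.5, 1.0), st.floats(0.0, 0.99))
    def test_closed_forms_equal_series(self, TI, TM):
        assert ct.slab_total_transmission(TI, TM) == pytest.approx(
            series_transmission(TI, TM), abs=1e-12)
        assert ct.slab_total_reflection(TI, TM) == pytest.approx(
            series_reflection(TI, TM), abs=1e-12)

    @given(st.floats(0.05, 1.0), st.floats(0.0, 1.0))
    def test_energy_conservation(self, TI, TM):
        t = ct.slab_total_transmission(TI, TM)
        r = ct.slab_total_reflection(TI, TM)
        assert t + r <= 1.0 + 1e-12
        if TM == 1.0:
            assert t + r == pytest.approx(1.0, abs=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ct.InvalidInputError):
            ct.slab_total_transmission(1.2, 0.5)
        with pytest.raises(ct.InvalidInputError):
            ct.slab_total_reflection(0.9, -0.1)


class TestInversion:
    @pytest.mark.parametrize("TI,Ttot,expected", [
        (1.0, 0.37, 0.37),
        (0.96, 0.923077, 1.0),
    ])
    def test_examples(self, TI, Ttot, expected):
        assert ct.invert_slab_transmission(TI, Ttot) == pytest.approx(
            expected, abs=1e-6)

    @given(st.floats(0.5, 1.0), st.floats(0.01, 1.0))
    def test_roundtrip_identity(self, TI, TM):
        t = ct.slab_total_transmission(TI, TM)
        assert ct.invert_slab_transmission(TI, t) == pytest.approx(
            TM, rel=1e-12, abs=1e-13)
        t2 = ct.slab_total_transmission(TI, ct.invert_slab_transmission(TI, t))
        assert t2 == pytest.approx(t, rel=1e-12, abs=1e-13)

    def test_negative_root_branch_is_unphysical(self):
        # the quadratic's other root is non-positive for feasible inputs,
        # which is why the positive branch is taken
        for TI in np.linspace(0.5, 0.99, 9):
            for TM in np.linspace(0.05, 1.0, 9):
                Ttot = ct.slab_total_transmission(TI, TM)
                r2 = (1 - TI) ** 2
                minus = (-(TI**2) - np.sqrt(TI**4 + 4 * Ttot**2 * r2)) / (2 * Ttot * r2)
                assert minus <= 0

    def test_infeasible_and_invalid(self):
        with pytest.raises(ct.InfeasibleInputError):
            ct.invert_slab_transmission(0.96, 0.93)   # above the TM=1 ceiling
        with pytest.raises(ct.InvalidInputError):
            ct.invert_slab_transmission(0.96, 0.0)


class TestCuvette:
    def test_wall_transmission_examples(self):
        assert ct.cuvette_wall_transmission(1.33, 1.33, 1.33) == pytest.approx(1.0)
        # Fresnel values chained through the two-interface closed form
        tg1 = ct.interface_transmission(1.0, 1.46)
        tg2 = ct.interface_transmission(1.46, 1.33)
        expected = tg1 * tg2 / (1 - (1 - tg1) * (1 - tg2))
        assert ct.cuvette_wall_transmission(1.0, 1.46, 1.33) == pytest.approx(
            expected, abs=1e-15)
        assert expected == pytest.approx(0.963012, abs=1e-5)
        # inner interface vanishes when wall and medium match
        assert ct.cuvette_wall_transmission(1.0, 1.46, 1.46) == pytest.approx(
            ct.interface_transmission(1.0, 1.46), abs=1e-15)

    def test_spec_validation(self):
        with pytest.raises(ct.InvalidInputError):
            ct.CuvetteSpec(1.0, 0.9, 1.33, 10.0)
        with pytest.raises(ct.InvalidInputError):
            ct.CuvetteSpec(1.0, 1.46, 1.33, -1.0)


class TestEvaluateExtinction:
    def test_equal_transmissions_give_zero(self, quartz_water_cuvette):
        assert ct.evaluate_extinction(0.5, 0.5, quartz_water_cuvette) == pytest.approx(0.0)

    def test_forward_inverse_roundtrip(self, quartz_water_cuvette):
        spec = quartz_water_cuvette
        mut = 0.1
        tm = np.exp(-mut * spec.path_length_mm)
        t_s = cuvette_total_transmission(spec, tm)
        t_r = cuvette_total_transmission(spec, 1.0)
        assert ct.evaluate_extinction(t_s, t_r, spec) == pytest.approx(mut, abs=1e-10)

    def test_uncorrected_evaluation_shows_neglect_bias(self, quartz_water_cuvette):
        spec = quartz_water_cuvette
        mua = 1e-5
        tm = np.exp(-mua * spec.path_length_mm)
        t_s = cuvette_total_transmission(spec, tm)
        t_r = cuvette_total_transmission(spec, 1.0)
        mu_naive = naive_extinction(t_s, t_r, spec.path_length_mm)
        rel = (mu_naive - mua) / mua
        limit = neglect_error_small_absorption_limit(spec)
        assert rel == pytest.approx(limit, rel=1e-3)

    def test_concentration_scaling(self, quartz_water_cuvette):
        spec = quartz_water_cuvette
        tm = np.exp(-0.2 * spec.path_length_mm)
        t_s = cuvette_total_transmission(spec, tm)
        t_r = cuvette_total_transmission(spec, 1.0)
        mu1 = ct.evaluate_extinction(t_s, t_r, spec, concentration=1.0)
        mu2 = ct.evaluate_extinction(t_s, t_r, spec, concentration=2.0)
        assert mu2 == pytest.approx(mu1 / 2.0)

    def test_infeasible_raises(self, quartz_water_cuvette):
        with pytest.raises(ct.InfeasibleInputError):
            ct.evaluate_extinction(0.99, 0.9, quartz_water_cuvette)


class TestNeglectError:
    def test_matched_indices_no_error(self):
        spec = ct.CuvetteSpec(1.33, 1.33, 1.33, 10.0)
        err = ct.neglect_multireflection_error(spec, np.logspace(-4, 0, 10))
        assert np.allclose(err, 0.0, atol=1e-12)

    @pytest.mark.parametrize("n_wall,limit_pct", [
        (1.59, 0.699),   # common higher-index cuvette glass
        (1.70, 1.295),   # larger glass/medium index ratio
    ])
    def test_small_absorption_limits(self, n_wall, limit_pct):
        spec = ct.CuvetteSpec(1.0, n_wall, 1.33, 10.0)
        limit = neglect_error_small_absorption_limit(spec)
        assert limit * 100 == pytest.approx(limit_pct, abs=5e-4)
        # numeric curve agrees with the closed-form limit at tiny absorption
        err = ct.neglect_multireflection_error(spec, np.array([1e-6]))
        assert err[0] == pytest.approx(limit, rel=1e-4)

    def test_curve_monotone_decreasing_to_zero(self, quartz_water_cuvette):
        mua = np.logspace(-5, 1.0, 40)
        err = ct.neglect_multireflection_error(quartz_water_cuvette, mua)
        assert np.all(np.diff(err) < 0)
        # converges toward zero (1/mua tail) for strong absorption
        assert err[-1] < 0.01 * err[0]

    def test_rejects_bad_grid(self, quartz_water_cuvette):
        with pytest.raises(ct.InvalidInputError):
            ct.neglect_multireflection_error(quartz_water_cuvette, [])
        with pytest.raises(ct.InvalidInputError):
            ct.neglect_multireflection_error(quartz_water_cuvette, [-0.1])
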