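"""Synthetic measurement fixtures with known ground truth.

The validation measurements behind this kind of instrument — polystyrene
microsphere suspensions in quartz cuvettes — are emulated here: a Mie
forward model produces the ground-truth scattering spectrum, the
multireflection model turns it into cuvette transmissions, and multiplicative
Gaussian noise stands in for photometric noise.  Everything is seeded, so
fixtures are bit-reproducible.

The generator models neither etaloning nor fiber-mode noise (both are
mitigated in hardware on the real instrument) nor spectrometer response:
its purpose is exercising the evaluation pipeline, not emulating detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError
from .multireflection import CuvetteSpec, cuvette_total_transmission
from .scattering import SphereSuspension, scattering_coefficient_spectrum
from .spectra import Spectrum

__all__ = ["FixtureSpec", "MeasurementFixture", "generate_measurement_pair"]


def _default_suspension() -> SphereSuspension:
    # the thin-cuvette validation sample: 3.917 um spheres, measured sd
    # 0.03 um, concentration high enough for structure but min transmission
    # kept above 10%
    return SphereSuspension(diameter_um=3.917, sd_um=0.03,
                            n_particle=1.586, n_medium=1.33,
                            volume_fraction=0.003)


def _default_cuvette() -> CuvetteSpec:
    # 0.5 mm quartz cuvette with water-based medium
    return CuvetteSpec(n_surround=1.0, n_wall=1.46, n_medium=1.33,
                       path_length_mm=0.5)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic sample/reference measurement pair.

    The default wavelength grid covers the instrument's 300-2150 nm range at
    1 nm; ``masked_intervals_nm`` (default: the 1900-2000 nm water band)
    emulates wavelengths the detector cannot evaluate.
    """

    suspension: SphereSuspension = field(default_factory=_default_suspension)
    cuvette: CuvetteSpec = field(default_factory=_default_cuvette)
    wavelength_nm: np.ndarray = field(
        default_factory=lambda: np.arange(300.0, 2150.0 + 1.0, 1.0))
    noise_sd: float = 0.005
    masked_intervals_nm: tuple = ((1900.0, 2000.0),)
    baseline: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise InvalidInputError(f"noise sd must be >= 0, got {self.noise_sd}")
        wl = np.asarray(self.wavelength_nm, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise InvalidInputError("wavelength grid must be 1-d increasing")
        object.__setattr__(self, "wavelength_nm", wl)


@dataclass(frozen=True)
class MeasurementFixture:
    """A generated pair plus its ground truth."""

    sample: Spectrum
    reference: Spectrum
    mus_true: Spectrum          # ground-truth scattering coefficient [1/mm]
    spec: FixtureSpec


def generate_measurement_pair(spec: FixtureSpec) -> MeasurementFixture:
    """Generate (sample, reference, ground-truth mu_s) spectra.

    reference = baseline * Ttot(TM=1) * noise — the cuvette filled with the
    matched non-absorbing medium; sample = baseline * Ttot(exp(-mu_s d)) *
    independent noise.  Masked intervals are zeroed and masked in both.
    With ``noise_sd = 0`` the pipeline recovers mu_s exactly.
    """
    rng = np.random.default_rng(spec.seed)
    wl = spec.wavelength_nm
    mus = scattering_coefficient_spectrum(spec.suspension, wl)
    tm = np.exp(-mus * spec.cuvette.path_length_mm)
    t_sample = np.asarray(cuvette_total_transmission(spec.cuvette, tm))
    t_reference = np.asarray(cuvette_total_transmission(
        spec.cuvette, np.ones_like(tm)))

    noise_r = 1.0 + spec.noise_sd * rng.standard_normal(wl.size)
    noise_s = 1.0 + spec.noise_sd * rng.standard_normal(wl.size)
    sample_i = spec.baseline * t_sample * noise_s
    reference_i = spec.baseline * t_reference * noise_r

    mask = np.ones(wl.size, dtype=bool)
    for lo, hi in spec.masked_intervals_nm:
        mask &= ~((wl >= lo) & (wl <= hi))
    sample_i = np.where(mask, sample_i, 0.0)
    reference_i = np.where(mask, reference_i, 0.0)

    return MeasurementFixture(
        sample=Spectrum(wl, sample_i, mask.copy()),
        reference=Spectrum(wl, reference_i, mask.copy()),
        mus_true=Spectrum(wl, mus),
        spec=spec,
    )
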