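"""End-to-end evaluation of measured spectra.

From a sample and a reference intensity spectrum (same cuvette, reference
filled with a non-absorbing medium) to the multireflection-corrected
extinction spectrum, and its comparison against a Mie prediction.

The measured ratio I/I0 only fixes the *relative* transmission; the
absolute sample transmission needed by the multireflection inversion is
recovered by scaling with the model transmission of the reference cuvette,
which is computable because the reference medium is non-absorbing and its
index known.  Wavelengths whose transmission is infeasible under the model
(noise pushing it above the transparent ceiling, or non-positive
intensities) are masked, never fabricated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError
from .multireflection import (CuvetteSpec, cuvette_total_transmission,
                              invert_slab_transmission, naive_extinction)
from .scattering import SphereSuspension, scattering_coefficient_spectrum
from .spectra import Spectrum, interpolate_masked  # noqa: F401  (re-export)

__all__ = ["ComparisonReport", "extinction_spectrum", "compare_to_mie"]


def extinction_spectrum(sample: Spectrum, reference: Spectrum,
                        spec: CuvetteSpec, concentration: float = 1.0,
                        naive: bool = False,
                        n_medium_reference=None) -> Spectrum:
    """Evaluate the extinction coefficient spectrum [1/(concentration mm)].

    With ``naive=True`` the plain Beer-Lambert ``-ln(I/I0)/(c d)`` is used
    (the uncorrected standard method, kept for comparison); otherwise both
    transmissions run through the multireflection inversion.
    """
    sample.require_same_grid(reference)
    if concentration <= 0:
        raise InvalidInputError("concentration must be > 0")
    wl = sample.wavelength_nm
    mask = sample.mask & reference.mask
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = sample.values / reference.values
    ok = mask & np.isfinite(ratio) & (ratio > 0)

    out = np.full(wl.size, np.nan)
    d = spec.path_length_mm
    if naive:
        out[ok] = naive_extinction(ratio[ok], 1.0, d, concentration)
        return Spectrum(wl, out, ok)

    tg = np.broadcast_to(np.asarray(spec.wall_transmission), wl.shape)
    # absolute sample transmission = measured ratio * model reference transmission
    ref_spec = spec if n_medium_reference is None else \
        spec.with_medium_index(n_medium_reference)
    t_ref_model = np.broadcast_to(
        np.asarray(cuvette_total_transmission(ref_spec, 1.0)), wl.shape)
    t_abs = ratio * t_ref_model
    ceiling = np.asarray(cuvette_total_transmission(spec, 1.0))
    ceiling = np.broadcast_to(ceiling, wl.shape)
    feasible = ok & (t_abs <= ceiling * (1.0 + 1e-6))
    if np.any(feasible):
        tm = invert_slab_transmission(tg[feasible], t_abs[feasible])
        out[feasible] = -np.log(np.clip(tm, 1e-300, None)) / (concentration * d)
    return Spectrum(wl, out, feasible)


@dataclass(frozen=True)
class ComparisonReport:
    """Per-wavelength relative deviation of a measurement from a Mie model."""

    wavelength_nm: np.ndarray
    rel_error: np.ndarray        # (measured - model)/model, NaN where masked
    mask: np.ndarray
    mean_abs_rel_error: float
    max_abs_rel_error: float

    def __post_init__(self) -> None:
        if self.mean_abs_rel_error > self.max_abs_rel_error + 1e-15:
            raise InvalidInputError("mean |error| cannot exceed max |error|")

    def summary(self) -> str:
        return (f"compared wavelengths   {int(self.mask.sum())}\n"
                f"mean |rel error|       {self.mean_abs_rel_error:.4%}\n"
                f"max  |rel error|       {self.max_abs_rel_error:.4%}")


def compare_to_mie(measured: Spectrum, susp: SphereSuspension,
                   n_nodes: int = 11) -> ComparisonReport:
    """Compare a measured mu_s/mu_t spectrum with the Mie forward model.

    The mean is the mean of *absolute* relative errors, computed over the
    measured spectrum's valid mask only.
    """
    wl = measured.wavelength_nm
    model = scattering_coefficient_spectrum(susp, wl, n_nodes=n_nodes)
    if np.any(model[measured.mask] == 0):
        raise InvalidInputError("Mie model is zero at a compared wavelength")
    rel = np.full(wl.size, np.nan)
    rel[measured.mask] = (measured.values[measured.mask]
                          - model[measured.mask]) / model[measured.mask]
    if not np.any(measured.mask):
        raise InvalidInputError("no valid wavelengths to compare")
    abs_rel = np.abs(rel[measured.mask])
    return ComparisonReport(
        wavelength_nm=wl,
        rel_error=rel,
        mask=measured.mask.copy(),
        mean_abs_rel_error=float(abs_rel.mean()),
        max_abs_rel_error=float(abs_rel.max()),
    )
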