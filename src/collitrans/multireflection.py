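"""Multireflection optics of plane-parallel slabs and cuvettes.

Light crossing a slab (or a cuvette: glass wall / medium / glass wall) is
partially reflected at every refractive-index step.  The multiply reflected
orders travel a longer path through the medium, so the total transmission is
not simply ``TI**2 * TM``: summing all orders gives a geometric series with
the closed forms implemented here.  Neglecting this when evaluating a
transmission measurement with plain Beer-Lambert biases the recovered
extinction coefficient; :func:`neglect_multireflection_error` quantifies that
bias and :func:`evaluate_extinction` removes it.

Conventions
-----------
* normal incidence only; Fresnel reflectance is ``((n1-n2)/(n1+n2))**2``
* walls are non-absorbing and non-scattering
* lengths in mm, coefficients in 1/mm, wavelengths in nm
* all functions broadcast over numpy arrays

Notation: ``TI`` is the single-interface transmission, ``TM`` the single-pass
internal transmission of the medium (``exp(-mu_t * d)``), ``TG`` the
transmission of one composite cuvette wall, ``Ttot``/``Rtot`` the total
transmitted/reflected fractions of the stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InfeasibleInputError, InvalidInputError

__all__ = [
    "InterfacePair",
    "CuvetteSpec",
    "SlabRadiometry",
    "interface_transmission",
    "slab_total_transmission",
    "slab_total_reflection",
    "invert_slab_transmission",
    "cuvette_wall_transmission",
    "cuvette_total_transmission",
    "evaluate_extinction",
    "naive_extinction",
    "neglect_multireflection_error",
    "neglect_error_small_absorption_limit",
]


@dataclass(frozen=True)
class InterfacePair:
    """A single refractive-index step.

    The interface transmission is symmetric: computed from either side it is
    identical, so the order of ``n_outer`` / ``n_inner`` does not matter.
    """

    n_outer: float
    n_inner: float

    def __post_init__(self) -> None:
        if self.n_outer <= 0 or self.n_inner <= 0:
            raise InvalidInputError(
                f"refractive indices must be positive, got "
                f"({self.n_outer}, {self.n_inner})"
            )

    @property
    def transmission(self) -> float:
        return interface_transmission(self.n_outer, self.n_inner)


@dataclass(frozen=True)
class CuvetteSpec:
    """Geometry and indices of a two-walled cuvette.

    Parameters
    ----------
    n_surround : refractive index of the surroundings (air: 1.0)
    n_wall : refractive index of the cuvette glass
    n_medium : refractive index of the filling medium
    path_length_mm : internal path length d through the medium [mm]

    Any of the three indices may be a per-wavelength array (matched shapes);
    scalar values model dispersion-free glass.
    """

    n_surround: float | np.ndarray
    n_wall: float | np.ndarray
    n_medium: float | np.ndarray
    path_length_mm: float

    def __post_init__(self) -> None:
        for name in ("n_surround", "n_wall", "n_medium"):
            v = np.asarray(getattr(self, name), dtype=float)
            if np.any(v < 1.0):
                raise InvalidInputError(f"{name} must be >= 1, got {v}")
        if self.path_length_mm <= 0:
            raise InvalidInputError(
                f"path_length_mm must be > 0, got {self.path_length_mm}"
            )

    @property
    def wall_transmission(self) -> float | np.ndarray:
        """Transmission TG of one composite wall (surround|glass|medium)."""
        return cuvette_wall_transmission(self.n_surround, self.n_wall, self.n_medium)

    def with_medium_index(self, n_medium: float | np.ndarray) -> "CuvetteSpec":
        return CuvetteSpec(self.n_surround, self.n_wall, n_medium, self.path_length_mm)


@dataclass(frozen=True)
class SlabRadiometry:
    """Total transmitted/reflected fractions of a slab at one condition."""

    T_total: float
    R_total: float
    T_medium: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.T_total <= 1.0 and 0.0 <= self.R_total <= 1.0):
            raise InvalidInputError("T_total and R_total must lie in [0, 1]")
        if self.T_total + self.R_total > 1.0 + 1e-12:
            raise InvalidInputError("T_total + R_total exceeds unity")


def _check_unit_interval(name: str, value, lo_open: bool = False):
    v = np.asarray(value, dtype=float)
    bad = (v < 0) | (v > 1) | (~np.isfinite(v))
    if lo_open:
        bad |= v == 0
    if np.any(bad):
        raise InvalidInputError(f"{name} must lie in {'(' if lo_open else '['}0, 1], got {value}")
    return v


def interface_transmission(n1, n2):
    """Fresnel transmission of a single interface at normal incidence.

    ``T = 1 - ((n1 - n2)/(n1 + n2))**2``; symmetric in its arguments.
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any(n1 <= 0) or np.any(n2 <= 0):
        raise InvalidInputError("refractive indices must be positive")
    t = 1.0 - ((n1 - n2) / (n1 + n2)) ** 2
    return t if t.ndim else float(t)


def slab_total_transmission(TI, TM):
    """Total transmission of a slab including all internal reflections.

    Closed form of the geometric series over reflection orders:
    ``Ttot = TI**2 * TM / (1 - TM**2 * (1 - TI)**2)``.
    """
    TI = _check_unit_interval("TI", TI, lo_open=True)
    TM = _check_unit_interval("TM", TM)
    out = TI**2 * TM / (1.0 - TM**2 * (1.0 - TI) ** 2)
    return out if out.ndim else float(out)


def slab_total_reflection(TI, TM):
    """Total reflection of a slab including all internal reflections.

    ``Rtot = (1 - TI) + (1 - TI) * TI**2 * TM**2 / (1 - TM**2 * (1 - TI)**2)``.
    """
    TI = _check_unit_interval("TI", TI, lo_open=True)
    TM = _check_unit_interval("TM", TM)
    r = 1.0 - TI
    out = r + r * TI**2 * TM**2 / (1.0 - TM**2 * r**2)
    return out if out.ndim else float(out)


def invert_slab_transmission(TI, T_total, *, feasibility_rtol: float = 1e-6):
    """Recover the internal single-pass transmission TM from Ttot.

    Solves the quadratic behind :func:`slab_total_transmission` for TM and
    returns the positive root; the other root is non-positive for every
    feasible input (tested).  Exact inverse: the roundtrip
    ``slab_total_transmission(TI, invert_slab_transmission(TI, T))`` returns
    ``T`` to machine precision.

    ``feasibility_rtol`` tolerates measured/rounded transmissions a hair
    above the transparent-medium ceiling (TM is then clipped to 1); anything
    further above raises :class:`InfeasibleInputError`.
    """
    TI = _check_unit_interval("TI", TI, lo_open=True)
    T_total = np.asarray(T_total, dtype=float)
    if np.any(T_total <= 0) or np.any(~np.isfinite(T_total)):
        raise InvalidInputError(f"T_total must be positive, got {T_total}")
    ceiling = slab_total_transmission(TI, np.ones_like(T_total))
    if np.any(T_total > np.asarray(ceiling) * (1.0 + feasibility_rtol)):
        raise InfeasibleInputError(
            f"T_total={T_total} exceeds the transparent-medium ceiling "
            f"{ceiling} for TI={TI}; measurement inconsistent with the slab model"
        )
    # conjugate form of the positive quadratic root: cancellation-free for
    # small T_total and regular at TI = 1 (where the quadratic degenerates)
    r2 = (1.0 - TI) ** 2
    tm = 2.0 * T_total / (TI**2 + np.sqrt(TI**4 + 4.0 * T_total**2 * r2))
    tm = np.clip(tm, 0.0, 1.0)
    return tm if tm.ndim else float(tm)


def cuvette_wall_transmission(n_surround, n_wall, n_medium):
    """Transmission TG of one cuvette wall (two interfaces, all reflections).

    The wall is treated as a lossless slab between ``n_surround`` and
    ``n_medium``: ``TG = TG1*TG2 / (1 - (1-TG1)(1-TG2))`` with TG1, TG2 the
    Fresnel transmissions of its two interfaces.
    """
    TG1 = np.asarray(interface_transmission(n_surround, n_wall))
    TG2 = np.asarray(interface_transmission(n_wall, n_medium))
    out = TG1 * TG2 / (1.0 - (1.0 - TG1) * (1.0 - TG2))
    return out if out.ndim else float(out)


def cuvette_total_transmission(spec: CuvetteSpec, TM):
    """Total transmission of a filled cuvette (wall | medium | wall)."""
    return slab_total_transmission(spec.wall_transmission, TM)


def evaluate_extinction(T_total_sample, T_total_reference, spec: CuvetteSpec,
                        concentration: float = 1.0,
                        n_medium_reference=None):
    """Multireflection-corrected Beer-Lambert evaluation.

    Both total transmissions are inverted to internal single-pass
    transmissions (wall transmission TG replacing TI), then

    ``mu_t = -1/(c*d) * ln(TM_sample / TM_reference)``.

    Parameters
    ----------
    T_total_sample, T_total_reference
        Measured total transmissions (sample and reference cuvette).
    spec
        Cuvette geometry; ``spec.n_medium`` is the sample medium index.
    concentration
        Scaling constant c; with the default 1 the result is the extinction
        coefficient in 1/mm.
    n_medium_reference
        Index of the reference medium if it differs from the sample medium
        (default: same index, the usual matched-reference convention).

    Returns the extinction coefficient difference sample-minus-reference in
    1/(concentration * mm).
    """
    if concentration <= 0:
        raise InvalidInputError(f"concentration must be > 0, got {concentration}")
    TG_s = spec.wall_transmission
    tm_s = invert_slab_transmission(TG_s, T_total_sample)
    if n_medium_reference is None:
        TG_r = TG_s
    else:
        TG_r = spec.with_medium_index(n_medium_reference).wall_transmission
    tm_r = invert_slab_transmission(TG_r, T_total_reference)
    out = -np.log(np.asarray(tm_s) / np.asarray(tm_r)) / (concentration * spec.path_length_mm)
    return out if out.ndim else float(out)


def naive_extinction(T_total_sample, T_total_reference, path_length_mm: float,
                     concentration: float = 1.0):
    """Uncorrected Beer-Lambert: ``-ln(I/I0)/(c*d)``, ignoring reflections."""
    if concentration <= 0 or path_length_mm <= 0:
        raise InvalidInputError("concentration and path length must be > 0")
    out = -np.log(np.asarray(T_total_sample, dtype=float) / np.asarray(T_total_reference, dtype=float))
    out = out / (concentration * path_length_mm)
    return out if out.ndim else float(out)


def neglect_multireflection_error(spec: CuvetteSpec, mua_grid):
    """Relative error of plain Beer-Lambert evaluation vs true absorption.

    For each absorption coefficient the sample (absorbing medium) and the
    reference (same cuvette, non-absorbing medium of the same index) total
    transmissions are forward-modelled with the multireflection closed forms,
    then evaluated naively (plain ``-ln`` ratio).  Returned is
    ``(mua_naive - mua) / mua``.

    The curve decreases monotonically with absorption: it converges to the
    closed-form limit ``2 r**2 / (1 - r**2)`` (``r = 1 - TG``) as mua -> 0
    and to zero as mua -> infinity, because strongly absorbed higher
    reflection orders stop contributing.
    """
    mua = np.atleast_1d(np.asarray(mua_grid, dtype=float))
    if mua.size == 0:
        raise InvalidInputError("mua_grid must not be empty")
    if np.any(mua <= 0):
        raise InvalidInputError("mua_grid must be strictly positive")
    d = spec.path_length_mm
    TM = np.exp(-mua * d)
    T_sample = cuvette_total_transmission(spec, TM)
    T_reference = cuvette_total_transmission(spec, np.ones_like(TM))
    mua_naive = naive_extinction(T_sample, T_reference, d)
    return (mua_naive - mua) / mua


def neglect_error_small_absorption_limit(spec: CuvetteSpec) -> float:
    """Closed-form mua -> 0 limit of :func:`neglect_multireflection_error`.

    ``2 r**2 / (1 - r**2)`` with ``r = 1 - TG`` the reflectance of one wall.
    """
    r = 1.0 - np.asarray(spec.wall_transmission, dtype=float)
    out = 2.0 * r**2 / (1.0 - r**2)
    return out if out.ndim else float(out)
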