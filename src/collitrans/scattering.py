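"""Scattering models: Henyey-Greenstein, Mie phase functions, suspensions.

This module provides the ground truth for the forward-scattering error
studies and for synthetic validation spectra:

* the one-parameter Henyey-Greenstein (HG) phase function with exact
  inverse-CDF sampling and a closed-form cone fraction,
* tabulated phase functions (from Mie theory or user tables) with
  inverse-CDF sampling, normalisation and anisotropy bookkeeping,
* polydisperse microsphere suspensions and their scattering-coefficient
  spectra mu_s(lambda) via Gauss-Hermite quadrature over a Gaussian
  diameter distribution.

Conventions: angles are in-medium scattering angles; the size parameter uses
the in-medium wavelength ``lambda / n_medium``; phase functions are
normalised over solid angle, ``2 pi * int p(theta) sin(theta) dtheta = 1``;
mu_s is returned in 1/mm for diameters in um and wavelengths in nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite_e import hermegauss

from .dispersion import IndexLike, index_at
from .exceptions import ConvergenceError, InvalidInputError
from .mie import mie_amplitudes, mie_single

__all__ = [
    "PhaseFunction",
    "SphereSuspension",
    "hg_pdf",
    "hg_sample",
    "hg_cone_fraction",
    "phase_function_table",
    "mie_phase_function",
    "sample_tabulated",
    "scattering_coefficient_spectrum",
    "extinction_coefficient_spectrum",
    "suspension_mie_results",
]

DEPENDENT_SCATTERING_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# Henyey-Greenstein
# ---------------------------------------------------------------------------

def _check_g(g: float) -> float:
    g = float(g)
    if not np.isfinite(g) or abs(g) >= 1.0:
        raise InvalidInputError(f"HG anisotropy must satisfy |g| < 1, got {g}")
    return g


def hg_pdf(theta, g: float):
    """HG phase function p(theta), normalised over solid angle."""
    g = _check_g(g)
    mu = np.cos(np.asarray(theta, dtype=float))
    out = (1.0 - g * g) / (4.0 * np.pi * (1.0 + g * g - 2.0 * g * mu) ** 1.5)
    return out if out.ndim else float(out)


def hg_sample(g: float, rng: np.random.Generator, size=None):
    """Draw cos(theta) from the HG distribution by the exact inverse CDF."""
    g = _check_g(g)
    u = rng.random(size)
    if abs(g) < 1e-12:
        return 2.0 * u - 1.0
    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    return (1.0 + g * g - frac * frac) / (2.0 * g)


def hg_cone_fraction(g: float, theta_c: float) -> float:
    """Probability that an HG deflection falls inside the cone theta <= theta_c.

    Closed form of the HG CDF; for g = 0 the isotropic value
    ``(1 - cos(theta_c)) / 2`` (quadratic ~theta_c^2/4 for small cones).
    """
    g = _check_g(g)
    if not (0.0 < theta_c < np.pi):
        raise InvalidInputError(f"theta_c must lie in (0, pi), got {theta_c}")
    mu_c = np.cos(theta_c)
    if abs(g) < 1e-6:
        return float((1.0 - mu_c) / 2.0)
    return float((1.0 - g * g) / (2.0 * g)
                 * (1.0 / (1.0 - g) - 1.0 / np.sqrt(1.0 + g * g - 2.0 * g * mu_c)))


# ---------------------------------------------------------------------------
# Phase-function container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseFunction:
    """A single-scattering phase function, HG or tabulated.

    Tabulated kind: ``theta`` (ascending, radians, covering [0, pi]) and
    ``p`` normalised so the solid-angle integral is one.  The stored ``g``
    is the anisotropy the table (or the HG parameter) implies.
    """

    kind: str                       # "hg" | "tabulated"
    g: float
    theta: np.ndarray | None = field(default=None, repr=False)
    p: np.ndarray | None = field(default=None, repr=False)

    @classmethod
    def hg(cls, g: float) -> "PhaseFunction":
        return cls(kind="hg", g=_check_g(g))

    @classmethod
    def tabulated(cls, theta, p, *, renormalize: bool = True) -> "PhaseFunction":
        theta = np.asarray(theta, dtype=float)
        p = np.asarray(p, dtype=float)
        if theta.ndim != 1 or theta.shape != p.shape or theta.size < 2:
            raise InvalidInputError("theta and p must be matching 1-d arrays")
        if np.any(np.diff(theta) <= 0):
            raise InvalidInputError("theta grid must be strictly increasing")
        if np.any(p < 0):
            raise InvalidInputError("phase function must be non-negative")
        norm = 2.0 * np.pi * np.trapezoid(p * np.sin(theta), theta)
        if renormalize:
            if norm <= 0:
                raise InvalidInputError("phase function integrates to zero")
            p = p / norm
        elif abs(norm - 1.0) > 1e-6:
            raise InvalidInputError(
                f"tabulated phase function is not normalised (integral {norm})"
            )
        g = 2.0 * np.pi * np.trapezoid(p * np.cos(theta) * np.sin(theta), theta)
        return cls(kind="tabulated", g=float(g), theta=theta, p=p)

    def pdf(self, theta):
        if self.kind == "hg":
            return hg_pdf(theta, self.g)
        return np.interp(np.asarray(theta, dtype=float), self.theta, self.p)

    def sample_cos(self, rng: np.random.Generator, size=None):
        """Draw cos(theta) deflections (exact for HG, inverse-CDF for tables)."""
        if self.kind == "hg":
            return hg_sample(self.g, rng, size)
        return sample_tabulated(self, rng, size)

    def cone_fraction(self, theta_c: float) -> float:
        """Probability of a deflection inside the cone theta <= theta_c."""
        if self.kind == "hg":
            return hg_cone_fraction(self.g, theta_c)
        sel = self.theta <= theta_c
        if sel.sum() < 2:
            sel = self.theta <= max(theta_c, self.theta[1])
        th = self.theta[sel]
        return float(2.0 * np.pi * np.trapezoid(self.p[sel] * np.sin(th), th))

    def _cdf(self) -> np.ndarray:
        from scipy.integrate import cumulative_trapezoid

        w = 2.0 * np.pi * self.p * np.sin(self.theta)
        cdf = cumulative_trapezoid(w, self.theta, initial=0.0)
        return cdf / cdf[-1]


def sample_tabulated(phase: PhaseFunction, rng: np.random.Generator, size=None):
    """Inverse-CDF sampling of cos(theta) from a tabulated phase function.

    The CDF is accumulated on the theta grid by the trapezoid rule and
    inverted with linear within-bin interpolation in theta.
    """
    if phase.kind != "tabulated":
        raise InvalidInputError("sample_tabulated needs a tabulated phase function")
    cdf = phase._cdf()
    u = rng.random(size)
    theta = np.interp(u, cdf, phase.theta)
    return np.cos(theta)


# ---------------------------------------------------------------------------
# Mie phase-function tables
# ---------------------------------------------------------------------------

def _forward_refined_grid(x: float, n_points: int) -> np.ndarray:
    """Theta grid geometric near zero to resolve the diffraction lobe."""
    theta_min = min(1e-7, 0.01 / max(x, 1.0))
    n_fwd = n_points // 2
    fwd = np.geomspace(theta_min, 0.3, n_fwd)
    tail = np.linspace(0.3, np.pi, n_points - n_fwd + 1)[1:]
    return np.concatenate(([0.0], fwd, tail))


def phase_function_table(x: float, m: complex, theta_grid=None) -> PhaseFunction:
    """Tabulated unpolarised Mie phase function for one sphere.

    ``p(theta)`` is proportional to ``|S1|^2 + |S2|^2`` and normalised over
    solid angle.  With no grid supplied, the grid is refined adaptively
    (geometric spacing toward theta = 0) until the forward diffraction-lobe
    integral is stable to 1e-4 relative; an unresolved forward peak raises
    :class:`ConvergenceError`.
    """
    result = mie_single(x, m)

    def build(theta):
        s1, s2 = mie_amplitudes(result.an, result.bn, np.cos(theta))
        return PhaseFunction.tabulated(theta, np.abs(s1) ** 2 + np.abs(s2) ** 2)

    if theta_grid is not None:
        return build(np.asarray(theta_grid, dtype=float))

    theta_lobe = min(1.22 * np.pi / x, np.pi / 2)  # first Airy zero
    prev_lobe = None
    n_points = 2048
    for _ in range(6):
        phase = build(_forward_refined_grid(x, n_points))
        lobe = phase.cone_fraction(theta_lobe)
        if prev_lobe is not None and abs(lobe - prev_lobe) <= 1e-4 * abs(prev_lobe):
            return phase
        prev_lobe = lobe
        n_points *= 2
    raise ConvergenceError(
        f"forward-lobe integral did not converge for x={x}: the diffraction "
        "peak is unresolved at the maximum grid density"
    )


# ---------------------------------------------------------------------------
# Suspensions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SphereSuspension:
    """A polydisperse microsphere suspension.

    Parameters
    ----------
    diameter_um : mean sphere diameter [um]
    sd_um : standard deviation of the Gaussian diameter distribution [um]
    n_particle : sphere refractive index (constant, table or callable of nm)
    n_medium : suspending-medium refractive index (same options)
    volume_fraction : volume concentration c of spheres (dimensionless)
    """

    diameter_um: float
    sd_um: float = 0.0
    n_particle: IndexLike = 1.586      # polystyrene
    n_medium: IndexLike = 1.33         # water
    volume_fraction: float = 0.01

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise InvalidInputError(f"diameter must be > 0, got {self.diameter_um}")
        if self.sd_um < 0:
            raise InvalidInputError(f"diameter sd must be >= 0, got {self.sd_um}")
        if not 0.0 <= self.volume_fraction < 1.0:
            raise InvalidInputError(
                f"volume fraction must lie in [0, 1), got {self.volume_fraction}"
            )
        if self.volume_fraction > DEPENDENT_SCATTERING_THRESHOLD:
            warnings.warn(
                f"volume fraction {self.volume_fraction} exceeds "
                f"{DEPENDENT_SCATTERING_THRESHOLD}; independent-scattering "
                "assumption is doubtful (dependent scattering)",
                stacklevel=2,
            )

    def replace(self, **kw) -> "SphereSuspension":
        from dataclasses import replace

        return replace(self, **kw)

    def size_nodes(self, n_nodes: int = 11) -> tuple[np.ndarray, np.ndarray]:
        """Gauss-Hermite nodes/weights over the Gaussian diameter distribution.

        Returns (diameters_um, weights) with weights summing to one;
        monodisperse suspensions collapse to a single node.
        """
        if self.sd_um == 0.0:
            return np.array([self.diameter_um]), np.array([1.0])
        t, w = hermegauss(n_nodes)
        d = self.diameter_um + self.sd_um * t
        keep = d > 0
        d, w = d[keep], w[keep]
        return d, w / w.sum()


def suspension_mie_results(susp: SphereSuspension, wavelength_nm: float,
                           n_nodes: int = 11):
    """Per-size-node Mie results at one wavelength.

    Returns (diameters_um, weights, list of MieResult, n_medium).
    """
    n_med = index_at(susp.n_medium, wavelength_nm)
    n_par = index_at(susp.n_particle, wavelength_nm)
    m = n_par / n_med
    d, w = susp.size_nodes(n_nodes)
    x = np.pi * d * 1000.0 * n_med / wavelength_nm
    return d, w, [mie_single(xi, m) for xi in x], n_med


def _coefficient_spectrum(susp, wavelength_nm, n_nodes, which):
    wl = np.atleast_1d(np.asarray(wavelength_nm, dtype=float))
    if np.any(wl <= 0):
        raise InvalidInputError("wavelengths must be positive")
    out = np.empty(wl.shape)
    for i, lam in enumerate(wl):
        d, w, results, _ = suspension_mie_results(susp, lam, n_nodes)
        a_um = d / 2.0
        # volume fraction apportioned over nodes -> number density per node
        number_density = susp.volume_fraction * w / ((4.0 / 3.0) * np.pi * a_um**3)
        q = np.array([getattr(r, which) for r in results])
        cross_section = q * np.pi * a_um**2
        out[i] = np.sum(number_density * cross_section) * 1.0e3  # 1/um -> 1/mm
    return out


def scattering_coefficient_spectrum(susp: SphereSuspension, wavelength_nm,
                                    n_nodes: int = 11):
    """mu_s(lambda) [1/mm] of a suspension by Mie theory.

    Polydispersity is integrated by Gauss-Hermite quadrature (default 11
    nodes); mu_s is exactly linear in the volume fraction.
    """
    return _coefficient_spectrum(susp, wavelength_nm, n_nodes, "qsca")


def extinction_coefficient_spectrum(susp: SphereSuspension, wavelength_nm,
                                    n_nodes: int = 11):
    """mu_t(lambda) [1/mm]; equals mu_s for non-absorbing spheres."""
    return _coefficient_spectrum(susp, wavelength_nm, n_nodes, "qext")


def mie_phase_function(susp: SphereSuspension, wavelength_nm: float = 600.0,
                       theta_grid=None, n_nodes: int = 11) -> PhaseFunction:
    """Scattering-cross-section-weighted phase function of a suspension.

    For a monodisperse suspension this is the single-sphere Mie phase
    function at the given wavelength; polydisperse tables are the
    Csca-weighted mixture over the size nodes.
    """
    n_med = index_at(susp.n_medium, wavelength_nm)
    n_par = index_at(susp.n_particle, wavelength_nm)
    m = n_par / n_med
    d, w = susp.size_nodes(n_nodes)
    x = np.pi * d * 1000.0 * n_med / wavelength_nm

    if theta_grid is None:
        # resolve the narrowest diffraction lobe present in the mixture
        base = phase_function_table(float(x.max()), m)
        theta_grid = base.theta
        if d.size == 1:
            return base
    theta_grid = np.asarray(theta_grid, dtype=float)

    # per-node weight: number density (w_i / d_i^3); the in-medium wavenumber
    # is common to all nodes, so |S1|^2+|S2|^2 mixes directly
    mix = np.zeros_like(theta_grid)
    for xi, wi, di in zip(x, w, d):
        r = mie_single(xi, m)
        s1, s2 = mie_amplitudes(r.an, r.bn, np.cos(theta_grid))
        mix += (wi / di**3) * (np.abs(s1) ** 2 + np.abs(s2) ** 2)
    return PhaseFunction.tabulated(theta_grid, mix)
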