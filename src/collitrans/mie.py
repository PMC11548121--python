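"""Mie theory for homogeneous spheres.

Scattering of a plane wave by a sphere has the exact partial-wave solution of
Mie theory; this module computes the efficiencies Qext/Qsca, the anisotropy
factor g, and the angular scattering amplitudes S1/S2 from the Mie
coefficients a_n, b_n.

Numerics follow the classical stable scheme: the logarithmic derivative
D_n(mx) by downward recurrence (started well above the truncation order),
Riccati-Bessel functions of the real argument x by upward recurrence, and the
angular functions pi_n/tau_n by their three-term recurrence.  The series is
truncated at ``ceil(x + 4.05 x^(1/3) + 2)`` terms, the usual convergence
bound.

The relative refractive index m may be complex (absorbing spheres); for real
m the optical theorem forces Qext == Qsca, which the tests assert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError

__all__ = ["MieResult", "mie_single", "mie_amplitudes", "mie_coefficients"]

# beyond this the double-precision recurrences degrade and arrays get huge
_X_MAX = 2.0e4


def _n_terms(x: float) -> int:
    return int(np.ceil(x + 4.05 * x ** (1.0 / 3.0) + 2.0))


@dataclass(frozen=True)
class MieResult:
    """Efficiencies, anisotropy and partial-wave coefficients of one sphere."""

    x: float
    m: complex
    qext: float
    qsca: float
    g: float
    an: np.ndarray
    bn: np.ndarray

    @property
    def qabs(self) -> float:
        return self.qext - self.qsca


def mie_coefficients(x: float, m: complex) -> tuple[np.ndarray, np.ndarray]:
    """Mie partial-wave coefficients a_n, b_n for n = 1..nmax."""
    if not np.isfinite(x) or x <= 0:
        raise InvalidInputError(f"size parameter must be positive, got {x}")
    if x > _X_MAX:
        raise InvalidInputError(
            f"size parameter {x} exceeds the supported maximum {_X_MAX}; "
            "the partial-wave series is not evaluated at this size"
        )
    m = complex(m)
    if m.real <= 0:
        raise InvalidInputError(f"relative refractive index must have Re(m) > 0, got {m}")

    nmax = _n_terms(x)
    mx = m * x

    # log-derivative D_n(mx) by downward recurrence; start order per Bohren-Huffman
    nstart = max(nmax, int(np.ceil(abs(mx)))) + 16
    D = np.zeros(nstart + 1, dtype=complex)
    for n in range(nstart, 0, -1):
        D[n - 1] = n / mx - 1.0 / (D[n] + n / mx)
    D = D[1 : nmax + 1]

    n = np.arange(1, nmax + 1, dtype=float)

    # Riccati-Bessel psi_n(x), chi_n(x) upward from n = -1, 0
    psi = np.empty(nmax)
    chi = np.empty(nmax)
    psi_m1, psi_0 = np.cos(x), np.sin(x)
    chi_m1, chi_0 = -np.sin(x), np.cos(x)
    pm, p0 = psi_m1, psi_0
    cm, c0 = chi_m1, chi_0
    for k in range(1, nmax + 1):
        pn = (2 * k - 1) / x * p0 - pm
        cn = (2 * k - 1) / x * c0 - cm
        psi[k - 1], chi[k - 1] = pn, cn
        pm, p0 = p0, pn
        cm, c0 = c0, cn
    psi_prev = np.concatenate(([psi_0], psi[:-1]))
    chi_prev = np.concatenate(([chi_0], chi[:-1]))
    xi = psi - 1j * chi
    xi_prev = psi_prev - 1j * chi_prev

    da = D / m + n / x
    db = D * m + n / x
    an = (da * psi - psi_prev) / (da * xi - xi_prev)
    bn = (db * psi - psi_prev) / (db * xi - xi_prev)
    return an, bn


def mie_single(x: float, m: complex) -> MieResult:
    """Efficiencies and anisotropy of a single sphere.

    Parameters
    ----------
    x : size parameter ``pi * d * n_medium / lambda`` (in-medium wavelength)
    m : refractive index of the sphere relative to the medium

    Returns a :class:`MieResult`; ``qext >= qsca`` with equality for real m.
    """
    an, bn = mie_coefficients(x, m)
    nmax = an.size
    n = np.arange(1, nmax + 1, dtype=float)
    two_n_plus_1 = 2.0 * n + 1.0

    qext = (2.0 / x**2) * np.sum(two_n_plus_1 * (an.real + bn.real))
    qsca = (2.0 / x**2) * np.sum(two_n_plus_1 * (np.abs(an) ** 2 + np.abs(bn) ** 2))

    # asymmetry parameter: g * Qsca from cross products of adjacent orders
    a1, a2 = an[:-1], an[1:]
    b1, b2 = bn[:-1], bn[1:]
    nn = n[:-1]
    term1 = np.sum(nn * (nn + 2.0) / (nn + 1.0)
                   * (a1 * np.conj(a2) + b1 * np.conj(b2)).real)
    term2 = np.sum(two_n_plus_1 / (n * (n + 1.0)) * (an * np.conj(bn)).real)
    g = (4.0 / x**2) * (term1 + term2) / qsca if qsca > 0 else 0.0

    return MieResult(x=float(x), m=complex(m), qext=float(qext),
                     qsca=float(qsca), g=float(g), an=an, bn=bn)


def mie_amplitudes(an: np.ndarray, bn: np.ndarray, mu: np.ndarray
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Scattering amplitudes S1(mu), S2(mu) at cos(theta) values ``mu``.

    Evaluated by the pi_n/tau_n angular recurrence, vectorised over angles;
    memory stays O(len(mu)) regardless of the series length.
    """
    mu = np.asarray(mu, dtype=float)
    nmax = an.size
    s1 = np.zeros(mu.shape, dtype=complex)
    s2 = np.zeros(mu.shape, dtype=complex)
    pi_prev = np.zeros_like(mu)          # pi_0
    pi_cur = np.ones_like(mu)            # pi_1
    for k in range(1, nmax + 1):
        tau = k * mu * pi_cur - (k + 1.0) * pi_prev
        f = (2.0 * k + 1.0) / (k * (k + 1.0))
        s1 += f * (an[k - 1] * pi_cur + bn[k - 1] * tau)
        s2 += f * (an[k - 1] * tau + bn[k - 1] * pi_cur)
        if k < nmax:
            pi_next = ((2.0 * k + 1.0) * mu * pi_cur - (k + 1.0) * pi_prev) / k
            pi_prev, pi_cur = pi_cur, pi_next
    return s1, s2
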