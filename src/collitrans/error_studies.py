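"""Photometric error propagation: where should the transmission lie?

A systematic perturbation of the measured transmission propagates through
the (optionally multireflection-corrected) Beer-Lambert inversion into a
relative error of the extinction coefficient.  For an *absolute*
perturbation Delta the uncorrected error is ``|ln(1 + Delta/t)| / |ln t|``,
which diverges at both ends of the transmission range and has an interior
minimum near t = 1/e — this is what makes 25-50% transmission the sweet
spot of a collimated-transmission measurement.  A purely *relative*
perturbation gives ``|ln(1+Delta)|/|ln t|``, monotone in t with no interior
optimum; both kinds are implemented and the absolute kind is the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, NoInteriorMinimumError
from .multireflection import (CuvetteSpec, cuvette_total_transmission,
                              invert_slab_transmission)

__all__ = [
    "PerturbationModel",
    "extinction_error_vs_transmission",
    "optimal_transmission",
]


@dataclass(frozen=True)
class PerturbationModel:
    """A systematic transmission perturbation.

    kind 'absolute': t -> t + magnitude; kind 'relative': t -> t*(1+magnitude).
    Negative magnitudes model perturbations of the opposite sign.
    """

    kind: Literal["absolute", "relative"] = "absolute"
    magnitude: float = 0.01

    def __post_init__(self) -> None:
        if self.kind not in ("absolute", "relative"):
            raise InvalidInputError(f"unknown perturbation kind {self.kind!r}")
        if self.magnitude == 0 or not np.isfinite(self.magnitude):
            raise InvalidInputError("perturbation magnitude must be nonzero finite")

    def apply(self, t: np.ndarray) -> np.ndarray:
        if self.kind == "absolute":
            return t + self.magnitude
        return t * (1.0 + self.magnitude)


def extinction_error_vs_transmission(model: PerturbationModel, t_grid,
                                     spec: CuvetteSpec | None = None
                                     ) -> pd.DataFrame:
    """Relative extinction error caused by a perturbed transmission reading.

    For each internal transmission t on the grid, the (un)corrected
    inversion is evaluated at t and at the perturbed value; reported is
    ``|(mu_perturbed - mu)/mu|``.  When a cuvette is supplied, t is the
    internal medium transmission, the measured signal is its
    multireflection forward model, and the inversion applies the correction.
    Perturbed values leaving (0, 1) are flagged invalid, not dropped.

    Columns: t, error, valid.
    """
    t = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t.size == 0 or np.any((t <= 0) | (t >= 1)):
        raise InvalidInputError("t_grid must lie strictly inside (0, 1)")

    if spec is None:
        measured = t
    else:
        measured = np.asarray(cuvette_total_transmission(spec, t))
    perturbed = model.apply(measured)
    if spec is None:
        ceiling = 1.0
    else:
        ceiling = float(np.asarray(cuvette_total_transmission(spec, 1.0)))
    valid = (perturbed > 0) & (perturbed < ceiling)

    mu = -np.log(t)                       # in units of 1/d; d cancels in the ratio
    mu_pert = np.full_like(t, np.nan)
    if spec is None:
        mu_pert[valid] = -np.log(perturbed[valid])
    else:
        tg = spec.wall_transmission
        tm_pert = invert_slab_transmission(tg, perturbed[valid])
        mu_pert[valid] = -np.log(tm_pert)

    with np.errstate(invalid="ignore", divide="ignore"):
        err = np.abs((mu_pert - mu) / mu)
    return pd.DataFrame({"t": t, "error": err, "valid": valid})


def optimal_transmission(curve: pd.DataFrame) -> float:
    """Transmission minimising the propagated error, by parabolic refinement.

    Expects the output of :func:`extinction_error_vs_transmission`.  The
    grid minimum must be interior (not an endpoint of the valid range);
    monotone curves — e.g. any purely relative perturbation — raise
    :class:`NoInteriorMinimumError`, mirroring the fact that such a model
    admits no optimal transmission.
    """
    ok = curve[curve["valid"] & np.isfinite(curve["error"])].reset_index()
    if len(ok) < 3:
        raise InvalidInputError("curve has fewer than 3 valid points")
    i = int(ok["error"].idxmin())
    if i == 0 or i == len(ok) - 1:
        raise NoInteriorMinimumError(
            "error curve is monotone over the valid range; no interior "
            "optimal transmission exists for this perturbation model"
        )
    t0, t1, t2 = ok["t"].iloc[i - 1 : i + 2]
    e0, e1, e2 = ok["error"].iloc[i - 1 : i + 2]
    denom = (t1 - t0) * (e1 - e2) - (t1 - t2) * (e1 - e0)
    if denom == 0:
        return float(t1)
    t_star = t1 - 0.5 * ((t1 - t0) ** 2 * (e1 - e2)
                         - (t1 - t2) ** 2 * (e1 - e0)) / denom
    return float(t_star)
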