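"""Auto-alignment: find the source position that maximises the signal.

Non-plane-parallel samples deflect the ballistic beam, shifting its focus
off the detection pinhole.  The instrument compensates by moving the light
source in the focal plane of the illumination mirror until the detected
(spectrally integrated) signal peaks.  The search has two stages:

1. :func:`spiral_scan` — concentric rings of increasing radius around the
   start position, with in-ring spacing no larger than the detection radius
   so a signal disc of that radius cannot slip between probe points;
2. :func:`gradient_refine` — central-difference gradient ascent with step
   length proportional to the gradient norm (clipped to configured bounds).

If the scan exhausts its radius without crossing the threshold the search
reports *not found* and the measurement is cancelled at pipeline level.
The signal is an abstract ``position -> value`` callback; replayable
synthetic maps are supported through :func:`grid_signal`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "SearchConfig",
    "SearchOutcome",
    "spiral_scan",
    "gradient_refine",
    "autoalign",
    "grid_signal",
]

Signal = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class SearchConfig:
    """Parameters of the two-stage search (lengths in mm)."""

    start: tuple[float, float] = (0.0, 0.0)
    ring_step_mm: float = 0.2          # radial distance between rings
    spacing_mm: float = 0.2            # max arc distance between probes in a ring
    detection_radius_mm: float = 0.3   # radius of the disc a signal occupies
    threshold: float = 0.5
    max_radius_mm: float = 5.0
    grad_step_min_mm: float = 0.01
    grad_step_max_mm: float = 0.5
    grad_gain: float = 1.0             # step = gain * |gradient|, then clipped
    tol_mm: float = 1e-3
    max_evaluations: int = 10_000

    def __post_init__(self) -> None:
        if min(self.ring_step_mm, self.spacing_mm, self.detection_radius_mm,
               self.max_radius_mm, self.grad_step_min_mm, self.grad_step_max_mm,
               self.tol_mm) <= 0:
            raise InvalidInputError("all search lengths must be > 0")
        if self.spacing_mm > self.detection_radius_mm:
            raise InvalidInputError(
                "in-ring spacing must not exceed the detection radius, or the "
                "scan can step over the signal"
            )
        if self.grad_step_min_mm > self.grad_step_max_mm:
            raise InvalidInputError("grad_step_min_mm exceeds grad_step_max_mm")


@dataclass(frozen=True)
class SearchOutcome:
    """Result of a search stage: found position (or None) and bookkeeping."""

    position: np.ndarray | None
    value: float
    evaluations: int
    cancelled: bool = False

    @property
    def found(self) -> bool:
        return self.position is not None


def _ring_points(center: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    n = max(int(np.ceil(2.0 * np.pi * radius / spacing)), 6)
    ang = 2.0 * np.pi * np.arange(n) / n
    return center + radius * np.column_stack([np.cos(ang), np.sin(ang)])


def spiral_scan(signal: Signal, cfg: SearchConfig) -> SearchOutcome:
    """Outward ring scan until the signal crosses the threshold.

    Visits the start first, then rings of radius ``k * ring_step_mm``; the
    in-ring angular spacing never exceeds ``spacing_mm``, guaranteeing that
    any signal disc of radius >= detection_radius within the scan area
    contains a probe point (ring_step <= detection radius too).  Returns on
    the first probe at or above threshold; *not found* is a value.
    """
    center = np.asarray(cfg.start, dtype=float)
    evals = 0
    v = float(signal(center))
    evals += 1
    if v >= cfg.threshold:
        return SearchOutcome(center, v, evals)
    radius = cfg.ring_step_mm
    while radius <= cfg.max_radius_mm + 1e-12:
        for p in _ring_points(center, radius, cfg.spacing_mm):
            v = float(signal(p))
            evals += 1
            if v >= cfg.threshold:
                return SearchOutcome(p, v, evals)
        radius += cfg.ring_step_mm
    return SearchOutcome(None, v, evals)


def gradient_refine(signal: Signal, start, cfg: SearchConfig) -> SearchOutcome:
    """Adaptive gradient ascent from a point already above threshold.

    The gradient is estimated by central differences with probe spacing
    ``grad_step_min_mm``; the move length is ``grad_gain * |gradient|``
    clipped into [grad_step_min, grad_step_max].  Moves that would lower the
    signal shrink the step instead (backtracking); the search stops when the
    step falls below ``tol_mm``.  The returned signal never falls below the
    starting value.  If the evaluation budget runs out, the best position so
    far is returned with a warning.
    """
    import warnings

    pos = np.asarray(start, dtype=float)
    best_v = float(signal(pos))
    evals = 1
    h = cfg.grad_step_min_mm
    step_scale = 1.0
    while evals + 4 <= cfg.max_evaluations:
        gx = (signal(pos + [h, 0.0]) - signal(pos - [h, 0.0])) / (2.0 * h)
        gy = (signal(pos + [0.0, h]) - signal(pos - [0.0, h])) / (2.0 * h)
        evals += 4
        gnorm = float(np.hypot(gx, gy))
        if gnorm == 0.0:
            break
        step = float(np.clip(cfg.grad_gain * gnorm, cfg.grad_step_min_mm,
                             cfg.grad_step_max_mm)) * step_scale
        if step < cfg.tol_mm:
            break
        cand = pos + step * np.array([gx, gy]) / gnorm
        v = float(signal(cand))
        evals += 1
        if v >= best_v:
            pos, best_v = cand, v
            step_scale = 1.0
        else:
            step_scale *= 0.5
            if step_scale * cfg.grad_step_min_mm < cfg.tol_mm and \
               step * 0.5 < cfg.tol_mm:
                break
    else:
        warnings.warn("gradient refinement exhausted its evaluation budget; "
                      "returning best position so far", stacklevel=2)
    return SearchOutcome(pos, best_v, evals)


def autoalign(signal: Signal, cfg: SearchConfig) -> SearchOutcome:
    """Full alignment: spiral scan, then gradient refinement.

    The best-signal sequence is monotone non-decreasing across the two
    stages.  A failed scan propagates as a cancelled outcome.
    """
    coarse = spiral_scan(signal, cfg)
    if not coarse.found:
        return SearchOutcome(None, coarse.value, coarse.evaluations,
                             cancelled=True)
    fine = gradient_refine(signal, coarse.position, cfg)
    return SearchOutcome(fine.position, fine.value,
                         coarse.evaluations + fine.evaluations)


def grid_signal(x_mm, y_mm, values) -> Signal:
    """Bilinear interpolation signal over a gridded map (replayable)."""
    from scipy.interpolate import RegularGridInterpolator

    values = np.asarray(values, dtype=float)
    interp = RegularGridInterpolator(
        (np.asarray(x_mm, float), np.asarray(y_mm, float)), values,
        method="linear", bounds_error=False, fill_value=0.0)

    def signal(p) -> float:
        return float(interp(np.asarray(p, dtype=float)[None, :])[0])

    return signal
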