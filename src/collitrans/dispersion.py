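"""Refractive-index handling: constants or per-wavelength dispersion tables.

Anywhere the package takes a refractive index it accepts

* a plain number (dispersion-free),
* a callable ``n(wavelength_nm)``,
* a 2-column table ``(wavelength_nm, n)`` as an (N, 2) array, a pair of
  arrays, or a CSV path — interpolated linearly in wavelength.

Dispersion data are user-supplied (literature values); the package ships no
material database.
"""

from __future__ import annotations

from pathlib import Path
from typing import Callable, Union

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError

__all__ = ["IndexLike", "as_index_function", "index_at", "load_index_table"]

IndexLike = Union[float, Callable[[float], float], np.ndarray, tuple, str, Path]


def load_index_table(path: str | Path) -> np.ndarray:
    """Read a (wavelength_nm, n) CSV into an (N, 2) array."""
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise InvalidInputError(f"{path}: dispersion table needs two columns")
    return df.iloc[:, :2].to_numpy(dtype=float)


def as_index_function(n: IndexLike) -> Callable:
    """Normalise any accepted index representation to a callable of nm."""
    if callable(n):
        return n
    if isinstance(n, (str, Path)):
        n = load_index_table(n)
    if isinstance(n, tuple) and len(n) == 2:
        wl, vals = np.asarray(n[0], float), np.asarray(n[1], float)
    elif isinstance(n, np.ndarray) and n.ndim == 2:
        wl, vals = n[:, 0].astype(float), n[:, 1].astype(float)
    else:
        const = float(n)
        if const < 1.0:
            raise InvalidInputError(f"refractive index must be >= 1, got {const}")
        return lambda wavelength_nm, _c=const: (
            np.full_like(np.asarray(wavelength_nm, dtype=float), _c)
            if np.ndim(wavelength_nm) else _c
        )
    if wl.size < 2 or np.any(np.diff(wl) <= 0):
        raise InvalidInputError("dispersion table wavelengths must be increasing")
    if np.any(vals < 1.0):
        raise InvalidInputError("dispersion table contains indices < 1")
    return lambda wavelength_nm: np.interp(wavelength_nm, wl, vals)


def index_at(n: IndexLike, wavelength_nm) -> float | np.ndarray:
    """Evaluate an index representation at the given wavelength(s) [nm]."""
    out = as_index_function(n)(wavelength_nm)
    return float(out) if np.ndim(out) == 0 else np.asarray(out, dtype=float)
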