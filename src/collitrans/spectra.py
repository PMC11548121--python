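"""Spectrum container and CSV I/O.

A :class:`Spectrum` is a strictly increasing wavelength grid [nm], a value
array (intensity, transmission or a coefficient) and a validity mask.  File
format: two-column CSV ``wavelength_nm,value`` with an optional header; NaN
values mark masked wavelengths and survive a write/read roundtrip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import GridMismatchError, InvalidInputError, SpectrumParseError

__all__ = ["Spectrum", "read_spectrum", "write_spectrum", "interpolate_masked"]


@dataclass
class Spectrum:
    """Wavelength-resolved values with a validity mask (True = valid)."""

    wavelength_nm: np.ndarray
    values: np.ndarray
    mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelength_nm.ndim != 1 or self.wavelength_nm.shape != self.values.shape:
            raise InvalidInputError("wavelength and values must be matching 1-d arrays")
        if self.wavelength_nm.size and np.any(np.diff(self.wavelength_nm) <= 0):
            raise InvalidInputError("wavelength grid must be strictly increasing")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise InvalidInputError("mask shape must match values")
            self.mask = self.mask & np.isfinite(self.values)

    def __len__(self) -> int:
        return self.wavelength_nm.size

    def copy(self) -> "Spectrum":
        return Spectrum(self.wavelength_nm.copy(), self.values.copy(),
                        self.mask.copy())

    def valid_values(self) -> np.ndarray:
        return self.values[self.mask]

    def same_grid(self, other: "Spectrum") -> bool:
        return (len(self) == len(other)
                and np.array_equal(self.wavelength_nm, other.wavelength_nm))

    def require_same_grid(self, other: "Spectrum") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                "spectra are on different wavelength grids; resample explicitly "
                "before combining them"
            )

    def resample(self, wavelength_nm) -> "Spectrum":
        """Linear resampling onto a new grid; masked regions stay masked."""
        wl = np.asarray(wavelength_nm, dtype=float)
        vals = np.where(self.mask, self.values, np.nan)
        out = np.interp(wl, self.wavelength_nm, vals)
        return Spectrum(wl, out)


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column (wavelength_nm, value) CSV; NaN rows become masked."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise SpectrumParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise SpectrumParseError(f"{path}: expected two columns, got {df.shape[1]}")
    # headerless files: first row parsed as header; detect numeric column names
    header_lines = 1
    try:
        float(str(df.columns[0]))
        df = pd.read_csv(path, comment="#", header=None)
        header_lines = 0
    except ValueError:
        pass
    wl = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    bad = np.where(~np.isfinite(wl))[0]
    if bad.size:
        raise SpectrumParseError(f"{path}: non-numeric wavelength",
                                 line=int(bad[0]) + 1 + header_lines)
    if np.any(np.diff(wl) <= 0):
        i = int(np.where(np.diff(wl) <= 0)[0][0])
        raise SpectrumParseError(
            f"{path}: wavelength grid not strictly increasing",
            line=i + 2 + header_lines)
    return Spectrum(wl, vals)


def write_spectrum(spectrum: Spectrum, path: str | Path,
                   value_name: str = "value") -> None:
    """Write a spectrum as CSV; masked wavelengths are written as NaN."""
    vals = np.where(spectrum.mask, spectrum.values, np.nan)
    pd.DataFrame({"wavelength_nm": spectrum.wavelength_nm,
                  value_name: vals}).to_csv(path, index=False)


def interpolate_masked(spectrum: Spectrum) -> Spectrum:
    """Fill interior masked gaps by linear interpolation.

    Gaps need valid neighbours on both sides; leading/trailing gaps remain
    masked.  A fully masked spectrum is an error.
    """
    if not np.any(spectrum.mask):
        raise InvalidInputError("cannot interpolate a fully masked spectrum")
    if np.all(spectrum.mask):
        return spectrum.copy()
    wl = spectrum.wavelength_nm
    good = spectrum.mask
    values = spectrum.values.copy()
    values[~good] = np.interp(wl[~good], wl[good], spectrum.values[good])
    mask = np.ones_like(good)
    first, last = np.argmax(good), len(good) - 1 - np.argmax(good[::-1])
    mask[:first] = False
    mask[last + 1:] = False
    values[~mask] = np.nan
    return Spectrum(wl, values, mask)
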