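"""Optional matplotlib helpers (install the ``plot`` extra)."""

from __future__ import annotations

import numpy as np


def _axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_spectrum(spectrum, ax=None, label=None, **kw):
    """Line plot of a spectrum; masked regions are gaps."""
    ax = _axes(ax)
    vals = np.where(spectrum.mask, spectrum.values, np.nan)
    ax.plot(spectrum.wavelength_nm, vals, label=label, **kw)
    ax.set_xlabel("wavelength [nm]")
    return ax


def plot_error_curve(curve, ax=None, **kw):
    """Photometric error vs transmission (output of the error study)."""
    ax = _axes(ax)
    ok = curve["valid"]
    ax.semilogy(curve["t"][ok], curve["error"][ok], **kw)
    ax.set_xlabel("transmission t")
    ax.set_ylabel("relative extinction error")
    return ax


def plot_phase_function(phase, ax=None, **kw):
    """Semi-log polar-angle plot of a phase function."""
    ax = _axes(ax)
    if phase.kind == "tabulated":
        theta, p = phase.theta, phase.p
    else:
        theta = np.linspace(0, np.pi, 1000)
        p = phase.pdf(theta)
    ax.semilogy(np.degrees(theta), p, **kw)
    ax.set_xlabel("scattering angle [deg]")
    ax.set_ylabel("p(theta) [1/sr]")
    return ax
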