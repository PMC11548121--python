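"""Sphere-parameter estimation from a measured scattering spectrum.

The oscillations of the Mie scattering-coefficient spectrum of nearly
monodisperse spheres shift monotonically with the sphere diameter, which
makes the diameter identifiable from a broadband mu_s(lambda) measurement;
the volume concentration only scales the spectrum.  :class:`MieSphereModel`
fits (diameter, concentration) by least squares on log-spectrum residuals —
the log makes the concentration an additive offset and equalises the weight
of the oscillation structure across the spectrum.

Usage::

    model = MieSphereModel(measured_spectrum, initial_suspension)
    res = model.fit()
    print(res.summary())
    res.diameter_um, res.volume_fraction, res.bse

The absorption of the spheres is assumed negligible (mu_t == mu_s), the
standard situation for polystyrene in the visible/NIR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .exceptions import ConvergenceError, InvalidInputError
from .scattering import SphereSuspension, scattering_coefficient_spectrum
from .spectra import Spectrum

__all__ = ["MieSphereModel", "MieSphereFitResults", "fit_sphere_parameters"]


class MieSphereModel:
    """Model of a measured mu_s spectrum as a Mie microsphere suspension.

    Parameters
    ----------
    spectrum : measured scattering-coefficient spectrum [1/mm]; only valid,
        positive wavelengths enter the fit
    initial : starting suspension (nominal diameter, rough concentration);
        its sd, indices and medium are held fixed during the fit
    n_nodes : Gauss-Hermite nodes for the polydispersity quadrature
    """

    def __init__(self, spectrum: Spectrum, initial: SphereSuspension,
                 n_nodes: int = 11):
        sel = spectrum.mask & (spectrum.values > 0)
        if sel.sum() < 3:
            raise InvalidInputError("need at least 3 valid positive points to fit")
        self.spectrum = spectrum
        self.initial = initial
        self.n_nodes = n_nodes
        self.wavelength_nm = spectrum.wavelength_nm[sel]
        self.log_mus = np.log(spectrum.values[sel])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, initial: SphereSuspension,
                       wavelength_col: str = "wavelength_nm",
                       value_col: str = "mu_s", **kw) -> "MieSphereModel":
        return cls(Spectrum(df[wavelength_col].to_numpy(),
                            df[value_col].to_numpy()), initial, **kw)

    # -- forward model -----------------------------------------------------
    def predict_mus(self, diameter_um: float, volume_fraction: float
                    ) -> np.ndarray:
        susp = self.initial.replace(diameter_um=diameter_um,
                                    volume_fraction=volume_fraction)
        return scattering_coefficient_spectrum(susp, self.wavelength_nm,
                                               n_nodes=self.n_nodes)

    def _residuals(self, params: np.ndarray) -> np.ndarray:
        d, log_c = params
        if d <= 0:
            return np.full(self.log_mus.size, 1e6)
        mus = self.predict_mus(d, float(np.exp(log_c)))
        with np.errstate(divide="ignore"):
            return np.where(mus > 0, np.log(mus), -50.0) - self.log_mus

    def fit_concentration(self, diameter_um: float | None = None) -> float:
        """Closed-form concentration at fixed diameter.

        mu_s is exactly linear in the volume fraction, so at a known
        diameter the estimate is the ratio of the spectral means.
        """
        d = diameter_um if diameter_um is not None else self.initial.diameter_um
        shape = self.predict_mus(d, self.initial.volume_fraction)
        scale = float(np.exp(self.log_mus).mean() / shape.mean())
        return self.initial.volume_fraction * scale

    def fit(self, diff_step: float = 1e-5, max_nfev: int = 200
            ) -> "MieSphereFitResults":
        """Least-squares fit of (diameter, concentration).

        Deterministic given the initial suspension.  Raises
        :class:`ConvergenceError` with the optimizer trace on failure.
        """
        c0 = self.fit_concentration()
        x0 = np.array([self.initial.diameter_um, np.log(c0)])
        sol = least_squares(self._residuals, x0, method="lm",
                            diff_step=diff_step, max_nfev=max_nfev,
                            x_scale=[self.initial.diameter_um, 1.0])
        if not sol.success:
            raise ConvergenceError(
                f"sphere-parameter fit did not converge: {sol.message} "
                f"(nfev={sol.nfev}, cost={sol.cost:.3e}, x={sol.x})")

        n, p = self.log_mus.size, 2
        dof = max(n - p, 1)
        sigma2 = 2.0 * sol.cost / dof
        jtj = sol.jac.T @ sol.jac
        try:
            cov_internal = np.linalg.inv(jtj) * sigma2
        except np.linalg.LinAlgError:
            cov_internal = np.full((2, 2), np.nan)
        # delta method: internal params are (d, log c) -> report (d, c)
        c_hat = float(np.exp(sol.x[1]))
        jac_tr = np.diag([1.0, c_hat])
        cov = jac_tr @ cov_internal @ jac_tr.T

        return MieSphereFitResults(
            model=self,
            diameter_um=float(sol.x[0]),
            volume_fraction=c_hat,
            cov_params=cov,
            resid=sol.fun.copy(),
            cost=float(sol.cost),
            nfev=int(sol.nfev),
            message=str(sol.message),
        )


@dataclass(frozen=True)
class MieSphereFitResults:
    """Estimates, uncertainties and diagnostics of a sphere fit."""

    model: MieSphereModel
    diameter_um: float
    volume_fraction: float
    cov_params: np.ndarray
    resid: np.ndarray            # log-spectrum residuals
    cost: float
    nfev: int
    message: str = ""
    param_names: tuple = field(default=("diameter_um", "volume_fraction"))

    @property
    def params(self) -> np.ndarray:
        return np.array([self.diameter_um, self.volume_fraction])

    @property
    def bse(self) -> np.ndarray:
        """Standard errors of the estimates."""
        return np.sqrt(np.diag(self.cov_params))

    @property
    def resid_norm(self) -> float:
        return float(np.linalg.norm(self.resid))

    def predict(self, wavelength_nm=None) -> np.ndarray:
        """Fitted mu_s on the given (default: fitted) wavelength grid."""
        wl = self.model.wavelength_nm if wavelength_nm is None else wavelength_nm
        susp = self.model.initial.replace(diameter_um=self.diameter_um,
                                          volume_fraction=self.volume_fraction)
        return scattering_coefficient_spectrum(susp, wl,
                                               n_nodes=self.model.n_nodes)

    def summary(self) -> str:
        se = self.bse
        lines = [
            "Mie sphere-suspension fit",
            "=" * 54,
            f"observations          {self.model.log_mus.size}",
            f"residual norm (log)   {self.resid_norm:.4e}",
            f"function evaluations  {self.nfev}",
            "-" * 54,
            f"{'parameter':<18}{'estimate':>14}{'std err':>14}",
            f"{'diameter_um':<18}{self.diameter_um:>14.6f}{se[0]:>14.2e}",
            f"{'volume_fraction':<18}{self.volume_fraction:>14.6e}{se[1]:>14.2e}",
            "=" * 54,
        ]
        return "\n".join(lines)


def fit_sphere_parameters(measured: Spectrum, initial: SphereSuspension,
                          n_nodes: int = 11) -> MieSphereFitResults:
    """Convenience wrapper: build a :class:`MieSphereModel` and fit it."""
    return MieSphereModel(measured, initial, n_nodes=n_nodes).fit()
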