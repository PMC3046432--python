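"""Calibration and inverse extraction of optical properties from spectra.

`SpectralInversion` is the package's central model object: it holds one
calibrated diffuse reflectance spectrum together with the forward-model
ingredients (extinction basis, scaled Monte Carlo reflectance lookup), and
its :meth:`SpectralInversion.fit` minimizes the sum of squared *relative*
residuals between the measured spectrum and the forward model over the seven
free parameters

    {C_HbO2, C_dHb, C_bcar, C_lymph, A_gauss, a, b},

i.e. the four chromophore concentrations, the arbitrary 515 nm Gaussian
absorber magnitude, and the μs′ power-law amplitude and exponent. The
returned :class:`InversionResults` carries the estimates, approximate
standard errors from the Jacobian at the optimum, the derived optical summary
(THb, SO2, ⟨μs′⟩), convergence diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .spectral import (
    ChromophoreSet,
    ExtinctionBasis,
    OpticalSummary,
    ScatteringModel,
    WavelengthGrid,
    derive_summary,
)
from .transport import ReflectanceLookup, simulate_spectrum

__all__ = [
    "CalibrationRecord",
    "calibrate",
    "SpectralInversion",
    "InversionResults",
    "extract_cohort",
]

PARAM_NAMES = ("c_hbo2", "c_dhb", "c_bcar", "c_lymph", "a_gauss", "a", "b")


@dataclass(frozen=True)
class CalibrationRecord:
    """Reflectance-standard measurement used to remove instrument response."""

    reference: np.ndarray  # measured spectrum of the reflectance standard
    standard_reflectivity: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.reference) <= 0):
            raise ValueError("reference spectrum must be positive everywhere")


def calibrate(raw: np.ndarray, cal: CalibrationRecord) -> np.ndarray:
    """Instrument-response calibration of a raw spectrum.

    calibrated(λ) = raw(λ) / reference(λ) · standard_reflectivity(λ); the
    lamp/system throughput cancels in the ratio.
    """
    raw = np.asarray(raw, dtype=float)
    ref = np.asarray(cal.reference, dtype=float)
    if raw.shape != ref.shape:
        raise ValueError("raw spectrum and calibration reference grids differ")
    return raw / ref * cal.standard_reflectivity


class SpectralInversion:
    """Nonlinear least-squares inversion of one diffuse reflectance spectrum.

    Parameters
    ----------
    spectrum : array
        Calibrated diffuse reflectance, one value per grid wavelength,
        strictly positive.
    grid, basis, lookup
        Wavelength grid, extinction basis on that grid, and the scaled Monte
        Carlo reflectance lookup shared by forward simulation and inversion.
    bounds : dict, optional
        Per-parameter ``(lo, hi)`` overrides. Concentrations default to
        [0, 200] μM, the Gaussian magnitude to [0, 5] cm⁻¹, the scattering
        exponent b to [0, 2]; the amplitude a is bounded so that the μs′
        power law stays inside the lookup's μs′ hull for every admissible b.
    """

    def __init__(
        self,
        spectrum: np.ndarray,
        grid: WavelengthGrid,
        basis: ExtinctionBasis,
        lookup: ReflectanceLookup,
        bounds: dict[str, tuple[float, float]] | None = None,
    ) -> None:
        spectrum = np.asarray(spectrum, dtype=float)
        if spectrum.shape != grid.wavelengths.shape:
            raise ValueError("spectrum and grid shapes differ")
        if np.any(spectrum <= 0):
            raise ValueError("spectrum must be positive on the analysis window")
        self.spectrum = spectrum
        self.grid = grid
        self.basis = basis
        self.lookup = lookup

        hull_lo, hull_hi = lookup.musp_span
        b_hi = 2.0
        lam_lo, lam_hi = grid.span
        lam0 = 500.0
        a_lo = hull_lo * (lam_hi / lam0) ** b_hi
        a_hi = hull_hi * (lam_lo / lam0) ** b_hi
        default = {
            "c_hbo2": (0.0, 200.0),
            "c_dhb": (0.0, 200.0),
            "c_bcar": (0.0, 200.0),
            "c_lymph": (0.0, 200.0),
            "a_gauss": (0.0, 5.0),
            "a": (a_lo, a_hi),
            "b": (0.0, b_hi),
        }
        if bounds:
            default.update(bounds)
        self.bounds = default
        self._lo = np.array([self.bounds[p][0] for p in PARAM_NAMES])
        self._hi = np.array([self.bounds[p][1] for p in PARAM_NAMES])

    # -- forward model ----------------------------------------------------
    def predict(self, theta: np.ndarray) -> np.ndarray:
        c = ChromophoreSet(*np.clip(theta[:5], 0.0, None))
        s = ScatteringModel(a=theta[5], b=max(theta[6], 0.0))
        return simulate_spectrum(c, s, self.basis, self.grid, self.lookup)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return self.predict(theta) / self.spectrum - 1.0

    def _start_points(self, restarts: int, seed: int) -> np.ndarray:
        """Default heuristic start plus Latin-hypercube restarts."""
        mid = np.array([20.0, 10.0, 15.0, 0.5, 0.2, 8.0, 1.0])
        mid = np.clip(mid, self._lo + 1e-9, self._hi - 1e-9)
        pts = [mid]
        if restarts > 1:
            sampler = qmc.LatinHypercube(d=len(PARAM_NAMES), seed=seed)
            unit = sampler.random(restarts - 1)
            # sample concentrations on a compressed range: physiologic values
            # sit well below the 200 uM box ceiling
            hi_eff = self._hi.copy()
            hi_eff[:4] = np.minimum(hi_eff[:4], 120.0)
            hi_eff[4] = min(hi_eff[4], 1.0)
            pts.extend(self._lo + unit * (hi_eff - self._lo))
        return np.asarray(pts)

    def fit(
        self,
        restarts: int = 4,
        seed: int = 0,
        ftol: float = 1e-12,
        xtol: float = 1e-12,
        max_nfev: int = 400,
    ) -> "InversionResults":
        """Best-of-restarts trust-region reflective least squares."""
        x_scale = np.array([30.0, 30.0, 15.0, 5.0, 0.3, 8.0, 0.5])
        best = None
        n_used = 0
        for x0 in self._start_points(restarts, seed):
            n_used += 1
            try:
                res = least_squares(
                    self._residuals,
                    x0,
                    bounds=(self._lo, self._hi),
                    method="trf",
                    x_scale=x_scale,
                    ftol=ftol,
                    xtol=xtol,
                    gtol=1e-12,
                    max_nfev=max_nfev,
                )
            except Exception:  # singular step, bad start: try next restart
                continue
            if best is None or res.cost < best.cost:
                best = res
            if best.cost < 1e-18:  # exact fit reached, no point restarting
                break
        if best is None:
            raise RuntimeError("all inversion restarts failed")
        return InversionResults(self, best, n_restarts_used=n_used)


class InversionResults:
    """Estimates, uncertainties and diagnostics from a spectral inversion."""

    def __init__(self, model: SpectralInversion, opt_result, n_restarts_used: int):
        self.model = model
        self._opt = opt_result
        self.params = opt_result.x.copy()
        self.residual = opt_result.fun.copy()
        self.residual_norm = float(np.linalg.norm(opt_result.fun))
        self.cost = float(opt_result.cost)
        self.converged = bool(opt_result.success)
        self.n_restarts_used = n_restarts_used

        self.chromophores = ChromophoreSet(*np.clip(self.params[:5], 0.0, None))
        self.scattering = ScatteringModel(a=self.params[5], b=max(self.params[6], 0.0))
        self.optical_summary: OpticalSummary = derive_summary(
            self.chromophores, self.scattering, model.grid
        )

    @property
    def thb(self) -> float:
        return self.chromophores.thb

    @property
    def so2(self) -> float | None:
        return self.chromophores.so2

    @property
    def mean_musp(self) -> float:
        return self.optical_summary.mean_musp

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params)

    def bse(self) -> np.ndarray:
        """Approximate standard errors from the Jacobian at the optimum.

        Gauss–Newton covariance s²·(JᵀJ)⁻¹ with s² the residual variance; at
        active bounds the linearization is one-sided and the value is only
        indicative.
        """
        j = self._opt.jac
        n, p = j.shape
        dof = max(n - p, 1)
        s2 = 2.0 * self.cost / dof
        cov = s2 * np.linalg.pinv(j.T @ j)
        return np.sqrt(np.clip(np.diag(cov), 0.0, None))

    def params_series(self):
        import pandas as pd

        return pd.Series(self.params, index=PARAM_NAMES)

    def summary(self) -> str:
        se = self.bse()
        lines = [
            "Spectral inversion results",
            "=" * 46,
            f"{'parameter':<10}{'estimate':>12}{'std err':>12}",
            "-" * 46,
        ]
        units = {
            "c_hbo2": "uM", "c_dhb": "uM", "c_bcar": "uM",
            "c_lymph": "uM", "a_gauss": "cm^-1", "a": "cm^-1", "b": "",
        }
        for name, val, err in zip(PARAM_NAMES, self.params, se):
            lines.append(f"{name:<10}{val:>12.4g}{err:>12.3g}  {units[name]}")
        lines.append("-" * 46)
        so2 = self.so2
        lines.append(f"THb     = {self.thb:.4g} uM")
        lines.append(f"SO2     = {'undefined (THb = 0)' if so2 is None else f'{so2:.3f}'}")
        lines.append(f"<musp>  = {self.mean_musp:.4g} cm^-1")
        lines.append(
            f"residual norm = {self.residual_norm:.3g}, "
            f"converged = {self.converged}, restarts used = {self.n_restarts_used}"
        )
        return "\n".join(lines)


def extract_cohort(
    records,
    grid: WavelengthGrid,
    basis: ExtinctionBasis,
    lookup: ReflectanceLookup,
    restarts: int = 4,
    seed: int = 0,
) -> dict:
    """Batch inversion driver.

    ``records`` is any iterable of objects with ``site_id`` and ``spectrum``
    attributes (``cohort.SiteRecord`` in the pipeline). Every record gains a
    ``fit`` attribute (an :class:`InversionResults`) or a logged failure
    reason; a per-site failure never aborts the batch. Results depend only on
    each site's own spectrum, so they are invariant to input order.
    """
    records = list(records)
    failures: dict = {}
    n_converged = 0
    for rec in records:
        try:
            model = SpectralInversion(rec.spectrum, grid, basis, lookup)
            fit = model.fit(restarts=restarts, seed=seed)
            rec.fit = fit
            if fit.converged:
                n_converged += 1
            else:
                failures[rec.site_id] = "not converged"
        except Exception as exc:  # degenerate spectrum etc.
            rec.fit = None
            failures[rec.site_id] = str(exc)
    return {
        "n_sites": len(records),
        "n_converged": n_converged,
        "n_failed": len(failures),
        "failures": failures,
    }
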