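"""Wavelength grids, extinction basis, absorption/scattering composition.

This module is the symbol home for the optical quantities used throughout the
package: the absorption coefficient μa(λ) composed from chromophore
concentrations by Beer–Lambert superposition, the reduced scattering
coefficient μs′(λ) as a Mie-type power law, and the derived scalar summaries
(total hemoglobin THb, hemoglobin saturation SO2, wavelength-averaged ⟨μs′⟩).

Units: wavelengths in nm, lengths in cm, concentrations in μM, extinction
coefficients in cm⁻¹·μM⁻¹ (decadic factor folded in, μa = ε·C).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthGrid",
    "ExtinctionBasis",
    "ChromophoreSet",
    "ScatteringModel",
    "OpticalSummary",
    "compose_mua",
    "musp_curve",
    "derive_summary",
    "default_grid",
]

#: Names of the chromophores carried by every basis, in canonical order.
CHROMOPHORES = ("hbo2", "dhb", "bcar", "lymphazurin")

GAUSSIAN_CENTER_NM = 515.0
GAUSSIAN_SIGMA_NM = 10.0


class GridMismatchError(ValueError):
    """Raised when a basis or spectrum is evaluated on a foreign grid."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly ascending wavelength grid, by default within 450–600 nm."""

    wavelengths: np.ndarray

    def __init__(self, wavelengths, *, enforce_range: bool = True) -> None:
        lam = np.asarray(wavelengths, dtype=float)
        if lam.ndim != 1 or lam.size < 2:
            raise ValueError("wavelength grid needs at least 2 points")
        if np.any(np.diff(lam) <= 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if enforce_range and (lam[0] < 450.0 - 1e-9 or lam[-1] > 600.0 + 1e-9):
            raise ValueError(
                f"grid [{lam[0]}, {lam[-1]}] nm outside the 450–600 nm "
                "analysis window; pass enforce_range=False to override"
            )
        object.__setattr__(self, "wavelengths", lam)

    def __len__(self) -> int:
        return self.wavelengths.size

    def __eq__(self, other) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.wavelengths.shape == other.wavelengths.shape and np.array_equal(
            self.wavelengths, other.wavelengths
        )

    def __hash__(self) -> int:
        return hash(self.wavelengths.tobytes())

    def index_of(self, wavelength: float) -> int:
        """Index of the grid point nearest to ``wavelength``."""
        return int(np.argmin(np.abs(self.wavelengths - wavelength)))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.wavelengths[0]), float(self.wavelengths[-1])


def default_grid(step: float = 1.0) -> WavelengthGrid:
    """The 450–600 nm analysis grid at ``step`` nm spacing (default 1 nm)."""
    n = int(round((600.0 - 450.0) / step))
    return WavelengthGrid(np.linspace(450.0, 600.0, n + 1))


def _read_extinction_table(path) -> tuple[np.ndarray, np.ndarray]:
    arr = np.loadtxt(path, comments="#")
    lam, eps = arr[:, 0], arr[:, 1]
    if np.any(eps < 0):
        raise ValueError(f"negative extinction value in {path}")
    return lam, eps


@dataclass(frozen=True)
class ExtinctionBasis:
    """Per-chromophore extinction curves interpolated onto a grid.

    The basis carries curves for oxyhemoglobin, deoxyhemoglobin, β-carotene
    and Lymphazurin, plus the parameters of the arbitrary Gaussian absorber
    (center 515 nm, σ 10 nm) used to absorb the shape difference between
    tabulated and in-tissue β-carotene absorption.
    """

    grid: WavelengthGrid
    curves: dict[str, np.ndarray]
    gaussian_center: float = GAUSSIAN_CENTER_NM
    gaussian_sigma: float = GAUSSIAN_SIGMA_NM

    def __post_init__(self) -> None:
        for name in CHROMOPHORES:
            if name not in self.curves:
                raise ValueError(f"basis missing chromophore {name!r}")
            c = self.curves[name]
            if c.shape != self.grid.wavelengths.shape:
                raise GridMismatchError(
                    f"extinction curve {name!r} not defined on the basis grid"
                )
            if np.any(c < 0):
                raise ValueError(f"extinction curve {name!r} has negative values")

    @classmethod
    def from_files(
        cls,
        grid: WavelengthGrid,
        files: dict[str, Path],
        gaussian_center: float = GAUSSIAN_CENTER_NM,
        gaussian_sigma: float = GAUSSIAN_SIGMA_NM,
    ) -> "ExtinctionBasis":
        """Load two-column (wavelength_nm, epsilon) tables and interpolate."""
        curves = {}
        for name, path in files.items():
            lam, eps = _read_extinction_table(path)
            lo, hi = grid.span
            if lam[0] > lo or lam[-1] < hi:
                raise ValueError(
                    f"extinction table {path} covers [{lam[0]}, {lam[-1]}] nm, "
                    f"grid needs [{lo}, {hi}] nm"
                )
            curves[name] = np.interp(grid.wavelengths, lam, eps)
        return cls(grid, curves, gaussian_center, gaussian_sigma)

    @classmethod
    def default(cls, grid: WavelengthGrid | None = None) -> "ExtinctionBasis":
        """The packaged (synthetic) extinction tables on ``grid``."""
        if grid is None:
            grid = default_grid()
        data_dir = resources.files("marginspec") / "data"
        files = {
            name: data_dir / f"{name}_extinction_synthetic.tsv"
            for name in CHROMOPHORES
        }
        return cls.from_files(grid, files)

    def gaussian_shape(self) -> np.ndarray:
        """Unit-peak Gaussian absorber shape on the grid."""
        lam = self.grid.wavelengths
        return np.exp(-0.5 * ((lam - self.gaussian_center) / self.gaussian_sigma) ** 2)


@dataclass(frozen=True)
class ChromophoreSet:
    """Free absorber parameters of the fit.

    Concentrations in μM (Lymphazurin in μM-equivalent against the packaged
    curve); ``a_gauss`` is the peak absorption of the arbitrary Gaussian
    absorber in cm⁻¹.
    """

    c_hbo2: float = 0.0
    c_dhb: float = 0.0
    c_bcar: float = 0.0
    c_lymph: float = 0.0
    a_gauss: float = 0.0

    def __post_init__(self) -> None:
        for name in ("c_hbo2", "c_dhb", "c_bcar", "c_lymph", "a_gauss"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def thb(self) -> float:
        """Total hemoglobin concentration in μM."""
        return self.c_hbo2 + self.c_dhb

    @property
    def so2(self) -> float | None:
        """Hemoglobin saturation, or None when THb = 0 (flagged, not NaN)."""
        if self.thb == 0.0:
            return None
        return self.c_hbo2 / self.thb

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.c_hbo2, self.c_dhb, self.c_bcar, self.c_lymph, self.a_gauss]
        )


@dataclass(frozen=True)
class ScatteringModel:
    """Mie-type power law μs′(λ) = a·(λ/λ0)^(−b), λ0 = 500 nm by default."""

    a: float
    b: float
    lambda0: float = 500.0

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("scattering amplitude a must be > 0")
        if self.b < 0:
            raise ValueError("scattering power b must be >= 0")


@dataclass(frozen=True)
class OpticalSummary:
    """Scalar optical summary of one site.

    ``so2`` is None when THb = 0 (saturation undefined, flagged rather than
    propagated as NaN).
    """

    thb: float
    so2: float | None
    mean_musp: float
    c_bcar: float

    def __post_init__(self) -> None:
        if self.so2 is not None and not (0.0 <= self.so2 <= 1.0):
            raise ValueError("SO2 must lie in [0, 1]")
        if not self.mean_musp > 0:
            raise ValueError("mean musp must be > 0")


def compose_mua(
    c: ChromophoreSet, basis: ExtinctionBasis, grid: WavelengthGrid
) -> np.ndarray:
    """Beer–Lambert absorption spectrum μa(λ) in cm⁻¹ on ``grid``.

    μa(λ) = Σ_i ε_i(λ)·C_i + A_gauss·exp(−(λ−515)²/(2·10²)).
    """
    if basis.grid != grid:
        raise GridMismatchError("basis is not defined on the requested grid")
    mua = (
        c.c_hbo2 * basis.curves["hbo2"]
        + c.c_dhb * basis.curves["dhb"]
        + c.c_bcar * basis.curves["bcar"]
        + c.c_lymph * basis.curves["lymphazurin"]
        + c.a_gauss * basis.gaussian_shape()
    )
    return mua


def musp_curve(s: ScatteringModel, grid: WavelengthGrid) -> np.ndarray:
    """Reduced scattering spectrum μs′(λ) = a·(λ/λ0)^(−b) in cm⁻¹."""
    lo, hi = grid.span
    if not (lo <= s.lambda0 <= hi):
        raise ValueError("reference wavelength lambda0 outside the grid span")
    return s.a * (grid.wavelengths / s.lambda0) ** (-s.b)


def derive_summary(
    c: ChromophoreSet, s: ScatteringModel, grid: WavelengthGrid
) -> OpticalSummary:
    """THb, SO2 and the unweighted wavelength-averaged ⟨μs′⟩ over the grid."""
    return OpticalSummary(
        thb=c.thb,
        so2=c.so2,
        mean_musp=float(np.mean(musp_curve(s, grid))),
        c_bcar=c.c_bcar,
    )


def mean_musp(s: ScatteringModel, grid: WavelengthGrid) -> float:
    """Unweighted grid average of the power-law μs′(λ)."""
    return float(np.mean(musp_curve(s, grid)))
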