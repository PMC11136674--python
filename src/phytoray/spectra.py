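"""Spectra, wavebands, and band integration.

Every radiometric quantity that varies with wavelength -- surface
reflectivity :math:`\\rho_\\lambda`, transmissivity :math:`\\tau_\\lambda`,
source flux :math:`S_\\lambda` (W m^-2 nm^-1), and the normalised camera
response :math:`C_\\lambda` -- is represented as a :class:`Spectrum`:
tabulated values on a strictly increasing wavelength grid in nanometres.

Band integration follows the camera-weighting convention

.. math::

    \\rho_o = \\frac{\\int \\rho_\\lambda C_\\lambda S_\\lambda d\\lambda}
                   {\\int S_\\lambda d\\lambda},

with the plain band reflectivity/transmissivity being the same expression at
:math:`C_\\lambda \\equiv 1` (the source-weighted mean).  Note the
denominator deliberately excludes the camera response, so a camera that is
insensitive over part of the band genuinely loses signal rather than being
renormalised.  All integrals use trapezoidal quadrature on a common 1-nm
grid with band endpoints clipped by linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: Stefan-Boltzmann constant, W m^-2 K^-4
SIGMA_SB = 5.670374419e-8

#: Common internal wavelength grid (nm): PROSPECT's native range at 1 nm.
GRID_MIN_NM = 400.0
GRID_MAX_NM = 2500.0
COMMON_GRID = np.arange(GRID_MIN_NM, GRID_MAX_NM + 1.0, 1.0)


@dataclass(frozen=True)
class Spectrum:
    """A tabulated function of wavelength.

    Parameters
    ----------
    wavelengths_nm
        Strictly increasing wavelengths in nanometres.
    values
        Non-negative values, same length as the grid.  Units depend on role:
        dimensionless for reflectivity/transmissivity/camera response,
        W m^-2 nm^-1 for source flux.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if w.ndim != 1 or v.ndim != 1 or w.size != v.size or w.size == 0:
            raise ValueError("wavelengths and values must be matching 1-D arrays")
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite and non-negative")
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "values", v)

    # -- constructors -------------------------------------------------

    @classmethod
    def constant(cls, value: float,
                 lo: float = GRID_MIN_NM, hi: float = GRID_MAX_NM,
                 step: float = 1.0) -> "Spectrum":
        grid = np.arange(lo, hi + step / 2, step)
        return cls(grid, np.full(grid.size, float(value)))

    @classmethod
    def from_text(cls, path) -> "Spectrum":
        """Read a two-column delimited text file (wavelength_nm, value)."""
        arr = np.loadtxt(path, ndmin=2)
        if arr.shape[1] < 2:
            raise ValueError(f"{path}: expected two columns")
        order = np.argsort(arr[:, 0])
        return cls(arr[order, 0], arr[order, 1])

    def to_text(self, path) -> None:
        np.savetxt(path, np.column_stack([self.wavelengths_nm, self.values]),
                   fmt="%.6f", header="wavelength_nm value")

    # -- queries ------------------------------------------------------

    def __call__(self, wavelengths) -> np.ndarray:
        """Linear interpolation; zero outside the tabulated support."""
        return np.interp(np.asarray(wavelengths, dtype=float),
                         self.wavelengths_nm, self.values,
                         left=0.0, right=0.0)

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])


@dataclass(frozen=True)
class WaveBand:
    """A labelled wavelength interval [lambda_min, lambda_max] in nm.

    ``longwave`` bands carry thermally emitted radiation; their surface
    properties come from emissivity (Kirchhoff) rather than from spectra,
    and their source fluxes from the Stefan-Boltzmann law.
    """

    label: str
    lambda_min_nm: float
    lambda_max_nm: float
    longwave: bool = False

    def __post_init__(self) -> None:
        if not self.lambda_min_nm < self.lambda_max_nm:
            raise ValueError("band bounds must satisfy lambda_min < lambda_max")

    @property
    def width_nm(self) -> float:
        return self.lambda_max_nm - self.lambda_min_nm


@dataclass(frozen=True)
class BandProperties:
    """Band-integrated surface properties.

    ``rho``/``tau`` drive scattering between scene objects; ``rho_o``/
    ``tau_o`` are the camera-weighted analogues used for energy scattered
    toward a camera.
    """

    rho: float
    tau: float
    rho_o: float = field(default=np.nan)
    tau_o: float = field(default=np.nan)

    def __post_init__(self) -> None:
        ro = self.rho if np.isnan(self.rho_o) else self.rho_o
        to = self.tau if np.isnan(self.tau_o) else self.tau_o
        object.__setattr__(self, "rho_o", float(ro))
        object.__setattr__(self, "tau_o", float(to))
        for name in ("rho", "tau", "rho_o", "tau_o"):
            x = getattr(self, name)
            if not (-1e-12 <= x <= 1 + 1e-12):
                raise ValueError(f"{name}={x} outside [0, 1]")
        if self.rho + self.tau > 1 + 1e-9:
            raise ValueError("rho + tau must not exceed 1")


# ---------------------------------------------------------------------------
# operations


def resample(spectrum: Spectrum, grid) -> Spectrum:
    """Linear interpolation of a spectrum onto a new grid.

    Values outside the source support are zero.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("target grid is empty")
    return Spectrum(grid, spectrum(grid))


def _band_grid(band: WaveBand, *spectra: Spectrum) -> np.ndarray:
    """Integration grid: union of tabulated points inside the band plus the
    clipped band endpoints (endpoint values by linear interpolation), each
    interval subdivided 4x.  The refinement matters because products of
    piecewise-linear spectra are cubic within a cell; a refined trapezoid
    rule keeps the quadrature within ~1e-7 relative of the exact integral.
    """
    pts = [np.asarray([band.lambda_min_nm, band.lambda_max_nm])]
    for s in spectra:
        w = s.wavelengths_nm
        pts.append(w[(w >= band.lambda_min_nm) & (w <= band.lambda_max_nm)])
    grid = np.unique(np.concatenate(pts))
    if grid.size > 1:
        steps = np.linspace(grid[:-1], grid[1:], 5, axis=1)
        grid = np.unique(steps.ravel())
    return grid


def band_integrate_source(S: Spectrum, band: WaveBand) -> float:
    """Integral of a source flux spectrum over a band (W m^-2)."""
    lo, hi = S.support
    if band.lambda_max_nm < lo or band.lambda_min_nm > hi:
        warnings.warn(
            f"band {band.label!r} [{band.lambda_min_nm}, {band.lambda_max_nm}] nm "
            "does not overlap the source spectrum support; flux is zero",
            stacklevel=2)
        return 0.0
    grid = _band_grid(band, S)
    return float(np.trapezoid(S(grid), grid))


def band_surface_props(rho: Spectrum, tau: Spectrum, S: Spectrum,
                       band: WaveBand) -> tuple[float, float]:
    """Source-weighted band reflectivity and transmissivity (camera-free)."""
    return band_camera_props(rho, tau, None, S, band)


def band_camera_props(rho: Spectrum, tau: Spectrum, C: Spectrum | None,
                      S: Spectrum, band: WaveBand) -> tuple[float, float]:
    """Camera-weighted band properties (rho_o, tau_o).

    With ``C=None`` (or a unit response) this reduces to the plain
    source-weighted band properties.  Raises if the source carries no energy
    in the band, since the weighting is then undefined.
    """
    grid = _band_grid(band, rho, tau, S, *( [C] if C is not None else [] ))
    s = S(grid)
    denom = np.trapezoid(s, grid)
    if denom <= 0.0:
        raise ValueError(
            f"source spectrum integrates to zero over band {band.label!r}; "
            "band weighting is undefined")
    c = np.ones_like(grid) if C is None else C(grid)
    r = float(np.trapezoid(rho(grid) * c * s, grid) / denom)
    t = float(np.trapezoid(tau(grid) * c * s, grid) / denom)
    return r, t


def stefan_boltzmann_flux(T: float, emissivity: float = 1.0) -> float:
    """Hemispherical emitted flux eps*sigma*T^4 (W m^-2)."""
    if T < 0:
        raise ValueError("temperature must be non-negative (kelvin)")
    if not 0.0 <= emissivity <= 1.0:
        raise ValueError("emissivity must lie in [0, 1]")
    return emissivity * SIGMA_SB * float(T) ** 4
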