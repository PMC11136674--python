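"""Leaf reflectance/transmittance from biochemistry: a generalised plate model.

The leaf is modelled as a pile of ``N`` identical absorbing plates separated
by ``N - 1`` air gaps (the classic Allen plate model generalised by Stokes'
layer-adding system to non-integer ``N``).  Each plate combines:

* Fresnel reflection/refraction at the air-cell-wall interfaces, averaged
  over an incidence cone (a 40 deg cone for the leaf's upper surface, the
  full hemisphere for internal, diffuse radiation), and
* absorption of an isotropic beam crossing the plate, expressed through the
  exponential-integral function,
  ``theta(k) = (1 - k) e^{-k} + k^2 E_1(k)``.

The per-plate absorption coefficient ``k(lambda)`` is the concentration-
weighted sum of specific absorption coefficients of the leaf constituents
(chlorophyll, carotenoids, anthocyanins, water, dry matter -- or, in PRO
mode, protein and carbon-based constituents instead of bulk dry matter)
divided by ``N``.

Coefficient tables
------------------
The refractive index ``n(lambda)`` and specific absorption coefficients
``K_i(lambda)`` are data, not algorithm.  This package ships a *synthetic*
table (:meth:`AbsorptionTables.synthetic_default`) built from smooth
closed-form absorption bands placed at the documented feature wavelengths
(chlorophyll blue/red peaks, water overtone bands, SWIR dry-matter bands).
It is physically plausible and spans 400-2500 nm, but it is not a published
calibration; quantitative use should load a real calibration table with
:meth:`AbsorptionTables.from_text`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import exp1

from .spectra import Spectrum

#: constituent keys used in D mode and PRO mode
D_CONSTITUENTS = ("chlorophyll", "carotenoids", "anthocyanins", "water", "dry_mass")
PRO_CONSTITUENTS = ("chlorophyll", "carotenoids", "anthocyanins", "water",
                    "protein", "cbc")


@dataclass(frozen=True)
class LeafBiochemistry:
    """Leaf structure and constituent concentrations.

    Units: chlorophyll/carotenoids/anthocyanins in ug cm^-2; water
    (equivalent water thickness), dry mass (LMA), protein and carbon-based
    constituents (cbc) in g cm^-2.  ``n_layers`` is the effective number of
    elementary plates (>= 1, non-integer allowed).
    """

    n_layers: float = 1.5
    chlorophyll: float = 40.0
    carotenoids: float = 10.0
    anthocyanins: float = 0.5
    water_ewt: float = 0.015
    dry_mass_lma: float = 0.009
    protein: float = 0.001
    cbc: float = 0.008

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        for name in ("chlorophyll", "carotenoids", "anthocyanins",
                     "water_ewt", "dry_mass_lma", "protein", "cbc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def concentrations(self, mode: str) -> dict[str, float]:
        if mode == "D":
            return {"chlorophyll": self.chlorophyll,
                    "carotenoids": self.carotenoids,
                    "anthocyanins": self.anthocyanins,
                    "water": self.water_ewt,
                    "dry_mass": self.dry_mass_lma}
        if mode == "PRO":
            return {"chlorophyll": self.chlorophyll,
                    "carotenoids": self.carotenoids,
                    "anthocyanins": self.anthocyanins,
                    "water": self.water_ewt,
                    "protein": self.protein,
                    "cbc": self.cbc}
        raise ValueError(f"unknown mode {mode!r}; expected 'D' or 'PRO'")


def _gauss(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)


@dataclass(frozen=True)
class AbsorptionTables:
    """Refractive index and specific absorption coefficients, 400-2500 nm.

    ``coefficients`` maps constituent name to K_i(lambda); units cm^2/ug for
    pigments and cm^2/g for water, dry matter, protein and cbc, matching the
    concentration units of :class:`LeafBiochemistry`.
    """

    wavelengths_nm: np.ndarray
    refractive_index: np.ndarray
    coefficients: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        n = np.asarray(self.refractive_index, dtype=float)
        if not np.all(np.diff(w) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(n <= 1):
            raise ValueError("refractive index must exceed 1 everywhere")
        for key, k in self.coefficients.items():
            k = np.asarray(k, dtype=float)
            if k.shape != w.shape:
                raise ValueError(f"coefficient {key!r} length mismatch")
            if np.any(k < 0):
                raise ValueError(f"coefficient {key!r} must be non-negative")
            self.coefficients[key] = k
        object.__setattr__(self, "wavelengths_nm", w)
        object.__setattr__(self, "refractive_index", n)

    @classmethod
    def synthetic_default(cls) -> "AbsorptionTables":
        """Synthetic stand-in coefficient table (see module docstring).

        Smooth Gaussian absorption bands at the physically documented
        feature wavelengths; NOT a published calibration.
        """
        w = np.arange(400.0, 2501.0, 1.0)
        n = 1.40 + 0.14 * np.exp(-(w - 400.0) / 800.0)
        k_chl = (0.065 * _gauss(w, 430, 35) + 0.050 * _gauss(w, 460, 30)
                 + 0.020 * _gauss(w, 620, 40) + 0.110 * _gauss(w, 678, 24))
        k_car = 0.045 * _gauss(w, 450, 35) + 0.035 * _gauss(w, 480, 30)
        k_anth = 0.035 * _gauss(w, 548, 40)
        k_w = (0.5 * _gauss(w, 970, 45) + 1.3 * _gauss(w, 1200, 60)
               + 28.0 * _gauss(w, 1450, 55) + 7.0 * _gauss(w, 1780, 90)
               + 125.0 * _gauss(w, 1940, 70) + 80.0 * _gauss(w, 2300, 180)
               + 55.0 * _gauss(w, 2500, 200))
        k_dm = (0.8 * _gauss(w, 1500, 400) + 6.0 * _gauss(w, 1730, 120)
                + 9.0 * _gauss(w, 2100, 150) + 14.0 * _gauss(w, 2300, 110)
                + 10.0 * _gauss(w, 2480, 120))
        k_prot = (5.0 * _gauss(w, 1500, 200) + 18.0 * _gauss(w, 2050, 100)
                  + 16.0 * _gauss(w, 2170, 90))
        k_cbc = (1.0 * _gauss(w, 1200, 300) + 8.0 * _gauss(w, 1730, 110)
                 + 6.0 * _gauss(w, 2100, 200) + 12.0 * _gauss(w, 2270, 140))
        return cls(w, n, {
            "chlorophyll": k_chl, "carotenoids": k_car, "anthocyanins": k_anth,
            "water": k_w, "dry_mass": k_dm, "protein": k_prot, "cbc": k_cbc,
        })

    @classmethod
    def from_text(cls, path) -> "AbsorptionTables":
        """Load a delimited text table.

        First line is a header naming the columns: ``wavelength_nm n`` then
        one constituent name per remaining column.
        """
        with open(path) as fh:
            header = fh.readline().lstrip("#").split()
        arr = np.loadtxt(path, skiprows=1, ndmin=2)
        if header[:2] != ["wavelength_nm", "n"]:
            raise ValueError("expected columns: wavelength_nm n <constituents...>")
        coeffs = {name: arr[:, 2 + i] for i, name in enumerate(header[2:])}
        return cls(arr[:, 0], arr[:, 1], coeffs)

    def to_text(self, path) -> None:
        names = list(self.coefficients)
        data = np.column_stack([self.wavelengths_nm, self.refractive_index]
                               + [self.coefficients[k] for k in names])
        np.savetxt(path, data, fmt="%.6g",
                   header="wavelength_nm n " + " ".join(names), comments="")


# ---------------------------------------------------------------------------
# plate-model pieces


def layer_absorption(bio: LeafBiochemistry, tables: AbsorptionTables,
                     mode: str = "D") -> Spectrum:
    """Per-elementary-layer absorption coefficient k(lambda).

    ``k = sum_i C_i K_i(lambda) / N`` -- linear in every concentration.
    """
    conc = bio.concentrations(mode)
    k = np.zeros_like(tables.wavelengths_nm)
    for name, c in conc.items():
        if name not in tables.coefficients:
            raise KeyError(f"absorption table lacks constituent {name!r}")
        k = k + c * tables.coefficients[name]
    return Spectrum(tables.wavelengths_nm, k / bio.n_layers)


def isotropic_transmission(k) -> np.ndarray:
    """Transmission of an isotropic beam through an absorbing plate.

    ``theta(k) = (1 - k) e^{-k} + k^2 E_1(k)``; equals 1 at k = 0.
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(k < 0):
        raise ValueError("absorption coefficient must be non-negative")
    out = np.ones_like(k)
    pos = k > 0
    kp = k[pos]
    out[pos] = (1.0 - kp) * np.exp(-kp) + kp ** 2 * exp1(kp)
    return out


_GL_NODES, _GL_WEIGHTS = leggauss(96)


def average_transmissivity(alpha_deg: float, n) -> np.ndarray:
    """Fresnel interface transmissivity averaged over an incidence cone.

    Flux-weighted (sin(theta) cos(theta)) average of the unpolarised Fresnel
    power transmittance for radiation entering a medium of index ``n`` from
    air, over incidence angles 0..alpha.  Evaluated by Gauss-Legendre
    quadrature; vectorised over ``n``.
    """
    if not 0.0 < alpha_deg <= 90.0:
        raise ValueError("alpha must lie in (0, 90] degrees")
    n = np.atleast_1d(np.asarray(n, dtype=float))
    alpha = np.deg2rad(alpha_deg)
    theta = 0.5 * alpha * (_GL_NODES + 1.0)            # (K,)
    wgt = 0.5 * alpha * _GL_WEIGHTS
    ct = np.cos(theta)[:, None]
    st = np.sin(theta)[:, None]
    stt = st / n[None, :]
    ctt = np.sqrt(1.0 - stt ** 2)
    rs = (ct - n * ctt) / (ct + n * ctt)
    rp = (n * ct - ctt) / (n * ct + ctt)
    T = 1.0 - 0.5 * (rs ** 2 + rp ** 2)
    w = (st * ct)[:, 0] * wgt                          # flux weighting
    return (T * w[:, None]).sum(axis=0) / w.sum()


def plate_rt(k, n_refr, alpha_deg: float = 40.0) -> tuple[np.ndarray, np.ndarray]:
    """Reflectance/transmittance of a single absorbing plate.

    The top interface admits radiation within a cone of half-angle
    ``alpha_deg``; internal radiation (between the plate faces) is diffuse,
    so internal interface terms use the full-hemisphere average and the
    inside-out transmissivity ``tav(90, n) / n^2``.
    """
    k = np.atleast_1d(np.asarray(k, dtype=float))
    n = np.broadcast_to(np.atleast_1d(np.asarray(n_refr, dtype=float)), k.shape)
    if np.any(n <= 1):
        raise ValueError("refractive index must exceed 1")
    theta = isotropic_transmission(k)
    talf = average_transmissivity(alpha_deg, n)
    t12 = average_transmissivity(90.0, n)
    t21 = t12 / n ** 2
    r21 = 1.0 - t21
    denom = 1.0 - r21 ** 2 * theta ** 2
    T1 = talf * theta * t21 / denom
    R1 = (1.0 - talf) + r21 * theta * T1
    if np.any(T1 < -1e-12) or np.any(R1 < -1e-12) or np.any(R1 + T1 > 1 + 1e-9):
        raise ArithmeticError("plate model produced non-physical R/T")
    return R1, T1


def stack_layers(R1, T1, n_layers: float) -> tuple[np.ndarray, np.ndarray]:
    """Stokes solution for a stack of ``n_layers`` identical plates.

    Non-integer layer counts are handled through fractional powers of the
    Stokes eigenvalue ``b``.  Degenerate conservative (R + T = 1) and
    opaque (T = 0) plates take their analytic limits.
    """
    if n_layers < 0:
        raise ValueError("layer count must be non-negative")
    R1 = np.atleast_1d(np.asarray(R1, dtype=float))
    T1 = np.atleast_1d(np.asarray(T1, dtype=float))
    if np.any(R1 < 0) or np.any(T1 < 0) or np.any(R1 + T1 > 1 + 1e-9):
        raise ValueError("R1, T1 must be in [0,1] with R1 + T1 <= 1")
    if n_layers == 0:
        return np.zeros_like(R1), np.ones_like(T1)

    RN = np.empty_like(R1)
    TN = np.empty_like(T1)

    conservative = R1 + T1 >= 1.0 - 1e-12
    opaque = T1 <= 1e-14
    regular = ~(conservative | opaque)

    # conservative plate: random-walk limit
    t = T1[conservative]
    TN[conservative] = t / (t + (1.0 - t) * n_layers)
    RN[conservative] = 1.0 - TN[conservative]

    RN[opaque] = R1[opaque]
    TN[opaque] = 0.0

    r, t = R1[regular], T1[regular]
    small = r <= 1e-14                    # non-reflecting: pure Beer stacking
    D = np.sqrt(np.maximum((1 + r + t) * (1 + r - t) * (1 - r + t) * (1 - r - t),
                           0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(small, np.inf, (1 + r ** 2 - t ** 2 + D) / (2 * r))
        b = (1 - r ** 2 + t ** 2 + D) / (2 * t)
        bN = b ** n_layers
        denom = a ** 2 * bN ** 2 - 1.0
        Rr = a * (bN ** 2 - 1.0) / denom
        Tr = bN * (a ** 2 - 1.0) / denom
    Rr = np.where(small, 0.0, Rr)
    Tr = np.where(small, t ** n_layers, Tr)
    RN[regular] = Rr
    TN[regular] = Tr

    if np.any(RN < -1e-12) or np.any(TN < -1e-12) or np.any(RN + TN > 1 + 1e-9):
        raise ArithmeticError("layer stacking produced non-physical R/T")
    return RN, TN


def prospect(bio: LeafBiochemistry,
             tables: AbsorptionTables | None = None,
             mode: str = "D",
             alpha_deg: float = 40.0) -> tuple[Spectrum, Spectrum]:
    """Full-leaf hemispherical reflectance and transmittance spectra.

    Composes :func:`layer_absorption`, :func:`plate_rt` (one top plate with
    the ``alpha_deg`` incidence cone, diffuse interior plates), and
    :func:`stack_layers` for the remaining ``N - 1`` plates.  Returns
    (rho, tau) on the table's wavelength grid.
    """
    if tables is None:
        tables = AbsorptionTables.synthetic_default()
    k = layer_absorption(bio, tables, mode).values
    n = tables.refractive_index

    Ra, Ta = plate_rt(k, n, alpha_deg)       # top plate, restricted cone
    r, t = plate_rt(k, n, 90.0)              # interior plate, diffuse
    Rsub, Tsub = stack_layers(r, t, bio.n_layers - 1.0)

    denom = 1.0 - Rsub * r
    tran = Ta * Tsub / denom
    refl = Ra + Ta * Rsub * t / denom
    if np.any(refl < -1e-12) or np.any(tran < -1e-12) \
            or np.any(refl + tran > 1 + 1e-9):
        raise ArithmeticError("leaf model produced non-physical rho/tau")
    w = tables.wavelengths_nm
    return Spectrum(w, np.clip(refl, 0, None)), Spectrum(w, np.clip(tran, 0, None))
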