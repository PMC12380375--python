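"""Shared optical types, unit conventions, and spectroscopy utilities.

The package works in micrometres for every length.  Spectra may be tagged in
wavenumbers (cm^-1) or wavelengths (um); the conversion is
``nu[cm^-1] = 1e4 / lambda[um]``.  The free-space wavevector magnitude used by
every simulation is ``k = 2*pi/lambda`` in rad/um, with the time convention
``e^{-i omega t}`` so that a medium with extinction coefficient kappa >= 0
attenuates a forward-propagating wave ``E = E0 e^{i k n z}``.

The complex refractive index is ``n = m + i*kappa`` with m the (real)
refractive index and kappa the extinction coefficient.  Absorbance follows the
Beer-Lambert law ``A = rho * b * eps`` and the instrument definition
``A = -log10(I / I0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "OpticalConstants",
    "PlaneWave",
    "ComplexField2D",
    "RadialField1D",
    "wavelength_to_wavenumber",
    "wavenumber_to_wavelength",
    "wavenumber",
    "kk_real_from_imag",
    "kk_imag_from_real",
    "beer_lambert_absorbance",
    "molar_absorptivity_from_kappa",
    "absorbance_from_intensities",
]


def wavelength_to_wavenumber(lambda_um):
    """Convert wavelength in um to wavenumber in cm^-1."""
    lam = np.asarray(lambda_um, dtype=float)
    if np.any(lam <= 0):
        raise ValueError("wavelength must be positive")
    return 1.0e4 / lam


def wavenumber_to_wavelength(nu_cm):
    """Convert wavenumber in cm^-1 to wavelength in um."""
    nu = np.asarray(nu_cm, dtype=float)
    if np.any(nu <= 0):
        raise ValueError("wavenumber must be positive")
    return 1.0e4 / nu


def wavenumber(wavelength_um: float) -> float:
    """Free-space wavevector magnitude ``k = 2*pi/lambda`` in rad/um."""
    if wavelength_um <= 0:
        raise ValueError("wavelength must be positive")
    return 2.0 * np.pi / wavelength_um


@dataclass
class OpticalConstants:
    """Complex refractive index spectrum ``n = m + i*kappa`` on a spectral grid.

    Parameters
    ----------
    grid : array
        Strictly increasing spectral axis.
    m : array
        Real refractive index per grid point.
    kappa : array
        Extinction coefficient per grid point (nonnegative).
    unit : {"cm^-1", "um"}
        Whether `grid` holds wavenumbers or wavelengths.
    """

    grid: np.ndarray
    m: np.ndarray
    kappa: np.ndarray
    unit: Literal["cm^-1", "um"] = "cm^-1"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        if self.grid.ndim != 1:
            raise ValueError("grid must be one-dimensional")
        if not (self.grid.shape == self.m.shape == self.kappa.shape):
            raise ValueError("grid, m and kappa must have identical shapes")
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.kappa < 0):
            raise ValueError("kappa must be nonnegative")
        if self.unit not in ("cm^-1", "um"):
            raise ValueError(f"unknown spectral unit {self.unit!r}")

    @property
    def n(self) -> np.ndarray:
        """Complex refractive index ``m + i*kappa``."""
        return self.m + 1j * self.kappa


@dataclass
class PlaneWave:
    """A monochromatic plane wave ``E(r) = E0 * e_hat * exp(i k . r)``.

    `polarization` is a complex unit 3-vector (e^H e = 1) orthogonal to the
    real unit `direction`; `wavelength` is in um.
    """

    amplitude: complex = 1.0 + 0.0j
    polarization: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0], complex))
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    wavelength: float = 1.0

    def __post_init__(self):
        self.polarization = np.asarray(self.polarization, dtype=complex)
        self.direction = np.asarray(self.direction, dtype=float)
        if self.polarization.shape != (3,) or self.direction.shape != (3,):
            raise ValueError("polarization and direction must be 3-vectors")
        nrm = float(np.vdot(self.polarization, self.polarization).real)
        if abs(nrm - 1.0) > 1e-8:
            raise ValueError("polarization must satisfy e^H e = 1")
        if abs(np.linalg.norm(self.direction) - 1.0) > 1e-8:
            raise ValueError("direction must be a unit vector")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def k(self) -> float:
        return wavenumber(self.wavelength)


@dataclass
class ComplexField2D:
    """Complex scalar field on a square regular grid with physical extent.

    `samples` is an (R, R) complex array; `fov` the physical side length in um.
    Physical coordinates are centred on the grid (the origin sits at the grid
    centre), x increasing rightward along columns, y downward along rows.
    """

    samples: np.ndarray
    fov: float
    wavelength: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=complex)
        if self.samples.ndim != 2 or min(self.samples.shape) < 2:
            raise ValueError("samples must be a 2-D grid with R >= 2")
        if not np.all(np.isfinite(self.samples[np.logical_not(np.isnan(self.samples))])):
            raise ValueError("samples must be finite")
        if self.fov <= 0:
            raise ValueError("fov must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def resolution(self) -> int:
        return self.samples.shape[0]

    def axes(self):
        """Centred physical coordinate axes (x along columns, y along rows)."""
        r = self.samples.shape[0]
        step = self.fov / r
        x = (np.arange(r) - r // 2) * step
        return x, x.copy()

    @property
    def intensity(self) -> np.ndarray:
        """Detected intensity ``I = E^H E`` per pixel."""
        return np.abs(self.samples) ** 2


@dataclass
class RadialField1D:
    """Complex field sampled on a nonnegative, increasing radial grid.

    `domain` distinguishes the spatial (radius in um) and reciprocal (radial
    frequency in um^-1, ordinary-frequency convention) representations.
    """

    samples: np.ndarray
    radii: np.ndarray
    domain: Literal["spatial", "reciprocal"]
    wavelength: float

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=complex)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("need at least two radial samples")
        if self.samples.shape != self.radii.shape:
            raise ValueError("samples and radii must match")
        if np.any(self.radii < 0) or np.any(np.diff(self.radii) <= 0):
            raise ValueError("radii must be nonnegative and strictly increasing")
        if self.domain not in ("spatial", "reciprocal"):
            raise ValueError(f"unknown domain {self.domain!r}")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def r_max(self) -> float:
        return float(self.radii[-1])


# ---------------------------------------------------------------------------
# Kramers-Kronig relations
# ---------------------------------------------------------------------------

def _kk_grid_check(spectrum, grid):
    spectrum = np.asarray(spectrum, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 8:
        raise ValueError("KK transform needs a 1-D grid with at least 8 points")
    if spectrum.shape != grid.shape:
        raise ValueError("spectrum and grid must have the same shape")
    d = np.diff(grid)
    if np.any(d <= 0):
        raise ValueError("grid must be strictly increasing")
    if not np.allclose(d, d[0], rtol=1e-9, atol=0.0):
        raise ValueError("KK transform requires a uniform grid")
    return spectrum, grid, float(d[0])


def _hilbert_pv(spectrum, grid):
    """Principal-value integral (1/pi) P int f(w')/(w' - w) dw' on a uniform grid.

    Desingularised quadrature: the smooth part uses the midpoint sum with the
    singular node excluded, while the log-divergent part of the constant term
    is integrated analytically over the grid's support.
    """
    f, w, dw = _kk_grid_check(spectrum, grid)
    npts = w.size
    diff = w[None, :] - w[:, None]          # w_j - w_i
    with np.errstate(divide="ignore", invalid="ignore"):
        kern = np.where(diff != 0.0, 1.0 / diff, 0.0)
    out = (kern @ f) * dw
    # analytic PV of the constant f(w_i) over [w_0 - dw/2, w_-1 + dw/2]
    lo = w[0] - 0.5 * dw
    hi = w[-1] + 0.5 * dw
    log_term = f * np.log((hi - w) / (w - lo))
    # subtract the discrete sum of the constant, add back its exact PV
    const_sum = (kern @ np.ones(npts)) * dw
    out = out - f * const_sum + log_term
    # the excluded singular cell contributes f'(w_i)*dw for the smooth part
    fp = np.gradient(f, dw)
    out = out + fp * dw
    return out / np.pi


def kk_real_from_imag(imag_spectrum, grid):
    """Real part of a causal response from its imaginary part (KK relation).

    Implements ``chi1(w) = (1/pi) P int chi2(w') / (w' - w) dw'`` with a
    discrete principal-value quadrature.  The imaginary part should decay
    toward the grid edges for the truncated integral to be accurate.
    """
    return _hilbert_pv(imag_spectrum, grid)


def kk_imag_from_real(real_spectrum, grid):
    """Imaginary part of a causal response from its real part.

    ``chi2(w) = -(1/pi) P int chi1(w') / (w' - w) dw'``.  A constant real
    offset is KK-invisible up to truncation effects.
    """
    return -_hilbert_pv(real_spectrum, grid)


# ---------------------------------------------------------------------------
# Absorbance
# ---------------------------------------------------------------------------

def beer_lambert_absorbance(rho, b, eps):
    """Beer-Lambert absorbance ``A = rho * b * eps`` (pointwise).

    rho is the molar concentration (M), b the path length (cm), eps the molar
    absorptivity spectrum (M^-1 cm^-1).
    """
    if rho < 0:
        raise ValueError("concentration must be nonnegative")
    if b < 0:
        raise ValueError("path length must be nonnegative")
    return rho * b * np.asarray(eps, dtype=float)


def molar_absorptivity_from_kappa(nu_cm, kappa, rho):
    """Molar absorptivity ``eps = 4 pi nu kappa / (2.303 rho)``.

    Links the extinction coefficient of the complex refractive index to the
    Beer-Lambert absorptivity; nu in cm^-1 so that eps carries M^-1 cm^-1.
    """
    if rho <= 0:
        raise ValueError("concentration must be positive")
    return 4.0 * np.pi * np.asarray(nu_cm, float) * np.asarray(kappa, float) / (2.303 * rho)


def absorbance_from_intensities(i_sample, i_background):
    """Instrument absorbance ``A = -log10(I / I0)`` per pixel.

    Pixels with nonpositive background are flagged NaN rather than raising:
    a dead background pixel invalidates only itself.
    """
    i_s = np.asarray(i_sample, dtype=float)
    i_0 = np.asarray(i_background, dtype=float)
    if i_s.shape != i_0.shape:
        raise ValueError("sample and background images must have the same shape")
    out = np.full(i_s.shape, np.nan)
    ok = (i_0 > 0) & (i_s > 0)
    out[ok] = -np.log10(i_s[ok] / i_0[ok])
    return out
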