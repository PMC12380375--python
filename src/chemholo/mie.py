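"""Scalar Mie forward model for a homogeneous sphere.

A plane wave ``e^{ikz}`` (unit amplitude, propagating along +z) strikes a
sphere of radius ``a`` and complex refractive index ``n = m + i*kappa``
centred at the origin.  Expanding in spherical waves, the scattered field
outside the sphere is

    ES(r, theta) = sum_t B_t h_t^(1)(k r) P_t(cos theta)

where ``P_t`` is the Legendre polynomial and ``h_t^(1)`` the spherical Hankel
function.  The coefficients follow from continuity of the scalar field and
its radial derivative across the sphere boundary (interior field
``A_t j_t(k n r)``)::

    B_t = (2t+1) i^t [n j_t'(kna) j_t(ka) - j_t(kna) j_t'(ka)]
                   / [j_t(kna) h_t'(ka) - n j_t'(kna) h_t(ka)]

In the radiation zone ``h_t(kr) -> e^{i(kr - (t+1) pi/2)}/(kr)``, so the far
field factorises into a radial envelope ``e^{ikr}/(ikr)`` and the angular
amplitude

    S(theta) = sum_t B_t e^{-i t pi/2} P_t(cos theta)

The angular coordinate maps to a transverse spatial frequency through
``sin(theta) = lambda * v``; sampling S on a radial frequency grid gives the
1-D reciprocal-domain representation whose order-0 inverse Hankel transform
is the (circularly symmetric) image-plane field.  An annular aperture with
numerical apertures (NA_in, NA_out) band-limits that representation between
``fl = NA_in/lambda`` and ``fu = NA_out/lambda``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Tuple

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import eval_legendre, spherical_jn, spherical_yn

from .hankel import HankelTransform
from .optics import ComplexField2D, RadialField1D, wavenumber

__all__ = [
    "Sphere",
    "MieSeries",
    "ApertureFilter",
    "mie_coefficients",
    "scattered_field_2d",
    "far_field_amplitude",
    "far_field_radial",
    "far_field_2d",
    "near_field_2d",
    "spatial_profile",
    "apply_bandpass_2d",
    "apply_bandpass_1d",
    "two_sphere_field",
]


@dataclass
class Sphere:
    """A homogeneous sphere: radius `a` (um), complex index, centre (x, y)."""

    a: float
    n: complex
    center: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.n = complex(self.n)
        if self.a <= 0:
            raise ValueError("radius must be positive")
        if self.n.real <= 0:
            raise ValueError("refractive index m must be positive")
        if self.n.imag < 0:
            raise ValueError("extinction coefficient kappa must be nonnegative")


@dataclass
class MieSeries:
    """Truncated scalar Mie coefficients for one sphere/wavelength pair."""

    coefficients: np.ndarray
    size_parameter: float
    truncation_order: int

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")


@dataclass
class ApertureFilter:
    """Annular collection aperture with centre obscuration.

    Passband in radial frequency: ``fl = NA_in/lambda <= v <= fu = NA_out/lambda``.
    """

    na_in: float
    na_out: float
    wavelength: float

    def __post_init__(self):
        if not (0.0 <= self.na_in < self.na_out):
            raise ValueError("need 0 <= NA_in < NA_out")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def fl(self) -> float:
        return self.na_in / self.wavelength

    @property
    def fu(self) -> float:
        return self.na_out / self.wavelength


def _sph_hankel(t, x, derivative=False):
    return spherical_jn(t, x, derivative=derivative) + 1j * spherical_yn(t, x, derivative=derivative)


def mie_coefficients(sphere: Sphere, wavelength: float) -> MieSeries:
    """Scalar Mie series coefficients B_t.

    Truncated at the Wiscombe-style cap ``N = ceil(ka + 4 (ka)^{1/3} + 2)``
    and then trimmed where the relative coefficient magnitude falls below
    1e-14.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    k = wavenumber(wavelength)
    ka = k * sphere.a
    kna = k * sphere.n * sphere.a
    n_cap = int(np.ceil(ka + 4.0 * ka ** (1.0 / 3.0) + 2.0))
    t = np.arange(n_cap + 1)

    j_ka = spherical_jn(t, ka)
    jp_ka = spherical_jn(t, ka, derivative=True)
    j_kna = spherical_jn(t, kna)
    jp_kna = spherical_jn(t, kna, derivative=True)
    h_ka = _sph_hankel(t, ka)
    hp_ka = _sph_hankel(t, ka, derivative=True)

    num = sphere.n * jp_kna * j_ka - j_kna * jp_ka
    den = j_kna * hp_ka - sphere.n * jp_kna * h_ka
    b = (2.0 * t + 1.0) * (1j ** t) * num / den

    mag = np.abs(b)
    peak = mag.max() if mag.max() > 0 else 1.0
    keep = np.nonzero(mag >= 1e-14 * peak)[0]
    order = int(keep[-1]) if keep.size else 0
    return MieSeries(coefficients=b[: order + 1], size_parameter=float(ka),
                     truncation_order=order)


def _series_eval(series: MieSeries, kr: np.ndarray, cos_theta: np.ndarray) -> np.ndarray:
    """Evaluate sum_t B_t h_t(kr) P_t(cos_theta) on flattened arrays."""
    out = np.zeros(kr.shape, complex)
    for t, bt in enumerate(series.coefficients):
        out += bt * _sph_hankel(t, kr) * eval_legendre(t, cos_theta)
    return out


def scattered_field_2d(sphere: Sphere, fov: float, resolution: int,
                       wavelength: float,
                       plane: Literal["vertical", "horizontal"] = "vertical",
                       z_plane: float = 0.0,
                       total: bool = False) -> ComplexField2D:
    """Scattered (or total) field of the Mie series on a 2-D plane.

    ``plane="vertical"`` evaluates the x-z plane through the sphere centre
    (rows = z, columns = x); ``plane="horizontal"`` the x-y plane at
    ``z_plane``.  Points inside the sphere are masked NaN (the interior field
    is out of scope).  `total` adds the incident plane wave ``e^{ikz}``.
    """
    series = mie_coefficients(sphere, wavelength)
    k = wavenumber(wavelength)
    step = fov / resolution
    ax = (np.arange(resolution) - resolution // 2) * step
    if plane == "vertical":
        x, z = np.meshgrid(ax, ax)
        y = np.zeros_like(x)
    elif plane == "horizontal":
        x, y = np.meshgrid(ax, ax)
        z = np.full_like(x, z_plane)
    else:
        raise ValueError("plane must be 'vertical' or 'horizontal'")
    x = x - sphere.center[0]
    y = y - sphere.center[1]
    r = np.sqrt(x**2 + y**2 + z**2)
    inside = r < sphere.a
    r_safe = np.where(r == 0, 1.0, r)
    cos_t = np.where(r == 0, 1.0, z / r_safe)
    es = _series_eval(series, k * np.where(inside, sphere.a, r_safe), cos_t)
    if total:
        es = es + np.exp(1j * k * z)
    es[inside] = np.nan
    return ComplexField2D(es, fov=fov, wavelength=wavelength)


def far_field_amplitude(series: MieSeries, cos_theta: np.ndarray) -> np.ndarray:
    """Angular far-field amplitude S(theta) = sum_t B_t e^{-i t pi/2} P_t."""
    cos_theta = np.asarray(cos_theta, dtype=float)
    out = np.zeros(cos_theta.shape, complex)
    for t, bt in enumerate(series.coefficients):
        out += bt * np.exp(-0.5j * np.pi * t) * eval_legendre(t, cos_theta)
    return out


def _far_field_on_frequencies(sphere: Sphere, wavelength: float, v: np.ndarray):
    """Far-field amplitude sampled on radial spatial frequencies.

    A propagating direction theta maps to the transverse frequency
    ``v = sin(theta)/lambda``; frequencies beyond the light cone ``1/lambda``
    are evanescent and carry no far-field amplitude.  The square-root kink at
    the light-cone edge is physical and limits how well discrete transforms
    of this spectrum can agree across sampling schemes.
    """
    series = mie_coefficients(sphere, wavelength)
    s = wavelength * np.asarray(v, dtype=float)
    prop = s <= 1.0
    out = np.zeros(np.shape(s), complex)
    cos_t = np.sqrt(np.clip(1.0 - s[prop] ** 2, 0.0, 1.0))
    out[prop] = far_field_amplitude(series, cos_t)
    return out


def far_field_radial(sphere: Sphere, wavelength: float, n_samples: int,
                     r_max: float) -> RadialField1D:
    """1-D reciprocal-domain far field on the DHT Bessel-zero grid.

    `r_max` is the spatial extent (um) of the conjugate image plane; the
    reciprocal grid follows from the DHT sampling theorem.  Frequencies above
    ``1/lambda`` are evanescent and carry no far-field amplitude.
    """
    if n_samples < 64:
        raise ValueError("need at least 64 radial samples")
    ht = HankelTransform(n_samples, r_max)
    samples = _far_field_on_frequencies(sphere, wavelength, ht.v)
    return RadialField1D(samples, ht.v.copy(), "reciprocal", wavelength)


def far_field_2d(sphere: Sphere, wavelength: float, fov: float,
                 resolution: int) -> Tuple[np.ndarray, np.ndarray]:
    """2-D far field sampled on the centred frequency grid of an image plane.

    Returns ``(F, freq_axis)`` where `F` is the (R, R) complex array on the
    grid with spacing ``1/fov`` (cycles/um) and `freq_axis` the centred axis.
    """
    freq = np.fft.fftshift(np.fft.fftfreq(resolution, d=fov / resolution))
    u, v = np.meshgrid(freq, freq)
    q = np.hypot(u, v)
    F = _far_field_on_frequencies(sphere, wavelength, q.ravel()).reshape(q.shape)
    return F, freq


def near_field_2d(sphere: Sphere, wavelength: float, fov: float,
                  resolution: int, aperture: Optional[ApertureFilter] = None,
                  total: bool = False) -> ComplexField2D:
    """Image-plane scattered field via the 2-D Fourier route.

    The far field is sampled on the image plane's frequency grid, optionally
    band-limited by `aperture`, and inverse-Fourier-transformed with physical
    scaling (frequency-bin area ``1/fov^2``).  `total` adds the incident
    plane wave (unit constant in the image plane).
    """
    F, freq = far_field_2d(sphere, wavelength, fov, resolution)
    if aperture is not None:
        u, v = np.meshgrid(freq, freq)
        q = np.hypot(u, v)
        mask = (q >= aperture.fl) & (q <= aperture.fu)
        if not mask.any():
            raise ValueError("empty passband: no grid frequency inside the annulus")
        F = F * mask
    # continuous inverse FT approximated by the DFT: sum F e^{2 pi i q.x} du dv
    # with du = dv = 1/fov; ifft2 carries 1/R^2, hence the R^2/fov^2 factor
    g = np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(F))) * resolution**2 / fov**2
    if total:
        g = g + 1.0
    return ComplexField2D(g, fov=fov, wavelength=wavelength)


def spatial_profile(sphere: Sphere, wavelength: float, n_samples: int,
                    r_max: float, aperture: Optional[ApertureFilter] = None,
                    total: bool = True) -> RadialField1D:
    """1-D image-plane radial profile: far field -> (aperture) -> inverse DHT.

    This is the standard 1-D representation used by the inverse-Mie training
    corpora: the spatial-domain total field (incident constant retained by
    default) on the near-uniform Bessel-zero radial grid of extent `r_max`.
    """
    far = far_field_radial(sphere, wavelength, n_samples, r_max)
    if aperture is not None:
        far = apply_bandpass_1d(far, aperture, clamp=True)
    ht = HankelTransform(n_samples, r_max)
    near = ht.inverse(far)
    if total:
        near = RadialField1D(near.samples + 1.0, near.radii, "spatial", wavelength)
    return near


def apply_bandpass_2d(field: ComplexField2D, filt: ApertureFilter) -> ComplexField2D:
    """Annular band-limit of a spatial 2-D field (FFT -> mask -> inverse FFT)."""
    r = field.resolution
    freq = np.fft.fftfreq(r, d=field.fov / r)
    u, v = np.meshgrid(freq, freq)
    q = np.hypot(u, v)
    mask = (q >= filt.fl) & (q <= filt.fu)
    if not mask.any():
        raise ValueError("empty passband: no grid frequency inside the annulus")
    spec = np.fft.fft2(field.samples) * mask
    return ComplexField2D(np.fft.ifft2(spec), fov=field.fov,
                          wavelength=field.wavelength)


def apply_bandpass_1d(field: RadialField1D, filt: ApertureFilter,
                      clamp: bool = False) -> RadialField1D:
    """Radial band-limit of a reciprocal-domain field.

    With ``clamp=True`` an empty passband is widened to retain the first
    grid frequency instead of raising (used by the NA sweep at its smallest
    apertures).
    """
    if field.domain != "reciprocal":
        raise ValueError("bandpass_1d expects a reciprocal-domain field")
    mask = (field.radii >= filt.fl) & (field.radii <= filt.fu)
    if not mask.any():
        if not clamp:
            raise ValueError("empty passband: no radial frequency inside the annulus")
        mask[0] = True
    return RadialField1D(field.samples * mask, field.radii.copy(),
                         "reciprocal", field.wavelength)


def two_sphere_field(sphere: Sphere, separation: float, wavelength: float,
                     fov: float, resolution: int, n_radial: int = 320):
    """Superposed field of two identical-property spheres in one FOV.

    The central sphere sits at the origin; the perturbing sphere is displaced
    by `separation` along -x.  Single-scattering superposition: each sphere
    contributes its own image-plane radial profile centred on its position,
    plus one incident plane wave.  Returns ``(field2d, half_line)`` where
    `half_line` is the right-half 1-D extraction through the central sphere
    (x in [0, fov/2], `n_radial` samples).
    """
    if separation < 2.0 * sphere.a:
        raise ValueError("spheres overlap: separation must be >= 2a")
    # radial profile dense enough to interpolate anywhere in the FOV
    extent = np.hypot(fov, fov) / 2.0 + separation + fov / 8.0
    n_prof = max(1024, int(40 * extent / wavelength))
    prof = spatial_profile(sphere, wavelength, n_prof, extent, total=False)
    spline_re = CubicSpline(prof.radii, prof.samples.real)
    spline_im = CubicSpline(prof.radii, prof.samples.imag)

    def ns(rr):
        rr = np.clip(rr, prof.radii[0], prof.radii[-1])
        return spline_re(rr) + 1j * spline_im(rr)

    step = fov / resolution
    ax = (np.arange(resolution) - resolution // 2) * step
    x, y = np.meshgrid(ax, ax)
    g2 = 1.0 + ns(np.hypot(x, y)) + ns(np.hypot(x + separation, y))
    field2d = ComplexField2D(g2, fov=fov, wavelength=wavelength)

    xs = np.linspace(0.0, fov / 2.0, n_radial + 1)[1:]
    half = 1.0 + ns(xs) + ns(xs + separation)
    half_line = RadialField1D(half, xs, "spatial", wavelength)
    return field2d, half_line
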