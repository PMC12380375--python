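"""Order-0 quasi-discrete Hankel transform on a Bessel-zero grid.

For circularly symmetric fields the 2-D Fourier transform reduces to the
order-0 Hankel transform (ordinary-frequency convention)::

    F(v) = 2*pi * int_0^inf f(r) J0(2*pi*v*r) r dr

The discrete scheme samples both domains at scaled zeros of J0: with
``j_1..j_{N+1}`` the first N+1 zeros, a spatial extent R and reciprocal extent
``V = j_{N+1} / (2*pi*R)``, the sample grids are ``r_n = j_n R / j_{N+1}`` and
``v_m = j_m / (2*pi*R)``.  The transform matrix follows from the
Fourier-Bessel quadrature for band-limited functions and is its own inverse
up to conditioning, which makes round trips nearly exact.
"""

from __future__ import annotations

import numpy as np
from scipy.special import j1, jn_zeros, j0

from .optics import RadialField1D

__all__ = ["HankelTransform", "inverse_hankel", "forward_hankel"]


class HankelTransform:
    """Order-0 quasi-DHT between a spatial extent R and its conjugate band V.

    Parameters
    ----------
    n_samples : int
        Number of radial samples N (>= 2).
    r_max : float
        Spatial extent R in um.  The reciprocal extent follows from the
        sampling theorem of the scheme: ``V = j_{N+1} / (2 pi R)`` in um^-1.
    """

    def __init__(self, n_samples: int, r_max: float):
        if n_samples < 2:
            raise ValueError("need at least 2 radial samples")
        if r_max <= 0:
            raise ValueError("r_max must be positive")
        zeros = jn_zeros(0, n_samples + 1)
        self.j = zeros[:n_samples]
        self.j_cap = zeros[n_samples]
        self.r_max = float(r_max)
        self.v_max = self.j_cap / (2.0 * np.pi * self.r_max)
        self.r = self.j * self.r_max / self.j_cap
        self.v = self.j / (2.0 * np.pi * self.r_max)
        cross = np.outer(self.j, self.j) / self.j_cap
        j1sq = j1(self.j) ** 2
        core = j0(cross) / j1sq[None, :]
        self._fwd = (4.0 * np.pi * self.r_max**2 / self.j_cap**2) * core
        self._inv = (4.0 * np.pi * self.v_max**2 / self.j_cap**2) * core

    @property
    def n_samples(self) -> int:
        return self.j.size

    # -- raw-array interface -------------------------------------------------
    def forward_samples(self, f: np.ndarray) -> np.ndarray:
        """Spatial samples at r_n -> reciprocal samples at v_m."""
        return self._fwd @ np.asarray(f)

    def inverse_samples(self, F: np.ndarray) -> np.ndarray:
        """Reciprocal samples at v_m -> spatial samples at r_n."""
        return self._inv @ np.asarray(F)

    # -- field interface -----------------------------------------------------
    def forward(self, field: RadialField1D) -> RadialField1D:
        if field.domain != "spatial":
            raise ValueError("forward transform expects a spatial-domain field")
        self._check_grid(field.radii, self.r)
        return RadialField1D(self.forward_samples(field.samples), self.v.copy(),
                             "reciprocal", field.wavelength)

    def inverse(self, field: RadialField1D) -> RadialField1D:
        if field.domain != "reciprocal":
            raise ValueError("inverse transform expects a reciprocal-domain field")
        self._check_grid(field.radii, self.v)
        return RadialField1D(self.inverse_samples(field.samples), self.r.copy(),
                             "spatial", field.wavelength)

    @staticmethod
    def _check_grid(given, expected):
        if given.shape != expected.shape or not np.allclose(given, expected,
                                                            rtol=1e-9, atol=0.0):
            raise ValueError("field grid does not match the transform's grid")

    @classmethod
    def from_reciprocal_grid(cls, radii: np.ndarray) -> "HankelTransform":
        """Reconstruct the transform whose reciprocal grid matches `radii`."""
        radii = np.asarray(radii, float)
        n = radii.size
        zeros = jn_zeros(0, n + 1)
        # v_m = j_m / (2 pi R)  ->  R = j_1 / (2 pi v_1)
        r_max = zeros[0] / (2.0 * np.pi * radii[0])
        ht = cls(n, r_max)
        cls._check_grid(radii, ht.v)
        return ht


def inverse_hankel(field: RadialField1D) -> RadialField1D:
    """Order-0 inverse DHT of a reciprocal-domain radial field.

    The spatial extent is fixed by the scheme's sampling theorem; the field's
    grid must be the Bessel-zero reciprocal grid produced by the forward
    model (e.g. :func:`chemholo.mie.far_field_radial`).
    """
    if field.domain != "reciprocal":
        raise ValueError("inverse_hankel expects a reciprocal-domain field")
    ht = HankelTransform.from_reciprocal_grid(field.radii)
    return ht.inverse(field)


def forward_hankel(field: RadialField1D) -> RadialField1D:
    """Order-0 forward DHT of a spatial-domain radial field."""
    if field.domain != "spatial":
        raise ValueError("forward_hankel expects a spatial-domain field")
    radii = field.radii
    n = radii.size
    zeros = jn_zeros(0, n + 1)
    r_max = radii[-1] * zeros[n] / zeros[n - 1]
    ht = HankelTransform(n, r_max)
    HankelTransform._check_grid(radii, ht.r)
    return ht.forward(field)
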