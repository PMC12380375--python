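"""Coupled-wave forward solver for plane-wave propagation through layer stacks.

A stack of L homogeneous layers (complex refractive index ``n_l``) is bounded
by L-1 internal interfaces at strictly increasing z-coordinates ``z_1..z_{L-1}``;
the first and last layers are unbounded.  The incident plane wave is specified
at ``z0`` inside layer 0 and propagates toward +z.  Inside layer l the field is
the sum of a +z-propagating amplitude ``P_up(l)`` anchored at the layer's lower
boundary and a -z-propagating amplitude ``P_down(l)`` anchored at its upper
boundary::

    E(l)(r) = [ P_up(l) e^{ i k s_z(l) (z - z_l)   }
              + P_down(l) e^{-i k s_z(l) (z - z_{l+1})} ] e^{i k (s_x x + s_y y)}

with the index-scaled direction components satisfying the dispersion relation
``s_x^2 + s_y^2 + s_z(l)^2 = n_l^2`` in every layer, ``Im(s_z) >= 0`` (decaying
branch).  Anchoring each amplitude at its entry boundary keeps all propagation
factors in the continuity equations decaying, so the linear system is well
conditioned even for absorbing layers.

Continuity of tangential E and H at each interface yields 2(L-1) equations per
polarization (s: E in the plane of the interface; p: H transverse).  The
amplitudes of the solution are stored as full 3-vectors built from polarization
unit vectors orthogonal to the propagation vector, so Gauss's law
``s . P = 0`` holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np

from .optics import PlaneWave, wavenumber

__all__ = [
    "LayerStack",
    "DirectionSpectrum",
    "LayerSolution",
    "SingularStackError",
    "solve_layered",
    "field_at",
    "reflectance_transmittance",
]


class SingularStackError(RuntimeError):
    """Raised when the boundary-condition system is singular."""


@dataclass
class LayerStack:
    """Layer geometry: per-layer complex indices and internal boundaries.

    ``n_layers`` has length L; ``boundaries`` the L-1 strictly increasing
    interface z-coordinates (um).  ``z0`` is the coordinate inside layer 0
    where the incident field is specified (must not exceed the first
    boundary).
    """

    n_layers: Sequence[complex]
    boundaries: Sequence[float]
    z0: float = 0.0

    def __post_init__(self):
        self.n_layers = np.asarray(self.n_layers, dtype=complex)
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        if self.n_layers.size < 2:
            raise ValueError("a stack needs at least 2 layers")
        if self.boundaries.size != self.n_layers.size - 1:
            raise ValueError("L layers require L-1 boundaries")
        if np.any(np.diff(self.boundaries) <= 0):
            raise ValueError("boundaries must be strictly increasing")
        if self.z0 > self.boundaries[0]:
            raise ValueError("z0 must lie inside the first layer")
        if np.any(self.n_layers.imag < 0):
            raise ValueError("extinction coefficients must be nonnegative")

    @property
    def n_layer_count(self) -> int:
        return int(self.n_layers.size)


@dataclass
class DirectionSpectrum:
    """Index-scaled propagation components, one longitudinal value per layer.

    ``sx``, ``sy`` are conserved across the stack (Snell); ``sz_per_layer``
    follows the dispersion relation with the decaying branch Im(sz) >= 0.
    """

    sx: float
    sy: float
    sz_per_layer: np.ndarray

    def __post_init__(self):
        self.sz_per_layer = np.asarray(self.sz_per_layer, dtype=complex)


def _sz_branch(n_layers: np.ndarray, sx: float, sy: float) -> np.ndarray:
    sz = np.sqrt(n_layers**2 - sx**2 - sy**2 + 0j)
    # decaying branch: Im >= 0; ties break toward Re >= 0
    flip = (sz.imag < 0) | ((sz.imag == 0) & (sz.real < 0))
    sz = np.where(flip, -sz, sz)
    return sz


def direction_spectrum(stack: LayerStack, incident: PlaneWave) -> DirectionSpectrum:
    """Transverse invariants and per-layer longitudinal components."""
    n0 = stack.n_layers[0]
    s_vec = n0 * incident.direction
    if abs(s_vec[0].imag) > 1e-12 or abs(s_vec[1].imag) > 1e-12:
        raise ValueError("transverse direction components must be real "
                         "(incidence layer must be lossless for oblique incidence)")
    sx, sy = float(s_vec[0].real), float(s_vec[1].real)
    sz = _sz_branch(stack.n_layers, sx, sy)
    if abs(sz[0]) <= 1e-12:
        raise ValueError("grazing incidence: |sz(0)| vanishes")
    return DirectionSpectrum(sx=sx, sy=sy, sz_per_layer=sz)


@dataclass
class LayerSolution:
    """Per-layer counter-propagating 3-vector amplitudes of a solved stack."""

    stack: LayerStack
    directions: DirectionSpectrum
    p_up: np.ndarray      # (L, 3) complex, +z-propagating, anchored at z_l
    p_down: np.ndarray    # (L, 3) complex, -z-propagating, anchored at z_{l+1}
    amp_up: np.ndarray    # (L,) scalar amplitudes along the polarization vectors
    amp_down: np.ndarray
    wavelength: float
    polarization: str

    def gauss_residuals(self) -> np.ndarray:
        """|s . P| for every stored amplitude (should vanish)."""
        sx, sy = self.directions.sx, self.directions.sy
        sz = self.directions.sz_per_layer
        res = []
        for l in range(self.stack.n_layer_count):
            s_up = np.array([sx, sy, sz[l]])
            s_dn = np.array([sx, sy, -sz[l]])
            res.append(abs(s_up @ self.p_up[l]))
            res.append(abs(s_dn @ self.p_down[l]))
        return np.asarray(res)


def _pol_vectors(pol: str, sx: float, sy: float, sz: complex, n: complex):
    """Unit polarization 3-vectors (up, down) orthogonal to the wavevector.

    The transverse wavevector is rotated onto the x-axis internally; callers
    pass the already-rotated sx (sy = 0 in the rotated frame).
    """
    if pol == "s":
        e = np.array([0.0, 1.0, 0.0], complex)
        return e, e.copy()
    # p-polarization: e = y_hat x s_hat
    e_up = np.array([sz, 0.0, -sx], complex) / n
    e_dn = np.array([-sz, 0.0, -sx], complex) / n
    return e_up, e_dn


def _solve_scalar(stack: LayerStack, sx_r: float, sz: np.ndarray, k: float,
                  pol: str, a0: complex):
    """Solve the per-polarization scalar continuity system.

    Unknowns: up-going amplitudes in layers 1..L-1 and down-going amplitudes
    in layers 0..L-2 (the incident up-going amplitude in layer 0 is given and
    the last layer carries no down-going wave).  Returns (amp_up, amp_down).
    """
    L = stack.n_layer_count
    nl = stack.n_layers
    z = stack.boundaries
    nun = 2 * (L - 1)

    def up_index(l):    # l in 1..L-1
        return l - 1

    def dn_index(l):    # l in 0..L-2
        return (L - 1) + l

    # propagation factor of the up wave of layer l from its anchor to z_b,
    # and of the down wave of layer l from its anchor to z_b
    def phase_up(l, zb):
        anchor = stack.z0 if l == 0 else z[l - 1]
        return np.exp(1j * k * sz[l] * (zb - anchor))

    def phase_dn(l, zb):
        anchor = z[l]  # upper boundary of layer l (valid for l <= L-2)
        return np.exp(-1j * k * sz[l] * (zb - anchor))

    # tangential-field weights per polarization:
    #   s-pol: E_y weight 1,                 H_x weight -/+ sz
    #   p-pol: E_x weight +/- sz/n,          H_y weight n
    def weights(l, updown):
        sgn = 1.0 if updown == "up" else -1.0
        if pol == "s":
            return 1.0, sgn * sz[l]
        return sgn * sz[l] / nl[l], nl[l]

    A = np.zeros((nun, nun), complex)
    rhs = np.zeros(nun, complex)
    row = 0
    for b in range(L - 1):        # interface between layer b and b+1 at z[b]
        lo, hi = b, b + 1
        zb = z[b]
        for comp in range(2):     # 0: tangential E, 1: tangential H
            # lower layer contributions
            we_u, wh_u = weights(lo, "up")
            we_d, wh_d = weights(lo, "dn")
            w_u = we_u if comp == 0 else wh_u
            w_d = we_d if comp == 0 else wh_d
            if lo == 0:
                rhs[row] -= a0 * w_u * phase_up(lo, zb)
            else:
                A[row, up_index(lo)] += w_u * phase_up(lo, zb)
            A[row, dn_index(lo)] += w_d * phase_dn(lo, zb)
            # upper layer contributions (moved to the other side)
            we_u, wh_u = weights(hi, "up")
            we_d, wh_d = weights(hi, "dn")
            w_u = we_u if comp == 0 else wh_u
            w_d = we_d if comp == 0 else wh_d
            A[row, up_index(hi)] -= w_u * phase_up(hi, zb)
            if hi <= L - 2:
                A[row, dn_index(hi)] -= w_d * phase_dn(hi, zb)
            row += 1

    try:
        cond_est = np.linalg.cond(A)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond_est = np.inf
    if not np.isfinite(cond_est) or cond_est > 1e13:
        # locate the worst-scaled boundary for the error message
        norms = np.linalg.norm(A, axis=1).reshape(L - 1, 2).sum(axis=1)
        bad = int(np.argmin(norms))
        raise SingularStackError(
            f"boundary-condition system is singular or near-singular "
            f"(cond ~ {cond_est:.2e}); offending boundary index {bad} "
            f"at z = {z[bad]:g} um")
    x = np.linalg.solve(A, rhs)

    amp_up = np.zeros(L, complex)
    amp_dn = np.zeros(L, complex)
    amp_up[0] = a0
    amp_up[1:] = x[: L - 1]
    amp_dn[: L - 1] = x[L - 1:]
    return amp_up, amp_dn


def solve_layered(stack: LayerStack, incident: PlaneWave,
                  polarization: Optional[Literal["s", "p"]] = None) -> LayerSolution:
    """Solve the boundary-value problem for a plane wave through a stack.

    The incident wave travels toward +z; its amplitude is specified at
    ``stack.z0`` inside layer 0.  At normal incidence the default
    polarization is x ("p" machinery with zero transverse wavevector).
    Returns a :class:`LayerSolution` whose boundary residuals vanish to
    machine precision (checked).
    """
    dirs = direction_spectrum(stack, incident)
    sx, sy = dirs.sx, dirs.sy
    sz = dirs.sz_per_layer
    k = wavenumber(incident.wavelength)

    if polarization is None:
        polarization = "p"  # x-polarized at normal incidence
    if polarization not in ("s", "p"):
        raise ValueError("polarization must be 's' or 'p'")

    # rotate the transverse wavevector onto the x-axis
    st = float(np.hypot(sx, sy))
    if st > 0:
        c, s = sx / st, sy / st
    else:
        c, s = 1.0, 0.0
    rot = np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])

    amp_up, amp_dn = _solve_scalar(stack, st, sz, k, polarization,
                                   incident.amplitude)

    L = stack.n_layer_count
    p_up = np.zeros((L, 3), complex)
    p_dn = np.zeros((L, 3), complex)
    for l in range(L):
        e_up, e_dn = _pol_vectors(polarization, st, 0.0, sz[l], stack.n_layers[l])
        p_up[l] = rot.T @ (amp_up[l] * e_up)
        p_dn[l] = rot.T @ (amp_dn[l] * e_dn)

    sol = LayerSolution(stack=stack, directions=dirs, p_up=p_up, p_down=p_dn,
                        amp_up=amp_up, amp_down=amp_dn,
                        wavelength=incident.wavelength,
                        polarization=polarization)
    _check_residuals(sol, incident)
    return sol


def _tangential(v: np.ndarray) -> np.ndarray:
    return v[:2]


def _check_residuals(sol: LayerSolution, incident: PlaneWave, tol: float = 1e-8):
    """Verify tangential-E continuity at every boundary."""
    z = sol.stack.boundaries
    scale = abs(incident.amplitude) or 1.0
    for b, zb in enumerate(z):
        e_lo = field_at(sol, 0.0, 0.0, zb, layer=b)
        e_hi = field_at(sol, 0.0, 0.0, zb, layer=b + 1)
        if np.max(np.abs(_tangential(e_lo) - _tangential(e_hi))) > tol * scale:
            raise SingularStackError(
                f"tangential-field continuity violated at boundary {b} "
                f"(z = {zb:g} um)")


def field_at(sol: LayerSolution, x: float, y: float, z, layer: Optional[int] = None):
    """Complex E 3-vector(s) of a solved stack at physical coordinates.

    `z` may be a scalar or an array; the layer is located from the boundary
    list unless `layer` pins the evaluation to one side of an interface.
    Returns shape (3,) for scalar z, else (len(z), 3).
    """
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    stack, dirs = sol.stack, sol.directions
    k = wavenumber(sol.wavelength)
    bounds = stack.boundaries
    out = np.zeros(z_arr.shape + (3,), complex)
    if layer is None:
        layer_of = np.searchsorted(bounds, z_arr, side="right")
    else:
        layer_of = np.full(z_arr.shape, layer, dtype=int)
    trans = np.exp(1j * k * (dirs.sx * x + dirs.sy * y))
    for l in np.unique(layer_of):
        sel = layer_of == l
        szl = dirs.sz_per_layer[l]
        anchor_up = stack.z0 if l == 0 else bounds[l - 1]
        up = sol.p_up[l][None, :] * np.exp(1j * k * szl * (z_arr[sel] - anchor_up))[:, None]
        if l <= stack.n_layer_count - 2:
            dn = sol.p_down[l][None, :] * np.exp(-1j * k * szl * (z_arr[sel] - bounds[l]))[:, None]
        else:
            dn = 0.0
        out[sel] = (up + dn) * trans
    if np.isscalar(z) or np.asarray(z).ndim == 0:
        return out[0]
    return out


def reflectance_transmittance(sol: LayerSolution):
    """Power reflectance and transmittance from the outer-layer amplitudes.

    Requires lossless outer layers (power bookkeeping is undefined when the
    unbounded media absorb).  The longitudinal power flux per unit |E|^2 is
    proportional to Re(sz), identical for both polarizations in lossless
    media, so R = |r|^2 and T = Re(sz_last)/Re(sz_0) * |t|^2.
    """
    n_first = sol.stack.n_layers[0]
    n_last = sol.stack.n_layers[-1]
    if abs(n_first.imag) > 0 or abs(n_last.imag) > 0:
        raise ValueError("outer layers must be lossless for R/T bookkeeping")
    sz0 = sol.directions.sz_per_layer[0]
    szL = sol.directions.sz_per_layer[-1]
    a0 = sol.amp_up[0]
    r = sol.amp_down[0] / a0
    t = sol.amp_up[-1] / a0
    R = abs(r) ** 2
    T = (szL.real / sz0.real) * abs(t) ** 2
    return float(R), float(T)
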