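"""Phase-stepped interferogram synthesis and complex-field reconstruction.

A nanopositioner steps the reference-arm optical path difference through
``Delta_1 .. Delta_M`` (uniform step delta).  With a collimated reference of
complex amplitude ER and an object field ES, the detector records per pixel

    I_m = |ES|^2 + |ER|^2 + ES ER* e^{-ik Delta_m} + ES* ER e^{+ik Delta_m}

Differencing consecutive frames cancels the DC terms and leaves a linear
system in the two conjugate cross-terms ``u = (e^{-ik delta}-1) ES ER*`` and
``u~ = (e^{+ik delta}-1) ES* ER``::

    I_{m+1} - I_m = e^{-ik Delta_m} u + e^{+ik Delta_m} u~

solved per pixel by the Moore-Penrose pseudo-inverse; ES then follows from
``ES = u / (ER* (e^{-ik delta} - 1))``.  Three frames (two differences)
suffice; with two frames the per-pixel system is underdetermined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .optics import ComplexField2D, wavenumber

__all__ = [
    "Interferogram",
    "ReconstructedField",
    "UnderdeterminedError",
    "SingularStepError",
    "uniform_deltas",
    "simulate_interferogram",
    "difference_images",
    "HologramReconstruction",
    "reconstruct_field",
    "load_experimental_stack",
    "save_stack",
]


class UnderdeterminedError(ValueError):
    """Fewer frames than the two cross-term unknowns require."""


class SingularStepError(ValueError):
    """The phase step makes the difference system rank-deficient."""


@dataclass
class Interferogram:
    """M phase-stepped intensity frames with their reference-arm offsets."""

    frames: np.ndarray          # (M, ny, nx) float
    deltas: np.ndarray          # (M,) reference offsets in um
    wavelength: float

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.deltas = np.asarray(self.deltas, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (M, ny, nx) stack")
        if self.frames.shape[0] != self.deltas.size:
            raise ValueError("one offset per frame required")
        if self.frames.shape[0] < 3:
            raise ValueError("an interferogram needs at least 3 frames")
        steps = np.diff(self.deltas)
        if not np.allclose(steps, steps[0], rtol=0.0, atol=1e-12):
            raise ValueError("offsets must be uniformly spaced")
        if np.any(self.frames < -1e-12):
            raise ValueError("intensities must be nonnegative")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def step(self) -> float:
        """Uniform step delta = Delta_{m+1} - Delta_m (um)."""
        return float(self.deltas[1] - self.deltas[0])

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


def uniform_deltas(n_frames: int, total_opd: float, start: float = 0.0,
                   convention: str = "total/M") -> np.ndarray:
    """Uniform reference-arm offsets starting at zero path difference.

    The default step convention is ``delta = total_opd / M`` (e.g. 32 frames
    over 2 um give delta = 0.0625 um); ``total/(M-1)`` spans the full range
    inclusively instead.
    """
    if convention == "total/M":
        step = total_opd / n_frames
    elif convention == "total/(M-1)":
        step = total_opd / (n_frames - 1)
    else:
        raise ValueError("convention must be 'total/M' or 'total/(M-1)'")
    return start + step * np.arange(n_frames)


def simulate_interferogram(e_obj: Union[ComplexField2D, np.ndarray],
                           e_ref: complex, deltas: np.ndarray,
                           wavelength: Optional[float] = None,
                           rng: Optional[np.random.Generator] = None,
                           noise_sigma: float = 0.0) -> Interferogram:
    """Synthesise the phase-stepped intensity stack of an object field.

    Each frame is ``|ES + ER e^{ik Delta_m}|^2`` per pixel (identically the
    four-term expansion above), optionally with additive Gaussian intensity
    noise of standard deviation `noise_sigma`.
    """
    if isinstance(e_obj, ComplexField2D):
        es = e_obj.samples
        wavelength = e_obj.wavelength if wavelength is None else wavelength
    else:
        es = np.asarray(e_obj, dtype=complex)
        if wavelength is None:
            raise ValueError("wavelength required for a bare array")
    deltas = np.asarray(deltas, dtype=float)
    steps = np.diff(deltas)
    if deltas.size < 2 or not np.allclose(steps, steps[0], rtol=0.0, atol=1e-12):
        raise ValueError("offsets must be uniformly spaced")
    k = wavenumber(wavelength)
    phase = np.exp(1j * k * deltas)
    frames = np.abs(es[None, ...] + e_ref * phase[:, None, None]) ** 2
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng()
        frames = frames + rng.normal(0.0, noise_sigma, frames.shape)
        frames = np.clip(frames, 0.0, None)
    return Interferogram(frames=frames, deltas=deltas, wavelength=wavelength)


def difference_images(ig: Interferogram) -> np.ndarray:
    """Consecutive frame differences ``D_m = I_{m+1} - I_m`` (M-1 images).

    The DC terms |ES|^2 + |ER|^2 cancel exactly.
    """
    return np.diff(ig.frames, axis=0)


@dataclass
class ReconstructedField:
    """Results of a phase-stepped reconstruction.

    `es` is the recovered complex sample field, `er` the reference amplitude
    used, `residual` the per-pixel least-squares residual of the difference
    system and `conjugate_mismatch` the per-pixel disagreement between the
    two conjugate channels (both should vanish for noiseless data).
    """

    es: np.ndarray
    er: complex
    residual: np.ndarray
    conjugate_mismatch: np.ndarray
    n_frames_used: int
    wavelength: float
    step: float

    @property
    def mean_residual(self) -> float:
        return float(np.mean(self.residual))

    def summary(self) -> str:
        lines = [
            "Phase-stepped hologram reconstruction",
            "=====================================",
            f"frames used            : {self.n_frames_used}",
            f"wavelength (um)        : {self.wavelength:g}",
            f"step delta (um)        : {self.step:g}",
            f"image shape            : {self.es.shape}",
            f"mean |ES|              : {np.mean(np.abs(self.es)):.6g}",
            f"mean LS residual       : {self.mean_residual:.3e}",
            f"mean conjugate mismatch: {np.mean(self.conjugate_mismatch):.3e}",
        ]
        return "\n".join(lines)


class HologramReconstruction:
    """Model object: reconstruct a complex field from an interferogram.

    Parameters
    ----------
    interferogram : Interferogram
        The phase-stepped intensity stack.
    reference : complex or array
        Reference-arm amplitude ER (scalar for a collimated reference, or a
        per-pixel image).
    """

    def __init__(self, interferogram: Interferogram,
                 reference: Union[complex, np.ndarray]):
        self.ig = interferogram
        self.reference = reference
        ref = np.asarray(reference)
        if np.any(np.abs(ref) == 0):
            raise ValueError("reference amplitude must be nonzero")

    def fit(self, n_frames: Optional[int] = None,
            first_frame: int = 0) -> ReconstructedField:
        """Solve the difference system on a window of consecutive frames.

        `n_frames` defaults to all frames; at least 3 are required.  Raises
        :class:`SingularStepError` when ``k*delta`` is a multiple of pi (the
        two cross-term columns degenerate).
        """
        ig = self.ig
        m_total = ig.n_frames
        if n_frames is None:
            n_frames = m_total - first_frame
        if n_frames < 3:
            raise UnderdeterminedError(
                "at least 3 frames (2 difference rows) are needed for the "
                "two cross-term unknowns")
        if first_frame < 0 or first_frame + n_frames > m_total:
            raise ValueError("frame window out of range")
        k = wavenumber(ig.wavelength)
        delta = ig.step
        frames = ig.frames[first_frame:first_frame + n_frames]
        deltas = ig.deltas[first_frame:first_frame + n_frames]

        d = np.diff(frames, axis=0).reshape(n_frames - 1, -1)
        p = np.stack([np.exp(-1j * k * deltas[:-1]),
                      np.exp(+1j * k * deltas[:-1])], axis=1)
        if np.linalg.matrix_rank(p, tol=1e-10 * np.sqrt(n_frames)) < 2:
            raise SingularStepError(
                f"phase step delta = {delta:g} um makes e^{{+-ik Delta}} "
                "columns degenerate (k*delta multiple of pi)")
        u, res, *_ = np.linalg.lstsq(p, d.astype(complex), rcond=None)
        fitted = p @ u
        residual = np.linalg.norm(d - fitted, axis=0)

        er = self.reference
        er_arr = np.asarray(er)
        shape = frames.shape[1:]
        er_pix = (np.broadcast_to(er_arr, shape) if er_arr.ndim else
                  np.full(shape, complex(er)))
        fac_minus = np.exp(-1j * k * delta) - 1.0
        fac_plus = np.exp(+1j * k * delta) - 1.0
        es1 = u[0].reshape(shape) / (np.conj(er_pix) * fac_minus)
        es2 = np.conj(u[1].reshape(shape) / (er_pix * fac_plus))
        es = es1
        mismatch = np.abs(es1 - es2)
        return ReconstructedField(
            es=es, er=complex(er) if er_arr.ndim == 0 else er_arr,  # type: ignore[arg-type]
            residual=residual.reshape(shape),
            conjugate_mismatch=mismatch, n_frames_used=n_frames,
            wavelength=ig.wavelength, step=delta)

    def fit_sinusoid(self) -> ReconstructedField:
        """Cross-check path: per-pixel sinusoid fit at the known wavelength.

        Fits ``I(Delta) = a0 + c cos(k Delta) + s sin(k Delta)`` by linear
        least squares over all frames and converts the fringe amplitude and
        phase to ES.  The pseudo-inverse difference solve is canonical; this
        exists to validate it.
        """
        ig = self.ig
        k = wavenumber(ig.wavelength)
        m = ig.n_frames
        basis = np.stack([np.ones(m), np.cos(k * ig.deltas),
                          np.sin(k * ig.deltas)], axis=1)
        y = ig.frames.reshape(m, -1)
        coef, *_ = np.linalg.lstsq(basis, y, rcond=None)
        shape = ig.frames.shape[1:]
        # I = ... + 2 Re(ES ER* e^{-ik Delta}) => c = 2 Re(ES ER*), s = 2 Im(ES ER*)
        cross = 0.5 * (coef[1] + 1j * coef[2]).reshape(shape)
        er = complex(np.asarray(self.reference).reshape(-1)[0])
        es = cross / np.conj(er)
        zeros = np.zeros(shape)
        return ReconstructedField(es=es, er=er, residual=zeros,
                                  conjugate_mismatch=zeros,
                                  n_frames_used=m, wavelength=ig.wavelength,
                                  step=ig.step)


def reconstruct_field(ig: Interferogram, reference: Union[complex, np.ndarray],
                      n_frames: Optional[int] = None) -> ReconstructedField:
    """Functional wrapper around :class:`HologramReconstruction`."""
    return HologramReconstruction(ig, reference).fit(n_frames=n_frames)


def load_experimental_stack(path, step: float, wavelength: float,
                            start: float = 0.0) -> Interferogram:
    """Read a multi-page TIFF intensity stack into an :class:`Interferogram`.

    Step metadata is supplied by the caller (um); frames are cast to float.
    A 200-frame acquisition with a 0.040 um step at lambda = 8 um loads
    directly; reconstruction then typically uses the first 3 frames.
    """
    import tifffile

    frames = tifffile.imread(str(path))
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None, ...]
    if frames.ndim != 3:
        raise ValueError("expected a multi-page 2-D image stack")
    deltas = start + step * np.arange(frames.shape[0])
    return Interferogram(frames=frames, deltas=deltas, wavelength=wavelength)


def save_stack(path, ig: Interferogram) -> None:
    """Write an interferogram as a float32 multi-page TIFF."""
    import tifffile

    tifffile.imwrite(str(path), ig.frames.astype(np.float32))
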