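"""Grid-search inversion of a 3-layer stack from a phase-sensitive measurement.

A target layer with unknown (m, d, kappa) is embedded in air.  A single
intensity measurement cannot separate m from d: any pair with the same
optical path length P = m*d produces the same field at the layer's exit
boundary.  A phase-sensitive measurement at a detector a finite distance
beyond the sample breaks the degeneracy, because the remaining air path
``(z_det - d)`` depends on the geometric thickness.

Given P as prior knowledge, the candidate set is ``m_i = m_min + i*eps`` with
``d_i = P / m_i`` (N = (m_max - m_min)/eps candidates).  Each candidate's
detector-plane field is simulated with the coupled-wave solver and scored by
the wrapped phase mismatch ``Theta = |phi_f(m_i, d_i) - phi_0|``; the argmin
wins.  Because kappa barely affects the phase, it is fitted afterwards by a
1-D grid search on the amplitude mismatch at the fixed (m_hat, d_hat).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .layered import LayerStack, field_at, solve_layered
from .optics import PlaneWave

__all__ = [
    "LayeredInverseProblem",
    "LayeredEstimate",
    "LayeredInversion",
    "grid_candidates",
    "simulate_measurement",
    "noise_robustness_experiment",
]


def _wrap_phase(phi):
    """Map a phase difference to (-pi, pi]."""
    return np.pi - np.mod(np.pi - phi, 2.0 * np.pi)


def _detector_field(m: float, d: float, kappa: float, detector_z: float,
                    wavelength: float) -> complex:
    """Detector-plane field of an air / layer / air stack.

    The layer occupies [0, d]; the detector sits at ``detector_z > d`` in the
    exit air space.  The incident unit plane wave is specified at the lower
    boundary (z0 = 0) at normal incidence, x-polarized.
    """
    stack = LayerStack(n_layers=[1.0, m + 1j * kappa, 1.0],
                       boundaries=[0.0, d], z0=0.0)
    sol = solve_layered(stack, PlaneWave(wavelength=wavelength))
    return complex(field_at(sol, 0.0, 0.0, detector_z)[0])


@dataclass
class LayeredInverseProblem:
    """Inputs of the layered grid-search inversion.

    `opl` is the known optical path length P = m*d of the target layer (um);
    `detector_z` the detector coordinate measured from the layer's lower
    boundary (um), i.e. d_true + dt with dt the boundary-to-detector gap;
    `measured` the (pixel-averaged) complex detector field.
    """

    opl: float
    detector_z: float
    measured: complex
    wavelength: float = 1.0
    m_range: tuple = (1.1, 2.0)
    epsilon: float = 1e-3
    kappa_range: tuple = (0.0, 0.1)

    def __post_init__(self):
        if self.opl <= 0:
            raise ValueError("optical path length must be positive")
        if self.epsilon <= 0:
            raise ValueError("grid precision must be positive")
        if self.m_range[0] < 1.0:
            raise ValueError("m_min must be >= 1")
        if self.m_range[1] <= self.m_range[0]:
            raise ValueError("m_range must be nondegenerate")


@dataclass
class LayeredEstimate:
    """Recovered layer parameters and the attained cost."""

    m_hat: float
    d_hat: float
    kappa_hat: Optional[float]
    cost: float
    kappa_cost: Optional[float] = None
    scan: Optional[pd.DataFrame] = None

    def summary(self) -> str:
        lines = [
            "Layered grid-search inversion",
            "=============================",
            f"m_hat      : {self.m_hat:.6g}",
            f"d_hat (um) : {self.d_hat:.6g}",
            f"kappa_hat  : {self.kappa_hat if self.kappa_hat is not None else 'not fitted'}",
            f"phase cost : {self.cost:.3e}",
        ]
        if self.kappa_cost is not None:
            lines.append(f"amp cost   : {self.kappa_cost:.3e}")
        return "\n".join(lines)


def grid_candidates(problem: LayeredInverseProblem) -> np.ndarray:
    """Candidate (m_i, d_i) pairs with m_i * d_i = P exactly.

    Half-open enumeration: ``m_i = m_min + i*eps`` for i in [0, N) with
    N = (m_max - m_min)/eps rounded to the nearest integer.
    """
    m_min, m_max = problem.m_range
    n = int(round((m_max - m_min) / problem.epsilon))
    if n < 1:
        raise ValueError("empty candidate grid")
    if n > 1e7:
        raise ValueError("precision too fine: more than 1e7 candidates")
    m = m_min + problem.epsilon * np.arange(n)
    d = problem.opl / m
    return np.column_stack([m, d])


class LayeredInversion:
    """Model object: fit (m, d) then kappa of the unknown middle layer."""

    def __init__(self, problem: LayeredInverseProblem):
        self.problem = problem

    def _phase_scan(self, kappa: float = 0.0) -> pd.DataFrame:
        p = self.problem
        cands = grid_candidates(p)
        phi_0 = np.angle(p.measured)
        rows = []
        for m_i, d_i in cands:
            try:
                f = _detector_field(m_i, d_i, kappa, p.detector_z, p.wavelength)
            except Exception as exc:  # forward failure carries candidate id
                raise RuntimeError(
                    f"forward solve failed for candidate m={m_i:g}, "
                    f"d={d_i:g}: {exc}") from exc
            rows.append((m_i, d_i, abs(_wrap_phase(np.angle(f) - phi_0))))
        return pd.DataFrame(rows, columns=["m", "d", "cost"])

    def fit_md(self, keep_scan: bool = False,
               kappa: float = 0.0) -> LayeredEstimate:
        """Grid search on the wrapped phase mismatch; ties break to smaller m.

        `kappa` is the extinction coefficient assumed in the candidate
        forward models (0 on the first pass; the fitted value on refinement
        passes).
        """
        scan = self._phase_scan(kappa)
        idx = int(scan["cost"].idxmin())  # idxmin returns the first minimum
        row = scan.loc[idx]
        return LayeredEstimate(m_hat=float(row["m"]), d_hat=float(row["d"]),
                               kappa_hat=None, cost=float(row["cost"]),
                               scan=scan if keep_scan else None)

    def fit_kappa(self, m_hat: float, d_hat: float) -> tuple:
        """1-D amplitude-mismatch grid search at fixed (m_hat, d_hat)."""
        p = self.problem
        k_lo, k_hi = p.kappa_range
        n = int(round((k_hi - k_lo) / p.epsilon)) + 1
        if n < 1:
            raise ValueError("empty kappa grid")
        kappas = k_lo + p.epsilon * np.arange(n)
        a_0 = abs(p.measured)
        costs = np.array([
            abs(abs(_detector_field(m_hat, d_hat, kap, p.detector_z,
                                    p.wavelength)) - a_0)
            for kap in kappas])
        i = int(np.argmin(costs))
        return float(kappas[i]), float(costs[i])

    def fit(self, keep_scan: bool = False, n_passes: int = 2) -> LayeredEstimate:
        """Full inversion: phase fit of (m, d), amplitude fit of kappa.

        Although kappa's impact on the detector phase is small, interface
        reflections make it nonzero; a coordinate-descent refinement pass
        (phase refit with the fitted kappa in the candidate models) removes
        the residual bias.  `n_passes=1` reproduces the plain two-stage
        search.
        """
        kappa = 0.0
        est = None
        for _ in range(max(1, n_passes)):
            est = self.fit_md(keep_scan=keep_scan, kappa=kappa)
            kappa_hat, kcost = self.fit_kappa(est.m_hat, est.d_hat)
            est.kappa_hat = kappa_hat
            est.kappa_cost = kcost
            if abs(kappa_hat - kappa) < 1e-15:
                break
            kappa = kappa_hat
        return est


def simulate_measurement(m: float, d: float, kappa: float, dt: float,
                         wavelength: float = 1.0, n_pixels: int = 16384,
                         noise_sigma: float = 0.0,
                         rng: Optional[np.random.Generator] = None) -> complex:
    """Ground-truth detector measurement for a flat 3-layer sample.

    For a flat stack under normal incidence every pixel sees the same field,
    so the measurement is the pixel average of `n_pixels` identical values
    plus independent Gaussian noise on the real and imaginary parts
    (`noise_sigma` quoted relative to the unit incident amplitude).
    """
    f = _detector_field(m, d, kappa, d + dt, wavelength)
    if noise_sigma <= 0:
        return f
    if rng is None:
        rng = np.random.default_rng()
    noise = (rng.normal(0.0, noise_sigma, n_pixels)
             + 1j * rng.normal(0.0, noise_sigma, n_pixels))
    return complex(f + noise.mean())


def noise_robustness_experiment(m_true: float, d_true: float, kappa_true: float,
                                dt: float, sigma_grid: Sequence[float],
                                n_reps: int = 5, seed: int = 0,
                                wavelength: float = 1.0,
                                m_range: tuple = (1.1, 2.0),
                                epsilon: float = 1e-3,
                                n_pixels: int = 16384) -> pd.DataFrame:
    """Relative-error table of the inversion under detector noise.

    For each noise level sigma the measurement is regenerated `n_reps` times,
    inverted, and the relative absolute errors of m, d and kappa recorded.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sigma in sigma_grid:
        for rep in range(n_reps):
            meas = simulate_measurement(m_true, d_true, kappa_true, dt,
                                        wavelength, n_pixels, sigma, rng)
            prob = LayeredInverseProblem(
                opl=m_true * d_true, detector_z=d_true + dt, measured=meas,
                wavelength=wavelength, m_range=m_range, epsilon=epsilon)
            est = LayeredInversion(prob).fit()
            rows.append({
                "sigma": sigma, "rep": rep,
                "m_hat": est.m_hat, "d_hat": est.d_hat,
                "kappa_hat": est.kappa_hat,
                "err_m": abs(est.m_hat - m_true) / m_true,
                "err_d": abs(est.d_hat - d_true) / d_true,
                "err_kappa": (abs(est.kappa_hat - kappa_true) / kappa_true
                              if kappa_true else abs(est.kappa_hat)),
            })
    df = pd.DataFrame(rows)
    return df
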