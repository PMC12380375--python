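"""Seeded, named simulation scenarios used as fixtures throughout the suite.

Each scenario reproduces one of the canonical configurations of the
framework's experiments (single-sphere field, equal-OPL layer pairs, radial
far-field pipeline, 32-frame hologram, training corpus, two-sphere FOV).
Artifacts are deterministic: the same spec and seed give byte-identical
files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np

from . import io
from .holography import save_stack, simulate_interferogram, uniform_deltas
from .inverse_mie import generate_dataset
from .layered import LayerStack
from .mie import Sphere, far_field_radial, near_field_2d, two_sphere_field

__all__ = ["SCENARIOS", "make_fixture", "reference_interferogram"]


def single_sphere():
    """Single sphere a=1 um, n=1.5+0.03i, lambda=1 um, FOV 16 um."""
    return Sphere(1.0, 1.5 + 0.03j), dict(wavelength=1.0, fov=16.0,
                                          resolution=128)


def equal_opl_layers():
    """Equal-OPL middle layers: (3+0.05j, 2 um) vs (1+0.05j, 6 um), lambda=1.5."""
    a = LayerStack(n_layers=[1.0, 3.0 + 0.05j, 1.0], boundaries=[0.0, 2.0],
                   z0=0.0)
    b = LayerStack(n_layers=[1.0, 1.0 + 0.05j, 1.0], boundaries=[0.0, 6.0],
                   z0=0.0)
    return a, b, 1.5


def reference_interferogram(resolution: int = 128):
    """32-frame hologram of the reference sphere, total OPD 2 um."""
    sphere, cfg = single_sphere()
    field = near_field_2d(sphere, cfg["wavelength"], cfg["fov"], resolution,
                          total=True)
    deltas = uniform_deltas(32, 2.0)
    return simulate_interferogram(field, 1.0 + 0.0j, deltas), field


def _make_single_sphere(outdir: Path, seed: int):
    sphere, cfg = single_sphere()
    field = near_field_2d(sphere, cfg["wavelength"], cfg["fov"],
                          cfg["resolution"], total=True)
    path = outdir / "single_sphere.h5"
    io.save_field2d(path, field)
    return {"field": path}


def _make_equal_opl_layers(outdir: Path, seed: int):
    from .layered import field_at, solve_layered
    from .optics import PlaneWave

    stack_a, stack_b, lam = equal_opl_layers()
    pw = PlaneWave(wavelength=lam)
    out = {}
    for tag, stack in (("a", stack_a), ("b", stack_b)):
        sol = solve_layered(stack, pw)
        z = np.linspace(-1.0, 8.0, 256)
        vals = field_at(sol, 0.0, 0.0, z)[:, 0]
        path = outdir / f"equal_opl_stack_{tag}.h5"
        from .optics import RadialField1D
        # stored as a 1-D complex trace vs z (reuse the radial container)
        io.save_radial(path, RadialField1D(vals, z - z[0] + 1e-9, "spatial",
                                           lam))
        out[f"stack_{tag}"] = path
    return out


def _make_radial_far_field(outdir: Path, seed: int):
    sphere = Sphere(2.0, 1.4 + 0.02j)
    far = far_field_radial(sphere, 1.0, 256, 16.0)
    path = outdir / "radial_far_field.h5"
    io.save_radial(path, far)
    return {"far_field": path}


def _make_reference_hologram(outdir: Path, seed: int):
    ig, field = reference_interferogram()
    h5 = outdir / "reference_hologram.h5"
    tif = outdir / "reference_hologram.tif"
    io.save_interferogram(h5, ig)
    save_stack(tif, ig)
    io.save_field2d(h5, field, name="ground_truth")
    return {"hologram_h5": h5, "hologram_tiff": tif}


def _make_training_corpus(outdir: Path, seed: int, levels: int = 10):
    ds = generate_dataset(levels)
    path = outdir / "training_corpus.h5"
    io.save_dataset(path, ds)
    return {"corpus": path}


def _make_two_spheres(outdir: Path, seed: int):
    sphere = Sphere(1.0, 1.5 + 0.01j)
    field2d, half = two_sphere_field(sphere, separation=4.0, wavelength=1.0,
                                     fov=16.0, resolution=256)
    path = outdir / "two_spheres.h5"
    io.save_field2d(path, field2d)
    io.save_radial(path, half, name="half_line")
    return {"two_spheres": path}


SCENARIOS = {
    "single_sphere": _make_single_sphere,
    "equal_opl_layers": _make_equal_opl_layers,
    "radial_far_field": _make_radial_far_field,
    "reference_hologram": _make_reference_hologram,
    "training_corpus": _make_training_corpus,
    "two_spheres": _make_two_spheres,
}


def make_fixture(name: str, outdir, seed: int = 0,
                 manifest: bool = True) -> dict:
    """Write the named scenario's artifact(s); returns {label: path}."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from "
                         f"{sorted(SCENARIOS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs = SCENARIOS[name](outdir, seed)
    if manifest:
        io.write_manifest(outdir / f"{name}_manifest.json",
                          {"scenario": name}, seed, outputs)
    return outputs
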