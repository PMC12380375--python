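"""File formats: HDF5 containers, delimited spectra, TIFF stacks, manifests.

Complex arrays are stored as paired ``<name>_real`` / ``<name>_imag``
datasets (HDF5 has no complex dialect that every downstream tool reads);
scalar metadata lives in attributes.  Every writer records the package
version and, where randomness is involved, the seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .holography import Interferogram
from .inverse_mie import MieDataset
from .nn import DenseNetwork
from .optics import ComplexField2D, OpticalConstants, RadialField1D

__all__ = [
    "save_field2d", "load_field2d",
    "save_radial", "load_radial",
    "save_interferogram", "load_interferogram",
    "save_dataset", "load_dataset",
    "save_network", "load_network",
    "save_spectrum", "load_spectrum",
    "field_to_tiff",
    "write_manifest", "file_checksum",
]


def _write_complex(group, name, arr):
    group.create_dataset(f"{name}_real", data=np.asarray(arr).real)
    group.create_dataset(f"{name}_imag", data=np.asarray(arr).imag)


def _read_complex(group, name):
    return np.asarray(group[f"{name}_real"]) + 1j * np.asarray(group[f"{name}_imag"])


def save_field2d(path, field: ComplexField2D, name: str = "field") -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        _write_complex(g, "samples", field.samples)
        g.attrs["fov_um"] = field.fov
        g.attrs["wavelength_um"] = field.wavelength
        g.attrs["kind"] = "ComplexField2D"


def load_field2d(path, name: str = "field") -> ComplexField2D:
    with h5py.File(path, "r") as f:
        g = f[name]
        return ComplexField2D(_read_complex(g, "samples"),
                              fov=float(g.attrs["fov_um"]),
                              wavelength=float(g.attrs["wavelength_um"]))


def save_radial(path, field: RadialField1D, name: str = "radial") -> None:
    with h5py.File(path, "a") as f:
        if name in f:
            del f[name]
        g = f.create_group(name)
        _write_complex(g, "samples", field.samples)
        g.create_dataset("radii", data=field.radii)
        g.attrs["domain"] = field.domain
        g.attrs["wavelength_um"] = field.wavelength


def load_radial(path, name: str = "radial") -> RadialField1D:
    with h5py.File(path, "r") as f:
        g = f[name]
        return RadialField1D(_read_complex(g, "samples"), np.asarray(g["radii"]),
                             str(g.attrs["domain"]),
                             float(g.attrs["wavelength_um"]))


def save_interferogram(path, ig: Interferogram) -> None:
    with h5py.File(path, "a") as f:
        if "interferogram" in f:
            del f["interferogram"]
        g = f.create_group("interferogram")
        g.create_dataset("frames", data=ig.frames)
        g.create_dataset("deltas", data=ig.deltas)
        g.attrs["wavelength_um"] = ig.wavelength


def load_interferogram(path) -> Interferogram:
    with h5py.File(path, "r") as f:
        g = f["interferogram"]
        return Interferogram(np.asarray(g["frames"]), np.asarray(g["deltas"]),
                             float(g.attrs["wavelength_um"]))


def save_dataset(path, ds: MieDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("inputs", data=ds.inputs)
        f.create_dataset("labels", data=ds.labels)
        f.create_dataset("radii", data=ds.radii)
        if ds.sweep_feature is not None:
            f.create_dataset("sweep_feature", data=ds.sweep_feature)
            f.attrs["sweep_name"] = ds.sweep_name or ""
        f.attrs["representation"] = ds.representation
        f.attrs["wavelength_um"] = ds.wavelength
        for key, (lo, hi) in ds.ranges.items():
            f.attrs[f"range_{key}"] = (lo, hi)


def load_dataset(path) -> MieDataset:
    with h5py.File(path, "r") as f:
        ranges = {k[len("range_"):]: tuple(v) for k, v in f.attrs.items()
                  if k.startswith("range_")}
        sweep = (np.asarray(f["sweep_feature"])
                 if "sweep_feature" in f else None)
        return MieDataset(
            inputs=np.asarray(f["inputs"]), labels=np.asarray(f["labels"]),
            representation=str(f.attrs["representation"]),
            radii=np.asarray(f["radii"]),
            wavelength=float(f.attrs["wavelength_um"]), ranges=ranges,
            sweep_feature=sweep,
            sweep_name=(str(f.attrs["sweep_name"]) if sweep is not None else None))


def save_network(path, net: DenseNetwork, extra: Optional[dict] = None) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("network")
        for key, val in net.state_dict().items():
            g.create_dataset(key, data=val)
        if extra:
            for k, v in extra.items():
                g.attrs[k] = v


def load_network(path) -> DenseNetwork:
    with h5py.File(path, "r") as f:
        g = f["network"]
        state = {k: np.asarray(v) for k, v in g.items()}
        return DenseNetwork.from_state_dict(state)


def save_spectrum(path, spec: OpticalConstants) -> None:
    """3-column delimited text: grid, m, kappa (header records the unit)."""
    header = f"grid[{spec.unit}] m kappa"
    np.savetxt(path, np.column_stack([spec.grid, spec.m, spec.kappa]),
               header=header)


def load_spectrum(path, unit: str = "cm^-1") -> OpticalConstants:
    with open(path) as f:
        first = f.readline()
    if "grid[" in first:
        unit = first.split("grid[")[1].split("]")[0]
    data = np.loadtxt(path)
    return OpticalConstants(grid=data[:, 0], m=data[:, 1], kappa=data[:, 2],
                            unit=unit)  # type: ignore[arg-type]


def field_to_tiff(path, field: ComplexField2D) -> None:
    """32-bit float multi-page TIFF: page 0 real part, page 1 imaginary."""
    import tifffile

    stack = np.stack([field.samples.real, field.samples.imag]).astype(np.float32)
    tifffile.imwrite(str(path), stack)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path, config: dict, seed: Optional[int],
                   outputs: Optional[dict] = None) -> None:
    """JSON run manifest: config, seed, package versions, output checksums."""
    import scipy

    from . import __version__

    manifest = {
        "config": config,
        "seed": seed,
        "versions": {"chemholo": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "h5py": h5py.__version__},
        "outputs": {},
    }
    if outputs:
        for name, p in outputs.items():
            manifest["outputs"][name] = {"path": str(p),
                                         "sha256": file_checksum(p)}
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
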