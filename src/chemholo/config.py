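"""Run configuration: a YAML-serialisable bundle of simulation parameters."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Parameters of a simulation/inversion run, recorded in every artifact.

    Only broadly shared knobs live here; operation-specific options stay
    keyword arguments of the respective functions.
    """

    wavelength_um: float = 1.0
    fov_um: float = 16.0
    resolution: int = 128
    n_frames: int = 32
    total_opd_um: float = 2.0
    seed: int = 0
    verbosity: int = 1
    sphere: Optional[dict] = None      # {"a": um, "m": ..., "kappa": ...}
    stack: Optional[dict] = None       # {"indices": [...], "boundaries": [...]}
    training: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    output_dir: str = "."

    def __post_init__(self):
        for name in ("wavelength_um", "fov_um", "total_opd_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.resolution < 2 or self.n_frames < 3:
            raise ValueError("resolution >= 2 and n_frames >= 3 required")

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
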