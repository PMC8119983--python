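"""Run configuration: a fully serializable description of one pipeline run."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .chromatin import ChromatinModel
from .nanotrack import TrackModelParams, default_energy_grid


@dataclass
class RunConfig:
    """Everything needed to reproduce a library build and tissue run."""

    seed: int = 0
    # damage library
    n_histories: int = 10_000
    energy_grid_mev: list = field(
        default_factory=lambda: default_energy_grid().tolist())
    track_model: TrackModelParams = field(default_factory=TrackModelParams)
    # chromatin
    chromatin: ChromatinModel = field(default_factory=ChromatinModel)
    # geometry
    footprint_um: tuple = (400.0, 400.0)
    # exposure
    densities_per_um2: list = field(
        default_factory=lambda: [0.01, 0.05, 0.1, 0.2, 0.5])
    straggling: bool = True
    # chord integration
    l_step_um: float = 0.01
    n_angles: int = 1000
    output_dir: str = "out"

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["track_model"] = asdict(self.track_model)
        d["chromatin"] = asdict(self.chromatin)
        d["footprint_um"] = list(self.footprint_um)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["track_model"] = TrackModelParams(**d.get("track_model", {}))
        d["chromatin"] = ChromatinModel(**d.get("chromatin", {}))
        d["footprint_um"] = tuple(d.get("footprint_um", (400.0, 400.0)))
        return cls(**d)

    @property
    def energy_grid(self) -> np.ndarray:
        return np.asarray(self.energy_grid_mev, dtype=float)
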