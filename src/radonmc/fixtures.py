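"""Small deterministic test assets: toy geometry and toy damage library.

Both are generated in seconds and are used by the test suite and for quick
interactive exploration; they are *scaled-down* versions of the defaults
(smaller footprint, coarser energy grid, fewer histories), not different
models.
"""

from __future__ import annotations

import numpy as np

from .nanotrack import DamageLibrary, TrackModelParams, build_library
from .tissue import TissueGeometry, place_nuclei


def make_toy_geometry(seed: int = 0, lx_um: float = 50.0,
                      ly_um: float = 50.0) -> TissueGeometry:
    """A 50 x 50 um epithelium sub-segment (~130 nuclei)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    return place_nuclei(rng, lx_um, ly_um)


def make_toy_library(seed: int = 0, n_histories: int = 200,
                     params: TrackModelParams = TrackModelParams()
                     ) -> DamageLibrary:
    """An 8-point, 200-history damage library spanning 10 keV - 8 MeV."""
    grid = np.array([0.01, 0.05, 0.2, 0.5, 0.9, 2.0, 4.0, 8.0])
    return build_library(grid, n_histories, params, seed)


def make_fixture(kind: str, seed: int = 0):
    """Dispatcher used by the command-line interface."""
    if kind == "toy-geometry":
        return make_toy_geometry(seed)
    if kind == "toy-library":
        return make_toy_library(seed)
    raise ValueError(f"unknown fixture kind {kind!r}")
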