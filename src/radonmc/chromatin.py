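"""Chromatin-fiber volume fraction of the cell nucleus.

The nano-scale damage library counts "potential" DSB clusters in a unit
volume in which every energy-deposition spot may sit on DNA.  In a real
nucleus only the fraction of the volume occupied by chromatin fiber is
DNA; the per-cell-type scale factor p_F is the ratio of total fiber volume
(a cylinder of radius ``fiber_radius`` and total length set by the genome
size and its compaction) to the spherical nucleus volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NM_PER_BLOCK = 50.0  # chromatin-fiber length per compaction block, nm


@dataclass(frozen=True)
class ChromatinModel:
    """Genome content and fiber geometry shared by all cell types.

    Defaults: 6.6 Gbp genome, 5.56 kbp per 50 nm fiber block, 16 nm fiber
    radius, giving a total fiber length of 59.35 mm per nucleus.
    """

    genome_size_bp: float = 6.6e9
    compaction_bp_per_block: float = 5.56e3
    fiber_radius_nm: float = 16.0

    def __post_init__(self):
        for name in ("genome_size_bp", "compaction_bp_per_block",
                     "fiber_radius_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def fiber_length_mm(model: ChromatinModel = ChromatinModel()) -> float:
    """Total chromatin-fiber length per nucleus in mm."""
    n_blocks = model.genome_size_bp / model.compaction_bp_per_block
    return n_blocks * NM_PER_BLOCK * 1e-6  # nm -> mm


def volume_fraction(r_nucleus_um: float,
                    model: ChromatinModel = ChromatinModel()) -> float:
    """Chromatin volume fraction p_F for a spherical nucleus of radius R (um).

    p_F = pi R_fiber^2 L_fiber / ((4 pi / 3) R_nucleus^3); must be in (0, 1).
    """
    if r_nucleus_um <= 0:
        raise ValueError("nucleus radius must be positive")
    fiber_vol_um3 = (np.pi * (model.fiber_radius_nm * 1e-3) ** 2
                     * fiber_length_mm(model) * 1e3)  # mm -> um
    nucleus_vol_um3 = (4.0 * np.pi / 3.0) * r_nucleus_um ** 3
    p_f = fiber_vol_um3 / nucleus_vol_um3
    if p_f >= 1.0:
        raise ValueError(
            f"unphysical nucleus: chromatin fraction {p_f:.3f} >= 1")
    return p_f


def equivalent_sphere_radius(volume_um3: float) -> float:
    """Radius (um) of the sphere with the given volume (um^3)."""
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return float((3.0 * volume_um3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def volume_fraction_for_volume(volume_um3: float,
                               model: ChromatinModel = ChromatinModel()
                               ) -> float:
    """p_F for a nucleus given its volume rather than its radius."""
    return volume_fraction(equivalent_sphere_radius(volume_um3), model)
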