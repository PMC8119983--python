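"""Isotropic chord averaging of per-hit quantities for spherical nuclei.

Under an isotropic flux the chord of a sphere of radius R entered at polar
angle theta (to the inward normal) is L = 2 R cos(theta), and a per-hit
quantity v(L) averages to

    V = sum over theta of 2 v(L) sin(theta) cos(theta) dtheta,

with theta discretized over [0, pi/2) (default 1000 midpoint bins).  With
v(L) = L this yields the textbook mean chord 4R/3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .integrator import _chord_quantities, dose_from_edep
from .nanotrack import DamageLibrary


def chord_weights(r_um: float, n_angles: int = 1000
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Midpoint chord lengths and isotropic-flux weights over theta bins."""
    if r_um <= 0:
        raise ValueError("radius must be positive")
    if n_angles < 2:
        raise ValueError("need at least 2 angle bins")
    dtheta = (np.pi / 2.0) / n_angles
    theta = (np.arange(n_angles) + 0.5) * dtheta
    chords = 2.0 * r_um * np.cos(theta)
    weights = 2.0 * np.sin(theta) * np.cos(theta) * dtheta
    return chords, weights


def average_functional(v, r_um: float, n_angles: int = 1000) -> float:
    """Average an arbitrary per-chord functional v(L) over isotropic entry."""
    chords, weights = chord_weights(r_um, n_angles)
    return float(np.sum(weights * np.asarray(v(chords), dtype=float)))


def average_over_chords(e_mev: float, r_um: float, library: DamageLibrary,
                        p_f: float, n_angles: int = 1000,
                        nucleus_volume_um3: float | None = None,
                        density_g_cm3: float = 1.0) -> dict:
    """Mean per-hit quantities at entry energy E for a sphere of radius R.

    Returns means (and SDs over entry angles) of energy deposition, dose,
    DSB clusters and complex DSBs per nucleus hit.
    """
    chords, weights = chord_weights(r_um, n_angles)
    wsum = float(weights.sum())
    if abs(wsum - 1.0) > 1e-3:
        raise RuntimeError("chord weights do not sum to 1")
    edep, dsb, cplx, _ = _chord_quantities(
        library, np.full_like(chords, e_mev), chords)
    dsb = dsb * p_f
    cplx = cplx * p_f
    out = {"energy_mev": e_mev, "mean_chord_um": float(np.sum(weights * chords))}
    for name, vals in (("edep_kev", edep), ("dsb", dsb), ("complex", cplx)):
        m = float(np.sum(weights * vals))
        var = float(np.sum(weights * (vals - m) ** 2))
        out[f"{name}_mean"] = m
        out[f"{name}_sd_angles"] = np.sqrt(max(var, 0.0))
    if nucleus_volume_um3 is not None:
        out["dose_gy_mean"] = dose_from_edep(
            out["edep_kev_mean"], nucleus_volume_um3, density_g_cm3)
    return out


def per_hit_curve(library: DamageLibrary, r_um: float, p_f: float,
                  nucleus_volume_um3: float | None = None,
                  n_angles: int = 1000,
                  energies: np.ndarray | None = None) -> pd.DataFrame:
    """Chord-averaged per-hit quantities over the library energy grid."""
    if energies is None:
        energies = library.energy_grid
    rows = [average_over_chords(float(e), r_um, library, p_f, n_angles,
                                nucleus_volume_um3) for e in energies]
    return pd.DataFrame(rows)


def complexity_fraction_curve(library: DamageLibrary, r_um: float,
                              p_f: float = 1.0, n_angles: int = 1000,
                              energies: np.ndarray | None = None
                              ) -> pd.DataFrame:
    """Chord-averaged complex-DSB fraction among DSB clusters vs energy.

    The chromatin fraction p_F cancels in the ratio.
    """
    df = per_hit_curve(library, r_um, p_f, None, n_angles, energies)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(df["dsb_mean"] > 0,
                        df["complex_mean"] / df["dsb_mean"], np.nan)
    return pd.DataFrame({"energy_mev": df["energy_mev"],
                         "complex_fraction": frac})
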