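"""Parameterized alpha-particle stopping power in liquid water.

The transport layer works from a tabulated linear stopping power S(E) for
helium ions in unit-density liquid water.  The bundled table is produced by
the parameterization below rather than taken from a transport toolkit:

* above 100 keV, a monotone log-log spline through control points derived
  from effective-charge (Barkas) scaling of proton stopping powers in water,
  with the Bragg maximum placed at 0.8 MeV;
* below 100 keV, a velocity-proportional power law ``S = A * E**0.35``
  matched continuously at 100 keV (electronic stopping in the
  Lindhard-Scharff regime, with the exponent softened to absorb the nuclear
  stopping contribution);
* a single global scale factor calibrated so that the CSDA ranges reproduce
  the canonical values for radon-progeny alphas in water
  (R(6.0 MeV) ~ 48 um, R(7.69 MeV) ~ 71 um).

The resulting table has a single maximum of ~234 keV/um at 0.8 MeV and CSDA
ranges R(1 MeV) = 5.25 um, R(6 MeV) = 48.2 um, R(7.69 MeV) = 70.9 um.
"""

from __future__ import annotations

import io

import numpy as np
from scipy.interpolate import PchipInterpolator

#: control points (E MeV, S keV/um) before global range calibration
CONTROL_POINTS: tuple[tuple[float, float], ...] = (
    (0.10, 140.0), (0.15, 163.0), (0.20, 178.0), (0.30, 200.0), (0.40, 212.0),
    (0.50, 218.0), (0.60, 222.0), (0.70, 224.0), (0.80, 225.0), (0.90, 219.0),
    (1.00, 208.0), (1.25, 193.0), (1.50, 178.0), (1.75, 164.0), (2.00, 152.0),
    (2.50, 134.0), (3.00, 121.0), (3.50, 111.0), (4.00, 103.0), (4.50, 95.3),
    (5.00, 88.6), (5.50, 83.0), (6.00, 78.3), (6.50, 74.2), (7.00, 70.5),
    (7.50, 67.2), (8.00, 64.3), (9.00, 59.3), (10.00, 55.2),
)

#: exponent of the low-energy electronic-stopping power law
LOW_E_EXPONENT = 0.35
#: boundary between the power-law and spline regimes (MeV)
LOW_E_BOUNDARY = 0.10
#: global scale chosen so CSDA ranges match canonical 6 / 7.69 MeV values
RANGE_CALIBRATION = 1.04

PROVENANCE = (
    "effective-charge-scaled proton stopping + low-E power law, "
    f"range-calibrated x{RANGE_CALIBRATION} (R(6 MeV)=48.2 um, "
    "R(7.69 MeV)=70.9 um)"
)


def stopping_power_model(energy_mev) -> np.ndarray:
    """Evaluate the parameterized stopping power (keV/um, unit density).

    Valid for 0 < E <= 10 MeV; vectorized over ``energy_mev``.
    """
    e = np.atleast_1d(np.asarray(energy_mev, dtype=float))
    if np.any(e <= 0.0) or np.any(e > 10.0):
        raise ValueError("stopping-power model covers 0 < E <= 10 MeV")
    ctrl = np.asarray(CONTROL_POINTS)
    spline = PchipInterpolator(np.log(ctrl[:, 0]), np.log(ctrl[:, 1]))
    a_low = ctrl[0, 1] / LOW_E_BOUNDARY ** LOW_E_EXPONENT
    out = np.empty_like(e)
    lo = e <= LOW_E_BOUNDARY
    out[lo] = a_low * e[lo] ** LOW_E_EXPONENT
    out[~lo] = np.exp(spline(np.log(e[~lo])))
    out *= RANGE_CALIBRATION
    if np.isscalar(energy_mev):
        return float(out[0])
    return out


def render_table(n_points: int = 180) -> str:
    """Render the bundled two-column text fixture (energy_MeV, S_keV_per_um)."""
    energies = np.geomspace(1e-3, 10.0, n_points)
    s = stopping_power_model(energies)
    buf = io.StringIO()
    buf.write("# Linear stopping power of alpha particles in liquid water "
              "(unit density)\n")
    buf.write(f"# provenance: {PROVENANCE}\n")
    buf.write("# energy_MeV   S_keV_per_um\n")
    for e, v in zip(energies, s):
        buf.write(f"{e:.6e}  {v:.6e}\n")
    return buf.getvalue()


def write_table(path) -> None:
    with open(path, "w") as fh:
        fh.write(render_table())
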