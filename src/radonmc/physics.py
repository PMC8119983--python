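"""Continuous-slowing-down (CSDA) transport of alpha particles in water.

Provides the stopping-power table, LET lookup, CSDA ranges and energy
degradation along path segments.  Media are liquid water at density
1.0 g/cm^3 (cell nuclei, serous and mucous layers) or 1.05 g/cm^3 (the
remaining epithelial tissue); density enters as a linear scale on the
stopping power, equivalently as water-equivalent pathlength.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass
from importlib import resources

import numpy as np
from scipy.interpolate import PchipInterpolator

#: Bohr energy-loss straggling variance rate for a bare helium ion in water,
#: d(sigma_E^2)/ds = 0.1569 * z^2 * (Z/A) * rho  [MeV^2 cm^2/g] -> MeV^2/um
BOHR_VARIANCE_RATE = 0.1569 * 4.0 * 0.5551 * 1e-4


@dataclass(frozen=True)
class MediumSpec:
    """A transport medium: name and mass density in g/cm^3."""

    name: str
    density: float

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")


WATER = MediumSpec("water", 1.0)
TISSUE = MediumSpec("epithelial tissue", 1.05)


class StoppingPowerTable:
    """Energy-indexed linear stopping power of alphas in unit-density water.

    Loaded from a two-column whitespace-delimited text file
    (energy_MeV, S_keV_per_um) with '#' comments.  Interpolation between
    nodes is log-log (stopping power is smooth on that scale).  The table
    also precomputes the CSDA range integral R(E) = int dE'/S(E') and its
    inverse, used for energy degradation along path segments.
    """

    def __init__(self, energies: np.ndarray, stopping_power: np.ndarray,
                 provenance: str = ""):
        energies = np.asarray(energies, dtype=float)
        stopping_power = np.asarray(stopping_power, dtype=float)
        if energies.ndim != 1 or energies.size < 4:
            raise ValueError("need a 1-D table with at least 4 nodes")
        if not np.all(np.diff(energies) > 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(stopping_power <= 0):
            raise ValueError("stopping power must be strictly positive")
        self.energies = energies
        self.stopping_power = stopping_power
        self.provenance = provenance
        self._log_e = np.log(energies)
        self._log_s = np.log(stopping_power)
        self._interp = PchipInterpolator(self._log_e, self._log_s)
        # dense cumulative range grid (unit-density water, um)
        e_dense = np.geomspace(energies[0], energies[-1], 4000)
        s_dense = self._let_unit(e_dense)
        inv = 1.0 / s_dense
        r = np.concatenate(
            [[0.0], np.cumsum(0.5 * (inv[1:] + inv[:-1]) * np.diff(e_dense))]
        ) * 1e3  # MeV / (keV/um) -> um
        # energy below the table floor deposits locally: R(floor) := 0
        self._e_dense = e_dense
        self._r_dense = r

    # -- construction -----------------------------------------------------

    @classmethod
    def from_text(cls, path) -> "StoppingPowerTable":
        provenance = ""
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") and "provenance:" in line:
                    provenance = line.split("provenance:", 1)[1].strip()
        data = np.loadtxt(path)
        return cls(data[:, 0], data[:, 1], provenance=provenance)

    @classmethod
    @functools.cache
    def default(cls) -> "StoppingPowerTable":
        ref = resources.files("radonmc") / "data" / "alpha_water_stopping.txt"
        with resources.as_file(ref) as path:
            return cls.from_text(path)

    # -- core lookups (unit density) --------------------------------------

    def _check_coverage(self, e: np.ndarray) -> None:
        if np.any(e < self.energies[0]):
            raise ValueError(
                f"energy below table floor {self.energies[0]:g} MeV")
        if np.any(e > self.energies[-1]):
            raise ValueError(
                f"energy above table ceiling {self.energies[-1]:g} MeV")

    def _let_unit(self, e) -> np.ndarray:
        return np.exp(self._interp(np.log(np.asarray(e, dtype=float))))

    def let(self, energy_mev) -> np.ndarray | float:
        """Stopping power (keV/um) at unit density; vectorized."""
        e = np.asarray(energy_mev, dtype=float)
        self._check_coverage(e)
        out = self._let_unit(e)
        return float(out) if np.isscalar(energy_mev) else out

    def range_of_energy(self, energy_mev) -> np.ndarray | float:
        """CSDA range (um) in unit-density water; vectorized."""
        e = np.asarray(energy_mev, dtype=float)
        self._check_coverage(e)
        out = np.interp(e, self._e_dense, self._r_dense)
        return float(out) if np.isscalar(energy_mev) else out

    def energy_of_range(self, residual_range_um) -> np.ndarray | float:
        """Inverse of :meth:`range_of_energy`; 0 below the table floor."""
        r = np.asarray(residual_range_um, dtype=float)
        out = np.interp(r, self._r_dense, self._e_dense)
        out = np.where(r <= 0.0, 0.0, out)
        return float(out) if np.isscalar(residual_range_um) else out

    def straggling_sigma_range(self, energy_mev) -> float:
        """Bohr range-straggling standard deviation (um) for full stopping.

        sigma_R^2 = int_0^R c / S(E(s))^2 ds with c the Bohr variance rate.
        """
        e0 = float(energy_mev)
        self._check_coverage(np.asarray(e0))
        mask = self._e_dense <= e0
        e = self._e_dense[mask]
        s_mev_um = self._let_unit(e) * 1e-3  # MeV/um
        # ds = dE / S  ->  integrate c / S^2 * dE / S over energy
        integrand = BOHR_VARIANCE_RATE / s_mev_um ** 3
        var = np.trapezoid(integrand, e)
        return float(np.sqrt(max(var, 0.0)))


def let_of_energy(energy_mev, medium: MediumSpec = WATER,
                  table: StoppingPowerTable | None = None):
    """Linear energy transfer (keV/um) at energy E in the given medium.

    Linear density scaling: S(E, rho) = S_water(E) * rho / 1.0.
    """
    table = table or StoppingPowerTable.default()
    return table.let(energy_mev) * medium.density


def csda_range(energy_mev, medium: MediumSpec = WATER,
               table: StoppingPowerTable | None = None):
    """CSDA pathlength (um) from energy E down to the table floor."""
    table = table or StoppingPowerTable.default()
    return table.range_of_energy(energy_mev) / medium.density


def energy_after_pathlength(energy_mev, path_um, medium: MediumSpec = WATER,
                            table: StoppingPowerTable | None = None,
                            straggling: bool = False,
                            rng: np.random.Generator | None = None):
    """Residual energy (MeV) after slowing down over ``path_um``; 0 if stopped.

    Deterministic CSDA by default, evaluated through the range integral
    (the zero-step limit of explicit dE = S(E) ds stepping).  With
    ``straggling=True`` a single Gaussian energy perturbation with the Bohr
    variance accumulated over the traversed path is applied.
    """
    if path_um < 0:
        raise ValueError("path must be non-negative")
    table = table or StoppingPowerTable.default()
    e0 = float(energy_mev)
    table._check_coverage(np.asarray(e0))
    residual = table.range_of_energy(e0) - path_um * medium.density
    e1 = float(table.energy_of_range(residual))
    if straggling and e1 > 0.0:
        if rng is None:
            raise ValueError("straggling requires an rng")
        traversed = path_um * medium.density
        sigma = float(np.sqrt(BOHR_VARIANCE_RATE * traversed))
        e1 = max(0.0, e1 + rng.normal(0.0, sigma))
        if e1 < table.energies[0]:
            e1 = 0.0
    return e1
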