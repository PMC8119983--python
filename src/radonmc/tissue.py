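"""Bronchial-epithelium exposure simulation.

A 400 x 400 um segment of bronchial epithelium, 57.8 um thick, is packed
with spherical nuclei of six cell types (ciliated, pre-ciliated, goblet,
basal, secretory, indetermined) whose depth distributions follow measured
areal portions at six tabulated depths (linear between, zero at the
surface and the basement membrane).  A 6 um serous (cilia) layer and a
5 um mucous layer sit on the luminal surface; radon-progeny alphas
(Po-214 7.69 MeV with probability 0.896, Po-218 6.0 MeV with 0.104) are
emitted isotropically from uniform positions in the mucous layer, whose
footprint is expanded by 80 um on each side so the flux entering the
segment is uniform.

Transport is straight-line CSDA (optionally with Bohr range straggling)
through media of density 1.0 g/cm^3 (mucous, serous, nuclei) and
1.05 g/cm^3 (remaining tissue).  Every nucleus traversal is scored with
the chord integrator; energy deposition is tallied in 1 um depth bins and
per nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatin import (ChromatinModel, equivalent_sphere_radius,
                        volume_fraction_for_volume)
from .integrator import _chord_quantities, dose_from_edep
from .nanotrack import DamageLibrary
from .physics import StoppingPowerTable, TISSUE, WATER

THICKNESS_UM = 57.8
REGION_BOUNDARIES_UM = (0.0, 12.0, 24.0, 36.0, 48.0, 57.8)
MUCOUS_THICKNESS_UM = 5.0
SEROUS_THICKNESS_UM = 6.0
SOURCE_MARGIN_UM = 80.0
PO214_ENERGY_MEV = 7.69
PO218_ENERGY_MEV = 6.0
PO214_FRACTION = 0.896

#: nominal nucleus volumes (um^3) and areal frequencies (per mm^2 of
#: basement membrane) of the six cell types
CELL_TYPE_TABLE = pd.DataFrame(
    {
        "name": ["ciliated", "pre-ciliated", "goblet", "basal",
                 "secretory", "indetermined"],
        "nucleus_volume_um3": [310.0, 310.0, 243.0, 201.0, 230.0, 156.0],
        "areal_frequency_per_mm2": [17900.0, 2200.0, 5300.0, 17100.0,
                                    1800.0, 9600.0],
    }
)

#: nucleus areal portions (%) at six depths from the epithelium surface
DEPTH_PORTION_DEPTHS_UM = np.array([0.0, 12.0, 24.0, 36.0, 48.0, 57.8])
DEPTH_PORTION_PERCENT = pd.DataFrame(
    {
        "ciliated": [0.0, 5.0, 19.0, 11.0, 5.0, 0.0],
        "pre-ciliated": [0.0, 0.0, 2.4, 2.6, 2.0, 0.0],
        "goblet": [0.0, 0.0, 1.0, 3.0, 3.5, 0.0],
        "basal": [0.0, 0.0, 0.2, 8.3, 21.0, 0.0],
        "secretory": [0.0, 1.8, 2.4, 1.4, 0.4, 0.0],
        "indetermined": [0.0, 0.8, 1.9, 3.4, 4.8, 0.0],
    },
    index=DEPTH_PORTION_DEPTHS_UM,
)


@dataclass(frozen=True)
class CellTypeSpec:
    """Constants of one epithelial cell type."""

    name: str
    nucleus_volume_um3: float
    areal_frequency_per_mm2: float
    nucleus_radius_um: float
    p_f: float


def default_cell_types(chromatin: ChromatinModel = ChromatinModel()
                       ) -> list[CellTypeSpec]:
    specs = []
    for _, row in CELL_TYPE_TABLE.iterrows():
        v = float(row["nucleus_volume_um3"])
        specs.append(CellTypeSpec(
            name=str(row["name"]),
            nucleus_volume_um3=v,
            areal_frequency_per_mm2=float(row["areal_frequency_per_mm2"]),
            nucleus_radius_um=equivalent_sphere_radius(v),
            p_f=volume_fraction_for_volume(v, chromatin),
        ))
    return specs


class DepthPortionTable:
    """Depth-dependent areal portions and the derived placement densities."""

    def __init__(self, depths_um: np.ndarray = DEPTH_PORTION_DEPTHS_UM,
                 portions_percent: pd.DataFrame = DEPTH_PORTION_PERCENT,
                 step_um: float = 0.02):
        self.depths = np.asarray(depths_um, dtype=float)
        self.portions = portions_percent
        if np.any(portions_percent.to_numpy() < 0):
            raise ValueError("areal portions must be non-negative")
        self.grid = np.arange(0.0, THICKNESS_UM + step_um / 2, step_um)
        self._pdf = {}
        self._cdf = {}
        for name in portions_percent.columns:
            vals = np.interp(self.grid, self.depths,
                             portions_percent[name].to_numpy())
            norm = np.trapezoid(vals, self.grid)
            if norm <= 0:
                raise ValueError(f"all-zero areal portions for {name!r}")
            pdf = vals / norm
            cdf = np.concatenate(
                [[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1])
                                  * np.diff(self.grid))])
            cdf /= cdf[-1]
            self._pdf[name] = pdf
            self._cdf[name] = cdf

    def pdf(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        """(depth grid, normalized placement density) for one cell type."""
        return self.grid, self._pdf[name]

    def sample_depth(self, name: str, rng: np.random.Generator,
                     n: int = 1) -> np.ndarray:
        u = rng.random(n)
        return np.interp(u, self._cdf[name], self.grid)


@dataclass
class TissueGeometry:
    """Placed nuclei plus the layer/segment dimensions."""

    lx_um: float
    ly_um: float
    centers: np.ndarray  # (n, 3): x, y, depth z
    radii: np.ndarray
    type_index: np.ndarray  # index into cell_types
    cell_types: list[CellTypeSpec]
    thickness_um: float = THICKNESS_UM
    mucous_um: float = MUCOUS_THICKNESS_UM
    serous_um: float = SEROUS_THICKNESS_UM
    margin_um: float = SOURCE_MARGIN_UM
    region_boundaries: tuple = REGION_BOUNDARIES_UM
    _hash: dict = field(default=None, repr=False)

    @property
    def n_nuclei(self) -> int:
        return len(self.radii)

    @property
    def source_area_um2(self) -> float:
        return (self.lx_um + 2 * self.margin_um) * \
            (self.ly_um + 2 * self.margin_um)

    @property
    def overburden_um(self) -> float:
        return self.mucous_um + self.serous_um

    def segment_mass_kg(self) -> float:
        """Mass of the scored 0-57.8 um segment (nuclei at 1.0 g/cm^3)."""
        v_seg = self.lx_um * self.ly_um * self.thickness_um
        v_nuc = float(np.sum(4.0 * np.pi / 3.0 * self.radii ** 3))
        return ((v_seg - v_nuc) * TISSUE.density + v_nuc * WATER.density) \
            * 1e-15

    def region_of_depth(self, z) -> np.ndarray:
        return np.clip(np.searchsorted(self.region_boundaries, z,
                                       side="right") - 1, 0, 4)

    # -- spatial hash over the x-y plane ----------------------------------

    CELL_UM = 10.0

    def _build_hash(self):
        nx = max(1, int(np.ceil(self.lx_um / self.CELL_UM)))
        ny = max(1, int(np.ceil(self.ly_um / self.CELL_UM)))
        cells: dict[int, list[int]] = {}
        ix = np.clip((self.centers[:, 0] // self.CELL_UM).astype(int), 0,
                     nx - 1)
        iy = np.clip((self.centers[:, 1] // self.CELL_UM).astype(int), 0,
                     ny - 1)
        for i, (a, b) in enumerate(zip(ix, iy)):
            cells.setdefault(a * ny + b, []).append(i)
        self._hash = {
            "nx": nx, "ny": ny,
            "cells": {k: np.asarray(v, dtype=np.int64)
                      for k, v in cells.items()},
        }

    def candidates_along(self, x0, y0, x1, y1) -> np.ndarray:
        """Nucleus indices whose x-y cells lie near the projected segment."""
        if self._hash is None:
            self._build_hash()
        h = self._hash
        nx, ny = h["nx"], h["ny"]
        length = float(np.hypot(x1 - x0, y1 - y0))
        n_pts = max(2, int(length / 5.0) + 2)
        xs = np.linspace(x0, x1, n_pts)
        ys = np.linspace(y0, y1, n_pts)
        ix = (xs // self.CELL_UM).astype(int)
        iy = (ys // self.CELL_UM).astype(int)
        keys = set()
        for a, b in zip(ix, iy):
            for da in (-1, 0, 1):
                for db in (-1, 0, 1):
                    ca, cb = a + da, b + db
                    if 0 <= ca < nx and 0 <= cb < ny:
                        keys.add(ca * ny + cb)
        lists = [h["cells"][k] for k in keys if k in h["cells"]]
        if not lists:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(lists))


def place_nuclei(rng: np.random.Generator,
                 lx_um: float = 400.0, ly_um: float = 400.0,
                 cell_types: list[CellTypeSpec] | None = None,
                 portions: DepthPortionTable | None = None,
                 max_attempts: int = 5000,
                 allow_overlap: bool = False) -> TissueGeometry:
    """Pack non-overlapping nucleus spheres by depth-dependent density.

    Per cell type, N = round(areal frequency x footprint area) centers are
    drawn with depth from the type's areal-portion density and x-y uniform
    (strictly inside the footprint); rejection sampling enforces pairwise
    sphere non-overlap.  Deterministic given the generator state.
    """
    cell_types = cell_types or default_cell_types()
    portions = portions or DepthPortionTable()
    area_mm2 = lx_um * ly_um * 1e-6
    counts = [int(np.rint(ct.areal_frequency_per_mm2 * area_mm2))
              for ct in cell_types]
    order = np.argsort([-ct.nucleus_radius_um for ct in cell_types])
    centers, radii, type_idx = [], [], []
    # incremental hash grid for overlap tests (3-D, coarse)
    cell = 10.0
    occupied: dict[tuple, list[int]] = {}

    def neighbours(p):
        kx, ky, kz = (int(p[0] // cell), int(p[1] // cell),
                      int(p[2] // cell))
        out = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    out.extend(occupied.get((kx + dx, ky + dy, kz + dz), ()))
        return out

    for j in order:
        ct = cell_types[j]
        r = ct.nucleus_radius_um
        for _ in range(counts[j]):
            for attempt in range(max_attempts):
                z = float(portions.sample_depth(ct.name, rng, 1)[0])
                x = rng.uniform(0.0, lx_um)
                y = rng.uniform(0.0, ly_um)
                p = np.array([x, y, z])
                if allow_overlap:
                    break
                idx = neighbours(p)
                if not idx:
                    break
                d2 = np.sum((np.asarray([centers[i] for i in idx]) - p) ** 2,
                            axis=1)
                rr = np.asarray([radii[i] for i in idx]) + r
                if np.all(d2 > rr ** 2):
                    break
            else:
                packed = len(centers)
                raise RuntimeError(
                    f"nucleus placement failed for {ct.name} after "
                    f"{max_attempts} attempts ({packed} placed)")
            i_new = len(centers)
            centers.append(p)
            radii.append(r)
            type_idx.append(j)
            key = (int(p[0] // cell), int(p[1] // cell), int(p[2] // cell))
            occupied.setdefault(key, []).append(i_new)
    return TissueGeometry(
        lx_um=lx_um, ly_um=ly_um,
        centers=np.asarray(centers, dtype=float).reshape(-1, 3),
        radii=np.asarray(radii, dtype=float),
        type_index=np.asarray(type_idx, dtype=np.int64),
        cell_types=cell_types,
    )


@dataclass
class EmissionBatch:
    """Sampled alpha emissions from the mucous layer."""

    origins: np.ndarray  # (n, 3): x, y, depth z (z negative above surface)
    directions: np.ndarray  # (n, 3) unit vectors, z component toward depth
    energies_mev: np.ndarray
    nuclide: np.ndarray  # 0 = Po-214, 1 = Po-218

    def __len__(self):
        return len(self.energies_mev)


def sample_emissions(geometry: TissueGeometry, rng: np.random.Generator,
                     density_per_um2: float | None = None,
                     n: int | None = None,
                     source: tuple = ((PO214_ENERGY_MEV, PO214_FRACTION),
                                      (PO218_ENERGY_MEV,
                                       1.0 - PO214_FRACTION)),
                     ) -> EmissionBatch:
    """Sample isotropic emissions uniform in the expanded mucous slab.

    One emission per 5 um^3 mucous section (1 x 1 x 5 um) equals one per
    um^2 of mucous footprint, so N = density x source area.
    """
    if (density_per_um2 is None) == (n is None):
        raise ValueError("give exactly one of density_per_um2 or n")
    if n is None:
        if density_per_um2 < 0:
            raise ValueError("density must be non-negative")
        n = int(np.rint(density_per_um2 * geometry.source_area_um2))
    m = geometry.margin_um
    x = rng.uniform(-m, geometry.lx_um + m, n)
    y = rng.uniform(-m, geometry.ly_um + m, n)
    z = rng.uniform(-(geometry.overburden_um),
                    -(geometry.overburden_um - geometry.mucous_um), n)
    mu = rng.uniform(-1.0, 1.0, n)  # cos(polar), +1 = straight down
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - mu ** 2)
    directions = np.column_stack([s * np.cos(phi), s * np.sin(phi), mu])
    energies = np.array([e for e, _ in source])
    probs = np.array([p for _, p in source], dtype=float)
    probs /= probs.sum()
    which = rng.choice(len(source), size=n, p=probs)
    return EmissionBatch(np.column_stack([x, y, z]), directions,
                         energies[which], which.astype(np.int8))


@dataclass
class RayResult:
    """Scored quantities of one traced emission."""

    depth_bins: np.ndarray  # bin indices with deposits (inside footprint)
    depth_edep_kev: np.ndarray
    depth_pathlength_um: np.ndarray
    nucleus_ids: np.ndarray
    entry_energies_mev: np.ndarray
    chords_um: np.ndarray
    nucleus_edep_kev: np.ndarray
    tallies: dict  # mucous / serous / tissue_in / tissue_out / escaped (keV)


def _trace_downward(geometry: TissueGeometry, table: StoppingPowerTable,
                    o: np.ndarray, d: np.ndarray, e0: float,
                    r0_water_um: float) -> RayResult:
    """Trace one downward ray through layers and nuclei.

    ``r0_water_um`` is the (possibly straggled) water-equivalent range of
    the particle; the energy at water-equivalent path w along the ray is
    E(w) = energy_of_range(r0 - w).
    """
    dz = d[2]
    t_surface = (0.0 - o[2]) / dz
    t_bottom = (geometry.thickness_um - o[2]) / dz
    t_serous = (-geometry.serous_um - o[2]) / dz
    # maximum useful t: path exhausts the range even at minimum density 1.0
    t_max = min(t_bottom, r0_water_um)
    tallies = {"mucous": 0.0, "serous": 0.0, "tissue_in": 0.0,
               "tissue_out": 0.0, "escaped": 0.0}
    empty = np.empty(0)
    if t_max <= t_surface:
        # stops before the epithelium surface
        t_stop = min(r0_water_um, t_surface)
        e_serous_in = float(table.energy_of_range(r0_water_um
                                                  - min(t_stop, t_serous)))
        tallies["mucous"] = (e0 - e_serous_in) * 1e3
        e_left = float(table.energy_of_range(r0_water_um - t_stop))
        tallies["serous"] = (e_serous_in - e_left) * 1e3
        tallies["escaped"] = e_left * 1e3
        return RayResult(empty.astype(int), empty, empty, empty.astype(int),
                         empty, empty, empty, tallies)

    # nucleus intersections between surface and bottom
    p0 = o + t_surface * d
    p1 = o + min(t_bottom, t_surface + (t_max - t_surface) * 1.05) * d
    cand = geometry.candidates_along(p0[0], p0[1], p1[0], p1[1])
    sphere_t1 = np.empty(0)
    sphere_t2 = np.empty(0)
    sphere_id = np.empty(0, dtype=np.int64)
    if len(cand):
        c = geometry.centers[cand]
        rr = geometry.radii[cand]
        oc = c - o[None, :]
        b = oc @ d
        disc = b ** 2 - (np.sum(oc * oc, axis=1) - rr ** 2)
        ok = disc > 0.0
        if ok.any():
            sq = np.sqrt(disc[ok])
            t1 = b[ok] - sq
            t2 = b[ok] + sq
            keep = (t2 > t_surface) & (t1 < t_bottom) & (t1 > 0.0)
            sphere_t1 = np.maximum(t1[keep], t_surface)
            sphere_t2 = t2[keep]
            sphere_id = cand[ok][keep]
            order = np.argsort(sphere_t1)
            sphere_t1, sphere_t2, sphere_id = (sphere_t1[order],
                                               sphere_t2[order],
                                               sphere_id[order])

    # breakpoints: layer boundaries, 1 um depth-bin crossings, sphere walls
    zbins = np.arange(1.0, geometry.thickness_um, 1.0)
    t_pts = np.concatenate([
        [0.0, t_serous, t_surface], (zbins - o[2]) / dz, [t_bottom],
        sphere_t1, sphere_t2])
    t_pts = np.unique(t_pts[(t_pts >= 0.0) & (t_pts <= t_bottom)])
    t_mid = 0.5 * (t_pts[1:] + t_pts[:-1])
    seg_len = np.diff(t_pts)
    z_mid = o[2] + t_mid * dz

    # medium per segment: nuclei 1.0, other tissue 1.05, layers 1.0
    in_nucleus = np.full(len(t_mid), -1, dtype=np.int64)
    for a, b_, i in zip(sphere_t1, sphere_t2, sphere_id):
        in_nucleus[(t_mid > a) & (t_mid < b_)] = i
    density = np.where(z_mid < 0.0, 1.0,
                       np.where(in_nucleus >= 0, WATER.density,
                                TISSUE.density))
    w = np.concatenate([[0.0], np.cumsum(seg_len * density)])
    e_pts = table.energy_of_range(r0_water_um - w)
    de_kev = -np.diff(e_pts) * 1e3  # deposit per segment

    x_mid = o[0] + t_mid * d[0]
    y_mid = o[1] + t_mid * d[1]
    inside = ((x_mid >= 0.0) & (x_mid <= geometry.lx_um)
              & (y_mid >= 0.0) & (y_mid <= geometry.ly_um))
    in_tissue = z_mid >= 0.0
    in_serous = (z_mid < 0.0) & (z_mid >= -geometry.serous_um)
    in_mucous = z_mid < -geometry.serous_um

    tallies["mucous"] = float(de_kev[in_mucous].sum())
    tallies["serous"] = float(de_kev[in_serous].sum())
    tallies["tissue_in"] = float(de_kev[in_tissue & inside].sum())
    tallies["tissue_out"] = float(de_kev[in_tissue & ~inside].sum())
    tallies["escaped"] = float(e_pts[-1]) * 1e3

    score = in_tissue & inside & (seg_len > 0.0)
    bins = np.minimum(z_mid[score].astype(int),
                      int(geometry.thickness_um))
    # track length only while the particle is still alive in the segment
    alive = e_pts[:-1] > 0.0
    path_scored = np.where(alive, seg_len, 0.0)[score]
    # nucleus scoring
    hit_ids = np.empty(0, dtype=np.int64)
    hit_e = np.empty(0)
    hit_chord = np.empty(0)
    hit_edep = np.empty(0)
    if len(sphere_t1):
        w_at = np.interp(sphere_t1, t_pts, w)
        e_at = np.asarray(table.energy_of_range(r0_water_um - w_at),
                          dtype=float).reshape(-1)
        live = e_at > 0.0
        hit_ids = sphere_id[live]
        hit_e = e_at[live]
        hit_chord = (sphere_t2 - sphere_t1)[live]
        hit_edep = np.array([
            float(de_kev[in_nucleus == i].sum()) for i in hit_ids])
    return RayResult(bins, de_kev[score], path_scored, hit_ids, hit_e,
                     hit_chord, hit_edep, tallies)


def trace_alpha(geometry: TissueGeometry, table: StoppingPowerTable,
                origin, direction, energy_mev: float,
                straggling: bool = False,
                rng: np.random.Generator | None = None) -> RayResult:
    """Trace one emission; upward-directed alphas deposit in the mucous."""
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    r0 = float(table.range_of_energy(energy_mev))
    if straggling:
        if rng is None:
            raise ValueError("straggling requires an rng")
        r0 = max(r0 + rng.normal(0.0, table.straggling_sigma_range(
            energy_mev)), 1e-6)
    if d[2] <= 1e-9:
        # upward or horizontal: mucous then (for upward) the open air
        t_top = ((-geometry.overburden_um - o[2]) / d[2]
                 if d[2] < 0 else np.inf)
        t_stop = min(r0, t_top)
        e_left = float(table.energy_of_range(r0 - t_stop))
        tallies = {"mucous": (energy_mev - e_left) * 1e3, "serous": 0.0,
                   "tissue_in": 0.0, "tissue_out": 0.0,
                   "escaped": e_left * 1e3}
        empty = np.empty(0)
        return RayResult(empty.astype(int), empty, empty, empty.astype(int),
                         empty, empty, empty, tallies)
    return _trace_downward(geometry, table, o, d, energy_mev, r0)


@dataclass
class ExposureResult:
    """Aggregated outcome of a tissue run at one emission density."""

    density_per_um2: float
    n_emissions: int
    tissue_dose_gy: float
    dose_by_nuclide_gy: dict
    depth_profile: pd.DataFrame  # depth bin, edep per nuclide (keV)
    cell_stats: pd.DataFrame
    nucleus_table: pd.DataFrame  # per-nucleus depth, hits, edep, dose, damage
    hit_histograms: dict  # type name -> np.ndarray of nucleus hit counts
    complex_by_multiplicity: pd.DataFrame
    seed: int | None = None


def run_exposure(geometry: TissueGeometry, library: DamageLibrary,
                 density_per_um2: float, seed: int,
                 table: StoppingPowerTable | None = None,
                 straggling: bool = True,
                 source: tuple = ((PO214_ENERGY_MEV, PO214_FRACTION),
                                  (PO218_ENERGY_MEV, 1.0 - PO214_FRACTION)),
                 ) -> ExposureResult:
    """Simulate one emission density and aggregate damage per cell type."""
    table = table or StoppingPowerTable.default()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    emissions = sample_emissions(geometry, rng,
                                 density_per_um2=density_per_um2,
                                 source=source)
    n_bins = int(np.ceil(geometry.thickness_um))
    n_nuclides = len(source)
    depth_edep = np.zeros((n_nuclides, n_bins))
    depth_path = np.zeros(n_bins)
    tissue_edep = np.zeros(n_nuclides)
    n_nuc = geometry.n_nuclei
    nucleus_edep = np.zeros(n_nuc)
    nucleus_hits = np.zeros(n_nuc, dtype=np.int64)
    hit_ids_all, hit_e_all, hit_chord_all = [], [], []

    down = emissions.directions[:, 2] > 1e-9
    # upward/horizontal emissions never reach the tissue; skip them
    idx_down = np.flatnonzero(down)
    r0_all = np.asarray(table.range_of_energy(emissions.energies_mev),
                        dtype=float)
    if straggling:
        sig = {e: table.straggling_sigma_range(e)
               for e in np.unique(emissions.energies_mev)}
        sigma = np.array([sig[e] for e in emissions.energies_mev])
        r0_all = np.maximum(r0_all + rng.normal(0.0, 1.0, len(r0_all))
                            * sigma, 1e-6)
    for i in idx_down:
        res = _trace_downward(geometry, table, emissions.origins[i],
                              emissions.directions[i],
                              float(emissions.energies_mev[i]),
                              float(r0_all[i]))
        k = emissions.nuclide[i]
        if len(res.depth_bins):
            np.add.at(depth_edep[k], res.depth_bins, res.depth_edep_kev)
            np.add.at(depth_path, res.depth_bins, res.depth_pathlength_um)
        tissue_edep[k] += res.tallies["tissue_in"]
        if len(res.nucleus_ids):
            np.add.at(nucleus_hits, res.nucleus_ids, 1)
            np.add.at(nucleus_edep, res.nucleus_ids, res.nucleus_edep_kev)
            hit_ids_all.append(res.nucleus_ids)
            hit_e_all.append(res.entry_energies_mev)
            hit_chord_all.append(res.chords_um)

    # vectorized damage for all hits via the library profile
    nucleus_dsb = np.zeros(n_nuc)
    nucleus_complex = np.zeros(n_nuc)
    if hit_ids_all:
        ids = np.concatenate(hit_ids_all)
        e_in = np.clip(np.concatenate(hit_e_all), None, library.ceiling)
        chords = np.concatenate(hit_chord_all)
        _, dsb, cplx, _ = _chord_quantities(library, e_in, chords)
        p_f = np.array([ct.p_f for ct in geometry.cell_types])
        scale = p_f[geometry.type_index[ids]]
        np.add.at(nucleus_dsb, ids, dsb * scale)
        np.add.at(nucleus_complex, ids, cplx * scale)

    mass = geometry.segment_mass_kg()
    from .integrator import KEV_TO_JOULE
    dose_by_nuclide = {i: tissue_edep[i] * KEV_TO_JOULE / mass
                       for i in range(n_nuclides)}
    volumes = np.array([geometry.cell_types[j].nucleus_volume_um3
                        for j in geometry.type_index]) \
        if n_nuc else np.empty(0)
    nucleus_dose = np.array([dose_from_edep(e, v) for e, v in
                             zip(nucleus_edep, volumes)]) if n_nuc \
        else np.empty(0)
    rows = []
    histograms = {}
    mult_rows = []
    for j, ct in enumerate(geometry.cell_types):
        sel = geometry.type_index == j
        n_cells = int(sel.sum())
        doses = nucleus_dose[sel] if n_cells else np.empty(0)
        hits = nucleus_hits[sel]
        histograms[ct.name] = hits.copy()
        rows.append({
            "cell_type": ct.name, "n_nuclei": n_cells,
            "mean_hits": float(hits.mean()) if n_cells else np.nan,
            "mean_dose_gy": float(doses.mean()) if n_cells else np.nan,
            "mean_dsb": float(nucleus_dsb[sel].mean()) if n_cells
            else np.nan,
            "mean_complex": float(nucleus_complex[sel].mean()) if n_cells
            else np.nan,
        })
        for m in range(1, int(hits.max()) + 1 if n_cells else 1):
            on = hits == m
            if on.any():
                mult_rows.append({
                    "cell_type": ct.name, "n_hits": m,
                    "n_nuclei": int(on.sum()),
                    "total_complex": float(nucleus_complex[sel][on].sum()),
                })
    with np.errstate(invalid="ignore", divide="ignore"):
        let_depth = np.where(depth_path > 0.0,
                             depth_edep.sum(axis=0) / depth_path, 0.0)
    depth_profile = pd.DataFrame({
        "depth_um": np.arange(n_bins) + 0.5,
        **{f"edep_kev_nuclide{i}": depth_edep[i] for i in
           range(n_nuclides)},
        "edep_kev_total": depth_edep.sum(axis=0),
        "pathlength_um": depth_path,
        "edep_per_pathlength_kev_um": let_depth,
    })
    nucleus_table = pd.DataFrame({
        "nucleus_id": np.arange(n_nuc),
        "cell_type": [geometry.cell_types[j].name
                      for j in geometry.type_index],
        "depth_um": geometry.centers[:, 2] if n_nuc else np.empty(0),
        "radius_um": geometry.radii,
        "n_hits": nucleus_hits,
        "edep_kev": nucleus_edep,
        "dose_gy": nucleus_dose,
        "n_dsb": nucleus_dsb,
        "n_complex": nucleus_complex,
    })
    return ExposureResult(
        density_per_um2=density_per_um2, n_emissions=len(emissions),
        tissue_dose_gy=float(sum(dose_by_nuclide.values())),
        dose_by_nuclide_gy=dose_by_nuclide,
        depth_profile=depth_profile,
        cell_stats=pd.DataFrame(rows),
        nucleus_table=nucleus_table,
        hit_histograms=histograms,
        complex_by_multiplicity=pd.DataFrame(
            mult_rows, columns=["cell_type", "n_hits", "n_nuclei",
                                "total_complex"]),
        seed=seed,
    )
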