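"""Epithelium geometry, emission sampling, transport and exposure runs."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from radonmc.nanotrack import build_library
from radonmc.physics import csda_range, WATER
from radonmc.tissue import (DEPTH_PORTION_PERCENT, DepthPortionTable,
                            TissueGeometry, default_cell_types,
                            place_nuclei, run_exposure, sample_emissions,
                            trace_alpha)


@pytest.fixture(scope="module")
def mini_library():
    """Coarse 3-point library: transport tests do not need damage detail."""
    return build_library(np.array([0.01, 1.0, 8.0]), 50, seed=2)


class TestDepthPortions:
    def test_zero_at_surface_and_basement_membrane(self):
        t = DepthPortionTable()
        for name in DEPTH_PORTION_PERCENT.columns:
            grid, pdf = t.pdf(name)
            assert pdf[0] == 0.0
            assert pdf[-1] == 0.0

    def test_normalized_to_unit_integral(self):
        t = DepthPortionTable()
        for name in DEPTH_PORTION_PERCENT.columns:
            grid, pdf = t.pdf(name)
            assert np.trapezoid(pdf, grid) == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_column_rejected(self):
        bad = DEPTH_PORTION_PERCENT.copy()
        bad["ciliated"] = 0.0
        with pytest.raises(ValueError, match="all-zero"):
            DepthPortionTable(portions_percent=bad)

    def test_sampling_follows_density(self):
        t = DepthPortionTable()
        rng = np.random.default_rng(0)
        z = t.sample_depth("basal", rng, 20000)
        # basal mass concentrates in the deep half of the epithelium
        assert np.mean(z > 30.0) > 0.9
        assert z.min() >= 0.0 and z.max() <= 57.8


class TestPlacement:
    def test_counts_follow_areal_frequencies(self, toy_geometry):
        """N per type = round(frequency x 0.0025 mm^2) on the 50 um toy."""
        expected = [round(ct.areal_frequency_per_mm2 * 0.0025)
                    for ct in toy_geometry.cell_types]
        got = [int(np.sum(toy_geometry.type_index == j))
               for j in range(6)]
        assert got == expected
        assert toy_geometry.n_nuclei == sum(expected)

    def test_no_pair_of_spheres_overlaps(self, toy_geometry):
        c, r = toy_geometry.centers, toy_geometry.radii
        d2 = np.sum((c[:, None, :] - c[None, :, :]) ** 2, axis=-1)
        rr = (r[:, None] + r[None, :]) ** 2
        np.fill_diagonal(d2, np.inf)
        assert np.all(d2 > rr)

    def test_centers_inside_footprint_and_depth(self, toy_geometry):
        c = toy_geometry.centers
        assert np.all((c[:, 0] > 0) & (c[:, 0] < 50.0))
        assert np.all((c[:, 1] > 0) & (c[:, 1] < 50.0))
        assert np.all((c[:, 2] >= 0) & (c[:, 2] <= 57.8))

    def test_deterministic_given_seed(self):
        a = place_nuclei(np.random.default_rng(3), 50.0, 50.0)
        b = place_nuclei(np.random.default_rng(3), 50.0, 50.0)
        assert np.array_equal(a.centers, b.centers)
        assert np.array_equal(a.type_index, b.type_index)

    def test_full_size_ciliated_count(self):
        """Table 1 frequency x 0.16 mm^2 gives 2864 ciliated nuclei."""
        ct = default_cell_types()[0]
        assert round(ct.areal_frequency_per_mm2 * 0.16) == 2864


class TestEmissions:
    def test_density_to_count(self, small_geometry):
        rng = np.random.default_rng(0)
        em = sample_emissions(small_geometry, rng, density_per_um2=0.1)
        assert len(em) == round(0.1 * 260.0 ** 2)

    def test_isotropy(self, small_geometry):
        rng = np.random.default_rng(1)
        em = sample_emissions(small_geometry, rng, n=100_000)
        mu = em.directions[:, 2]
        se = mu.std() / np.sqrt(len(mu))
        assert abs(mu.mean()) < 3 * se
        norms = np.linalg.norm(em.directions, axis=1)
        assert np.allclose(norms, 1.0)

    def test_nuclide_ratio(self, small_geometry):
        rng = np.random.default_rng(2)
        em = sample_emissions(small_geometry, rng, n=100_000)
        frac_po214 = np.mean(em.nuclide == 0)
        assert frac_po214 == pytest.approx(0.896, abs=0.003)
        assert set(np.unique(em.energies_mev)) == {6.0, 7.69}

    def test_origins_inside_mucous_slab(self, small_geometry):
        rng = np.random.default_rng(3)
        em = sample_emissions(small_geometry, rng, n=1000)
        assert np.all((em.origins[:, 2] >= -11.0)
                      & (em.origins[:, 2] <= -6.0))
        assert np.all((em.origins[:, 0] >= -80.0)
                      & (em.origins[:, 0] <= 180.0))

    def test_argument_validation(self, small_geometry):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError):
            sample_emissions(small_geometry, rng)
        with pytest.raises(ValueError):
            sample_emissions(small_geometry, rng, density_per_um2=0.1,
                             n=10)


class TestTraceAlpha:
    def test_range_bound_normal_incidence(self, small_geometry, table,
                                          mini_library):
        """6 MeV straight down from the mucous top cannot deposit beyond
        csda_range(6 MeV) - 11 um of overburden."""
        res = trace_alpha(small_geometry, table, [50.0, 50.0, -11.0],
                          [0.0, 0.0, 1.0], 6.0)
        max_depth = csda_range(6.0, WATER, table) - 11.0
        deep = res.depth_bins[res.depth_edep_kev > 0]
        assert deep.max() <= np.ceil(max_depth)

    def test_energy_balance_per_emission(self, small_geometry, table):
        """E0 equals deposits in mucous + serous + tissue (in and out of
        the footprint) plus escaping energy, within 0.5%."""
        rng = np.random.default_rng(7)
        em = sample_emissions(small_geometry, rng, n=500)
        for i in range(len(em)):
            res = trace_alpha(small_geometry, table, em.origins[i],
                              em.directions[i], float(em.energies_mev[i]))
            total = sum(res.tallies.values())
            assert total == pytest.approx(em.energies_mev[i] * 1e3,
                                          rel=5e-3)

    def test_entry_energy_monotone_along_ray(self, small_geometry, table):
        """Deeper nuclei along one ray are entered at lower energy."""
        rng = np.random.default_rng(8)
        checked = 0
        em = sample_emissions(small_geometry, rng, n=4000)
        for i in range(len(em)):
            res = trace_alpha(small_geometry, table, em.origins[i],
                              em.directions[i], float(em.energies_mev[i]))
            if len(res.entry_energies_mev) >= 2:
                assert np.all(np.diff(res.entry_energies_mev) <= 1e-12)
                checked += 1
            if checked >= 50:
                break
        assert checked >= 10

    def test_chords_bounded_by_diameter(self, small_geometry, table):
        rng = np.random.default_rng(9)
        em = sample_emissions(small_geometry, rng, n=1000)
        for i in range(200):
            res = trace_alpha(small_geometry, table, em.origins[i],
                              em.directions[i], float(em.energies_mev[i]))
            for nid, chord in zip(res.nucleus_ids, res.chords_um):
                assert chord <= 2 * small_geometry.radii[nid] + 1e-9

    def test_hash_candidates_cover_brute_force(self, toy_geometry):
        """Spatial-hash candidate lists contain every sphere the segment
        passes within reach of (brute-force cross-check)."""
        rng = np.random.default_rng(10)
        c = toy_geometry.centers
        r = toy_geometry.radii
        for _ in range(300):
            p0 = rng.uniform([-20, -20], [70, 70])
            p1 = p0 + rng.uniform(-60, 60, 2)
            cand = set(toy_geometry.candidates_along(*p0, *p1))
            d = p1 - p0
            L = np.hypot(*d)
            if L < 1e-9:
                continue
            u = d / L
            ap = c[:, :2] - p0
            t = np.clip(ap @ u, 0.0, L)
            closest = ap - t[:, None] * u[None, :]
            dist = np.hypot(closest[:, 0], closest[:, 1])
            for j in np.flatnonzero(dist <= r):
                assert j in cand

    def test_upward_emission_never_reaches_tissue(self, small_geometry,
                                                  table):
        res = trace_alpha(small_geometry, table, [50.0, 50.0, -8.0],
                          [0.0, 0.6, -0.8], 7.69)
        assert res.tallies["tissue_in"] == 0.0
        assert len(res.nucleus_ids) == 0
        assert res.tallies["mucous"] > 0.0


class TestRunExposure:
    def test_zero_density_zero_everything(self, small_geometry,
                                          mini_library):
        res = run_exposure(small_geometry, mini_library, 0.0, seed=1)
        assert res.n_emissions == 0
        assert res.tissue_dose_gy == 0.0
        assert np.all(res.cell_stats["mean_hits"] == 0.0)

    def test_seed_reproducibility(self, small_geometry, mini_library):
        a = run_exposure(small_geometry, mini_library, 0.05, seed=9)
        b = run_exposure(small_geometry, mini_library, 0.05, seed=9)
        pd.testing.assert_frame_equal(a.cell_stats, b.cell_stats)
        pd.testing.assert_frame_equal(a.depth_profile, b.depth_profile)

    def test_removing_nuclei_leaves_tissue_energy(self, small_geometry,
                                                  mini_library):
        """Control experiment: deleting all nuclei (density 1.0 vs 1.05
        swap) changes total segment energy deposition by < 0.5%."""
        empty = TissueGeometry(
            small_geometry.lx_um, small_geometry.ly_um,
            np.empty((0, 3)), np.empty(0), np.empty(0, dtype=np.int64),
            small_geometry.cell_types)
        a = run_exposure(small_geometry, mini_library, 0.5, seed=5,
                         straggling=False)
        b = run_exposure(empty, mini_library, 0.5, seed=5,
                         straggling=False)
        ea = a.tissue_dose_gy * small_geometry.segment_mass_kg()
        eb = b.tissue_dose_gy * empty.segment_mass_kg()
        assert ea == pytest.approx(eb, rel=5e-3)

    def test_source_margin_is_sufficient(self, small_geometry, table):
        """Emissions originating >= 80 um outside the footprint cannot
        reach it (lateral reach < sqrt(range^2 - overburden^2) ~ 70 um),
        so widening the margin leaves the segment dose unchanged."""
        rng = np.random.default_rng(11)
        for _ in range(300):
            y = rng.uniform(-80.0, 180.0)
            z = rng.uniform(-11.0, -6.0)
            mu = rng.uniform(-1.0, 1.0)
            phi = rng.uniform(0.0, 2 * np.pi)
            s = np.sqrt(1 - mu ** 2)
            res = trace_alpha(small_geometry, table,
                              [-80.0, y, z],
                              [s * np.cos(phi), s * np.sin(phi), mu], 7.69)
            assert res.tallies["tissue_in"] == 0.0

    def test_hit_chance_ordering(self, small_geometry, mini_library):
        """Basal nuclei are hit least; ciliated more than every type except
        secretory, with which it sits in a statistical tie (the two share
        the shallow band of the depth distribution)."""
        res = run_exposure(small_geometry, mini_library, 0.5, seed=21)
        hits = dict(zip(res.cell_stats["cell_type"],
                        res.cell_stats["mean_hits"]))
        assert hits["basal"] == min(hits.values())
        for name in ("pre-ciliated", "goblet", "indetermined", "basal"):
            assert hits["ciliated"] > hits[name]
        assert hits["ciliated"] == pytest.approx(hits["secretory"],
                                                 rel=0.25)

    def test_per_hit_dose_increases_with_depth(self, small_geometry,
                                               mini_library):
        """Within every cell type, deeper nuclei receive more dose per hit
        (slower alphas of higher LET reach them) and are hit less often."""
        res = run_exposure(small_geometry, mini_library, 1.0, seed=22,
                           straggling=False)
        nt = res.nucleus_table
        for name, grp in nt.groupby("cell_type"):
            hit = grp[grp["n_hits"] > 0]
            if len(hit) < 20:
                continue
            med = hit["depth_um"].median()
            shallow = hit[hit["depth_um"] <= med]
            deep = hit[hit["depth_um"] > med]
            dose_per_hit = lambda g: (g["dose_gy"] / g["n_hits"]).mean()
            assert dose_per_hit(deep) > dose_per_hit(shallow), name
            assert deep["n_hits"].mean() < shallow["n_hits"].mean(), name

    def test_hit_histogram_consistency(self, small_geometry, mini_library):
        res = run_exposure(small_geometry, mini_library, 0.3, seed=13)
        for _, row in res.cell_stats.iterrows():
            h = res.hit_histograms[row["cell_type"]]
            assert h.mean() == pytest.approx(row["mean_hits"], rel=1e-9)
        mult = res.complex_by_multiplicity
        if len(mult):
            for name, grp in mult.groupby("cell_type"):
                row = res.cell_stats.set_index("cell_type").loc[name]
                assert grp["total_complex"].sum() <= \
                    row["mean_complex"] * row["n_nuclei"] * (1 + 1e-9)
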