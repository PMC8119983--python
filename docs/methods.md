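# Methods

This note documents the models behind `radonmc`, the parameters that
matter, the numerical choices, and what the synthetic components do and do
not capture.

## Alpha-particle transport

Transport is the continuous-slowing-down approximation (CSDA) on straight
rays. Everything derives from a single tabulated linear stopping power
S(E) for helium ions in unit-density liquid water, bundled as a plain-text
fixture (`radonmc/data/alpha_water_stopping.txt`) and interpolated
log-log (PCHIP). The table itself is generated by
`radonmc.stopping_model`:

* above 100 keV, a monotone log-log spline through control points derived
  by effective-charge (Barkas) scaling of proton stopping powers in water,
  with the Bragg maximum placed at 0.8 MeV (~234 keV/µm);
* below 100 keV, a velocity-proportional power law S = A·E^0.35 matched
  continuously at 100 keV — the exponent is softened below the
  Lindhard–Scharff E^0.45 to absorb the nuclear-stopping contribution;
* one global scale factor (1.04) calibrated so CSDA ranges reproduce the
  canonical literature values for radon-progeny alphas in water:
  R(6.0 MeV) = 48.1 µm, R(7.69 MeV) = 70.8 µm (also R(1 MeV) = 5.2 µm,
  R(60 keV) = 0.71 µm).

Ranges R(E) = ∫ dE′/S(E′) and their inverse are precomputed on a dense
grid; `energy_after_pathlength` evaluates the zero-step limit of explicit
dE = S·ds stepping through that inverse (the test suite checks agreement
with a 1 nm-step Euler oracle to 0.5 %). Density enters linearly:
S(E, ρ) = ρ·S_water(E), i.e. path lengths are water-equivalent. Optional
energy-loss straggling is Gaussian with the Bohr variance rate
0.1569·z²·(Z/A)·ρ MeV²/cm; in tissue runs it is applied as a single
per-trajectory range perturbation with
σ_R² = ∫ c/S(E)² ds (σ_R ≈ 0.5 µm for 7.69 MeV), which has the same
end-of-range distribution as per-step noise under CSDA.

Secondary electrons are not transported; their energy is deposited
locally through the radial profile of the nano-scale model (below). No
nuclear scattering or lateral deflection is modeled: multiple-scattering
deflection of MeV alphas over these path lengths is well below a degree.

## Nano-scale damage model and its calibration

The 1 µm track segment in a 5 µm-radius cylinder is populated with
deposition spots: N ~ Poisson(ΔE_CSDA/ē) spots whose energies are
exponential with mean ē, rescaled so their sum equals the CSDA energy
loss over the traversed length exactly (≤ 1 µm; shorter when the particle
stops). Longitudinal positions are uniform; radial offsets follow a 2-D
Gaussian of scale σ_r about the axis (an exponential profile is available
via configuration). 20 % of spots are flagged as DNA-strand spots, strand
1 or 2 with equal probability. Strand spots convert to SSBs with the
linear 5–37.5 eV induction ramp. SSBs are clustered with DBSCAN
(ε = 3.3 nm, minimum 2 points; with these settings DBSCAN reduces exactly
to connected components of the ε-neighborhood graph, which is what the
brute-force oracle in the tests computes). DSB = cluster with both
strands present; complex DSB = DSB with > 2 SSBs.

ē and σ_r are the calibration surface: the micro-physics they condense
(ionization clustering, secondary-electron spectra) is not modeled
explicitly. Defaults **ē = 35 eV, σ_r = 1.6 nm** were fixed by a 2-D scan
against two published track-structure benchmarks — the complex-DSB
fraction among DSB clusters ≈ 40 % at 8 MeV and a chord-averaged maximum
≈ 82 % in the MeV Bragg region — and are recorded in the library
metadata. The calibrated model reaches 0.47 at 8 MeV and a chord-averaged
maximum of 0.80; the two ends of the published span cannot be matched
simultaneously within this two-parameter family (a heavier-tailed radial
profile raises the 8 MeV value faster than the peak), and we accept the
residual mismatch rather than add structure with no independent
constraint. With the Gaussian profile, > 99 % of deposited energy lies
within 100 nm of the axis at 8 MeV, consistent with the near-axis
concentration that justifies the 5 µm unit-cylinder radius. The absolute
yield works out to ~20 DSB/Gy/Gbp for a 10 µm nucleus at 2 MeV, in the
range of published alpha-particle values.

The damage library stores, per grid energy (default 40 points: 28
log-spaced over 10 keV–2 MeV where LET varies fastest, 12 linear over
2–8 MeV), the ensemble of per-history records (segment LET, energy
deposit, SSB/DSB/complex counts) plus summary means and SDs. Library
damage is "potential": it assumes DNA everywhere in the unit volume and
is rescaled by the chromatin volume fraction p_F of the actual cell type
(p_F·V_nucleus is constant across types — same genome in every nucleus).

## Chord integration and isotropic averaging

For a nucleus traversal, entry energy E and geometric chord L determine
damage by stepping along the chord with the library's energy-interpolated
per-µm rates, decrementing energy with the library's own mean energy-loss
rate (kept consistent with the physics table by the segment-energy
scaling above). Numerically the stepping is evaluated in its zero-step
limit through two precomputed cumulative functions (path-from-energy and
damage-from-energy); a 1 nm explicit-step oracle agrees to 0.5 %.
Stopping inside the nucleus deposits the residual energy (including the
sub-10 keV remainder) locally. Expected mode returns real-valued means;
sampled mode draws a Poisson DSB total with binomial thinning for the
complex subset.

Isotropic per-hit averages use the polar-angle quadrature
V̄ = Σ 2 v(2R cos θ) sin θ cos θ Δθ with 1000 midpoint bins over
[0, π/2); midpoint placement makes the weight sum exact to O(Δθ²) and
reproduces the 4R/3 mean chord to < 0.1 % (machine precision at 10⁶
bins). SDs are reported over entry angles.

## Epithelium model

Geometry: 400 × 400 µm footprint, 57.8 µm thick, five depth regions
(boundaries 12/24/36/48/57.8 µm), 6 µm serous and 5 µm mucous layers
above the surface. Six cell types with the nominal nucleus volumes
(310/310/243/201/230/156 µm³) and areal frequencies
(17 900/2 200/5 300/17 100/1 800/9 600 per mm²); spheres of the
equivalent-volume radius. Depth placement densities are the tabulated
areal portions at six depths, linearly interpolated on a 0.02 µm grid,
zero at both faces, normalized per type; centers are drawn by inverse
CDF (depth) × uniform (x–y), with rejection sampling enforcing full
sphere non-overlap (a stronger condition than non-coincident centers;
packing ~22 % succeeds in a few thousand attempts per nucleus at most).
The interior cells of the source table are partially garbled in available
renderings; the transcription bundled here was chosen as the unique
six-token reading per row and cross-checked against the frequency ×
volume products (see "Known limitations").

Emissions: one per 5 µm³ mucous section ≡ one per µm² of mucous
footprint; N = density × (footprint + 2 × 80 µm margin)². Origins are
uniform in the expanded mucous slab, directions isotropic, energy
7.69 MeV (Po-214) with probability 0.896 else 6.0 MeV (Po-218). The
80 µm margin is provably sufficient: the lateral reach of a 7.69 MeV
alpha that still enters the tissue is √(71² − 11²) ≈ 70 µm, so emissions
farther out contribute exactly zero (tested).

Each downward ray is traced through mucous/serous (ρ = 1.0), tissue
(ρ = 1.05) and nuclei (ρ = 1.0) with breakpoints at layer boundaries,
1 µm depth-bin crossings and sphere walls (found via a 10 µm x–y spatial
hash validated against brute-force intersection); energies at breakpoints
come from the water-equivalent range inverse, so per-emission energy
balance is exact by construction. Scoring: per-depth energy and track
length (inside the footprint), per-nuclide tissue dose over the segment
mass (nuclei at 1.0, rest at 1.05 g/cm³), per-nucleus hits and energy;
per-hit DSB/complex damage is evaluated vectorized from (entry energy,
chord) through the chord integrator. Upward emissions deposit in the
mucus and escape. Tissue outside the footprint is modeled as
nucleus-free tissue; deleting all nuclei changes segment energy by
< 0.2 % (density-swap control), so this simplification is immaterial.

The depth profile carries both raw energy per bin and energy per unit
track length. The raw histogram of an isotropic plane source peaks at
the surface (grazing rays contribute 1/cos θ track length per unit
depth); the per-track-length profile is the Bragg-structure quantity and
peaks at ~30 µm (6 MeV) and ~50 µm (7.69 MeV).

## Exposure units

WL and WLM follow their definitions (1 WL = 20.8 µJ/m³,
1 WLM = 1 WL × 170 h = 3.54 × 10⁻³ J·h/m³). The density↔WLM map is
anchored to the reported mine-exposure correspondence (0.74 emissions/µm²
after 8 h at 5.7 WL) rather than re-derived from aerosol deposition
physics, which is outside this model's scope:
WLM(d) = (5.7 × 8/170) × d/0.74, giving 0.036 WLM at density 0.1 and
0.181 at 0.5.

## Problem sizes

Default study conditions are 10⁴ histories per library energy and the
full 400 × 400 µm segment. The bundled acceptance script uses 600
histories per energy and 10⁴ emissions per mono-energetic profile run —
sizes at which every reported mean has a fractional standard error well
below the tolerance it is compared at; the test suite uses 400 histories
and additionally a 100 × 100 µm sub-segment for transport property
checks. Mean-hit statistics for the rarest type (secretory, 288 nuclei
per segment) carry placement-realization noise of ~2.5 % (SD), so the
corresponding test averages three placement realizations.

## Known limitations

* Indirect (radical-mediated) damage, DNA repair kinetics, cell-cycle
  radiosensitivity, mucociliary clearance and non-uniform progeny
  deposition are all out of scope; damage numbers are initial direct
  yields.
* The nano-scale spot process is a calibrated surrogate, not an ab-initio
  track-structure simulation: its two parameters are constrained only by
  the complex-fraction benchmarks, and its absolute DSB yields should be
  read with that in mind. Passing tests demonstrate internal consistency
  and agreement with the calibration targets, not fidelity to any
  specific cell line.
* The depth-portion table transcription carries irreducible uncertainty;
  its secretory column integrates to ~1.7 × the secretory
  frequency × volume product (the worst internal inconsistency of the
  source data), and secretory hit statistics inherit a commensurate
  (~+9 %) offset against the published mean. The ciliated and secretory
  types end up in a statistical tie for the highest hit chance; published
  results put ciliated first by a similar small margin.
* CSDA transport has no angular scattering; depth-of-maximum positions
  are reproduced to ~2 µm, within the smearing that scattering would add.
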