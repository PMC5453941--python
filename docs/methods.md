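# Methods

This note records the models, conventions and numerical choices behind
`poremap`, and what the synthetic generators do and do not emulate.

## Coordinate conventions and data model

All lengths are Angstrom, energies kcal/mol, temperatures K, times ps.
Particle indices are 0-based internally; residue numbers are 1-based in
all file I/O. Boxes are orthorhombic; triclinic cells are rejected with an
explicit error rather than silently mishandled. The membrane normal is +z.

The *pore frame* places the pore's xy center of mass at the origin and
z = 0 at the bilayer midplane, defined as the mean of the two per-leaflet
PO4-plane means (leaflets are split about the pore COM z). All reaction
coordinates — the planar radial distance `xy` of the cargo COM, the axial
distance `z`, and the pore-shape coordinate — are measured in this frame.

Centers of mass and radii of gyration are mass-unweighted: at
coarse-grained resolution bead masses are nearly uniform, and the analysis
should not depend on a mass table the input formats do not carry.
Periodic-robust COMs use a two-pass scheme (circular mean per axis, then a
minimum-image average about that center), exact for clusters narrower than
half the box about their own center; the circular-mean first pass is
reliable up to cluster radii of ~0.38 box lengths.

Residue polarity uses a residue-level table: positive {ARG, LYS, HIS},
negative {ASP, GLU}, polar-uncharged {SER, THR, ASN, GLN, TYR, CYS, TRP,
GLY}, hydrophobic {ALA, VAL, LEU, ILE, PRO, PHE, MET} and heme (HEC/HEM).
The table is configurable because published surface-class percentages are
sensitive to where GLY, CYS, TRP and the heme are placed; no atom-level
override (e.g. heme propionate oxygens) is attempted. Unknown residues
classify as hydrophobic with a logged warning so lipid/ion/solvent species
pass through analyses that ignore them.

## Free-energy landscapes (Boltzmann inversion)

A 2D histogram of the cargo COM over two coordinates is normalised and
inverted, `F = −RT ln P`. Default bin widths are 2 Å for `xy` and `z` and
1 Å for the shape coordinate — fine enough to resolve stage regions
10–15 Å wide with ≥5 bins, coarse enough that toy-scale sampling fills the
bins. Three zero-reference conventions are supported:

* `plateau` (default): bins never sampled define F = 0; occupied bins are
  shifted so the least-sampled occupied bin sits at zero, hence sampled
  free energies are ≤ 0. This matches landscapes whose flat unsampled rim
  is drawn at zero energy.
* `max_F`: identical shift without assigning values to empty bins.
* `global_min`: the most-populated bin is the zero.

Free-energy *differences* are invariant to the choice; only the offset
moves. No multi-temperature reweighting (WHAM/MBAR) is performed — the
analysis model is a single equilibrium trajectory at one temperature.

1D PMFs marginalise the probability over the other coordinate inside a
rectangular stage window, renormalise within the window and invert. Three
stage windows ship as named defaults (`stage1`: 25–40 Å xy, 15–30 Å z;
`stage2`: 0–10 Å xy, −5–5 Å z; `stage3`: 10–25 Å xy, −30 to −20 Å z),
describing rim attachment, cavity residence and exit of a permeation
pathway. A window that misses the grid yields an empty profile and a
warning, not an error.

Basins are strict local minima of the profile (below zero under the
plateau/max reference). Because histogram noise creates single-bin dips,
`basin_barriers` takes a `min_depth` merge threshold: adjacent minima
separated by a barrier smaller than `min_depth` (measured from the
shallower minimum) merge into the deeper one. The barrier A→B is the
maximum free energy on the path between the basins minus F(A); barrier
search is 1D only — no 2D minimum-energy-path search.

## Synthetic generators (the testable ground truth)

The generators emulate the *statistics* of a pore-permeation study, not
its dynamics:

* `sample_boltzmann_mc` — single-particle Metropolis MC targeting
  exp(−U/RT), Gaussian proposals, 10% burn-in discarded. Metropolis was
  chosen over Langevin/Brownian dynamics deliberately: the analyses need
  correct stationary distributions, not kinetics, and Metropolis is the
  simplest sampler that is exactly correct. Potentials: harmonic,
  quartic double well (exact analytic barrier `h` at the midpoint, wells
  at ±a with U = 0), flat-in-a-box, and tabulated grids. 1D potentials
  embed on the x axis, 2D on (x, z).
* `run_replica_exchange` — parallel Metropolis chains on a temperature
  ladder (default 309–380 K, swap attempts every 1000 steps) with the
  standard swap criterion; per-pair acceptance ratios are reported and the
  lowest-temperature trajectory is tagged for analysis. The ladder
  validates non-decreasing temperatures so the degenerate equal-temperature
  pair (a useful identity test: acceptance exactly 1) remains expressible.
* `make_bilayer` — one PO4 bead per lipid at Normal(±24 Å, σ) plus a
  4-bead chain along a direction drawn from a von Mises–Fisher
  distribution about the inward normal. The vMF concentration κ maps to
  the order parameter through the closed form
  ⟨cos²θ⟩ = 1 + 2/κ² − 2coth(κ)/κ, inverted numerically (`kappa_for_order`)
  so a target ⟨P₂⟩ (e.g. 0.60, typical of lipids around a toroidal pore)
  can be dialed in exactly. Lateral positions are uniform at 65 Å² per
  lipid; there is no lipid–lipid interaction, no area fluctuation and no
  toroidal rim — the generator reproduces axial densities and order
  parameters, nothing else.
* `make_pore_assembly` — n dimer bead clouds (Gaussian laterally, uniform
  over the ring height, offsets recentred so dimer COMs are *exactly* at
  the n-gon vertices) with the vertex ring stretched along x by a factor
  ≥ 1; opposite-dimer pairing is by index offset n/2. An even dimer count
  is required.
* `place_cargo_replicas` — default 6 axial positions at 13 Å spacing
  centered on z = 0 × 8 uniformly random orientations (Shoemake-style
  random rotations via scipy) = 48 initial replicas. At the two axial
  positions nearest the pore mouths, orientations that clash with the
  pore (any bead pair < 3 Å) are re-rolled up to a retry cap.
* `add_ions` — counts from `round(c·N_A·V)`; Cl⁻ balances the cation
  charge exactly. Divalent cations can be enriched in slabs around the
  leaflet planes by a piecewise-constant axial density — a statistical
  emulation of divalent-headgroup association, not a mechanistic one.

Every generator is deterministic under a fixed seed. Because the
generators are statistical stand-ins, passing tests demonstrate that the
*analysis* code is correct on data with known ground truth; they say
nothing about force fields, kinetics, lipid self-assembly or any specific
biological system.

## Contacts and interface counts

Residue-residue contact = minimum bead-bead distance below the cutoff
(default 6.5 Å, minimum image), the standard definition at coarse-grained
bead resolution; temporal aggregation is the fraction of analysed frames
in contact. The production path uses a periodic cKDTree; tests pin it to
a naive O(N²) double loop, exactly.

On all-atom structures, interface counts use standard-literature geometric
criteria (configurable module constants): hydrogen bond = donor–acceptor
heavy-atom distance < 3.5 Å with donor-H⋯acceptor angle > 120° (hydrogens
are located by a < 1.25 Å attachment search; without hydrogens a
distance-only < 3.0 Å fallback applies, with a warning); salt bridge = any
Arg/Lys/His side-chain N within 4.0 Å of an Asp/Glu side-chain O, counted
once per residue pair; hydrophobic contact = side-chain carbon pairs of
hydrophobic residues < 5.0 Å, per residue pair. The energy split is a
diagnostic fixed-charge pairwise sum — Coulomb with ε_r = 1 (332.0636
kcal·Å/(mol·e²)) plus 12-6 Lennard-Jones with Lorentz–Berthelot combining,
over cross-group pairs within 12 Å, with user-supplied per-atom-name
parameters. It is not a force-field reimplementation: no PME/reaction
field, no polarisability, no exclusions.

## Membrane profiles

Axial densities are normalised z-histograms (default 1 Å bins). Peak
detection smooths with a 3-bin moving average and reports the two most
prominent peaks at least `min_separation` (default 10 Å) apart; membrane
thickness is their |z₊ − z₋|, absent when fewer than two peaks exist.
The chain vector is first-to-last chain bead per lipid; Pₓ is averaged
over lipids per frame and over frames for the trajectory mean.
Zero-length vectors are skipped with a warning. Per-carbon deuterium
order parameters and area-per-lipid are out of scope.

## Pore shape and surfaces

The shape coordinate Δd = max − min over opposite-dimer COM distances is
invariant under rigid motions and scales linearly with uniform scaling.
The cavity diameter is found by a 0.5 Å grid search for the widest empty
axis-centered cylinder, evaluated in the z = 0 slab only.

SASA uses Shrake–Rupley point counting on a golden-spiral point set
(deterministic for a fixed count, default 960 points): element-based
heavy-atom radii with a 1.4 Å probe for all-atom structures, a uniform
2.3 Å bead radius with a 2.6 Å probe (half a CG water-bead diameter) for
coarse-grained structures; both tables are configurable, and a missing
radius raises an error naming the particle type. Points exactly on a
neighbor surface count as buried, so coincident particles occlude each
other completely. The buried fraction of a component is
(SASA_isolated − SASA_in_complex)/SASA_isolated × 100. Surface-class
percentages on real proteins are approximate by construction — they
inherit the classification-table choices above.

## Back-mapping

Correspondence is one point per residue: CG backbone bead ↔ all-atom Cα
(backbone-atom mean when no Cα exists). Helix segments need ≥ 4 residues
for axis estimation; the axis is the leading principal component with the
sign fixed N→C. Rigid fits use least-squares superposition restricted to
proper rotations, so a mirrored target yields a positive residual rather
than an inverted helix. Loops between fitted segments are straight-line
Cα placeholders flagged in the B-factor column (0 = fitted, 1 =
placeholder); loop relaxation/minimisation is explicitly out of scope, as
is side-chain rebuilding. Segments omitted from the definitions are
simply not back-mapped, which also covers deliberately excluded domains.
A clash report lists fitted heavy-atom pairs closer than 2.0 Å.

## Pipeline and reproducibility

The pipeline validates its YAML config against a closed schema (unknown
keys or stage names are named in the error), seeds every generator from
one master seed, and writes CSV artifacts with a fixed float format plus
JSON artifacts carrying provenance (package version, config hash over the
scientific state, seed). Runs are byte-reproducible: the same seed and
parameters produce identical bytes in any output directory. The demo
system is intentionally small (96 lipids per leaflet, a 6-dimer ring of
16 Å radius, a 10-bead cargo on a 2 kcal/mol double well, ~200 frames) so
the full stage chain completes in seconds on one CPU; the acceptance-scale
landscape recovery uses 10⁶ Metropolis steps.

## Known limitations

* Orthorhombic boxes only; no triclinic minimum image.
* Histogram inversion needs converged sampling; unsampled bins carry the
  reference value, not an estimate, and no reweighting is attempted.
* The interface-energy split is diagnostic, not thermodynamic.
* The contact-matrix KDTree path wraps coordinates into the box; the
  definition is bead-bead minimum distance, not residue centers.
* GRO files carry 0.001 nm (0.01 Å) coordinate precision — round trips
  through GRO are exact only to that quantum, PDB to 0.001 Å.
* The generators share no thermostat/barostat/force-field machinery with
  real simulations; they validate analysis code, not simulation physics.
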