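# poremap

Trajectory analysis for protein-cargo permeation through oligomeric
membrane pores, at coarse-grained or all-atom resolution.

Simulations of a folded cargo (e.g. cytochrome c) escaping through a
membrane-embedded oligomeric pore (e.g. a Bax dimer ring) produce long
particle trajectories that must be reduced to a small set of physically
meaningful observables: a free-energy landscape over the permeation
coordinates, stage-wise potentials of mean force, residue-contact
statistics at the pore-cargo interface, membrane order and density
profiles, pore-shape metrics and surface-polarity decompositions, and —
for follow-up atomistic work — all-atom coordinates reconstructed from the
coarse-grained ensemble. `poremap` implements that analysis chain as a
tested Python library, together with a synthetic-trajectory generator that
provides *known* statistical ground truth (Boltzmann sampling under an
analytic potential, a bilayer with tunable order, a dimer ring with
controllable ellipticity) so every stage is verifiable without
microsecond-scale simulations.

## The core statistics

* **Free-energy landscape** over the permeation coordinates: with `P(xy, z)`
  the probability of finding the cargo center of mass at planar radial
  distance `xy` from the pore axis and axial distance `z` from the pore
  center, the landscape is the Boltzmann inversion
  `F(xy, z) = -RT ln P(xy, z)` (R = 1.987×10⁻³ kcal/(mol·K)), with the
  never-sampled plateau defining the zero of energy. 1D PMFs are obtained
  by marginalising `P` inside rectangular stage regions and inverting; basin
  and barrier heights are read off the profiles.
* **Chain order parameter** `Pₓ = ½(3 cos²τ − 1)`, τ the angle between a
  lipid chain vector and the membrane normal: 1 = perfectly aligned,
  0 = isotropic, −0.5 = in-plane.
* **Residue contacts**: residues are in contact in a frame when any
  inter-particle distance (minimum image) is below a cutoff (default 6.5 Å);
  contact matrices aggregate the fraction of frames in contact, and
  contacting pairs are classified by residue polarity.
* **Pore shape**: the shape-change coordinate `Δd` is the difference between
  the longest and shortest center-of-mass distance of opposite dimer pairs
  around the ring (0 for a regular polygon).
* **SASA decomposition**: Shrake–Rupley point counting on a deterministic
  golden-spiral point set, split into positive / negative / polar-uncharged
  / hydrophobic residue classes.
* **Back-mapping**: each coarse-grained helix segment's position and
  orientation is measured (centroid + principal axis) and an all-atom
  reference helix is placed by least-squares rigid superposition (Kabsch,
  proper rotations only); loops are emitted as flagged placeholders.
* **Replica exchange**: the synthetic sampler runs Metropolis Monte Carlo on
  a temperature ladder (default 309–380 K, swaps attempted every 1000 steps)
  with the swap criterion `min(1, exp[(1/RT_i − 1/RT_j)(U_i − U_j)])`.

## Worked example

Recover a known 3 kcal/mol barrier from Metropolis samples
(`examples/01_pmf_from_sampling.py`):

```python
from poremap import (PotentialSpec, sample_boltzmann_mc, bin_probability,
                     free_energy, pmf_1d, basin_barriers)

potential = PotentialSpec.double_well(barrier=3.0, well=10.0,
                                      k_transverse=0.1, ndim=2)
trajectory = sample_boltzmann_mc(potential, temperature=310.0,
                                 n_steps=500_000, step_size=1.2, seed=0)
grid = free_energy(bin_probability(trajectory, [0], ("xy", "z")),
                   reference="plateau")
profile = basin_barriers(pmf_1d(grid, "z")[0], min_depth=0.5)
```

prints

```
sampled frames: 450000
basin at z = -10.1 A, F = -5.41 kcal/mol
basin at z = +9.9 A, F = -5.35 kcal/mol
barrier between the wells: 2.96 kcal/mol (ground truth 3.0)
```

The sampler was driven by a double well with minima at z = ±10 Å and an
exact 3 kcal/mol barrier; the landscape module recovers both the basin
positions and the barrier from the positional histogram alone, which is the
consistency that `-RT ln P` inversion promises for converged sampling.
The other scripts in `examples/` cover replica exchange, membrane
profiles, contacts, pore shape/SASA, back-mapping and the end-to-end
pipeline (`poremap demo --seed 0 --outdir out` on the shell).

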