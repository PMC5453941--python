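"""Synthetic structures and trajectories with known statistical ground truth.

The generators emulate the study conditions of a replica-exchange simulation
of a protein cargo permeating an oligomeric membrane pore: Boltzmann-
distributed cargo positions under a known potential on a 309-380 K replica
ladder with swaps attempted every 1000 steps, a bilayer with headgroup
planes near +/-24 Angstrom and tunable chain tilt, a hexagonal ring of six
(or eight) dimer bead groups with controllable ellipticity, cargo replicas
placed at 13 Angstrom axial intervals with random orientations, and ions at
0.035 M with optional surface enrichment.  Every generator is deterministic
under a fixed seed, so each analysis stage admits parameter-recovery tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .model import Frame, R_KCAL, StructuralError, Topology, Trajectory

AVOGADRO = 6.02214076e23
#: Formal charges of supported ion species.
ION_CHARGES = {"NA": 1, "K": 1, "CA": 2, "MG": 2, "CL": -1}


# ---------------------------------------------------------------------------
# Potentials
# ---------------------------------------------------------------------------

@dataclass
class PotentialSpec:
    """A known potential energy surface U(x), kcal/mol, in 1-3 dimensions.

    Forms
    -----
    harmonic : ``U = 0.5 * sum_i k_i (x_i - c_i)^2``
    double_well : quartic double well along the last coordinate with wells at
        ``+/-well`` (U = 0 there) and an exact barrier ``barrier`` at 0;
        higher dimensions add harmonic transverse terms of stiffness
        ``k_transverse``.
    flat : zero inside the rectangular ``bounds``, infinite outside.
    tabulated : bilinear interpolation on a rectangular grid; infinite
        outside the grid.

    1D potentials live on the x axis, 2D on (x, z), 3D on (x, y, z) when
    embedded into particle coordinates.
    """

    form: str
    ndim: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ndim not in (1, 2, 3):
            raise ValueError("dimensionality must be 1, 2 or 3")
        if self.form == "tabulated":
            from scipy.interpolate import RegularGridInterpolator

            grids = self.params["grids"]
            values = np.asarray(self.params["values"], dtype=np.float64)
            if values.shape != tuple(len(g) for g in grids):
                raise ValueError("tabulated grid must be rectangular")
            if not np.all(np.isfinite(values)):
                raise ValueError("tabulated potential must be finite on its grid")
            self._interp = RegularGridInterpolator(
                grids, values, bounds_error=False, fill_value=np.inf
            )

    # -- constructors ------------------------------------------------------
    @classmethod
    def harmonic(cls, k: float | Sequence[float] = 1.0,
                 center: float | Sequence[float] = 0.0, ndim: int = 1) -> "PotentialSpec":
        k = np.broadcast_to(np.asarray(k, dtype=np.float64), (ndim,)).copy()
        center = np.broadcast_to(np.asarray(center, dtype=np.float64), (ndim,)).copy()
        return cls("harmonic", ndim, {"k": k, "center": center})

    @classmethod
    def double_well(cls, barrier: float = 3.0, well: float = 10.0,
                    k_transverse: float = 0.1, ndim: int = 1) -> "PotentialSpec":
        return cls("double_well", ndim,
                   {"barrier": float(barrier), "well": float(well),
                    "k_transverse": float(k_transverse)})

    @classmethod
    def flat(cls, bounds: Sequence[tuple[float, float]]) -> "PotentialSpec":
        lo = np.array([b[0] for b in bounds], dtype=np.float64)
        hi = np.array([b[1] for b in bounds], dtype=np.float64)
        return cls("flat", len(bounds), {"lo": lo, "hi": hi})

    @classmethod
    def tabulated(cls, grids: Sequence[np.ndarray], values: np.ndarray) -> "PotentialSpec":
        return cls("tabulated", len(grids), {"grids": tuple(grids), "values": values})

    # -- evaluation --------------------------------------------------------
    def energy(self, x: np.ndarray) -> np.ndarray:
        """Vectorised potential energy for points of shape (..., ndim)."""
        x = np.asarray(x, dtype=np.float64)
        if self.form == "harmonic":
            d = x - self.params["center"]
            return 0.5 * (self.params["k"] * d * d).sum(axis=-1)
        if self.form == "double_well":
            h, a = self.params["barrier"], self.params["well"]
            kt = self.params["k_transverse"]
            zz = x[..., -1]
            u = h * ((zz * zz - a * a) / (a * a)) ** 2
            if self.ndim > 1:
                u = u + 0.5 * kt * (x[..., :-1] ** 2).sum(axis=-1)
            return u
        if self.form == "flat":
            inside = np.all((x >= self.params["lo"]) & (x <= self.params["hi"]), axis=-1)
            return np.where(inside, 0.0, np.inf)
        if self.form == "tabulated":
            return self._interp(x)
        raise ValueError(f"unknown potential form {self.form!r}")

    def _scalar_energy_fn(self) -> Callable[[tuple], float]:
        """Fast pure-Python energy for the Metropolis inner loop."""
        if self.form == "harmonic":
            k = tuple(self.params["k"])
            c = tuple(self.params["center"])

            def u_harm(x):
                return 0.5 * sum(ki * (xi - ci) ** 2 for ki, xi, ci in zip(k, x, c))
            return u_harm
        if self.form == "double_well":
            h, a, kt = (self.params["barrier"], self.params["well"],
                        self.params["k_transverse"])
            a2 = a * a

            def u_dw(x):
                z = x[-1]
                u = h * ((z * z - a2) / a2) ** 2
                for xi in x[:-1]:
                    u += 0.5 * kt * xi * xi
                return u
            return u_dw
        if self.form == "flat":
            lo, hi = tuple(self.params["lo"]), tuple(self.params["hi"])

            def u_flat(x):
                for xi, l, h_ in zip(x, lo, hi):
                    if xi < l or xi > h_:
                        return math.inf
                return 0.0
            return u_flat
        interp = self._interp

        def u_tab(x):
            return float(interp(np.asarray(x)))
        return u_tab


_AXIS_EMBED = {1: (0,), 2: (0, 2), 3: (0, 1, 2)}


def _embed(samples: np.ndarray, ndim: int) -> np.ndarray:
    """Embed d-dimensional MC samples into 3D coordinates (1D->x, 2D->(x,z))."""
    coords = np.zeros((samples.shape[0], 3))
    coords[:, list(_AXIS_EMBED[ndim])] = samples
    return coords


def _single_particle_topology(tag: str = "cargo") -> Topology:
    return Topology(names=["BB"], residue_indices=[1], residue_names=["GLY"],
                    group_tags=tag)


# ---------------------------------------------------------------------------
# Metropolis Monte Carlo and replica exchange
# ---------------------------------------------------------------------------

def sample_boltzmann_mc(
    potential: PotentialSpec,
    temperature: float = 310.0,
    n_steps: int = 100_000,
    step_size: float = 1.0,
    seed: int = 0,
    x0: Sequence[float] | None = None,
    burn_in: float = 0.1,
) -> Trajectory:
    """Metropolis chain targeting exp(-U/RT); returns a one-particle trajectory.

    Gaussian displacement proposals of width ``step_size`` per coordinate;
    the first ``burn_in`` fraction of the chain is discarded.  Deterministic
    for a fixed seed.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    samples, _ = _mc_chain(potential, temperature, n_steps, step_size,
                           np.random.default_rng(seed), x0)
    keep = samples[int(burn_in * n_steps):]
    traj = Trajectory(
        _single_particle_topology(),
        _embed(keep, potential.ndim)[:, None, :],
        np.array([1e4, 1e4, 1e4]),
        np.arange(keep.shape[0], dtype=np.float64),
        temperature,
    )
    return traj


def _mc_chain(potential, temperature, n_steps, step_size, rng, x0,
              state=None):
    """Run a Metropolis chain; returns (samples, final_state)."""
    d = potential.ndim
    u_fn = potential._scalar_energy_fn()
    if state is None:
        x = (0.0,) * d if x0 is None else tuple(float(v) for v in x0)
        u = u_fn(x)
        if not math.isfinite(u):
            raise ValueError("potential is not finite at the starting point")
    else:
        x, u = state
    steps = rng.normal(0.0, step_size, size=(n_steps, d))
    logu = np.log(rng.random(n_steps))
    rt = R_KCAL * temperature
    out = np.empty((n_steps, d))
    for i in range(n_steps):
        prop = tuple(xi + si for xi, si in zip(x, steps[i]))
        u_new = u_fn(prop)
        if u_new <= u or (u_new - u) < -rt * logu[i]:
            x, u = prop, u_new
        out[i] = x
    return out, (x, u)


@dataclass
class ReplicaLadder:
    """Temperature ladder for replica exchange.

    Defaults mirror the study setup: temperatures spanning 309-380 K and
    swap attempts every 1000 integration steps.  Temperatures must be
    non-decreasing with at least two entries; a ladder collapsed onto a
    single distinct temperature with fewer than two replicas is rejected.
    """

    temperatures: Sequence[float] = field(
        default_factory=lambda: tuple(np.linspace(309.0, 380.0, 8)))
    swap_interval: int = 1000
    seed: int = 0

    def __post_init__(self):
        temps = np.asarray(self.temperatures, dtype=np.float64)
        if temps.size < 2:
            raise ValueError("degenerate ladder: need at least two replicas")
        if np.any(np.diff(temps) < 0):
            raise ValueError("ladder temperatures must be non-decreasing")
        if np.any(temps <= 0):
            raise ValueError("temperatures must be positive")
        self.temperatures = temps


@dataclass
class ReplicaExchangeResult:
    """Per-temperature trajectories plus neighbor-swap acceptance statistics."""

    trajectories: list[Trajectory]
    swap_attempts: dict[tuple[int, int], int]
    swap_accepts: dict[tuple[int, int], int]

    @property
    def acceptance(self) -> dict[tuple[int, int], float]:
        return {p: (self.swap_accepts[p] / a if a else float("nan"))
                for p, a in self.swap_attempts.items()}

    @property
    def analysis_trajectory(self) -> Trajectory:
        """The lowest-temperature trajectory (the one analysed downstream)."""
        return self.trajectories[0]


def run_replica_exchange(
    potential: PotentialSpec,
    ladder: ReplicaLadder,
    n_steps: int = 100_000,
    step_size: float = 1.0,
    seed: int | None = None,
    burn_in: float = 0.1,
) -> ReplicaExchangeResult:
    """Replica-exchange Metropolis MC on a temperature ladder.

    Neighbor swaps are attempted every ``ladder.swap_interval`` steps with
    the Metropolis criterion ``min(1, exp[(1/RT_i - 1/RT_j)(U_i - U_j)])``;
    per-pair acceptance ratios are reported.  Trajectories are returned per
    temperature slot (ascending); the lowest-temperature one is tagged as
    the analysis trajectory.
    """
    seed = ladder.seed if seed is None else seed
    temps = ladder.temperatures
    n_rep = len(temps)
    rng = np.random.default_rng(seed)
    betas = 1.0 / (R_KCAL * temps)
    states = [None] * n_rep
    chunks: list[list[np.ndarray]] = [[] for _ in range(n_rep)]
    attempts = {(i, i + 1): 0 for i in range(n_rep - 1)}
    accepts = {(i, i + 1): 0 for i in range(n_rep - 1)}
    done = 0
    while done < n_steps:
        chunk = min(ladder.swap_interval, n_steps - done)
        for r in range(n_rep):
            samples, states[r] = _mc_chain(
                potential, temps[r], chunk, step_size, rng, None, states[r])
            chunks[r].append(samples)
        done += chunk
        if done >= n_steps:
            break
        for i in range(n_rep - 1):
            ui, uj = states[i][1], states[i + 1][1]
            delta = (betas[i] - betas[i + 1]) * (ui - uj)
            attempts[(i, i + 1)] += 1
            if delta >= 0 or rng.random() < math.exp(delta):
                accepts[(i, i + 1)] += 1
                states[i], states[i + 1] = states[i + 1], states[i]
    top = _single_particle_topology()
    trajectories = []
    for r in range(n_rep):
        samples = np.concatenate(chunks[r])
        keep = samples[int(burn_in * n_steps):]
        trajectories.append(Trajectory(
            top, _embed(keep, potential.ndim)[:, None, :],
            np.array([1e4, 1e4, 1e4]),
            np.arange(keep.shape[0], dtype=np.float64), temps[r]))
    return ReplicaExchangeResult(trajectories, attempts, accepts)


# ---------------------------------------------------------------------------
# Bilayer
# ---------------------------------------------------------------------------

def _vmf_cos(rng: np.ndarray, kappa: float, n: int) -> np.ndarray:
    """Sample cos(theta) of a von Mises-Fisher distribution about the pole."""
    if np.isinf(kappa):
        return np.ones(n)
    if kappa == 0:
        return rng.uniform(-1.0, 1.0, n)
    u = rng.random(n)
    # inverse-CDF for the vMF polar angle on S^2
    return 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa


def sample_vmf(rng, kappa: float, n: int, mu: np.ndarray) -> np.ndarray:
    """Unit vectors from a von Mises-Fisher distribution with mean ``mu``."""
    w = _vmf_cos(rng, kappa, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(np.clip(1.0 - w * w, 0.0, None))
    vecs = np.column_stack([s * np.cos(phi), s * np.sin(phi), w])
    mu = np.asarray(mu, dtype=np.float64)
    mu = mu / np.linalg.norm(mu)
    if np.allclose(mu, [0, 0, 1]):
        return vecs
    if np.allclose(mu, [0, 0, -1]):
        return vecs * np.array([1.0, 1.0, -1.0])
    rot, _ = Rotation.align_vectors([mu], [[0.0, 0.0, 1.0]])
    return vecs @ rot.as_matrix().T


def vmf_mean_cos2(kappa: float) -> float:
    """Closed-form <cos^2 theta> of the vMF polar angle on the sphere."""
    if np.isinf(kappa):
        return 1.0
    if kappa < 1e-8:
        return 1.0 / 3.0
    if kappa > 20:  # coth(k) ~ 1 to double precision
        return 1.0 + 2.0 / kappa**2 - 2.0 / kappa
    coth = 1.0 / np.tanh(kappa)
    return 1.0 + 2.0 / kappa**2 - 2.0 * coth / kappa


def kappa_for_order(p2_target: float) -> float:
    """Invert <P2>(kappa) = 0.5(3<cos^2> - 1) for the vMF concentration."""
    if not -0.5 < p2_target < 1.0:
        raise ValueError("target order parameter must be in (-0.5, 1)")
    if p2_target <= 0.0:
        raise ValueError("only aligned targets (P2 > 0) are invertible for kappa")

    def f(k):
        return 0.5 * (3.0 * vmf_mean_cos2(k) - 1.0) - p2_target
    return brentq(f, 1e-6, 1e6)


def make_bilayer(
    n_lipids_per_leaflet: int = 128,
    headgroup_z: float = 24.0,
    z_sigma: float = 1.0,
    tilt_kappa: float = 20.0,
    seed: int = 0,
    area_per_lipid: float = 65.0,
    n_chain_beads: int = 4,
    chain_spacing: float = 4.7,
) -> tuple[Topology, Frame]:
    """Coarse-grained bilayer with PO4 headgroup planes near ``+/-headgroup_z``.

    Each lipid is one PO4 bead (z drawn as Normal(+/-headgroup_z, z_sigma))
    followed by ``n_chain_beads`` chain beads along a direction drawn from a
    von Mises-Fisher distribution about the inward membrane normal with
    concentration ``tilt_kappa`` (inf = perfectly aligned, 0 = isotropic).
    The lateral box edge is set by the area per lipid.
    """
    if n_lipids_per_leaflet < 1:
        raise ValueError("need at least one lipid per leaflet")
    rng = np.random.default_rng(seed)
    n = 2 * n_lipids_per_leaflet
    box_xy = math.sqrt(n_lipids_per_leaflet * area_per_lipid)
    box = np.array([box_xy, box_xy, 4.0 * headgroup_z + 40.0])
    names, resids, resnames, chains = [], [], [], []
    coords = []
    resid = 0
    for leaflet, sign in (("upper", 1.0), ("lower", -1.0)):
        xy = rng.uniform(0.0, box_xy, size=(n_lipids_per_leaflet, 2))
        z = sign * headgroup_z + rng.normal(0.0, z_sigma, n_lipids_per_leaflet)
        # chains point from the headgroup toward the bilayer midplane
        dirs = sample_vmf(rng, tilt_kappa, n_lipids_per_leaflet,
                          np.array([0.0, 0.0, -sign]))
        for i in range(n_lipids_per_leaflet):
            resid += 1
            head = np.array([xy[i, 0], xy[i, 1], z[i]])
            beads = [head] + [head + (j + 1) * chain_spacing * dirs[i]
                              for j in range(n_chain_beads)]
            coords.extend(beads)
            names.extend(["PO4"] + [f"C{j+1}A" for j in range(n_chain_beads)])
            resids.extend([resid] * (n_chain_beads + 1))
            resnames.extend(["DSPC"] * (n_chain_beads + 1))
            chains.extend(["L" if sign > 0 else "M"] * (n_chain_beads + 1))
    top = Topology(names, resids, resnames, chains, group_tags="lipid")
    frame = Frame(np.asarray(coords), box)
    return top, frame


def lipid_chain_pairs(topology: Topology) -> list[tuple[int, int]]:
    """(first, last) chain-bead index per lipid residue, for order parameters."""
    pairs = []
    lipid_idx = topology.select(group="lipid")
    by_res: dict[tuple, list[int]] = {}
    for i in lipid_idx:
        key = (str(topology.chain_ids[i]), int(topology.residue_indices[i]))
        by_res.setdefault(key, []).append(int(i))
    for idx in by_res.values():
        chain_beads = [i for i in idx if not str(topology.names[i]).startswith("PO4")]
        if len(chain_beads) >= 2:
            pairs.append((chain_beads[0], chain_beads[-1]))
    return pairs


# ---------------------------------------------------------------------------
# Pore assembly, cargo placement, ions
# ---------------------------------------------------------------------------

_PORE_RESNAME_CYCLE = ("LYS", "GLU", "SER", "LEU")


def make_pore_assembly(
    n_dimers: int = 6,
    ring_radius: float = 24.0,
    stretch: float = 1.0,
    beads_per_dimer: int = 12,
    seed: int = 0,
    height: float = 24.0,
) -> tuple[Topology, Frame]:
    """Ring of dimer bead groups at regular n-gon vertices, stretched along x.

    Dimer centers of mass sit exactly at ``(stretch * R cos t_i, R sin t_i, 0)``
    with ``t_i = 2 pi i / n`` (bead offsets are recentered so the COM is
    exact); ``dimer_assignments`` maps labels 1..n to bead indices.  An even
    dimer count is required so opposite-vertex pairs exist.
    """
    if n_dimers % 2 != 0:
        raise ValueError("n_dimers must be even so opposite-vertex pairs exist")
    if stretch < 1.0:
        raise ValueError("stretch must be >= 1")
    rng = np.random.default_rng(seed)
    angles = 2.0 * np.pi * np.arange(n_dimers) / n_dimers
    coms = np.column_stack([
        stretch * ring_radius * np.cos(angles),
        ring_radius * np.sin(angles),
        np.zeros(n_dimers),
    ])
    names, resids, resnames, chains, coords = [], [], [], [], []
    assignments: dict[int, list[int]] = {}
    resid = 0
    for d in range(n_dimers):
        offsets = np.column_stack([
            rng.normal(0.0, 2.0, beads_per_dimer),
            rng.normal(0.0, 2.0, beads_per_dimer),
            rng.uniform(-height / 2.0, height / 2.0, beads_per_dimer),
        ])
        offsets -= offsets.mean(axis=0)  # exact dimer COM at the vertex
        beads = coms[d] + offsets
        start = len(coords)
        coords.extend(beads)
        assignments[d + 1] = list(range(start, start + beads_per_dimer))
        for b in range(beads_per_dimer):
            resid += 1
            names.append("BB")
            resids.append(resid)
            resnames.append(_PORE_RESNAME_CYCLE[b % len(_PORE_RESNAME_CYCLE)])
            chains.append(chr(ord("A") + d))
    side = 2.0 * stretch * ring_radius + 60.0
    top = Topology(names, resids, resnames, chains, group_tags="pore",
                   dimer_assignments=assignments)
    frame = Frame(np.asarray(coords), np.array([side, side, 2.0 * height + 80.0]))
    return top, frame


@dataclass
class PlacementScheme:
    """Initial cargo replica placement: axial ladder x random orientations.

    Defaults mirror the study setup: six axial positions at 13 Angstrom
    intervals, eight random orientations each (48 replicas in total).
    """

    n_axial_positions: int = 6
    axial_spacing: float = 13.0
    n_orientations: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.axial_spacing <= 0:
            raise ValueError("axial spacing must be positive")
        if self.n_axial_positions < 1 or self.n_orientations < 1:
            raise ValueError("counts must be >= 1")


class PlacementError(RuntimeError):
    """Raised when clash-free cargo placement cannot be found."""


def place_cargo_replicas(
    cargo_frame: Frame,
    scheme: PlacementScheme,
    pore_frame: Frame | None = None,
    clearance: float = 3.0,
    max_retries: int = 100,
) -> list[Frame]:
    """Initial frames for cargo replicas along the pore axis.

    Produces ``n_axial_positions * n_orientations`` frames (axial-position
    major): the cargo COM is placed at axial positions spaced by
    ``axial_spacing`` and centered on z = 0, with a uniformly random
    orientation each.  At the two axial positions nearest the pore mouths a
    clash check against ``pore_frame`` (min distance < ``clearance``)
    triggers an orientation re-roll, up to ``max_retries``.
    """
    coords = cargo_frame.coordinates
    if coords.shape[0] == 0:
        raise ValueError("cargo structure is empty")
    rng = np.random.default_rng(scheme.seed)
    centered = coords - coords.mean(axis=0)
    n = scheme.n_axial_positions
    z_positions = (np.arange(n) - (n - 1) / 2.0) * scheme.axial_spacing
    check_positions: set[int] = set()
    if pore_frame is not None and pore_frame.coordinates.size:
        half = np.ptp(pore_frame.coordinates[:, 2]) / 2.0
        for mouth_z in (-half, half):
            check_positions.add(int(np.argmin(np.abs(z_positions - mouth_z))))
    frames = []
    for k, zk in enumerate(z_positions):
        for _ in range(scheme.n_orientations):
            for attempt in range(max_retries + 1):
                rot = Rotation.random(random_state=rng)
                placed = centered @ rot.as_matrix().T + np.array([0.0, 0.0, zk])
                if k not in check_positions or pore_frame is None:
                    break
                d2 = ((placed[:, None, :] - pore_frame.coordinates[None, :, :]) ** 2
                      ).sum(axis=-1)
                if d2.min() >= clearance**2:
                    break
            else:
                raise PlacementError(
                    f"could not place cargo without clashes at z={zk:.1f} "
                    f"after {max_retries} retries"
                )
            frames.append(Frame(placed, cargo_frame.box.copy(), time=0.0))
    return frames


def add_ions(
    topology: Topology | None,
    frame: Frame,
    concentrations: Mapping[str, float] = None,
    surface_enrichment: float = 1.0,
    seed: int = 0,
    leaflet_z: float = 24.0,
    slab_halfwidth: float = 5.0,
) -> tuple[Topology, Frame]:
    """Add ions at given molar concentrations; chloride balances the charge.

    Counts follow ``round(c * N_A * V)``.  Divalent cations (Ca, Mg) are
    placed with axial density enhanced by ``surface_enrichment`` inside
    slabs of half-width ``slab_halfwidth`` around ``+/-leaflet_z`` (a
    statistical emulation of surface association, not a mechanistic one).
    The returned system has zero net ion charge.
    """
    if concentrations is None:
        concentrations = {"NA": 0.035, "CA": 0.035}
    box = frame.box
    volume_l = float(np.prod(box)) * 1e-27  # Angstrom^3 -> liter
    if volume_l <= 0:
        raise ValueError("box volume must be positive")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    for species, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {species}")
        sp = species.upper()
        if sp not in ION_CHARGES:
            raise ValueError(f"unsupported ion species {species!r}")
        counts[sp] = int(round(conc * AVOGADRO * volume_l))
    positive = sum(c * ION_CHARGES[s] for s, c in counts.items() if ION_CHARGES[s] > 0)
    counts["CL"] = counts.get("CL", 0) + positive

    names, resids, resnames, coords = [], [], [], []
    resid0 = int(topology.residue_indices.max()) if topology is not None and len(topology) else 0
    resid = resid0
    for species, count in counts.items():
        if count == 0:
            continue
        xy = rng.uniform(0.0, box[:2], size=(count, 2))
        if ION_CHARGES[species] == 2 and surface_enrichment != 1.0:
            z = _enriched_z(rng, count, box[2], leaflet_z, slab_halfwidth,
                            surface_enrichment)
        else:
            z = rng.uniform(-box[2] / 2.0, box[2] / 2.0, count)
        for i in range(count):
            resid += 1
            names.append(species)
            resids.append(resid)
            resnames.append(species)
            coords.append([xy[i, 0], xy[i, 1], z[i]])
    ion_top = Topology(names, resids, resnames, ["I"] * len(names),
                       group_tags="ion")
    ion_coords = np.asarray(coords).reshape(-1, 3)
    if topology is None:
        return ion_top, Frame(ion_coords, box.copy())
    combined = Topology.concatenate([topology, ion_top])
    return combined, Frame(np.vstack([frame.coordinates, ion_coords]), box.copy())


def _enriched_z(rng, n, box_z, leaflet_z, halfwidth, factor):
    """Piecewise-constant axial density with weight ``factor`` in the slabs."""
    lo, hi = -box_z / 2.0, box_z / 2.0
    edges = np.array([lo, -leaflet_z - halfwidth, -leaflet_z + halfwidth,
                      leaflet_z - halfwidth, leaflet_z + halfwidth, hi])
    widths = np.diff(edges)
    weights = np.array([1.0, factor, 1.0, factor, 1.0]) * widths
    probs = weights / weights.sum()
    seg = rng.choice(5, size=n, p=probs)
    return edges[seg] + rng.random(n) * widths[seg]


def ion_charge(topology: Topology) -> int:
    """Net formal charge of all ion particles in a topology."""
    total = 0
    for i in topology.select(group="ion"):
        total += ION_CHARGES.get(str(topology.names[i]).upper(), 0)
    return total


# ---------------------------------------------------------------------------
# Simple structural fixtures
# ---------------------------------------------------------------------------

def make_helix(
    n_residues: int = 16,
    rise: float = 1.5,
    twist_deg: float = 100.0,
    radius: float = 2.3,
    resname: str = "ALA",
    chain_id: str = "A",
    name: str = "CA",
    start_resid: int = 1,
) -> tuple[Topology, Frame]:
    """Ideal alpha-helix C-alpha trace along +z (one particle per residue)."""
    if n_residues < 4:
        raise ValueError("a helix needs at least 4 residues")
    t = np.deg2rad(twist_deg) * np.arange(n_residues)
    coords = np.column_stack([radius * np.cos(t), radius * np.sin(t),
                              rise * np.arange(n_residues)])
    coords -= coords.mean(axis=0)
    top = Topology(
        names=[name] * n_residues,
        residue_indices=np.arange(start_resid, start_resid + n_residues),
        residue_names=[resname] * n_residues,
        chain_ids=[chain_id] * n_residues,
        group_tags="protein",
    )
    return top, Frame(coords, np.array([200.0, 200.0, 200.0]))
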