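"""Config-driven orchestration of all analysis stages.

A run takes a validated :class:`RunConfig` (typically loaded from a YAML
file), generates or loads its input system, executes the requested stages
and writes CSV/JSON artifacts plus a log into the output directory.  All
randomness is seeded, so a given config reproduces its outputs
byte-identically.  Every JSON artifact carries provenance metadata (config
hash, package version, seed).

Config schema (YAML)::

    seed: 0                # master seed for all generators
    outdir: out            # output directory
    stages: [simulate, landscape, contacts, membrane, shape, surface, backmap]
    params:                # optional per-stage parameter overrides
      simulate: {n_lipids_per_leaflet: 48, n_steps: 20000, ...}
      landscape: {bin_widths: [2.0, 2.0], reference: plateau}
      contacts: {cutoff: 6.5}
      membrane: {bin_width: 1.0}
      shape: {probe_step: 0.5}
      surface: {n_points: 240}

Unknown top-level keys or stage names fail validation with the offending
keys named.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import contact_matrix, contact_number_profiles, polarity_contact_fractions
from .geometry import recenter, rg_rmsd_series
from .io import write_structure, write_trajectory
from .landscape import STAGE_REGIONS, basin_barriers, bin_probability, free_energy, pmf_1d
from .membrane import axial_density, chain_order_parameter, profile_peaks
from .model import Frame, Topology, Trajectory
from .backmap import (FragmentLibrary, SegmentDefinition, backmap_assembly,
                      coarse_grain_backbone)
from .shape import cavity_diameter, pore_ellipticity, sasa, surface_decomposition
from .synth import (PotentialSpec, add_ions, kappa_for_order, lipid_chain_pairs,
                    make_bilayer, make_helix, make_pore_assembly,
                    sample_boltzmann_mc)

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "landscape", "contacts", "membrane", "shape",
              "surface", "backmap")

_FLOAT_FMT = "%.6f"


class ConfigError(ValueError):
    """Raised when a run configuration violates the schema."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    outdir: str = "poremap_out"
    stages: tuple[str, ...] = ALL_STAGES
    params: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        allowed = {"seed", "outdir", "stages", "params"}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        stages = tuple(data.get("stages", ALL_STAGES))
        bad = [s for s in stages if s not in ALL_STAGES]
        if bad:
            raise ConfigError(f"unknown stages: {bad} (valid: {list(ALL_STAGES)})")
        params = data.get("params", {}) or {}
        bad_stage_params = [s for s in params if s not in ALL_STAGES]
        if bad_stage_params:
            raise ConfigError(f"params given for unknown stages: {bad_stage_params}")
        return cls(seed=int(data.get("seed", 0)),
                   outdir=str(data.get("outdir", "poremap_out")),
                   stages=stages, params=params)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "outdir": self.outdir,
                "stages": list(self.stages), "params": self.params}

    def sha256(self) -> str:
        # hash only scientific state, so identical analyses written to
        # different directories produce byte-identical artifacts
        state = {"seed": self.seed, "stages": list(self.stages),
                 "params": self.params}
        return hashlib.sha256(
            json.dumps(state, sort_keys=True).encode()).hexdigest()


@dataclass
class DemoSystem:
    """Bundled end-to-end synthetic fixture (pore + bilayer + cargo + ions)."""

    topology: Topology
    trajectory: Trajectory
    pore_selection: np.ndarray
    cargo_selection: np.ndarray
    po4_selection: np.ndarray
    chain_pairs: list[tuple[int, int]]


def generate_demo(
    seed: int = 0,
    n_lipids_per_leaflet: int = 96,
    n_dimers: int = 6,
    ring_radius: float = 16.0,
    beads_per_dimer: int = 10,
    n_steps: int = 20000,
    thin: int = 100,
    barrier: float = 2.0,
    well: float = 15.0,
) -> DemoSystem:
    """Self-contained toy permeation system exercising every analysis stage.

    A static hexagonal pore ring sits in a static bilayer; a small cargo
    moves according to Metropolis samples of a known 2D double-well
    potential over (x, z), so the landscape stage has an analytic ground
    truth.  Ions are added at 0.035 M with divalent surface enrichment.
    Deterministic under a fixed seed.
    """
    pore_top, pore_frame = make_pore_assembly(
        n_dimers=n_dimers, ring_radius=ring_radius, stretch=1.05,
        beads_per_dimer=beads_per_dimer, seed=seed)
    kappa = kappa_for_order(0.60)
    bil_top, bil_frame = make_bilayer(
        n_lipids_per_leaflet=n_lipids_per_leaflet, headgroup_z=24.0,
        z_sigma=1.0, tilt_kappa=kappa, seed=seed + 1)
    cargo_top, cargo_frame = make_helix(10, resname="LYS", chain_id="X")
    cargo_top.retag(np.arange(len(cargo_top)), "cargo")

    box = np.array([bil_frame.box[0], bil_frame.box[1], 140.0])
    # center the bilayer laterally on the pore axis
    bil_coords = bil_frame.coordinates - np.array(
        [bil_frame.box[0] / 2.0, bil_frame.box[1] / 2.0, 0.0])

    ion_top, ion_frame = add_ions(None, Frame(bil_coords, box),
                                  {"NA": 0.035, "CA": 0.035},
                                  surface_enrichment=3.0, seed=seed + 2)

    combined = Topology.concatenate([pore_top, cargo_top, bil_top, ion_top])
    combined.dimer_assignments = {
        k: np.asarray(v) for k, v in pore_top.dimer_assignments.items()}

    pot = PotentialSpec.double_well(barrier=barrier, well=well,
                                    k_transverse=0.05, ndim=2)
    mc = sample_boltzmann_mc(pot, 310.0, n_steps=n_steps, step_size=1.5,
                             seed=seed + 3)
    samples = mc.coordinates[::thin, 0, :]  # (x, 0, z) per frame

    cargo_centered = cargo_frame.coordinates - cargo_frame.coordinates.mean(axis=0)
    n_frames = samples.shape[0]
    n_total = len(combined)
    coords = np.empty((n_frames, n_total, 3))
    n_pore, n_cargo = len(pore_top), len(cargo_top)
    static = np.vstack([bil_coords, ion_frame.coordinates])
    for f in range(n_frames):
        coords[f, :n_pore] = pore_frame.coordinates
        coords[f, n_pore:n_pore + n_cargo] = cargo_centered + samples[f]
        coords[f, n_pore + n_cargo:] = static
    traj = Trajectory(combined, coords, box,
                      np.arange(n_frames, dtype=np.float64), 310.0)
    return DemoSystem(
        topology=combined,
        trajectory=traj,
        pore_selection=combined.select(group="pore"),
        cargo_selection=combined.select(group="cargo"),
        po4_selection=combined.select(group="lipid", name="PO4"),
        chain_pairs=lipid_chain_pairs(combined),
    )


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = dict(payload)
    payload["provenance"] = {
        "poremap_version": __version__,
        "config_sha256": config.sha256(),
        "seed": config.seed,
    }
    path.write_text(json.dumps(payload, sort_keys=True, indent=2,
                               default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run(config: RunConfig) -> Path:
    """Execute the configured stages; returns the output directory.

    A stage failure aborts the run with the stage name; outputs of earlier
    stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("poremap")
    root.addHandler(handler)
    try:
        _run_stages(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()
    return outdir


def _run_stages(config: RunConfig, outdir: Path) -> None:
    p = config.params
    demo = generate_demo(seed=config.seed, **p.get("simulate", {}))
    traj = recenter(demo.trajectory, demo.pore_selection, demo.po4_selection)
    current = None
    try:
        for stage in config.stages:
            current = stage
            logger.info("running stage %s", stage)
            globals()[f"_stage_{stage}"](config, outdir, demo, traj)
    except Exception as exc:
        raise RuntimeError(f"stage {current!r} failed: {exc}") from exc


def _stage_simulate(config, outdir, demo, traj):
    write_structure(demo.topology, traj.frame(0), outdir / "system.gro")
    write_trajectory(traj, outdir / "trajectory.traj")
    series = rg_rmsd_series(traj, demo.cargo_selection, 0)
    series.to_csv(outdir / "rg_rmsd_cargo.csv", index=False,
                  float_format=_FLOAT_FMT)
    _write_json(outdir / "simulate.json", {
        "n_frames": len(traj),
        "n_particles": len(demo.topology),
        "temperature_K": traj.temperature,
    }, config)


def _stage_landscape(config, outdir, demo, traj):
    p = config.params.get("landscape", {})
    grid = bin_probability(traj, demo.cargo_selection, ("xy", "z"),
                           bin_widths=tuple(p.get("bin_widths", (2.0, 2.0))))
    grid = free_energy(grid, reference=p.get("reference", "plateau"))
    cx, cz = grid.centers
    rows = []
    for i, x in enumerate(cx):
        for j, z in enumerate(cz):
            rows.append((x, z, grid.counts[i, j], grid.probability[i, j],
                         grid.free_energy[i, j], int(grid.unsampled[i, j])))
    pd.DataFrame(rows, columns=["xy", "z", "count", "P", "F", "unsampled"]).to_csv(
        outdir / "landscape_xy_z.csv", index=False, float_format=_FLOAT_FMT)
    profiles = pmf_1d(grid, "z") + [
        pr for pr in pmf_1d(grid, "z", STAGE_REGIONS)
        if pr.centers.size and np.isfinite(pr.free_energy).any()]
    pmf_rows = []
    basins_payload = {}
    for prof in profiles:
        basin_barriers(prof, min_depth=p.get("basin_min_depth", 0.5))
        name = prof.region or "full"
        for c, fval, cnt in zip(prof.centers, prof.free_energy, prof.counts):
            pmf_rows.append((name, c, fval, cnt))
        basins_payload[name] = {
            "basin_z": [float(prof.centers[b]) for b in prof.basins],
            "basin_F": [float(prof.free_energy[b]) for b in prof.basins],
            "barriers": {f"{a}->{b}": v for (a, b), v in prof.barriers.items()},
        }
    pd.DataFrame(pmf_rows, columns=["region", "z", "F", "count"]).to_csv(
        outdir / "pmf_z.csv", index=False, float_format=_FLOAT_FMT)
    _write_json(outdir / "basins.json", {
        "temperature_K": grid.temperature,
        "reference": grid.reference,
        "profiles": basins_payload}, config)


def _stage_contacts(config, outdir, demo, traj):
    p = config.params.get("contacts", {})
    cm = contact_matrix(traj, demo.pore_selection, demo.cargo_selection,
                        cutoff=p.get("cutoff", 6.5))
    cm.to_frame().to_csv(outdir / "contact_matrix.csv", float_format=_FLOAT_FMT)
    prof_a, prof_b = contact_number_profiles(cm)
    prof_a.to_csv(outdir / "contact_profile_pore.csv", float_format=_FLOAT_FMT)
    prof_b.to_csv(outdir / "contact_profile_cargo.csv", float_format=_FLOAT_FMT)
    fractions = polarity_contact_fractions(cm, demo.topology)
    _write_json(outdir / "contact_fractions.json", {
        "cutoff_A": cm.cutoff, "n_frames": cm.n_frames,
        "percent": fractions}, config)


def _stage_membrane(config, outdir, demo, traj):
    p = config.params.get("membrane", {})
    prof = axial_density(traj, demo.po4_selection,
                         bin_width=p.get("bin_width", 1.0))
    prof.to_frame().to_csv(outdir / "po4_density.csv", index=False,
                           float_format=_FLOAT_FMT)
    peaks, thickness = profile_peaks(prof)
    mean_px, series = chain_order_parameter(traj, demo.chain_pairs)
    series.to_csv(outdir / "order_parameter.csv", header=True,
                  float_format=_FLOAT_FMT)
    _write_json(outdir / "membrane.json", {
        "po4_peaks_z": peaks,
        "thickness_A": thickness,
        "mean_Px": mean_px}, config)


def _stage_shape(config, outdir, demo, traj):
    p = config.params.get("shape", {})
    dimers = demo.topology.dimer_assignments
    values = [pore_ellipticity(traj.frame(i), dimers) for i in range(len(traj))]
    pd.DataFrame({"time": traj.times, "ellipticity": values}).to_csv(
        outdir / "ellipticity.csv", index=False, float_format=_FLOAT_FMT)
    diameter = cavity_diameter(traj.frame(0), demo.pore_selection,
                               probe_step=p.get("probe_step", 0.5))
    _write_json(outdir / "shape.json", {
        "cavity_diameter_A": diameter,
        "mean_ellipticity_A": float(np.mean(values))}, config)


def _stage_surface(config, outdir, demo, traj):
    p = config.params.get("surface", {})
    n_points = p.get("n_points", 240)
    sel = np.concatenate([demo.pore_selection, demo.cargo_selection])
    per_res = sasa(demo.topology, traj.frame(0), mode="cg",
                   n_points=n_points, selection=sel)
    per_res.to_csv(outdir / "sasa_per_residue.csv", index=False,
                   float_format=_FLOAT_FMT)
    decomp = surface_decomposition(per_res, demo.topology)
    _write_json(outdir / "surface.json", {
        "total_A2": decomp.total,
        "areas_A2": decomp.areas,
        "fractions": decomp.fractions,
        "hydrophilic_fraction": decomp.hydrophilic_fraction}, config)


def _stage_backmap(config, outdir, demo, traj):
    # two-helix toy round trip: forward-map a known all-atom pair, back-map it
    top1, fr1 = make_helix(12, resname="ALA", chain_id="A", start_resid=1)
    top2, fr2 = make_helix(12, resname="ALA", chain_id="A", start_resid=17)
    fr2 = Frame(fr2.coordinates + np.array([12.0, 0.0, 0.0]), fr2.box)
    aa_top = Topology.concatenate([top1, top2])
    aa_frame = Frame(np.vstack([fr1.coordinates, fr2.coordinates]), fr1.box)
    cg_top, cg_frame = coarse_grain_backbone(aa_top, aa_frame)
    library = FragmentLibrary({"h1": (top1, fr1), "h2": (top2, fr2)})
    segs = [SegmentDefinition("A", 1, 12, "h1"), SegmentDefinition("A", 17, 28, "h2")]
    out_top, out_frame, report = backmap_assembly(cg_top, cg_frame, segs, library)
    write_structure(out_top, out_frame, outdir / "backmapped.pdb",
                    b_factors=getattr(out_frame, "b_factors", None))
    _write_json(outdir / "backmap.json", {
        "segment_rmsd_A": report.segment_rmsd,
        "n_placeholder_residues": len(report.placeholder_residues),
        "n_clashes": len(report.clashes)}, config)
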