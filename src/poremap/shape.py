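"""Pore-shape metrics and solvent-accessible surface area (SASA) analysis.

The pore-shape reaction coordinate is the ellipticity of the dimer ring:
the difference between the longest and shortest center-of-mass distance of
opposite dimer pairs around the ring (0 for a regular polygon).  SASA is
computed by Shrake-Rupley point counting on a deterministic golden-spiral
point set, decomposed per residue and per polarity class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import Frame, PolarityClass, Topology

#: Heavy-atom van der Waals radii (Angstrom) for all-atom structures.
AA_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "FE": 1.80, "ZN": 1.39,
    "NA": 2.27, "K": 2.75, "CA": 2.31, "MG": 1.73,
}
#: Uniform bead radius and probe radius for coarse-grained structures
#: (half a CG water-bead diameter as the probe), Angstrom.
CG_BEAD_RADIUS = 2.3
CG_PROBE_RADIUS = 2.6
AA_PROBE_RADIUS = 1.4

HYDROPHILIC_CLASSES = (
    PolarityClass.POSITIVE, PolarityClass.NEGATIVE, PolarityClass.POLAR_UNCHARGED,
)


class PairingError(ValueError):
    """Raised when opposite-dimer pairing is impossible (odd dimer count)."""


class RadiusError(KeyError):
    """Raised when no van der Waals radius is available for a particle type."""


def pore_ellipticity(frame: Frame, dimer_assignments: Mapping[int, Sequence[int]]) -> float:
    """Shape-change coordinate: max minus min opposite-dimer COM distance, Angstrom.

    Dimers are paired by index offset n/2 around the ring (label i with
    label i + n/2); the value is 0 for a regular polygon and grows with the
    deformation of the ring toward an ellipse.  Invariant to rigid motions.
    """
    labels = sorted(dimer_assignments)
    n = len(labels)
    if n % 2 != 0 or n == 0:
        raise PairingError("opposite-dimer pairing requires an even dimer count")
    coms = {
        lab: frame.coordinates[np.asarray(dimer_assignments[lab], dtype=np.int64)]
        .mean(axis=0)
        for lab in labels
    }
    dists = [
        float(np.linalg.norm(coms[labels[i]] - coms[labels[i + n // 2]]))
        for i in range(n // 2)
    ]
    return float(max(dists) - min(dists))


def cavity_diameter(
    frame: Frame,
    pore_selection: Sequence[int],
    probe_step: float = 0.5,
    slab_halfwidth: float | None = None,
) -> float:
    """Diameter of the largest empty axis-centered cylinder at z = 0, Angstrom.

    Grid search in steps of ``probe_step``: the radius is the largest
    multiple of the step such that no pore bead center lies within the
    cylinder.  ``slab_halfwidth`` restricts the beads considered to
    |z| <= halfwidth (None = all beads).
    """
    sel = np.asarray(pore_selection, dtype=np.int64)
    if sel.size == 0:
        raise ValueError("empty pore selection")
    coords = frame.coordinates[sel]
    if slab_halfwidth is not None:
        coords = coords[np.abs(coords[:, 2]) <= slab_halfwidth]
        if coords.shape[0] == 0:
            raise ValueError("no pore beads inside the z = 0 slab")
    radial = np.hypot(coords[:, 0], coords[:, 1])
    r_max = np.floor(radial.min() / probe_step + 1e-9) * probe_step
    return float(2.0 * r_max)


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set (golden spiral)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(1.0 - z * z)
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _particle_radii(
    topology: Topology,
    mode: str,
    radii_table: Mapping[str, float] | None,
) -> np.ndarray:
    if mode == "cg":
        base = radii_table or {}
        return np.array([
            float(base.get(str(n).upper(), CG_BEAD_RADIUS)) for n in topology.names
        ])
    from .io import _guess_element

    table = dict(AA_RADII)
    if radii_table:
        table.update({k.upper(): v for k, v in radii_table.items()})
    radii = np.empty(len(topology))
    for i, (name, resname) in enumerate(zip(topology.names, topology.residue_names)):
        elem = _guess_element(str(name), str(resname)).upper()
        if elem not in table:
            raise RadiusError(
                f"no van der Waals radius for particle {name!r} (element {elem!r})"
            )
        radii[i] = table[elem]
    return radii


def atom_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float,
    n_points: int = 960,
) -> np.ndarray:
    """Per-particle Shrake-Rupley SASA, Angstrom^2 (deterministic point set)."""
    coords = np.asarray(coords, dtype=np.float64)
    radii = np.asarray(radii, dtype=np.float64)
    n = coords.shape[0]
    sphere = golden_spiral_points(n_points)
    ext = radii + probe_radius
    tree = cKDTree(coords)
    max_reach = 2.0 * ext.max()
    areas = np.empty(n)
    for i in range(n):
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        pts = coords[i] + ext[i] * sphere
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbors:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            # points exactly on a neighbor surface count as buried
            accessible &= d2 > ext[j] ** 2 * (1.0 + 1e-12)
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * accessible.mean()
    return areas


def sasa(
    topology: Topology,
    frame: Frame,
    mode: str = "aa",
    radii_table: Mapping[str, float] | None = None,
    probe_radius: float | None = None,
    n_points: int = 960,
    selection: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Per-residue solvent-accessible surface areas.

    ``mode='aa'`` uses an element-based heavy-atom radius table and a 1.4
    Angstrom probe; ``mode='cg'`` uses a uniform 2.3 Angstrom bead radius
    and a 2.6 Angstrom probe (half a CG water-bead diameter).  Returns a
    DataFrame with columns ``chain, resid, resname, area``.
    """
    if mode not in ("aa", "cg"):
        raise ValueError("mode must be 'aa' or 'cg'")
    if probe_radius is None:
        probe_radius = AA_PROBE_RADIUS if mode == "aa" else CG_PROBE_RADIUS
    idx = np.arange(len(topology)) if selection is None else \
        np.asarray(selection, dtype=np.int64)
    sub = topology.subset(idx)
    radii = _particle_radii(sub, mode, radii_table)
    areas = atom_sasa(frame.coordinates[idx], radii, probe_radius, n_points)
    df = pd.DataFrame({
        "chain": [str(c) for c in sub.chain_ids],
        "resid": sub.residue_indices,
        "resname": [str(r) for r in sub.residue_names],
        "area": areas,
    })
    out = (df.groupby(["chain", "resid", "resname"], sort=False)["area"]
             .sum().reset_index())
    return out


@dataclass
class SurfaceDecomposition:
    """SASA split into the four polarity classes, with fractions summing to 1."""

    total: float
    areas: dict[str, float]
    fractions: dict[str, float]
    probe_radius: float

    @property
    def hydrophilic_fraction(self) -> float:
        return sum(self.fractions[c.value] for c in HYDROPHILIC_CLASSES)


def surface_decomposition(
    per_residue_sasa: pd.DataFrame,
    topology: Topology,
    probe_radius: float = AA_PROBE_RADIUS,
) -> SurfaceDecomposition:
    """Aggregate per-residue SASA into the four polarity classes.

    Residue polarity comes from the topology's populated classes; the
    hydrophilic fraction is the sum of the positive, negative and
    polar-uncharged fractions.
    """
    class_of: dict[tuple, PolarityClass] = {}
    for i in range(len(topology)):
        key = (str(topology.chain_ids[i]), int(topology.residue_indices[i]),
               str(topology.residue_names[i]))
        class_of.setdefault(key, topology.polarity[i])
    areas = {c.value: 0.0 for c in PolarityClass}
    for _, row in per_residue_sasa.iterrows():
        key = (row["chain"], int(row["resid"]), row["resname"])
        cls = class_of.get(key)
        if cls is None:  # residue not in topology: classify by name
            from .model import classify_residue

            cls = classify_residue(row["resname"])
        areas[cls.value] += float(row["area"])
    total = sum(areas.values())
    fractions = {k: (v / total if total > 0 else 0.0) for k, v in areas.items()}
    return SurfaceDecomposition(total, areas, fractions, probe_radius)


def buried_fraction(
    topology: Topology,
    frame: Frame,
    component_selection: Sequence[int],
    mode: str = "aa",
    **sasa_kwargs,
) -> float:
    """Percentage of a component's SASA buried by the rest of the complex.

    ``(SASA_isolated - SASA_in_complex) / SASA_isolated * 100`` over the
    component's particles.
    """
    comp = np.asarray(component_selection, dtype=np.int64)
    if comp.size == 0:
        raise ValueError("empty component selection")
    probe = sasa_kwargs.pop("probe_radius", None)
    if probe is None:
        probe = AA_PROBE_RADIUS if mode == "aa" else CG_PROBE_RADIUS
    n_points = sasa_kwargs.pop("n_points", 960)
    radii_table = sasa_kwargs.pop("radii_table", None)
    radii_all = _particle_radii(topology, mode, radii_table)
    complex_areas = atom_sasa(frame.coordinates, radii_all, probe, n_points)
    in_complex = complex_areas[comp].sum()
    isolated = atom_sasa(frame.coordinates[comp], radii_all[comp], probe,
                         n_points).sum()
    if isolated <= 0:
        raise ValueError("component has zero isolated SASA")
    return float((isolated - in_complex) / isolated * 100.0)
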