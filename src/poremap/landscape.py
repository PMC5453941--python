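"""Free-energy landscapes by Boltzmann inversion of positional histograms.

A 2D probability histogram P over two reaction coordinates — the planar
radial distance of the cargo center of mass from the pore axis ("xy"), the
axial distance along the pore axis ("z"), or the pore-shape coordinate
("shape", the ellipticity of the dimer ring) — is inverted to a free energy
F = -RT ln P (kcal/mol).  Under the plateau reference convention,
never-sampled bins define the zero of energy, so sampled bins carry
non-positive free energies; this matches landscapes whose flat, unsampled
rim is drawn at zero.  The 2D landscape can be decomposed into 1D PMF
profiles over named stage regions, and basins/barriers extracted from the
profiles.

No multi-temperature reweighting (WHAM/MBAR) is performed: analysis targets
a single-temperature trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .model import R_KCAL, Trajectory
from .shape import pore_ellipticity


@dataclass(frozen=True)
class RegionSpec:
    """A rectangular stage window in the (xy, z) plane, Angstrom.

    The shipped defaults name the three permeation stages: attachment to
    the outer rim (stage1), residence in the inner cavity (stage2) and exit
    at the far opening (stage3).
    """

    name: str
    xy_range: tuple[float, float]
    z_range: tuple[float, float]

    def __post_init__(self):
        if self.xy_range[0] >= self.xy_range[1] or self.z_range[0] >= self.z_range[1]:
            raise ValueError("region ranges must be non-degenerate")


#: The three permeation-stage regions (Angstrom).
STAGE_REGIONS: tuple[RegionSpec, ...] = (
    RegionSpec("stage1", (25.0, 40.0), (15.0, 30.0)),
    RegionSpec("stage2", (0.0, 10.0), (-5.0, 5.0)),
    RegionSpec("stage3", (10.0, 25.0), (-30.0, -20.0)),
)


@dataclass
class LandscapeGrid:
    """Binned probability (and optionally free energy) over two coordinates."""

    coord_names: tuple[str, str]
    edges: tuple[np.ndarray, np.ndarray]
    counts: np.ndarray
    probability: np.ndarray
    temperature: float
    free_energy: np.ndarray | None = None
    reference: str | None = None
    unsampled: np.ndarray | None = None

    @property
    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        return tuple(0.5 * (e[1:] + e[:-1]) for e in self.edges)


@dataclass
class PMFProfile:
    """1D potential of mean force along one coordinate (kcal/mol)."""

    axis: str
    centers: np.ndarray
    free_energy: np.ndarray
    counts: np.ndarray
    region: str | None = None
    reference: str | None = None
    basins: list[int] = field(default_factory=list)
    barriers: dict[tuple[int, int], float] = field(default_factory=dict)


_DEFAULT_BIN_WIDTHS = {"xy": 2.0, "z": 2.0, "shape": 1.0}


def _coordinate_series(
    trajectory: Trajectory,
    cargo_selection: Sequence[int],
    coord: str,
) -> np.ndarray:
    """Per-frame reaction-coordinate values for the cargo center of mass."""
    sel = np.asarray(cargo_selection, dtype=np.int64)
    com = trajectory.coordinates[:, sel, :].mean(axis=1)
    if coord == "xy":
        return np.hypot(com[:, 0], com[:, 1])
    if coord == "z":
        return com[:, 2]
    if coord == "shape":
        dimers = trajectory.topology.dimer_assignments
        if not dimers:
            raise ValueError("'shape' coordinate needs dimer_assignments on the topology")
        return np.array([
            pore_ellipticity(trajectory.frame(i), dimers)
            for i in range(len(trajectory))
        ])
    raise ValueError(f"unknown coordinate {coord!r} (use 'xy', 'z' or 'shape')")


def bin_probability(
    trajectory: Trajectory,
    cargo_selection: Sequence[int],
    coords: tuple[str, str] = ("xy", "z"),
    bin_widths: tuple[float, float] | None = None,
    ranges: tuple[tuple[float, float], tuple[float, float]] | None = None,
) -> LandscapeGrid:
    """Normalized 2D positional histogram of the cargo COM (pore-centered).

    Default bin widths: 2 Angstrom for xy and z, 1 Angstrom for the shape
    coordinate.
    """
    if len(trajectory) == 0:
        raise ValueError("empty trajectory")
    values = [_coordinate_series(trajectory, cargo_selection, c) for c in coords]
    widths = tuple(
        _DEFAULT_BIN_WIDTHS.get(c, 2.0) for c in coords
    ) if bin_widths is None else bin_widths
    edges = []
    for v, w, i in zip(values, widths, range(2)):
        if ranges is not None and ranges[i] is not None:
            lo, hi = ranges[i]
        else:
            lo, hi = float(np.min(v)), float(np.max(v))
            hi = lo + w if hi <= lo else hi
        nbins = max(1, int(np.ceil((hi - lo) / w)))
        edges.append(lo + w * np.arange(nbins + 1))
    counts, _, _ = np.histogram2d(values[0], values[1], bins=edges)
    prob = counts / counts.sum()
    return LandscapeGrid(
        coord_names=tuple(coords),
        edges=(edges[0], edges[1]),
        counts=counts,
        probability=prob,
        temperature=trajectory.temperature,
    )


def free_energy(
    grid: LandscapeGrid,
    temperature: float | None = None,
    reference: str = "plateau",
) -> LandscapeGrid:
    """Boltzmann inversion F = -RT ln P with a zero-reference convention.

    reference:
      * ``plateau`` — never-sampled bins define F = 0 (they are flagged in
        ``grid.unsampled``); occupied bins are shifted so the least-sampled
        occupied bin sits just below zero, hence F <= 0 where sampled.
      * ``max_F`` — the highest occupied-bin free energy is the zero.
      * ``global_min`` — the most-populated bin is the zero.
    """
    t = grid.temperature if temperature is None else temperature
    if t is None or t <= 0:
        raise ValueError("temperature must be positive")
    if reference not in ("plateau", "max_F", "global_min"):
        raise ValueError(f"unknown reference convention {reference!r}")
    p = grid.probability
    occupied = p > 0
    if not occupied.any():
        raise ValueError("grid has no occupied bins")
    rt = R_KCAL * t
    f = np.full_like(p, np.nan, dtype=np.float64)
    with np.errstate(divide="ignore"):
        f[occupied] = -rt * np.log(p[occupied])
    if reference in ("plateau", "max_F"):
        shift = np.nanmax(f[occupied])
    else:
        shift = np.nanmin(f[occupied])
    f[occupied] -= shift
    unsampled = ~occupied
    if reference == "plateau":
        f[unsampled] = 0.0
    return LandscapeGrid(
        coord_names=grid.coord_names,
        edges=grid.edges,
        counts=grid.counts,
        probability=p,
        temperature=t,
        free_energy=f,
        reference=reference,
        unsampled=unsampled,
    )


def pmf_1d(
    grid: LandscapeGrid,
    axis: str,
    regions: Sequence[RegionSpec] | None = None,
) -> list[PMFProfile]:
    """1D PMFs along ``axis``, one per stage region (or one over the whole grid).

    Probability is marginalized over the other coordinate restricted to each
    region's window, renormalized within the window and inverted with the
    grid's reference convention (plateau/max_F: profile maximum at zero).
    A region that misses the grid yields an empty profile with a warning.
    """
    if axis not in grid.coord_names:
        raise ValueError(f"axis {axis!r} not in grid coordinates {grid.coord_names}")
    ax = grid.coord_names.index(axis)
    other = 1 - ax
    t = grid.temperature
    rt = R_KCAL * t
    reference = grid.reference or "plateau"
    centers = grid.centers
    profiles: list[PMFProfile] = []
    if regions is None:
        region_list: Sequence = [None]
    else:
        region_list = regions
    for region in region_list:
        mask_ax = np.ones(centers[ax].size, dtype=bool)
        mask_other = np.ones(centers[other].size, dtype=bool)
        name = None
        if region is not None:
            name = region.name
            win = {"xy": region.xy_range, "z": region.z_range}
            if grid.coord_names[ax] in win:
                lo, hi = win[grid.coord_names[ax]]
                mask_ax = (centers[ax] >= lo) & (centers[ax] <= hi)
            if grid.coord_names[other] in win:
                lo, hi = win[grid.coord_names[other]]
                mask_other = (centers[other] >= lo) & (centers[other] <= hi)
        if not mask_ax.any() or not mask_other.any():
            warnings.warn(f"region {name!r} lies outside the landscape grid")
            profiles.append(PMFProfile(axis, np.array([]), np.array([]),
                                       np.array([]), region=name,
                                       reference=reference))
            continue
        sub = grid.counts[np.ix_(mask_ax, mask_other)] if ax == 0 else \
            grid.counts[np.ix_(mask_other, mask_ax)].T
        marg = sub.sum(axis=1)
        total = marg.sum()
        f = np.full(marg.shape, np.nan)
        if total > 0:
            p = marg / total
            occ = p > 0
            with np.errstate(divide="ignore"):
                f[occ] = -rt * np.log(p[occ])
            shift = np.nanmax(f[occ]) if reference in ("plateau", "max_F") \
                else np.nanmin(f[occ])
            f[occ] -= shift
        profiles.append(PMFProfile(
            axis, centers[ax][mask_ax], f, marg, region=name,
            reference=reference))
    return profiles


def basin_barriers(profile: PMFProfile, min_depth: float = 0.0) -> PMFProfile:
    """Locate basins (local minima) and inter-basin barrier heights.

    A basin is a finite local minimum of the profile (below the zero
    reference when the profile uses a plateau/maximum reference).  Adjacent
    minima whose separating barrier, measured from the shallower minimum,
    is below ``min_depth`` (kcal/mol) are merged into the deeper one —
    this prunes single-bin noise dips in histogram-derived profiles.  The
    barrier from basin A to basin B is the maximum free energy on the 1D
    path between them minus F(A); barriers are reported for every ordered
    basin pair.  The input profile is returned with ``basins`` (bin
    indices, ordered along the axis) and ``barriers`` filled in.
    """
    f = profile.free_energy
    finite = np.isfinite(f)
    if not finite.any():
        raise ValueError("profile has no finite bins")
    idx = np.flatnonzero(finite)
    fv = f[idx]
    basins: list[int] = []
    for j in range(fv.size):
        left = fv[j - 1] if j > 0 else np.inf
        right = fv[j + 1] if j < fv.size - 1 else np.inf
        if fv[j] < left and fv[j] < right:
            if profile.reference in ("plateau", "max_F") and fv[j] >= 0:
                continue
            basins.append(int(idx[j]))
    # merge basins separated by barriers shallower than min_depth
    merged = True
    while merged and min_depth > 0 and len(basins) > 1:
        merged = False
        for k in range(len(basins) - 1):
            a, b = basins[k], basins[k + 1]
            saddle = np.nanmax(f[min(a, b):max(a, b) + 1])
            if saddle - max(f[a], f[b]) < min_depth:
                basins.pop(k if f[a] > f[b] else k + 1)
                merged = True
                break
    barriers: dict[tuple[int, int], float] = {}
    for a in basins:
        for b in basins:
            if a == b:
                continue
            lo, hi = sorted((a, b))
            path = f[lo:hi + 1]
            barrier = float(np.nanmax(path) - f[a])
            barriers[(a, b)] = max(barrier, 0.0)
    profile.basins = basins
    profile.barriers = barriers
    return profile
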