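"""Pore-centered coordinate framing and global structural metrics (Rg, RMSD).

The pore frame puts the pore's xy center of mass at the origin and the
bilayer midplane (mean of the two leaflet PO4-plane means) at z = 0, so that
the axial coordinate z measures the distance of the cargo to the pore center
along the pore axis.  Minimum-image conventions apply to orthorhombic boxes
only; triclinic boxes are rejected at the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .model import Frame, SelectionError, StructuralError, Trajectory


def minimum_image(vectors: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap displacement vectors into the minimum-image convention."""
    box = np.asarray(box, dtype=np.float64)
    return vectors - box * np.round(vectors / box)


def wrapped_com(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Mass-unweighted center of mass robust to periodic wrapping.

    Two passes: a circular mean per axis locates the cluster center, then
    the minimum-image displacements about that center are averaged.  A
    group split across a periodic boundary therefore gets exactly the COM
    of its unwrapped copy, for any cluster narrower than half the box
    about its own center (single-anchor unwrapping would already fail for
    clusters wider than half the box, such as a pore ring in a tight
    membrane patch).  The circular mean itself is reliable for clusters
    extending to less than ~0.38 of the box length from their center.
    """
    box = np.asarray(box, dtype=np.float64)
    theta = 2.0 * np.pi * coords / box
    center = box / (2.0 * np.pi) * np.arctan2(
        np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0))
    disp = minimum_image(coords - center, box)
    com = center + disp.mean(axis=0)
    # report the periodic image closest to the input coordinates, so that
    # unwrapped (out-of-box) data keeps its affine relation to the COM
    return com + box * np.round((coords.mean(axis=0) - com) / box)


@dataclass(frozen=True)
class PoreFrameTransform:
    """Translation into the pore frame: subtract ``origin`` (axis is +z)."""

    origin: np.ndarray
    axis: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=np.float64))
        axis = np.array([0.0, 0.0, 1.0]) if self.axis is None else np.asarray(self.axis)
        object.__setattr__(self, "axis", axis / np.linalg.norm(axis))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords - self.origin


def pore_frame_transform(
    frame: Frame,
    pore_selection: Sequence[int],
    leaflet_selection: Sequence[int],
) -> PoreFrameTransform:
    """Compute the pore-centered transform for one frame.

    The leaflet selection (PO4 beads of both leaflets) is split into upper
    and lower leaflets about the pore COM z; the new z origin is the mean of
    the two per-leaflet plane means, which places headgroup planes at
    symmetric +/- positions.
    """
    pore_selection = np.asarray(pore_selection, dtype=np.int64)
    leaflet_selection = np.asarray(leaflet_selection, dtype=np.int64)
    if pore_selection.size == 0 or leaflet_selection.size == 0:
        raise SelectionError("pore and leaflet selections must be non-empty")
    com = wrapped_com(frame.coordinates[pore_selection], frame.box)
    leaf = frame.coordinates[leaflet_selection]
    # z of leaflet beads measured relative to the pore COM, minimum image
    dz = minimum_image(leaf - com, frame.box)[:, 2]
    upper, lower = dz[dz >= 0], dz[dz < 0]
    if upper.size and lower.size:
        z_mid = com[2] + 0.5 * (upper.mean() + lower.mean())
    else:  # single-leaflet selection: fall back to its plane
        z_mid = com[2] + dz.mean()
    return PoreFrameTransform(origin=np.array([com[0], com[1], z_mid]))


def recenter(
    trajectory: Trajectory,
    pore_selection: Sequence[int],
    leaflet_selection: Sequence[int],
) -> Trajectory:
    """Return a pore-centered copy of the trajectory.

    Per frame, the pore xy-COM is moved to the origin and z = 0 is placed at
    the bilayer midplane.  Idempotent: recentering an already centered
    trajectory is the identity to numerical precision.
    """
    out = trajectory.copy()
    for i in range(len(out)):
        t = pore_frame_transform(out.frame(i), pore_selection, leaflet_selection)
        out.coordinates[i] = t.apply(out.coordinates[i])
    return out


def radius_of_gyration(coords: np.ndarray) -> float:
    """Mass-unweighted radius of gyration (all particles weighted equally)."""
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt((centered**2).sum(axis=1).mean()))


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition (Kabsch) of ``mobile`` onto ``reference``.

    Returns ``(rotation_matrix, translation, rmsd)`` such that
    ``mobile @ R.T + t`` best fits the reference in the least-squares sense.
    Only proper rotations are produced (no reflections).
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape:
        raise StructuralError(
            f"selection size mismatch: mobile {mobile.shape[0]} vs "
            f"reference {reference.shape[0]} particles"
        )
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - cr, mobile - cm)
    rmsd = rssd / np.sqrt(mobile.shape[0])
    rmat = rot.as_matrix()
    translation = cr - cm @ rmat.T
    return rmat, translation, float(rmsd)


def rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """RMSD (Angstrom) after optimal rigid superposition."""
    return superpose(mobile, reference)[2]


def rg_rmsd_series(
    trajectory: Trajectory,
    selection: Sequence[int],
    reference_frame: Frame | int = 0,
) -> pd.DataFrame:
    """Per-frame radius of gyration and RMSD to a reference.

    RMSD is computed after optimal rigid superposition of the selected
    particles; Rg weights all selected particles equally.  Returns a
    DataFrame with columns ``time, rg, rmsd``.
    """
    sel = np.asarray(selection, dtype=np.int64)
    if sel.size == 0:
        raise SelectionError("empty selection")
    if isinstance(reference_frame, int):
        reference_frame = trajectory.frame(reference_frame)
    ref = reference_frame.coordinates
    ref = ref[sel] if ref.shape[0] == trajectory.coordinates.shape[1] else ref
    if ref.shape[0] != sel.size:
        raise StructuralError(
            f"reference has {ref.shape[0]} particles, selection has {sel.size}"
        )
    rows = []
    for i in range(len(trajectory)):
        coords = trajectory.coordinates[i, sel]
        rows.append((trajectory.times[i], radius_of_gyration(coords), rmsd(coords, ref)))
    return pd.DataFrame(rows, columns=["time", "rg", "rmsd"])


def rmsd_matrix(
    trajectory: Trajectory,
    selection: Sequence[int],
    stride: int = 1,
) -> np.ndarray:
    """Symmetric frame-by-frame RMSD matrix (after superposition), Angstrom."""
    sel = np.asarray(selection, dtype=np.int64)
    if sel.size == 0:
        raise SelectionError("empty selection")
    idx = np.arange(0, len(trajectory), stride)
    if idx.size < 2:
        raise StructuralError("need at least two frames after striding")
    coords = [trajectory.coordinates[i, sel] for i in idx]
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = rmsd(coords[i], coords[j])
    return mat
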