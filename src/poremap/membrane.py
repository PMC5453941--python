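"""Axial density profiles and the second-rank lipid chain order parameter.

Density profiles are normalized z-histograms of a selection (lipid PO4
headgroups, ion species) in the pore-centered frame; peak detection uses a
3-bin moving average and reports the peak-to-peak membrane thickness.  The
order parameter is Px = 0.5 (3 cos^2 tau - 1), where tau is the angle
between a lipid chain vector (first to last chain bead) and the membrane
normal: 1 for perfectly aligned chains, 0 for an isotropic distribution,
-0.5 for chains lying in the membrane plane.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .model import SelectionError, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class AxialProfile:
    """Normalized density along z (one species), integrating to 1."""

    centers: np.ndarray
    density: np.ndarray
    bin_width: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z": self.centers, "density": self.density})


def axial_density(
    trajectory: Trajectory,
    selection: Sequence[int],
    bin_width: float = 1.0,
    z_range: tuple[float, float] | None = None,
) -> AxialProfile:
    """Probability density of selected particles along z, over all frames."""
    sel = np.asarray(selection, dtype=np.int64)
    if sel.size == 0:
        raise SelectionError("empty selection")
    z = trajectory.coordinates[:, sel, 2].ravel()
    if z_range is None:
        lo, hi = float(z.min()), float(z.max())
        hi = lo + bin_width if hi <= lo else hi
    else:
        lo, hi = z_range
    nbins = max(1, int(np.ceil((hi - lo) / bin_width)))
    edges = lo + bin_width * np.arange(nbins + 1)
    density, _ = np.histogram(z, bins=edges, density=True)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return AxialProfile(centers, density, bin_width)


def profile_peaks(
    profile: AxialProfile,
    min_separation: float = 10.0,
) -> tuple[np.ndarray, float | None]:
    """Peak z-positions (after 3-bin smoothing) and peak-to-peak thickness.

    The two dominant peaks (highest smoothed density, at least
    ``min_separation`` Angstrom apart) define the implied membrane
    thickness |z+ - z-|; with fewer than two peaks the thickness is None.
    """
    d = profile.density
    if d.size == 0:
        raise ValueError("empty profile")
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(d, kernel, mode="same") if d.size >= 3 else d.copy()
    distance = max(1, int(round(min_separation / profile.bin_width)))
    idx, props = find_peaks(smooth, distance=distance)
    if idx.size == 0 and d.size:
        idx = np.array([int(np.argmax(smooth))])
    peaks_z = profile.centers[idx]
    if idx.size < 2:
        return peaks_z, None
    top2 = idx[np.argsort(smooth[idx])[-2:]]
    z_a, z_b = profile.centers[top2]
    return peaks_z, float(abs(z_a - z_b))


def chain_order_parameter(
    trajectory: Trajectory,
    chain_pairs: Sequence[tuple[int, int]],
    normal: Sequence[float] = (0.0, 0.0, 1.0),
) -> tuple[float, pd.Series]:
    """Mean second-rank order parameter Px and its per-frame series.

    ``chain_pairs`` gives (first, last) chain-bead indices per lipid (see
    :func:`poremap.synth.lipid_chain_pairs`); Px is averaged over lipids in
    each frame, and the trajectory mean over frames is returned first.
    Zero-length chain vectors are skipped with a logged warning.
    """
    if not chain_pairs:
        raise SelectionError("no lipid chain vectors given")
    n_hat = np.asarray(normal, dtype=np.float64)
    n_hat = n_hat / np.linalg.norm(n_hat)
    first = np.array([p[0] for p in chain_pairs], dtype=np.int64)
    last = np.array([p[1] for p in chain_pairs], dtype=np.int64)
    per_frame = np.empty(len(trajectory))
    warned = False
    for fi in range(len(trajectory)):
        vec = trajectory.coordinates[fi, last] - trajectory.coordinates[fi, first]
        norms = np.linalg.norm(vec, axis=1)
        ok = norms > 0
        if not ok.all() and not warned:
            logger.warning("skipping %d zero-length lipid chain vectors",
                           int((~ok).sum()))
            warned = True
        cos_tau = (vec[ok] @ n_hat) / norms[ok]
        per_frame[fi] = float(np.mean(0.5 * (3.0 * cos_tau**2 - 1.0)))
    series = pd.Series(per_frame, index=trajectory.times, name="Px")
    return float(per_frame.mean()), series
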