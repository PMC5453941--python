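"""Residue-level interface statistics between two particle groups.

Two residues are in contact in a frame when their minimum inter-particle
distance (minimum image) is below a cutoff, 6.5 Angstrom by default — a
standard choice at coarse-grained bead resolution.  Contacts are aggregated
over frames as the fraction of analyzed frames in contact.  On all-atom
structures, hydrogen bonds, salt bridges and hydrophobic contacts are
counted with standard-literature geometric criteria, and a fixed-charge
pairwise Coulomb/Lennard-Jones split gives a diagnostic interaction-energy
decomposition (not a force-field reimplementation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import minimum_image
from .model import Frame, PolarityClass, SelectionError, Topology, Trajectory
from .shape import HYDROPHILIC_CLASSES

logger = logging.getLogger(__name__)

#: Coulomb constant in kcal/mol * Angstrom / e^2.
COULOMB_KCAL = 332.0636

HBOND_DISTANCE = 3.5        # donor-acceptor heavy-atom cutoff, Angstrom
HBOND_ANGLE = 120.0         # minimum donor-H...acceptor angle, degrees
HBOND_FALLBACK_DISTANCE = 3.0  # distance-only criterion without hydrogens
SALT_BRIDGE_DISTANCE = 4.0
HYDROPHOBIC_DISTANCE = 5.0
ENERGY_CUTOFF = 12.0

_BASIC_SIDECHAIN_N = {
    "ARG": {"NE", "NH1", "NH2"},
    "LYS": {"NZ"},
    "HIS": {"ND1", "NE2"},
}
_ACIDIC_SIDECHAIN_O = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
}
_HYDROPHOBIC_RESIDUES = {"ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET"}
_BACKBONE_ATOMS = {"N", "CA", "C", "O", "H", "HA", "HN", "OXT"}


@dataclass
class ContactMatrix:
    """Residue-by-residue contact frequencies between two groups.

    ``values[i, j]`` is the fraction of analyzed frames in which residue
    ``row_keys[i]`` (group A) and ``col_keys[j]`` (group B) were in contact.
    """

    row_keys: list[tuple]
    col_keys: list[tuple]
    values: np.ndarray
    cutoff: float
    n_frames: int

    def to_frame(self) -> pd.DataFrame:
        labels = lambda keys: [f"{c}:{r}:{n}" for c, r, n in keys]
        return pd.DataFrame(self.values, index=labels(self.row_keys),
                            columns=labels(self.col_keys))

    def transpose(self) -> "ContactMatrix":
        return ContactMatrix(self.col_keys, self.row_keys, self.values.T.copy(),
                             self.cutoff, self.n_frames)


@dataclass
class InterfaceCounts:
    """Per-structure interface counts and pairwise energy split."""

    h_bonds: float
    salt_bridges: float
    hydrophobic_contacts: float
    elec_energy: float
    vdw_energy: float

    @property
    def electrostatic_share(self) -> float:
        """Fraction of the total attraction carried by electrostatics."""
        total = abs(self.elec_energy) + abs(self.vdw_energy)
        return abs(self.elec_energy) / total if total > 0 else float("nan")


def _residue_index_map(topology: Topology, selection: np.ndarray):
    keys = topology.residue_keys(selection)
    key_pos = {k: i for i, k in enumerate(keys)}
    particle_res = np.array([
        key_pos[(str(topology.chain_ids[i]), int(topology.residue_indices[i]),
                 str(topology.residue_names[i]))]
        for i in selection
    ])
    return keys, particle_res


def contact_matrix(
    trajectory: Trajectory,
    groupA_selection: Sequence[int],
    groupB_selection: Sequence[int],
    cutoff: float = 6.5,
    frame_range: tuple[int, int] | None = None,
) -> ContactMatrix:
    """Residue-residue contact frequencies at a distance cutoff.

    Residues are in contact in a frame iff any inter-particle distance
    (minimum image) is below ``cutoff``; the matrix entry is the fraction of
    frames in contact.  Selections must be disjoint.
    """
    selA = np.asarray(groupA_selection, dtype=np.int64)
    selB = np.asarray(groupB_selection, dtype=np.int64)
    if selA.size == 0 or selB.size == 0:
        raise SelectionError("contact selections must be non-empty")
    if np.intersect1d(selA, selB).size:
        raise SelectionError("contact selections must be disjoint")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = trajectory.topology
    keysA, resA = _residue_index_map(top, selA)
    keysB, resB = _residue_index_map(top, selB)
    lo, hi = (0, len(trajectory)) if frame_range is None else frame_range
    frames = range(lo, hi)
    n_frames = len(frames)
    if n_frames == 0:
        raise ValueError("empty frame range")
    acc = np.zeros((len(keysA), len(keysB)))
    for fi in frames:
        coords = trajectory.coordinates[fi]
        box = trajectory.boxes[fi]
        wrappedA = coords[selA] % box
        wrappedB = coords[selB] % box
        treeA = cKDTree(wrappedA, boxsize=box)
        treeB = cKDTree(wrappedB, boxsize=box)
        pairs = treeA.query_ball_tree(treeB, cutoff)
        hit = np.zeros((len(keysA), len(keysB)), dtype=bool)
        for ia, js in enumerate(pairs):
            if js:
                hit[resA[ia], resB[js]] = True
        acc += hit
    return ContactMatrix(keysA, keysB, acc / n_frames, cutoff, n_frames)


def contact_number_profiles(
    matrix: ContactMatrix,
    threshold: float | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Per-residue contact counts for each side of the interface.

    Counts partner residues whose frame-fraction is >= ``threshold``
    (default: any contact, i.e. fraction > 0).  Returns (group A profile,
    group B profile) indexed by residue label.
    """
    if threshold is None or threshold <= 0:
        mask = matrix.values > 0
    else:
        mask = matrix.values >= threshold
    labels = lambda keys: [f"{c}:{r}:{n}" for c, r, n in keys]
    a = pd.Series(mask.sum(axis=1), index=labels(matrix.row_keys), name="contacts")
    b = pd.Series(mask.sum(axis=0), index=labels(matrix.col_keys), name="contacts")
    return a, b


def polarity_contact_fractions(
    matrix: ContactMatrix,
    topology: Topology,
    threshold: float | None = None,
) -> dict[str, float]:
    """Percentages of contact pairs by polarity pairing.

    Hydrophilic = positive, negative or polar-uncharged residues.  Returns
    percentages for hydrophilic-hydrophilic, hydrophobic-hydrophobic and
    mixed pairs; the three sum to 100 (over contacting pairs).
    """
    if threshold is None or threshold <= 0:
        mask = matrix.values > 0
    else:
        mask = matrix.values >= threshold
    class_by_key: dict[tuple, PolarityClass] = {}
    for i in range(len(topology)):
        key = (str(topology.chain_ids[i]), int(topology.residue_indices[i]),
               str(topology.residue_names[i]))
        class_by_key.setdefault(key, topology.polarity[i])
    philic = set(HYDROPHILIC_CLASSES)
    counts = {"hydrophilic_hydrophilic": 0, "hydrophobic_hydrophobic": 0, "mixed": 0}
    rows, cols = np.nonzero(mask)
    for i, j in zip(rows, cols):
        ca = class_by_key[matrix.row_keys[i]]
        cb = class_by_key[matrix.col_keys[j]]
        if ca in philic and cb in philic:
            counts["hydrophilic_hydrophilic"] += 1
        elif ca not in philic and cb not in philic:
            counts["hydrophobic_hydrophobic"] += 1
        else:
            counts["mixed"] += 1
    total = sum(counts.values())
    if total == 0:
        return {k: 0.0 for k in counts}
    return {k: 100.0 * v / total for k, v in counts.items()}


def _elements(topology: Topology) -> np.ndarray:
    from .io import _guess_element

    return np.array([
        _guess_element(str(n), str(r)).upper()
        for n, r in zip(topology.names, topology.residue_names)
    ], dtype=object)


def interface_counts(
    topology: Topology,
    frame: Frame,
    groupA_selection: Sequence[int],
    groupB_selection: Sequence[int],
    parameters: Mapping[str, tuple[float, float, float]] | pd.DataFrame | None = None,
) -> InterfaceCounts:
    """Hydrogen bonds, salt bridges, hydrophobic contacts and energy split.

    Criteria (all-atom, configurable module constants): H-bond = donor to
    acceptor heavy-atom distance < 3.5 Angstrom with a donor-H...acceptor
    angle > 120 degrees; salt bridge = any Arg/Lys/His side-chain nitrogen
    within 4.0 Angstrom of an Asp/Glu side-chain oxygen, counted once per
    residue pair; hydrophobic contact = side-chain carbon pair of
    hydrophobic residues within 5.0 Angstrom, counted once per residue pair.
    Without hydrogens in the structure, H-bonds fall back to a distance-only
    criterion (< 3.0 Angstrom) with a logged warning.

    ``parameters`` maps atom name -> (charge e, sigma Angstrom, epsilon
    kcal/mol) for the Coulomb (epsilon_r = 1) plus 12-6 Lennard-Jones energy
    split over cross-group pairs within 12 Angstrom; omit it to skip the
    energy evaluation (energies reported as 0).
    """
    selA = np.asarray(groupA_selection, dtype=np.int64)
    selB = np.asarray(groupB_selection, dtype=np.int64)
    if np.intersect1d(selA, selB).size:
        raise SelectionError("interface selections must be disjoint")
    coords = frame.coordinates
    elements = _elements(topology)
    names = topology.names
    resnames = topology.residue_names

    def residue_key(i):
        return (str(topology.chain_ids[i]), int(topology.residue_indices[i]))

    has_h = bool(np.any(elements == "H"))

    # -- hydrogen bonds ----------------------------------------------------
    h_bonds = 0
    if has_h:
        attached: dict[int, list[int]] = {i: [] for i in range(len(topology))}
        h_idx = np.flatnonzero(elements == "H")
        heavy_idx = np.flatnonzero(elements != "H")
        if h_idx.size and heavy_idx.size:
            tree = cKDTree(coords[heavy_idx])
            for h in h_idx:
                dist, j = tree.query(coords[h])
                if dist < 1.25:
                    attached[int(heavy_idx[j])].append(int(h))
        for donors, acceptors in ((selA, selB), (selB, selA)):
            don = [i for i in donors if elements[i] in ("N", "O") and attached.get(int(i))]
            acc = [i for i in acceptors if elements[i] in ("N", "O")]
            for d in don:
                for a in acc:
                    r_da = np.linalg.norm(coords[d] - coords[a])
                    if r_da >= HBOND_DISTANCE:
                        continue
                    for h in attached[int(d)]:
                        v1 = coords[d] - coords[h]
                        v2 = coords[a] - coords[h]
                        cosang = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2))
                        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                        if angle > HBOND_ANGLE:
                            h_bonds += 1
                            break
    else:
        logger.warning(
            "structure has no hydrogens: counting hydrogen bonds by the "
            "distance-only fallback (< %.1f Angstrom)", HBOND_FALLBACK_DISTANCE)
        polarA = [i for i in selA if elements[i] in ("N", "O")]
        polarB = [i for i in selB if elements[i] in ("N", "O")]
        for d in polarA:
            for a in polarB:
                if np.linalg.norm(coords[d] - coords[a]) < HBOND_FALLBACK_DISTANCE:
                    h_bonds += 1

    # -- salt bridges (per residue pair) -----------------------------------
    def side_atoms(sel, table):
        out = []
        for i in sel:
            allowed = table.get(str(resnames[i]).upper())
            if allowed and str(names[i]).upper() in allowed:
                out.append(int(i))
        return out

    bridge_pairs = set()
    for basic_sel, acidic_sel in ((selA, selB), (selB, selA)):
        for n_at in side_atoms(basic_sel, _BASIC_SIDECHAIN_N):
            for o_at in side_atoms(acidic_sel, _ACIDIC_SIDECHAIN_O):
                if np.linalg.norm(coords[n_at] - coords[o_at]) < SALT_BRIDGE_DISTANCE:
                    bridge_pairs.add(frozenset((residue_key(n_at), residue_key(o_at))))
    salt_bridges = len(bridge_pairs)

    # -- hydrophobic contacts (per residue pair) ----------------------------
    def sidechain_carbons(sel):
        return [int(i) for i in sel
                if str(resnames[i]).upper() in _HYDROPHOBIC_RESIDUES
                and elements[i] == "C"
                and str(names[i]).upper() not in _BACKBONE_ATOMS]

    hydro_pairs = set()
    for ca_ in sidechain_carbons(selA):
        for cb_ in sidechain_carbons(selB):
            if np.linalg.norm(coords[ca_] - coords[cb_]) < HYDROPHOBIC_DISTANCE:
                hydro_pairs.add((residue_key(ca_), residue_key(cb_)))
    hydrophobic = len(hydro_pairs)

    # -- energy split --------------------------------------------------------
    elec = vdw = 0.0
    if parameters is not None:
        params = _parameter_table(parameters)
        for ia in selA:
            qa, sa, ea = _lookup(params, str(names[ia]))
            for ib in selB:
                r = float(np.linalg.norm(coords[ia] - coords[ib]))
                if r > ENERGY_CUTOFF or r == 0.0:
                    continue
                qb, sb, eb = _lookup(params, str(names[ib]))
                elec += COULOMB_KCAL * qa * qb / r
                sig = 0.5 * (sa + sb)
                eps = np.sqrt(ea * eb)
                if eps > 0:
                    sr6 = (sig / r) ** 6
                    vdw += 4.0 * eps * (sr6 * sr6 - sr6)
    return InterfaceCounts(float(h_bonds), float(salt_bridges),
                           float(hydrophobic), float(elec), float(vdw))


def _parameter_table(parameters) -> dict[str, tuple[float, float, float]]:
    if isinstance(parameters, pd.DataFrame):
        return {
            str(row.iloc[0]).upper(): (float(row.iloc[1]), float(row.iloc[2]),
                                       float(row.iloc[3]))
            for _, row in parameters.iterrows()
        }
    return {k.upper(): tuple(map(float, v)) for k, v in parameters.items()}


def _lookup(params, name):
    key = name.upper()
    if key not in params:
        raise KeyError(f"no charge/LJ parameters for atom {name!r}")
    return params[key]
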