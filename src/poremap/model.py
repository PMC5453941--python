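"""Core data model: particles, topologies, frames and trajectories.

All coordinates are in Angstrom, energies in kcal/mol, temperatures in K,
times in ps.  Particle indices are 0-based internally; residue numbers are
1-based (the convention of PDB/GRO files).  Boxes are orthorhombic; the
membrane normal is the +z axis throughout the package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Gas constant in kcal/(mol K).
R_KCAL = 1.987e-3

#: Default analysis temperature (body temperature), K.
DEFAULT_TEMPERATURE = 310.0


class PolarityClass(str, Enum):
    """Residue-level polarity classes used for surface and contact statistics."""

    POSITIVE = "positive"
    NEGATIVE = "negative"
    POLAR_UNCHARGED = "polar_uncharged"
    HYDROPHOBIC = "hydrophobic"


#: Default residue -> polarity classification table.  Configurable: every
#: function that classifies residues accepts a ``table`` override.  Heme
#: (HEC/HEM) is classified hydrophobic at residue level; no atom-level
#: override for the propionate oxygens is attempted.
DEFAULT_POLARITY_TABLE: dict[str, PolarityClass] = {
    **{r: PolarityClass.POSITIVE for r in ("ARG", "LYS", "HIS")},
    **{r: PolarityClass.NEGATIVE for r in ("ASP", "GLU")},
    **{
        r: PolarityClass.POLAR_UNCHARGED
        for r in ("SER", "THR", "ASN", "GLN", "TYR", "CYS", "TRP", "GLY")
    },
    **{
        r: PolarityClass.HYDROPHOBIC
        for r in ("ALA", "VAL", "LEU", "ILE", "PRO", "PHE", "MET", "HEC", "HEM")
    },
}

_AMINO_ACIDS = frozenset(DEFAULT_POLARITY_TABLE) - {"HEC", "HEM"}
_LIPID_RESNAMES = frozenset({"DSPC", "DPPC", "POPC", "DOPC", "POPE", "DOPE", "LIP"})
_ION_RESNAMES = frozenset({"NA", "CL", "CA", "K", "MG", "ION", "NA+", "CL-", "CA2"})
_WATER_RESNAMES = frozenset({"W", "HOH", "SOL", "TIP3", "WAT", "SPC"})


def classify_residue(
    residue_name: str,
    table: Mapping[str, PolarityClass] | None = None,
    *,
    _warned: set[str] | None = None,
) -> PolarityClass:
    """Look up the polarity class of a residue name.

    Unknown residues are classified hydrophobic with a logged warning so that
    lipid/ion/solvent species pass through without aborting an analysis.
    """
    table = DEFAULT_POLARITY_TABLE if table is None else table
    name = residue_name.upper()
    if name in table:
        return PolarityClass(table[name])
    if _warned is None or name not in _warned:
        # known lipid/ion/solvent species pass through quietly at debug level
        level = (logging.DEBUG if guess_group_tag(name) in ("lipid", "ion", "water")
                 else logging.WARNING)
        logger.log(level, "unknown residue %r classified as hydrophobic", residue_name)
        if _warned is not None:
            _warned.add(name)
    return PolarityClass.HYDROPHOBIC


def guess_group_tag(residue_name: str) -> str:
    """Heuristic group tag from a residue name (retag proteins explicitly)."""
    name = residue_name.upper()
    if name in _AMINO_ACIDS:
        return "protein"
    if name in _LIPID_RESNAMES:
        return "lipid"
    if name in _ION_RESNAMES:
        return "ion"
    if name in _WATER_RESNAMES:
        return "water"
    return "other"


@dataclass(frozen=True)
class Particle:
    """A single particle (atom or coarse-grained bead)."""

    index: int
    name: str
    residue_index: int
    residue_name: str
    chain_id: str
    group_tag: str
    polarity_class: PolarityClass


class SelectionError(ValueError):
    """Raised when a particle selection is empty or inconsistent."""


class StructuralError(ValueError):
    """Raised when particle counts or selection sizes disagree."""


class Topology:
    """Immutable-ish particle table with residue/chain identity and grouping.

    Stored columnar (numpy arrays) for speed; :meth:`particle` materialises a
    :class:`Particle` view on demand.  ``dimer_assignments`` maps dimer labels
    (1..n) to particle index arrays and must partition the "pore" particles.
    """

    def __init__(
        self,
        names: Sequence[str],
        residue_indices: Sequence[int],
        residue_names: Sequence[str],
        chain_ids: Sequence[str] | None = None,
        group_tags: Sequence[str] | str | None = None,
        polarity: Sequence[PolarityClass] | None = None,
        dimer_assignments: Mapping[int, Sequence[int]] | None = None,
        polarity_table: Mapping[str, PolarityClass] | None = None,
    ):
        self.names = np.asarray(names, dtype=object)
        n = len(self.names)
        self.residue_indices = np.asarray(residue_indices, dtype=np.int64)
        self.residue_names = np.asarray(residue_names, dtype=object)
        if chain_ids is None:
            chain_ids = ["A"] * n
        self.chain_ids = np.asarray(chain_ids, dtype=object)
        if group_tags is None:
            group_tags = [guess_group_tag(r) for r in self.residue_names]
        elif isinstance(group_tags, str):
            group_tags = [group_tags] * n
        self.group_tags = np.asarray(group_tags, dtype=object)
        if polarity is None:
            warned: set[str] = set()
            polarity = [
                classify_residue(r, polarity_table, _warned=warned)
                for r in self.residue_names
            ]
        self.polarity = np.asarray([PolarityClass(p) for p in polarity], dtype=object)
        for arr in (self.residue_indices, self.residue_names, self.chain_ids,
                    self.group_tags, self.polarity):
            if len(arr) != n:
                raise StructuralError(
                    f"topology column length {len(arr)} != particle count {n}"
                )
        self.dimer_assignments: dict[int, np.ndarray] = {}
        if dimer_assignments:
            self.dimer_assignments = {
                int(k): np.asarray(v, dtype=np.int64)
                for k, v in dimer_assignments.items()
            }
            self._check_dimer_partition()

    def _check_dimer_partition(self) -> None:
        pore = set(np.flatnonzero(self.group_tags == "pore").tolist())
        assigned: list[int] = []
        for idx in self.dimer_assignments.values():
            assigned.extend(idx.tolist())
        if len(assigned) != len(set(assigned)):
            raise StructuralError("dimer assignments overlap")
        if pore and set(assigned) != pore:
            raise StructuralError(
                "dimer assignments must partition the 'pore' particles"
            )

    def __len__(self) -> int:
        return len(self.names)

    @property
    def n_particles(self) -> int:
        return len(self.names)

    def particle(self, i: int) -> Particle:
        return Particle(
            index=i,
            name=str(self.names[i]),
            residue_index=int(self.residue_indices[i]),
            residue_name=str(self.residue_names[i]),
            chain_id=str(self.chain_ids[i]),
            group_tag=str(self.group_tags[i]),
            polarity_class=self.polarity[i],
        )

    def __iter__(self) -> Iterator[Particle]:
        return (self.particle(i) for i in range(len(self)))

    def select(
        self,
        group: str | None = None,
        resname: str | Iterable[str] | None = None,
        name: str | Iterable[str] | None = None,
        chain: str | None = None,
    ) -> np.ndarray:
        """Return 0-based particle indices matching all given criteria."""
        mask = np.ones(len(self), dtype=bool)
        if group is not None:
            mask &= self.group_tags == group
        if resname is not None:
            wanted = {resname} if isinstance(resname, str) else set(resname)
            mask &= np.isin(self.residue_names.astype(str), list(wanted))
        if name is not None:
            wanted = {name} if isinstance(name, str) else set(name)
            mask &= np.isin(self.names.astype(str), list(wanted))
        if chain is not None:
            mask &= self.chain_ids == chain
        return np.flatnonzero(mask)

    def retag(self, indices: Sequence[int], tag: str) -> None:
        """Assign a group tag (e.g. 'pore', 'cargo') to the given particles."""
        self.group_tags[np.asarray(indices, dtype=np.int64)] = tag

    def residue_keys(self, indices: Sequence[int] | None = None) -> list[tuple]:
        """Ordered unique (chain, resid, resname) keys over the given particles."""
        idx = np.arange(len(self)) if indices is None else np.asarray(indices)
        seen: dict[tuple, None] = {}
        for i in idx:
            seen.setdefault(
                (str(self.chain_ids[i]), int(self.residue_indices[i]),
                 str(self.residue_names[i])), None
            )
        return list(seen)

    def subset(self, indices: Sequence[int]) -> "Topology":
        idx = np.asarray(indices, dtype=np.int64)
        return Topology(
            names=self.names[idx],
            residue_indices=self.residue_indices[idx],
            residue_names=self.residue_names[idx],
            chain_ids=self.chain_ids[idx],
            group_tags=self.group_tags[idx],
            polarity=self.polarity[idx],
        )

    @staticmethod
    def concatenate(parts: Sequence["Topology"]) -> "Topology":
        return Topology(
            names=np.concatenate([p.names for p in parts]),
            residue_indices=np.concatenate([p.residue_indices for p in parts]),
            residue_names=np.concatenate([p.residue_names for p in parts]),
            chain_ids=np.concatenate([p.chain_ids for p in parts]),
            group_tags=np.concatenate([p.group_tags for p in parts]),
            polarity=np.concatenate([p.polarity for p in parts]),
        )


@dataclass
class Frame:
    """One trajectory frame: N x 3 coordinates (Angstrom) and an orthorhombic box."""

    coordinates: np.ndarray
    box: np.ndarray = field(default_factory=lambda: np.array([1e4, 1e4, 1e4]))
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise StructuralError("coordinates must be an N x 3 array")
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        if np.any(self.box <= 0):
            raise StructuralError("box lengths must be positive")

    @property
    def n_particles(self) -> int:
        return self.coordinates.shape[0]

    def copy(self) -> "Frame":
        return Frame(self.coordinates.copy(), self.box.copy(), self.time)


class Trajectory:
    """Ordered frames sharing one topology, stored as stacked arrays.

    Parameters
    ----------
    topology : Topology
    coordinates : (n_frames, N, 3) array, Angstrom
    boxes : (n_frames, 3) or (3,) array
    times : (n_frames,) array, ps
    temperature : float, K (default 310 K, the analysis temperature)
    """

    def __init__(
        self,
        topology: Topology,
        coordinates: np.ndarray,
        boxes: np.ndarray | None = None,
        times: np.ndarray | None = None,
        temperature: float = DEFAULT_TEMPERATURE,
    ):
        self.topology = topology
        self.coordinates = np.asarray(coordinates, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise StructuralError("trajectory coordinates must be (F, N, 3)")
        if self.coordinates.shape[1] != len(topology):
            raise StructuralError(
                f"frame particle count {self.coordinates.shape[1]} does not match "
                f"topology particle count {len(topology)}"
            )
        f = self.coordinates.shape[0]
        if boxes is None:
            boxes = np.array([1e4, 1e4, 1e4])
        boxes = np.asarray(boxes, dtype=np.float64)
        if boxes.ndim == 1:
            boxes = np.broadcast_to(boxes, (f, 3)).copy()
        self.boxes = boxes
        self.times = (
            np.arange(f, dtype=np.float64) if times is None
            else np.asarray(times, dtype=np.float64)
        )
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        self.temperature = float(temperature)

    @classmethod
    def from_frames(
        cls,
        topology: Topology,
        frames: Sequence[Frame],
        temperature: float = DEFAULT_TEMPERATURE,
    ) -> "Trajectory":
        if not frames:
            raise StructuralError("a trajectory needs at least one frame")
        return cls(
            topology,
            np.stack([f.coordinates for f in frames]),
            np.stack([f.box for f in frames]),
            np.array([f.time for f in frames]),
            temperature,
        )

    def __len__(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_frames(self) -> int:
        return len(self)

    def frame(self, i: int) -> Frame:
        return Frame(self.coordinates[i], self.boxes[i], float(self.times[i]))

    def __iter__(self) -> Iterator[Frame]:
        return (self.frame(i) for i in range(len(self)))

    def copy(self) -> "Trajectory":
        return Trajectory(
            self.topology, self.coordinates.copy(), self.boxes.copy(),
            self.times.copy(), self.temperature,
        )
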