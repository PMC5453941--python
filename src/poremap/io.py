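"""Structure and trajectory I/O.

Structures are read and written as PDB or GRO through biotite (GRO
nanometers are converted to Angstrom on read).  Trajectories use a plain
multi-frame text format documented below, with an optional thin adapter for
the XTC binary format (requires MDAnalysis).

Text trajectory layout::

    # poremap-traj 1
    # natoms N
    # frame time=<ps> box=<bx> <by> <bz>
    x y z          (N lines, Angstrom)
    # frame ...

Occupancy and B-factor columns of PDB files are ignored on read.  Only
orthorhombic boxes are supported; triclinic boxes raise an error.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Sequence

import numpy as np

from .model import Frame, StructuralError, Topology, Trajectory

logger = logging.getLogger(__name__)

_TRICLINIC_TOL = 1e-6


class ParseError(ValueError):
    """Raised when a structure or trajectory file cannot be parsed."""


def _find_bad_record_line(path: Path) -> int | None:
    """Locate the first malformed ATOM/HETATM record of a PDB file, if any."""
    try:
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                if line.startswith(("ATOM", "HETATM")):
                    try:
                        float(line[30:38]); float(line[38:46]); float(line[46:54])
                        int(line[22:26])
                    except (ValueError, IndexError):
                        return lineno
    except OSError:
        return None
    return None


def _box_from_matrix(box_matrix: np.ndarray | None) -> np.ndarray:
    if box_matrix is None:
        return np.array([1e4, 1e4, 1e4])
    box_matrix = np.asarray(box_matrix, dtype=np.float64)
    if box_matrix.ndim == 3:
        box_matrix = box_matrix[0]
    off_diag = box_matrix - np.diag(np.diag(box_matrix))
    if np.abs(off_diag).max() > _TRICLINIC_TOL:
        raise ParseError(
            "triclinic boxes are not supported (orthorhombic only)"
        )
    diag = np.diag(box_matrix)
    if np.any(diag <= 0):
        return np.array([1e4, 1e4, 1e4])
    return diag.copy()


def read_structure(path, format: str | None = None) -> tuple[Topology, Frame]:
    """Read a PDB or GRO file into a (Topology, Frame) pair.

    Coordinates are returned in Angstrom; residue numbering (1-based) and
    particle names are preserved; polarity classes are populated from the
    default classification table.  ``format`` defaults to the file suffix.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("pdb", "gro"):
        raise ValueError(f"unsupported structure format {fmt!r}")
    try:
        if fmt == "pdb":
            from biotite.structure.io.pdb import PDBFile

            atoms = PDBFile.read(str(path)).get_structure(model=1)
        else:
            from biotite.structure.io.gro import GROFile

            atoms = GROFile.read(str(path)).get_structure(model=1)
    except Exception as exc:
        lineno = _find_bad_record_line(path) if fmt == "pdb" else None
        where = f" at line {lineno}" if lineno else ""
        raise ParseError(f"could not parse {fmt.upper()} file {path}{where}: {exc}") from exc
    box = _box_from_matrix(atoms.box)
    topology = Topology(
        names=[str(n) for n in atoms.atom_name],
        residue_indices=atoms.res_id,
        residue_names=[str(r) for r in atoms.res_name],
        chain_ids=[str(c) if c else "A" for c in atoms.chain_id],
    )
    frame = Frame(np.asarray(atoms.coord, dtype=np.float64), box)
    return topology, frame


def _guess_element(name: str, resname: str) -> str:
    resname = resname.upper()
    if resname in ("NA", "CL", "CA", "K", "MG") and name.upper() == resname:
        return resname.capitalize()
    stripped = re.sub(r"^\d+", "", name)
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "C"


def write_structure(topology: Topology, frame: Frame, path, format: str | None = None,
                    b_factors: Sequence[float] | None = None) -> None:
    """Write a (Topology, Frame) pair as a standard-conformant PDB or GRO file."""
    import biotite.structure as struc

    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt not in ("pdb", "gro"):
        raise ValueError(f"unsupported structure format {fmt!r}")
    coords = np.asarray(frame.coordinates, dtype=np.float64)
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    n = len(topology)
    atoms = struc.AtomArray(n)
    atoms.coord = coords
    atoms.chain_id = np.asarray([str(c)[:4] for c in topology.chain_ids])
    atoms.res_id = topology.residue_indices.astype(int)
    # the PDB residue-name column holds 3 characters; GRO holds 5
    max_res = 3 if fmt == "pdb" else 5
    res_names = [str(r)[:max_res] for r in topology.residue_names]
    if fmt == "pdb" and any(len(str(r)) > 3 for r in topology.residue_names):
        logger.warning("residue names longer than 3 characters truncated "
                       "for PDB output")
    atoms.res_name = np.asarray(res_names)
    atoms.atom_name = np.asarray([str(a)[:6] for a in topology.names])
    atoms.element = np.asarray(
        [_guess_element(str(a), str(r))
         for a, r in zip(topology.names, topology.residue_names)]
    )
    atoms.hetero = np.asarray(
        [topology.group_tags[i] not in ("protein", "pore", "cargo") for i in range(n)]
    )
    if b_factors is not None:
        atoms.set_annotation("b_factor", np.asarray(b_factors, dtype=np.float64))
    atoms.box = np.diag(frame.box)
    try:
        if fmt == "pdb":
            from biotite.structure.io.pdb import PDBFile

            f = PDBFile()
            f.set_structure(atoms)
            f.write(str(path))
        else:
            from biotite.structure.io.gro import GROFile

            f = GROFile()
            f.set_structure(atoms)
            if f.lines:  # replace the timestamped title for reproducible output
                f.lines[0] = "poremap structure"
            f.write(str(path))
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def write_trajectory(trajectory: Trajectory, path, format: str = "text") -> None:
    """Write a trajectory (text format by default, 'xtc' with MDAnalysis)."""
    path = Path(path)
    if format == "xtc":
        _write_xtc(trajectory, path)
        return
    if format != "text":
        raise ValueError(f"unsupported trajectory format {format!r}")
    n = trajectory.coordinates.shape[1]
    with open(path, "w") as fh:
        fh.write("# poremap-traj 1\n")
        fh.write(f"# natoms {n}\n")
        for i in range(len(trajectory)):
            b = trajectory.boxes[i]
            fh.write(f"# frame time={trajectory.times[i]:.4f} "
                     f"box={b[0]:.4f} {b[1]:.4f} {b[2]:.4f}\n")
            np.savetxt(fh, trajectory.coordinates[i], fmt="%.6f")


def read_trajectory(path, topology: Topology, format: str = "text",
                    temperature: float = 310.0) -> Trajectory:
    """Read a trajectory, checking the particle count against the topology.

    Frames are returned ordered by time; a truncated final frame raises a
    structural error rather than returning a silent short read.
    """
    path = Path(path)
    if format == "xtc":
        return _read_xtc(path, topology, temperature)
    if format != "text":
        raise ValueError(f"unsupported trajectory format {format!r}")
    n_expected = len(topology)
    coords: list[np.ndarray] = []
    boxes: list[np.ndarray] = []
    times: list[float] = []
    n_declared = None
    current: list[list[float]] | None = None

    def _close_frame():
        if current is None:
            return
        if len(current) != n_declared:
            raise StructuralError(
                f"truncated frame in {path}: expected {n_declared} particles, "
                f"found {len(current)}"
            )
        coords.append(np.asarray(current, dtype=np.float64))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#\s*natoms\s+(\d+)", line)
                if m:
                    n_declared = int(m.group(1))
                    if n_declared != n_expected:
                        raise StructuralError(
                            f"particle count mismatch in {path}: topology has "
                            f"{n_expected}, file declares {n_declared}"
                        )
                    continue
                m = re.match(
                    r"#\s*frame\s+time=([-\d.eE+]+)\s+box=([-\d.eE+]+)\s+"
                    r"([-\d.eE+]+)\s+([-\d.eE+]+)", line)
                if m:
                    _close_frame()
                    current = []
                    times.append(float(m.group(1)))
                    boxes.append(np.array([float(m.group(g)) for g in (2, 3, 4)]))
                continue
            if current is None:
                raise ParseError(f"coordinate line before frame header in {path}")
            parts = line.split()
            if len(parts) != 3:
                raise ParseError(f"malformed coordinate line in {path}: {line!r}")
            current.append([float(p) for p in parts])
    if n_declared is None:
        raise ParseError(f"{path} has no '# natoms' header")
    _close_frame()
    if not coords:
        raise ParseError(f"{path} contains no frames")
    order = np.argsort(np.asarray(times), kind="stable")
    return Trajectory(
        topology,
        np.stack(coords)[order],
        np.stack(boxes)[order],
        np.asarray(times)[order],
        temperature,
    )


def _write_xtc(trajectory: Trajectory, path: Path) -> None:
    from MDAnalysis.coordinates.XTC import XTCWriter

    n = trajectory.coordinates.shape[1]
    import MDAnalysis as mda

    u = mda.Universe.empty(n, trajectory=True)
    with XTCWriter(str(path), n_atoms=n) as w:
        for i in range(len(trajectory)):
            u.atoms.positions = trajectory.coordinates[i]
            u.dimensions = [*trajectory.boxes[i], 90.0, 90.0, 90.0]
            u.trajectory.ts.time = trajectory.times[i]
            w.write(u.atoms)


def _read_xtc(path: Path, topology: Topology, temperature: float) -> Trajectory:
    from MDAnalysis.coordinates.XTC import XTCReader

    reader = XTCReader(str(path))
    if reader.n_atoms != len(topology):
        raise StructuralError(
            f"particle count mismatch in {path}: topology has {len(topology)}, "
            f"file has {reader.n_atoms}"
        )
    coords, boxes, times = [], [], []
    for ts in reader:
        coords.append(ts.positions.astype(np.float64).copy())
        dims = ts.dimensions
        boxes.append(np.asarray(dims[:3], dtype=np.float64) if dims is not None
                     else np.array([1e4, 1e4, 1e4]))
        times.append(float(ts.time))
    reader.close()
    return Trajectory(topology, np.stack(coords), np.stack(boxes),
                      np.asarray(times), temperature)
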