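"""Multi-model PDB input/output and rigid-body geometry utilities.

Structures are held as lightweight :class:`Frame` objects (parallel numpy
arrays of atom metadata and coordinates) grouped into a :class:`Trajectory`.
Coordinates are in Angstrom, times in picoseconds, angles in degrees
throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Atom",
    "Frame",
    "Trajectory",
    "StructureError",
    "AtomSelectionError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "select_atom",
    "kabsch_rmsd",
    "dihedral",
]


class StructureError(ValueError):
    """Malformed or inconsistent structural input."""


class AtomSelectionError(LookupError):
    """An atom selection matched zero or more than one atom."""


@dataclass(frozen=True)
class Atom:
    """A single atom: PDB-convention name, author residue numbering, position in Å."""

    name: str
    residue_index: int
    residue_name: str
    chain: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureError(f"atom {self.name!r}: position must be a finite 3-vector")
        if not self.name:
            raise StructureError("atom name must be non-empty")
        object.__setattr__(self, "position", pos)


class Frame:
    """One trajectory frame: an ordered atom table plus coordinates.

    Atom metadata arrays may be shared between frames of one trajectory
    (all frames of a trajectory have identical atom ordering and count).
    """

    __slots__ = ("names", "residue_indices", "residue_names", "chains", "coords", "time_ps")

    def __init__(
        self,
        names: np.ndarray,
        residue_indices: np.ndarray,
        residue_names: np.ndarray,
        chains: np.ndarray,
        coords: np.ndarray,
        time_ps: float = 0.0,
    ) -> None:
        coords = np.asarray(coords, dtype=float)
        n = len(names)
        if coords.shape != (n, 3):
            raise StructureError(f"coords shape {coords.shape} does not match {n} atoms")
        if not np.all(np.isfinite(coords)):
            raise StructureError("non-finite coordinates")
        if time_ps < 0:
            raise StructureError("frame time must be non-negative")
        self.names = np.asarray(names, dtype=object)
        self.residue_indices = np.asarray(residue_indices, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype=object)
        self.chains = np.asarray(chains, dtype=object)
        self.coords = coords
        self.time_ps = float(time_ps)

    @classmethod
    def from_atoms(cls, atoms: Sequence[Atom], time_ps: float = 0.0) -> "Frame":
        if not atoms:
            raise StructureError("frame must contain at least one atom")
        return cls(
            names=np.array([a.name for a in atoms], dtype=object),
            residue_indices=np.array([a.residue_index for a in atoms], dtype=int),
            residue_names=np.array([a.residue_name for a in atoms], dtype=object),
            chains=np.array([a.chain for a in atoms], dtype=object),
            coords=np.array([a.position for a in atoms], dtype=float),
            time_ps=time_ps,
        )

    def __len__(self) -> int:
        return len(self.names)

    @property
    def atoms(self) -> list[Atom]:
        return [
            Atom(self.names[i], int(self.residue_indices[i]), self.residue_names[i],
                 self.chains[i], self.coords[i].copy())
            for i in range(len(self))
        ]

    def atom(self, i: int) -> Atom:
        return Atom(self.names[i], int(self.residue_indices[i]), self.residue_names[i],
                    self.chains[i], self.coords[i].copy())

    def with_coords(self, coords: np.ndarray, time_ps: float | None = None) -> "Frame":
        """New frame sharing this frame's atom metadata arrays."""
        return Frame(self.names, self.residue_indices, self.residue_names, self.chains,
                     coords, self.time_ps if time_ps is None else time_ps)


@dataclass
class Trajectory:
    """Ordered frames of one simulation replica.

    Frame times must be strictly increasing and consistent with
    ``frame_interval_ps`` within 1e-6 ps.
    """

    frames: list[Frame]
    replica_id: int = 1
    frame_interval_ps: float = 100.0

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("trajectory must contain at least one frame")
        if self.frame_interval_ps <= 0:
            raise StructureError("frame interval must be positive")
        n0 = len(self.frames[0])
        times = np.array([f.time_ps for f in self.frames])
        for k, f in enumerate(self.frames):
            if len(f) != n0:
                raise StructureError(
                    f"frame {k} has {len(f)} atoms, expected {n0} (inconsistent trajectory)"
                )
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise StructureError("frame times must be strictly increasing")
            if np.any(np.abs(dt - self.frame_interval_ps) > 1e-6):
                raise StructureError("frame times inconsistent with frame_interval_ps")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times_ps(self) -> np.ndarray:
        return np.array([f.time_ps for f in self.frames])


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _guess_element(atom_name: str) -> str:
    # protein heavy-atom names start with their element letter (CA is an
    # alpha carbon here, never calcium)
    for ch in atom_name.strip():
        if ch.isalpha():
            return ch.upper()
    return "C"


def read_multimodel_pdb(
    path: str | Path,
    frame_interval_ps: float = 100.0,
    replica_id: int = 1,
    include_hetatm: bool = False,
) -> Trajectory:
    """Read a (multi-)model PDB file into a :class:`Trajectory`.

    One :class:`Frame` per MODEL record (a single-model file yields one
    frame). HETATM records are ignored unless ``include_hetatm``. Frame
    times are synthesized from ``frame_interval_ps`` since PDB carries no
    time stamps.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    n_models = pdb.get_model_count()
    if n_models == 0:
        raise StructureError(f"{path}: no atoms found")

    frames: list[Frame] = []
    meta = None
    for m in range(1, n_models + 1):
        arr = pdb.get_structure(model=m)
        if not include_hetatm:
            arr = arr[~arr.hetero]
        if arr.array_length() == 0:
            raise StructureError(f"{path}: model {m} contains no (non-HETATM) atoms")
        if meta is None:
            meta = (
                np.array(arr.atom_name, dtype=object),
                np.array(arr.res_id, dtype=int),
                np.array(arr.res_name, dtype=object),
                np.array(arr.chain_id, dtype=object),
            )
            n0 = arr.array_length()
        elif arr.array_length() != n0:
            raise StructureError(
                f"{path}: model {m} has {arr.array_length()} atoms, "
                f"expected {n0} as in model 1"
            )
        frames.append(
            Frame(*meta, coords=np.asarray(arr.coord, dtype=float),
                  time_ps=(m - 1) * frame_interval_ps)
        )
    return Trajectory(frames, replica_id=replica_id, frame_interval_ps=frame_interval_ps)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL per frame).

    Single-frame trajectories are also written with MODEL/ENDMDL records for
    uniformity; the reader accepts both dialects. Occupancy/B-factor are
    written as 1.00/0.00.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    f0 = traj.frames[0]
    n = len(f0)
    template = struc.AtomArray(n)
    template.atom_name = np.array([str(x) for x in f0.names], dtype="U6")
    template.res_id = f0.residue_indices.copy()
    template.res_name = np.array([str(x) for x in f0.residue_names], dtype="U5")
    template.chain_id = np.array([str(x) for x in f0.chains], dtype="U4")
    template.element = np.array([_guess_element(str(x)) for x in f0.names], dtype="U2")
    template.hetero = np.zeros(n, dtype=bool)
    template.set_annotation("occupancy", np.ones(n))
    template.set_annotation("b_factor", np.zeros(n))

    stack = struc.stack([template] * len(traj.frames))
    stack.coord = np.stack([f.coords for f in traj.frames]).astype(np.float32)

    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def select_atom(
    frame: Frame,
    residue_index: int,
    atom_name: str,
    chain: str | None = None,
) -> Atom:
    """Select the unique atom with the given residue index and name.

    Raises :class:`AtomSelectionError` on zero matches or on ambiguity
    (e.g. the same residue number in two chains without a chain filter).
    """
    mask = (frame.residue_indices == residue_index) & (frame.names == atom_name)
    if chain is not None:
        mask &= frame.chains == chain
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise AtomSelectionError(
            f"no atom {atom_name!r} in residue {residue_index}"
            + (f" chain {chain!r}" if chain else "")
        )
    if len(idx) > 1:
        chains = sorted({str(frame.chains[i]) for i in idx})
        raise AtomSelectionError(
            f"ambiguous selection: atom {atom_name!r} residue {residue_index} "
            f"matches {len(idx)} atoms (chains {chains}); pass a chain"
        )
    return frame.atom(int(idx[0]))


# ---------------------------------------------------------------------------
# Rigid-body geometry
# ---------------------------------------------------------------------------

def _selected_coords(frame: Frame, selection: Iterable[str] | None) -> np.ndarray:
    if selection is None:
        return frame.coords
    sel = set(selection)
    mask = np.array([str(nm) in sel for nm in frame.names])
    return frame.coords[mask]


def kabsch_rmsd(
    reference: Frame,
    mobile: Frame,
    selection: Iterable[str] | None = None,
) -> float:
    """Minimal RMSD (Å) after optimal rigid superposition of ``mobile`` onto
    ``reference``, computed over atoms whose names are in ``selection``
    (all atoms if None). Invariant to rigid transforms of either frame."""
    a = _selected_coords(reference, selection)
    b = _selected_coords(mobile, selection)
    if a.shape != b.shape:
        raise StructureError(
            f"selection size mismatch: reference {a.shape[0]} vs mobile {b.shape[0]} atoms"
        )
    if a.shape[0] < 3:
        raise StructureError("superposition requires at least 3 atoms")
    a_c = a - a.mean(axis=0)
    b_c = b - b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a_c, b_c)
    return float(rssd / np.sqrt(a.shape[0]))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion angle in degrees, in (-180, 180].

    cis planar is 0°, trans planar is 180°. Raises on degenerate geometry
    (three consecutive points collinear)."""
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise StructureError("degenerate dihedral: three consecutive points collinear")
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)
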