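"""Reading, writing and selecting molecular ensembles.

A trajectory here is an ordered sequence of frames, each an ordered list of
atoms; the baseline interchange format is multi-model PDB (one MODEL per
frame).  A plain-text ``XYZT`` dialect is also supported for fast round-trips
of synthetic data.  Downstream analyses consume one representative atom per
residue (Cβ, falling back to Cα for glycine, following the residue-network
convention), produced by :func:`select_representatives`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

__all__ = [
    "AtomRecord",
    "Frame",
    "Trajectory",
    "Selection",
    "TrajectoryFormatError",
    "TrajectoryStructureError",
    "SelectionError",
    "EmptyWindowError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "read_xyzt",
    "write_xyzt",
    "select_representatives",
    "window_frames",
]

ANGSTROM_PER_NM = 10.0

# Average atomic masses (u) for elements common in biomolecules.  Unknown
# elements fall back to carbon with a warning.
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38, "MG": 24.305,
    "CA": 40.078, "NA": 22.990, "K": 39.098, "CL": 35.45, "MN": 54.938,
    "CU": 63.546, "F": 18.998, "BR": 79.904, "I": 126.904,
}


class TrajectoryFormatError(ValueError):
    """A file could not be parsed as the expected format."""


class TrajectoryStructureError(ValueError):
    """A parsed ensemble violates a structural invariant (e.g. atom counts)."""


class SelectionError(ValueError):
    """A representative-atom selection could not be built."""


class EmptyWindowError(ValueError):
    """A frame window matched no frames."""


def mass_of_element(element: str) -> float:
    """Atomic mass (u) for an element symbol; unknown symbols get carbon's."""
    key = element.strip().upper()
    if key in _ELEMENT_MASSES:
        return _ELEMENT_MASSES[key]
    warnings.warn(
        f"Unknown element symbol {element!r}; assigning carbon mass",
        stacklevel=2,
    )
    return _ELEMENT_MASSES["C"]


@dataclass(frozen=True)
class AtomRecord:
    """One atom of one frame: identity plus coordinates in Å."""

    atom_name: str
    residue_name: str
    residue_index: int
    chain_id: str
    element: str
    coordinates: tuple[float, float, float]
    mass: float

    def __post_init__(self):
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError(f"non-finite coordinates for atom {self.atom_name}")
        if self.mass <= 0:
            raise ValueError("atom mass must be positive")


@dataclass
class Frame:
    """An ordered set of atoms at one time point (time in ps)."""

    atoms: list[AtomRecord]
    time: float = 0.0

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n_atoms, 3) float array of coordinates, Å."""
        return np.asarray([a.coordinates for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray, time: float | None = None) -> "Frame":
        """Copy of this frame with replaced coordinates (labels preserved)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"expected coordinates of shape {(len(self.atoms), 3)}")
        atoms = [
            AtomRecord(
                a.atom_name, a.residue_name, a.residue_index, a.chain_id,
                a.element, (float(x), float(y), float(z)), a.mass,
            )
            for a, (x, y, z) in zip(self.atoms, coords)
        ]
        return Frame(atoms, self.time if time is None else time)


class Trajectory:
    """Ordered frames with strictly increasing times and a fixed atom roster."""

    def __init__(self, frames: Sequence[Frame], dt: float | None = None):
        frames = list(frames)
        if not frames:
            raise TrajectoryStructureError("a trajectory needs at least one frame")
        n = len(frames[0])
        for i, fr in enumerate(frames):
            if len(fr) != n:
                raise TrajectoryStructureError(
                    f"frame {i} has {len(fr)} atoms, expected {n}"
                )
        times = np.asarray([fr.time for fr in frames], dtype=float)
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise TrajectoryStructureError("frame times must be strictly increasing")
        self.frames = frames
        self.dt = dt

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0])

    @property
    def times(self) -> np.ndarray:
        return np.asarray([fr.time for fr in self.frames], dtype=float)

    def coordinates(self, indices: Sequence[int] | None = None) -> np.ndarray:
        """(n_frames, n_atoms_or_selected, 3) coordinate array, Å."""
        arr = np.stack([fr.coordinates for fr in self.frames])
        if indices is not None:
            arr = arr[:, np.asarray(indices, dtype=int), :]
        return arr


@dataclass
class Selection:
    """One representative atom per residue, in sequence order.

    ``indices`` point into ``Frame.atoms``; ``residue_labels`` is the parallel
    list of ``(chain_id, residue_index, residue_name)`` tuples.
    """

    indices: list[int]
    residue_labels: list[tuple[str, int, str]]
    masses: list[float] = field(default_factory=list)

    def __post_init__(self):
        if len(self.indices) != len(self.residue_labels):
            raise ValueError("indices and residue_labels must be parallel")
        if len(set(self.indices)) != len(self.indices):
            raise ValueError("selection indices must be unique")
        if not self.masses:
            self.masses = [0.0] * len(self.indices)

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def mass_array(self) -> np.ndarray:
        return np.asarray(self.masses, dtype=float)


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

def _stack_to_trajectory(stack, dt: float, times=None) -> Trajectory:
    if stack.stack_depth() == 0:
        raise TrajectoryFormatError("file contains no coordinate models")
    elements = [str(e) for e in stack.element]
    masses = [mass_of_element(e) if e else mass_of_element("C") for e in elements]
    frames = []
    for m in range(stack.stack_depth()):
        coords = stack.coord[m]
        atoms = [
            AtomRecord(
                atom_name=str(stack.atom_name[i]),
                residue_name=str(stack.res_name[i]),
                residue_index=int(stack.res_id[i]),
                chain_id=str(stack.chain_id[i]) or "A",
                element=elements[i],
                coordinates=(float(coords[i, 0]), float(coords[i, 1]), float(coords[i, 2])),
                mass=masses[i],
            )
            for i in range(stack.array_length())
        ]
        t = times[m] if times is not None else m * dt
        frames.append(Frame(atoms, time=float(t)))
    return Trajectory(frames, dt=dt)


def read_multimodel_pdb(path: str | Path, dt: float = 2.0) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Each MODEL becomes one frame; a file with bare ATOM records and no MODEL
    yields a single-frame trajectory.  Frame times are synthesized as
    ``model_ordinal * dt`` (dt in ps, default 2) because the PDB format
    carries no time field.  Alternate locations other than '' or 'A' are
    dropped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - biotite error text varies
        raise TrajectoryFormatError(f"cannot parse {path}: {exc}") from exc
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stack = pdb_file.get_structure(model=None, altloc="first")
    except Exception as exc:
        msg = str(exc)
        if "models" in msg.lower() or "model" in msg.lower():
            raise TrajectoryStructureError(
                f"inconsistent atom counts across MODELs in {path}: {msg}"
            ) from exc
        raise TrajectoryFormatError(f"cannot parse ATOM records in {path}: {msg}") from exc
    return _stack_to_trajectory(stack, dt=dt)


def write_multimodel_pdb(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (fixed-width standard columns)."""
    ref = traj.frames[0]
    n = len(ref)
    atoms = struc.AtomArray(n)
    atoms.coord = ref.coordinates
    atoms.chain_id = np.array([a.chain_id for a in ref.atoms], dtype="U4")
    atoms.res_id = np.array([a.residue_index for a in ref.atoms], dtype=int)
    atoms.res_name = np.array([a.residue_name for a in ref.atoms], dtype="U5")
    atoms.atom_name = np.array([a.atom_name for a in ref.atoms], dtype="U6")
    atoms.element = np.array([a.element for a in ref.atoms], dtype="U2")
    atoms.hetero = np.zeros(n, dtype=bool)
    stack = struc.stack([atoms] * len(traj))
    stack.coord = traj.coordinates()
    out = pdb.PDBFile()
    out.set_structure(stack)
    out.write(str(path))


# ---------------------------------------------------------------------------
# XYZT plain-text dialect
# ---------------------------------------------------------------------------

def write_xyzt(traj: Trajectory, path: str | Path) -> None:
    """Write the XYZT dialect: ``natoms ndim`` header, then per frame one
    ``time`` line followed by ``natoms`` lines of ``x y z`` (Å, ps)."""
    with open(path, "w") as fh:
        fh.write(f"{traj.n_atoms} 3\n")
        for fr in traj.frames:
            fh.write(f"{float(fr.time)!r}\n")
            for a in fr.atoms:
                x, y, z = (float(v) for v in a.coordinates)
                fh.write(f"{x!r} {y!r} {z!r}\n")


def read_xyzt(path: str | Path, template: Frame | None = None) -> Trajectory:
    """Read the XYZT dialect.

    Atom labels are taken from ``template`` when given (its atom count must
    match the header); otherwise generic one-bead glycine residues on chain A
    are synthesized.
    """
    path = Path(path)
    lines = path.read_text().split("\n")
    if not lines or not lines[0].strip():
        raise TrajectoryFormatError(f"{path}: empty file")
    try:
        natoms, ndim = (int(tok) for tok in lines[0].split())
    except ValueError as exc:
        raise TrajectoryFormatError(f"{path}:1: bad header {lines[0]!r}") from exc
    if ndim != 3:
        raise TrajectoryFormatError(f"{path}: only 3-dimensional data supported")
    if template is not None and len(template) != natoms:
        raise TrajectoryStructureError(
            f"template has {len(template)} atoms but file declares {natoms}"
        )
    frames = []
    i = 1
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            t = float(lines[i])
        except ValueError as exc:
            raise TrajectoryFormatError(f"{path}:{i + 1}: expected time value") from exc
        block = lines[i + 1: i + 1 + natoms]
        if len(block) < natoms:
            raise TrajectoryStructureError(
                f"{path}: truncated frame at line {i + 1}"
            )
        try:
            coords = np.array([[float(v) for v in ln.split()] for ln in block])
        except ValueError as exc:
            raise TrajectoryFormatError(
                f"{path}: bad coordinate line within frame at line {i + 1}"
            ) from exc
        if coords.shape != (natoms, 3):
            raise TrajectoryFormatError(f"{path}: bad coordinate block at line {i + 1}")
        if template is None:
            c_mass = mass_of_element("C")
            atoms = [
                AtomRecord("CA", "GLY", k + 1, "A", "C",
                           tuple(coords[k]), c_mass)
                for k in range(natoms)
            ]
            frames.append(Frame(atoms, time=t))
        else:
            frames.append(template.with_coordinates(coords, time=t))
        i += 1 + natoms
    return Trajectory(frames)


# ---------------------------------------------------------------------------
# Selections and windows
# ---------------------------------------------------------------------------

def select_representatives(
    traj: Trajectory | Frame,
    scheme: str = "CB_with_CA_for_GLY",
    custom: Iterable[int] | None = None,
) -> Selection:
    """Pick one representative atom per residue.

    Schemes: ``"CA"`` (α-carbons), ``"CB_with_CA_for_GLY"`` (β-carbons with
    the α-carbon standing in for glycine, the residue-network convention), or
    ``"custom"`` with an explicit index list (one per residue).
    """
    frame = traj.frames[0] if isinstance(traj, Trajectory) else traj
    # group atoms by residue, preserving file order
    residues: dict[tuple[str, int, str], dict[str, int]] = {}
    order: list[tuple[str, int, str]] = []
    for i, a in enumerate(frame.atoms):
        key = (a.chain_id, a.residue_index, a.residue_name)
        if key not in residues:
            residues[key] = {}
            order.append(key)
        residues[key].setdefault(a.atom_name, i)

    if scheme == "custom":
        if custom is None:
            raise SelectionError("custom scheme requires an index list")
        indices = [int(i) for i in custom]
        for i in indices:
            if not 0 <= i < len(frame.atoms):
                raise SelectionError(f"custom index {i} out of bounds")
        labels = [
            (frame.atoms[i].chain_id, frame.atoms[i].residue_index,
             frame.atoms[i].residue_name)
            for i in indices
        ]
        if len(set(labels)) != len(labels):
            raise SelectionError("custom selection picks a residue more than once")
        masses = [frame.atoms[i].mass for i in indices]
        return Selection(indices, labels, masses)

    indices, labels = [], []
    for key in order:
        chain, resid, resname = key
        names = residues[key]
        if scheme == "CA":
            if "CA" not in names:
                raise SelectionError(f"residue {chain}:{resid}:{resname} has no CA atom")
            idx = names["CA"]
        elif scheme == "CB_with_CA_for_GLY":
            if resname.upper() == "GLY":
                if "CA" not in names:
                    raise SelectionError(
                        f"glycine {chain}:{resid} has no CA atom"
                    )
                idx = names["CA"]
            elif "CB" in names:
                idx = names["CB"]
            elif "CA" in names:
                idx = names["CA"]
            else:
                raise SelectionError(
                    f"residue {chain}:{resid}:{resname} has neither CB nor CA"
                )
        else:
            raise SelectionError(f"unknown selection scheme {scheme!r}")
        indices.append(idx)
        labels.append(key)
    masses = [frame.atoms[i].mass for i in indices]
    return Selection(indices, labels, masses)


def window_frames(
    traj: Trajectory,
    start_time: float,
    end_time: float,
    stride_time: float | None = None,
) -> Trajectory:
    """Keep frames with times in ``[start_time, end_time]``, thinned so each
    kept frame is at least ``stride_time`` ps after the previous kept one."""
    if start_time >= end_time:
        raise ValueError("start_time must be < end_time")
    kept = []
    last_kept = None
    for fr in traj.frames:
        if fr.time < start_time or fr.time > end_time:
            continue
        if last_kept is None or stride_time is None or fr.time >= last_kept + stride_time:
            kept.append(fr)
            last_kept = fr.time
    if not kept:
        t = traj.times
        raise EmptyWindowError(
            f"window [{start_time}, {end_time}] ps matches no frames; "
            f"trajectory spans [{t[0]}, {t[-1]}] ps"
        )
    return Trajectory(kept, dt=traj.dt)


def last_fraction_window(
    traj: Trajectory, fraction: float = 0.15, stride_time: float | None = None
) -> Trajectory:
    """Window covering the last ``fraction`` of the simulated time span.

    Mirrors the convention of sampling the final segment of a production run
    (default: last 15% at the caller's stride).
    """
    t = traj.times
    span = t[-1] - t[0]
    start = t[-1] - fraction * span
    return window_frames(traj, start, t[-1], stride_time)
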