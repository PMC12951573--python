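"""Trajectory and topology I/O plus periodic-boundary geometry primitives.

Coordinates are held in nanometres internally. GRO files are read and written
in nm (the format's native unit); XYZ and PDB files are read and written in
Angstrom (their conventional unit) and converted on the fly. Only orthorhombic
boxes are supported: the analyses downstream all assume an L_x x L_y x L_z
periodic cell.

Topologies are supplied as a sidecar table (tab- or comma-delimited) rather
than parsed from force-field files; see :class:`Topology` for the column
contract.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Box",
    "Frame",
    "Topology",
    "Selection",
    "Trajectory",
    "TrajectoryParseError",
    "StructureError",
    "read_trajectory",
    "write_trajectory",
    "minimum_image_displacement",
    "minimum_image_distance",
    "center_of_mass",
    "HB_ROLES",
]

ANGSTROM_PER_NM = 10.0

#: Valid hydrogen-bond roles for topology atoms. ``donor-acceptor`` marks
#: atoms (typically hydroxyl oxygens) that act as both donor-heavy atom and
#: acceptor; it is accepted wherever either single role is required.
HB_ROLES = ("donor-heavy", "hydrogen", "acceptor", "donor-acceptor", "none")


class TrajectoryParseError(ValueError):
    """A coordinate file violates its format definition."""


class StructureError(ValueError):
    """Frames are mutually inconsistent or disagree with the topology."""


@dataclass(frozen=True)
class Box:
    """Orthorhombic periodic cell with edge lengths in nm."""

    lengths: np.ndarray

    def __post_init__(self) -> None:
        lengths = np.asarray(self.lengths, dtype=float).reshape(3)
        if not np.all(lengths > 0):
            raise ValueError(f"box lengths must be positive, got {lengths}")
        object.__setattr__(self, "lengths", lengths)

    @property
    def volume(self) -> float:
        """Cell volume in nm^3."""
        return float(np.prod(self.lengths))

    def wrap(self, coords: np.ndarray) -> np.ndarray:
        """Wrap coordinates into [0, L) per dimension."""
        return np.mod(coords, self.lengths)


@dataclass
class Frame:
    """A single configuration: N x 3 coordinates (nm) at a time point (ps)."""

    coords: np.ndarray
    time: float
    box: Box

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("frame coordinates must be an N x 3 array")


class Topology:
    """Per-atom metadata backing every analysis.

    Columns (one row per atom, in file order):

    ``element``
        chemical element symbol
    ``mass``
        atomic mass, amu
    ``vdw_radius``
        van der Waals radius, nm (may be NaN when SASA is not needed)
    ``molecule_id``
        integer molecule membership
    ``species_name``
        compound name shared by all atoms of a species (e.g. ``water``)
    ``hb_role``
        one of ``donor-heavy``, ``hydrogen``, ``acceptor``, ``donor-acceptor``,
        ``none``
    ``bonded_hydrogens``
        for donor-heavy atoms, the atom indices of their covalent hydrogens
        (comma-separated in the sidecar file, empty otherwise)
    ``atom_name``
        optional per-atom label used by name-filtered selections; defaults to
        the element symbol
    """

    REQUIRED = ("element", "mass", "vdw_radius", "molecule_id", "species_name",
                "hb_role")

    def __init__(self, table: pd.DataFrame,
                 bonded_hydrogens: dict[int, list[int]] | None = None):
        table = table.reset_index(drop=True)
        for col in self.REQUIRED:
            if col not in table.columns:
                raise ValueError(f"topology table missing column {col!r}")
        bad = set(table["hb_role"]) - set(HB_ROLES)
        if bad:
            raise ValueError(f"unknown hb_role values: {sorted(bad)}")
        if (table["species_name"].astype(str) == "").any():
            raise ValueError("species_name must be non-empty for every atom")
        if "atom_name" not in table.columns:
            table = table.assign(atom_name=table["element"])
        self.table = table
        self.bonded_hydrogens = {int(k): [int(i) for i in v]
                                 for k, v in (bonded_hydrogens or {}).items()}
        self._validate_hb()

    def _validate_hb(self) -> None:
        owner: dict[int, int] = {}
        for donor, hydrogens in self.bonded_hydrogens.items():
            if self.table.loc[donor, "hb_role"] not in ("donor-heavy", "donor-acceptor"):
                raise ValueError(f"atom {donor} lists hydrogens but is not donor-heavy")
            for h in hydrogens:
                if self.table.loc[h, "hb_role"] != "hydrogen":
                    raise ValueError(f"atom {h} bonded to donor {donor} is not labelled hydrogen")
                if h in owner:
                    raise ValueError(f"hydrogen {h} listed under two donors ({owner[h]}, {donor})")
                owner[h] = donor
        hydrogens = set(np.flatnonzero((self.table["hb_role"] == "hydrogen").to_numpy()))
        orphan = hydrogens - set(owner)
        if orphan:
            raise ValueError(f"hydrogens without a donor-heavy owner: {sorted(orphan)}")

    # -- convenience accessors -------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.table)

    @property
    def masses(self) -> np.ndarray:
        return self.table["mass"].to_numpy(dtype=float)

    @property
    def molecule_ids(self) -> np.ndarray:
        return self.table["molecule_id"].to_numpy(dtype=int)

    @property
    def species(self) -> np.ndarray:
        return self.table["species_name"].to_numpy(dtype=object)

    @property
    def vdw_radii(self) -> np.ndarray:
        return self.table["vdw_radius"].to_numpy(dtype=float)

    def atoms_of_species(self, name: str) -> np.ndarray:
        return np.flatnonzero(self.species == name)

    def molecules_of_species(self, name: str) -> np.ndarray:
        ids = self.molecule_ids[self.atoms_of_species(name)]
        return np.unique(ids)

    def donors(self) -> np.ndarray:
        mask = self.table["hb_role"].isin(["donor-heavy", "donor-acceptor"])
        return np.flatnonzero(mask.to_numpy())

    def acceptors(self) -> np.ndarray:
        mask = self.table["hb_role"].isin(["acceptor", "donor-acceptor"])
        return np.flatnonzero(mask.to_numpy())

    # -- sidecar I/O -----------------------------------------------------------
    @classmethod
    def read(cls, path: str | os.PathLike) -> "Topology":
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
        bonded: dict[int, list[int]] = {}
        if "bonded_hydrogens" in df.columns:
            for idx, cell in enumerate(df["bonded_hydrogens"]):
                if pd.isna(cell):
                    continue
                text = str(cell).strip()
                if text:
                    bonded[idx] = [int(float(tok)) for tok in text.split(",")]
            df = df.drop(columns=["bonded_hydrogens"])
        return cls(df, bonded)

    def write(self, path: str | os.PathLike) -> None:
        df = self.table.copy()
        df["bonded_hydrogens"] = [
            ",".join(str(i) for i in self.bonded_hydrogens.get(idx, []))
            for idx in range(len(df))
        ]
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class Selection:
    """A set of analysis sites: the atoms (or molecule centres of mass) of one
    species, optionally narrowed to named atoms."""

    species_name: str
    granularity: str = "molecule-COM"
    atom_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.granularity not in ("atom", "molecule-COM"):
            raise ValueError("granularity must be 'atom' or 'molecule-COM'")
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", tuple(self.atom_names))

    def atom_indices(self, topology: Topology) -> np.ndarray:
        idx = topology.atoms_of_species(self.species_name)
        if self.atom_names is not None:
            names = topology.table["atom_name"].to_numpy(dtype=object)[idx]
            idx = idx[np.isin(names, self.atom_names)]
        if idx.size == 0:
            raise ValueError(
                f"selection {self.species_name!r} resolves to no atoms")
        return idx

    def sites(self, frame: Frame, topology: Topology) -> np.ndarray:
        """Site coordinates for this selection in one frame, nm."""
        idx = self.atom_indices(topology)
        if self.granularity == "atom":
            return frame.coords[idx]
        mol_ids = np.unique(topology.molecule_ids[idx])
        return np.array([center_of_mass(frame, m, topology) for m in mol_ids])

    def n_sites(self, topology: Topology) -> int:
        idx = self.atom_indices(topology)
        if self.granularity == "atom":
            return idx.size
        return np.unique(topology.molecule_ids[idx]).size


class Trajectory:
    """An ordered sequence of frames sharing one topology and box.

    ``coords`` are wrapped coordinates, shape (n_frames, n_atoms, 3) in nm.
    ``unwrapped`` optionally carries continuous (image-unfolded) coordinates
    for displacement-based analyses such as the MSD; file readers leave it
    ``None`` because wrapped frames do not determine the unwrapped path.
    """

    def __init__(self, coords: np.ndarray, times: np.ndarray, box: Box,
                 topology: Topology | None = None,
                 unwrapped: np.ndarray | None = None):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError("trajectory coordinates must be (n_frames, n_atoms, 3)")
        times = np.asarray(times, dtype=float)
        if times.shape != (coords.shape[0],):
            raise ValueError("one time per frame required")
        if times.size > 1 and np.any(np.diff(times) < 0):
            raise StructureError("frame times must be non-decreasing")
        if topology is not None and topology.n_atoms != coords.shape[1]:
            raise StructureError(
                f"topology has {topology.n_atoms} atoms but frames have {coords.shape[1]}")
        if unwrapped is not None:
            unwrapped = np.asarray(unwrapped, dtype=float)
            if unwrapped.shape != coords.shape:
                raise ValueError("unwrapped coordinates must match coords shape")
        self.coords = coords
        self.times = times
        self.box = box
        self.topology = topology
        self.unwrapped = unwrapped

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(self.coords[i], float(self.times[i]), self.box)

    def __iter__(self) -> Iterable[Frame]:
        return (self.frame(i) for i in range(self.n_frames))


# ---------------------------------------------------------------------------
# Periodic-boundary geometry
# ---------------------------------------------------------------------------

def minimum_image_displacement(a: np.ndarray, b: np.ndarray, box: Box) -> np.ndarray:
    """Shortest periodic displacement vector(s) from ``b`` to ``a``, nm.

    Broadcasts over leading dimensions of ``a`` and ``b``.
    """
    delta = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return delta - box.lengths * np.round(delta / box.lengths)


def minimum_image_distance(a: np.ndarray, b: np.ndarray, box: Box) -> float | np.ndarray:
    """Shortest distance between ``a`` and ``b`` over all periodic images."""
    delta = minimum_image_displacement(a, b, box)
    return np.linalg.norm(delta, axis=-1)


def center_of_mass(frame: Frame, molecule_id: int, topology: Topology) -> np.ndarray:
    """Mass-weighted centre of a molecule made whole across the boundary.

    Atoms are unwrapped relative to the molecule's first atom before
    averaging, then the centre is wrapped back into the box, so a molecule
    straddling the boundary gets its physical centre, not the arithmetic mean
    of wrapped coordinates.
    """
    idx = np.flatnonzero(topology.molecule_ids == molecule_id)
    if idx.size == 0:
        raise ValueError(f"no atoms with molecule_id {molecule_id}")
    masses = topology.masses[idx]
    total = masses.sum()
    if total <= 0:
        raise ValueError(f"molecule {molecule_id} has non-positive total mass")
    ref = frame.coords[idx[0]]
    rel = minimum_image_displacement(frame.coords[idx], ref, frame.box)
    com = ref + (masses[:, None] * rel).sum(axis=0) / total
    return frame.box.wrap(com)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_trajectory(path: str | os.PathLike, format: str | None = None,
                    topology: Topology | None = None,
                    box: Box | None = None) -> Trajectory:
    """Read a (possibly multi-frame) coordinate file.

    Parameters
    ----------
    path:
        Coordinate file. Multi-frame files are plain concatenations (GRO,
        XYZ) or MODEL-record based (PDB).
    format:
        ``gro``, ``xyz`` or ``pdb``; inferred from the extension when omitted.
    topology:
        Optional sidecar topology; atom counts are cross-checked.
    box:
        Required for XYZ (the format carries no cell) and for PDB files
        without a CRYST1 record; ignored when the file carries a box.
    """
    path = os.fspath(path)
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").lower()
    format = format.lower()
    if format == "gro":
        traj = _read_gro(path)
    elif format in ("xyz", "pdb"):
        traj = _read_mdanalysis(path, format, box)
    else:
        raise ValueError(f"unsupported trajectory format {format!r}")
    if traj.box is None:  # pragma: no cover - guarded in readers
        raise ValueError("no box in file and none supplied")
    if topology is not None:
        traj = Trajectory(traj.coords, traj.times, traj.box, topology)
    return traj


def _read_gro(path: str) -> Trajectory:
    """Concatenated multi-frame GRO. Fixed columns, lengths in nm."""
    frames: list[np.ndarray] = []
    times: list[float] = []
    box_lengths = None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    n_frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        time = 0.0
        if "t=" in title:
            try:
                time = float(title.rsplit("t=", 1)[1].split()[0])
            except (ValueError, IndexError):
                time = float(n_frame)
        else:
            time = float(n_frame)
        try:
            n_atoms = int(lines[i + 1])
        except (ValueError, IndexError) as exc:
            raise TrajectoryParseError(
                f"{path}:{i + 2}: expected atom count, got {lines[i + 1]!r}") from exc
        atom_lines = lines[i + 2:i + 2 + n_atoms]
        if len(atom_lines) < n_atoms:
            raise TrajectoryParseError(f"{path}: truncated frame starting at line {i + 1}")
        coords = np.empty((n_atoms, 3))
        for j, line in enumerate(atom_lines):
            try:
                coords[j] = (float(line[20:28]), float(line[28:36]), float(line[36:44]))
            except ValueError as exc:
                raise TrajectoryParseError(
                    f"{path}:{i + 3 + j}: malformed GRO atom record") from exc
        box_line = lines[i + 2 + n_atoms].split()
        if len(box_line) < 3:
            raise TrajectoryParseError(
                f"{path}:{i + 3 + n_atoms}: malformed GRO box line")
        lengths = np.array([float(v) for v in box_line[:3]])
        if box_lengths is not None and not np.allclose(lengths, box_lengths):
            raise StructureError(f"{path}: box changes between frames")
        box_lengths = lengths
        if frames and coords.shape[0] != frames[0].shape[0]:
            raise StructureError(
                f"{path}: frame {n_frame + 1} has {coords.shape[0]} atoms, "
                f"frame 1 had {frames[0].shape[0]}")
        frames.append(coords)
        times.append(time)
        n_frame += 1
        i += 2 + n_atoms + 1
    if not frames:
        raise TrajectoryParseError(f"{path}: no frames found")
    return Trajectory(np.stack(frames), np.array(times), Box(box_lengths))


def _read_mdanalysis(path: str, format: str, box: Box | None) -> Trajectory:
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            universe = mda.Universe(path, format=format.upper())
        except Exception as exc:
            raise TrajectoryParseError(f"{path}: {exc}") from exc
        frames, times = [], []
        file_box = None
        for n, ts in enumerate(universe.trajectory):
            frames.append(universe.atoms.positions.astype(float) / ANGSTROM_PER_NM)
            times.append(float(ts.time) if ts.time is not None else float(n))
            if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                if not np.allclose(ts.dimensions[3:], 90.0):
                    raise StructureError(f"{path}: only orthorhombic boxes supported")
                file_box = Box(ts.dimensions[:3] / ANGSTROM_PER_NM)
    if file_box is None and box is None:
        raise ValueError(f"{path}: format carries no box; pass box= explicitly")
    return Trajectory(np.stack(frames), np.array(times), file_box or box)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path: str | os.PathLike,
                     format: str | None = None) -> None:
    """Write all frames to a GRO, XYZ or PDB file (plain concatenation /
    MODEL records)."""
    path = os.fspath(path)
    if format is None:
        format = os.path.splitext(path)[1].lstrip(".").lower()
    writer = {"gro": _write_gro, "xyz": _write_xyz, "pdb": _write_pdb}.get(format.lower())
    if writer is None:
        raise ValueError(f"unsupported trajectory format {format!r}")
    with open(path, "w") as fh:
        writer(traj, fh)


def _atom_labels(traj: Trajectory) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if traj.topology is not None:
        names = traj.topology.table["atom_name"].to_numpy(dtype=object)
        resids = traj.topology.molecule_ids
        resnames = np.array([s[:5] for s in traj.topology.species], dtype=object)
    else:
        names = np.array(["X"] * traj.n_atoms, dtype=object)
        resids = np.arange(1, traj.n_atoms + 1)
        resnames = np.array(["UNK"] * traj.n_atoms, dtype=object)
    return names, resids, resnames


def _write_gro(traj: Trajectory, fh: io.TextIOBase) -> None:
    names, resids, resnames = _atom_labels(traj)
    lx, ly, lz = traj.box.lengths
    for f in range(traj.n_frames):
        fh.write(f"kbsolv t= {traj.times[f]:.4f}\n{traj.n_atoms}\n")
        for a in range(traj.n_atoms):
            x, y, z = traj.coords[f, a]
            fh.write(f"{int(resids[a]) % 100000:>5d}{resnames[a]:<5.5s}"
                     f"{str(names[a]):>5.5s}{(a + 1) % 100000:>5d}"
                     f"{x:8.3f}{y:8.3f}{z:8.3f}\n")
        fh.write(f"{lx:10.5f}{ly:10.5f}{lz:10.5f}\n")


def _write_xyz(traj: Trajectory, fh: io.TextIOBase) -> None:
    names, _, _ = _atom_labels(traj)
    if traj.topology is not None:
        names = traj.topology.table["element"].to_numpy(dtype=object)
    for f in range(traj.n_frames):
        fh.write(f"{traj.n_atoms}\nkbsolv t= {traj.times[f]:.4f}\n")
        for a in range(traj.n_atoms):
            x, y, z = traj.coords[f, a] * ANGSTROM_PER_NM
            fh.write(f"{str(names[a]):<4s} {x:14.8f} {y:14.8f} {z:14.8f}\n")


def _write_pdb(traj: Trajectory, fh: io.TextIOBase) -> None:
    names, resids, resnames = _atom_labels(traj)
    lx, ly, lz = traj.box.lengths * ANGSTROM_PER_NM
    fh.write(f"CRYST1{lx:9.3f}{ly:9.3f}{lz:9.3f}"
             f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n")
    for f in range(traj.n_frames):
        fh.write(f"MODEL     {f + 1:>4d}\n")
        for a in range(traj.n_atoms):
            x, y, z = traj.coords[f, a] * ANGSTROM_PER_NM
            element = (traj.topology.table.loc[a, "element"]
                       if traj.topology is not None else "X")
            fh.write(f"ATOM  {(a + 1) % 100000:>5d} {str(names[a])[:4]:<4s}"
                     f"{str(resnames[a])[:3]:>4s} A{int(resids[a]) % 10000:>4d}    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                     f"          {str(element)[:2]:>2s}\n")
        fh.write("ENDMDL\n")
    fh.write("END\n")
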