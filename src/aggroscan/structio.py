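"""Structure and trajectory I/O with a uniform atom/residue/chain model.

Canonical internal units are Å for coordinates, Da for masses and ns for
time.  GRO files (nm) are converted on read/write; PDB files are native.
The parsers are deliberately strict about the fixed-column dialects so
that malformed inputs fail with the offending line number instead of
propagating garbage coordinates into downstream surface-area sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "ParseError",
    "read_pdb",
    "read_gro",
    "read_trajectory",
    "write_pdb",
    "write_gro",
    "write_scored_pdb",
    "VDW_RADII",
    "ATOMIC_MASSES",
]


class ParseError(ValueError):
    """Raised when a structure file violates its fixed-column dialect."""


# Bondi-style van der Waals radii (Å).  Unknown elements fall back to the
# generic carbon radius with a warning.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "B": 1.92,
    "NA": 2.27,
    "K": 2.75,
    "MG": 1.73,
    "ZN": 1.39,
    "CA": 2.31,
    "FE": 1.94,
}
_FALLBACK_RADIUS = 1.70

ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "BR": 79.904,
    "I": 126.904,
    "SE": 78.971,
    "B": 10.81,
    "NA": 22.990,
    "K": 39.098,
    "MG": 24.305,
    "ZN": 65.38,
    "CA": 40.078,
    "FE": 55.845,
}
_FALLBACK_MASS = 12.011


def element_vdw_radius(element: str) -> float:
    """Van der Waals radius (Å) for an element symbol, with fallback."""
    key = element.strip().upper()
    if key in VDW_RADII:
        return VDW_RADII[key]
    warnings.warn(
        f"unknown element {element!r}: using fallback vdW radius "
        f"{_FALLBACK_RADIUS} Å",
        stacklevel=2,
    )
    return _FALLBACK_RADIUS


def element_mass(element: str) -> float:
    key = element.strip().upper()
    return ATOMIC_MASSES.get(key, _FALLBACK_MASS)


def guess_element(atom_name: str) -> str:
    """Guess an element symbol from a PDB/GRO atom name.

    Digits and primes are ignored; two-letter symbols are recognised only
    when the stripped name starts with a known two-letter element (CL, BR,
    ...) to avoid mistaking CA (Cα) for calcium.
    """
    stripped = "".join(ch for ch in atom_name if ch.isalpha())
    if not stripped:
        raise ParseError(f"cannot guess element from atom name {atom_name!r}")
    two = stripped[:2].upper()
    if two in {"CL", "BR", "SE", "NA", "MG", "ZN", "FE"} and len(stripped) == 2:
        return two.capitalize()
    return stripped[0].upper()


@dataclass(frozen=True)
class Atom:
    """A single atom with identity, coordinates (Å) and physical constants."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_seq: int
    chain_id: str
    coords: np.ndarray
    mass: float
    vdw_radius: float
    bfactor: float = 0.0
    altloc: str = ""
    icode: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.serial}: coords must be a finite 3-vector")
        object.__setattr__(self, "coords", coords)
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.serial}: vdw_radius must be positive")
        if self.mass < 0:
            raise ValueError(f"atom {self.serial}: mass must be non-negative")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_seq, self.icode)


class Structure:
    """An ordered collection of atoms with residue/chain index maps."""

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: list[Atom] = list(atoms)
        seen: set[tuple] = set()
        for atom in self.atoms:
            key = (atom.chain_id, atom.residue_seq, atom.icode, atom.name)
            if key in seen:
                raise ValueError(
                    f"duplicate atom after altloc resolution: "
                    f"chain {atom.chain_id!r} residue {atom.residue_seq} "
                    f"name {atom.name!r}"
                )
            seen.add(key)
        # residue membership partitions the atom list
        self._residue_atoms: dict[tuple, list[int]] = {}
        for i, atom in enumerate(self.atoms):
            self._residue_atoms.setdefault(atom.residue_key, []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self):
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([a.vdw_radius for a in self.atoms], dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms], dtype=float)

    def residues(self) -> dict[tuple, list[int]]:
        """Map (chain_id, residue_seq, icode) -> member atom indices."""
        return {k: list(v) for k, v in self._residue_atoms.items()}

    def residue_name(self, key: tuple) -> str:
        return self.atoms[self._residue_atoms[key][0]].residue_name

    def subset(self, indices: Iterable[int]) -> "Structure":
        return Structure([self.atoms[i] for i in indices])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape does not match atom count")
        return Structure(
            [replace(a, coords=coords[i]) for i, a in enumerate(self.atoms)]
        )


@dataclass
class Trajectory:
    """A topology plus an ordered stack of coordinate frames (Å)."""

    topology: Structure
    frames: np.ndarray  # (n_frames, n_atoms, 3) in Å
    times: np.ndarray | None = None  # ns
    box: np.ndarray | None = field(default=None)  # Å, per-frame or single

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1] != len(self.topology):
            raise ValueError(
                "frames must be (n_frames, n_atoms, 3) matching the topology"
            )
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.frames.shape[0],):
                raise ValueError("one time stamp per frame required")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame_structure(self, index: int) -> Structure:
        return self.topology.with_coords(self.frames[index])


# ---------------------------------------------------------------------------
# PDB reading/writing
# ---------------------------------------------------------------------------

def _parse_pdb_atom_line(line: str, lineno: int) -> Atom | None:
    altloc = line[16:17].strip()
    if altloc not in ("", "A"):
        return None
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        resname = line[17:20].strip()
        chain = line[21:22].strip() or "A"
        resseq = int(line[22:26])
        icode = line[26:27].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except (ValueError, IndexError) as exc:
        raise ParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    bfac_field = line[60:66].strip()
    bfactor = float(bfac_field) if bfac_field else 0.0
    element_field = line[76:78].strip()
    element = element_field.capitalize() if element_field else guess_element(name)
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=resname,
        residue_seq=resseq,
        chain_id=chain,
        coords=np.array([x, y, z]),
        mass=element_mass(element),
        vdw_radius=element_vdw_radius(element),
        bfactor=bfactor,
        altloc=altloc,
        icode=icode,
    )


def read_pdb(path: str | Path) -> Structure:
    """Read ATOM/HETATM records from a PDB file into a :class:`Structure`.

    Only altloc ``'A'`` or blank is kept; later altlocs for the same atom
    are dropped.  vdW radii and masses come from the embedded element
    tables.  Stops at the first ENDMDL so that a multi-model file yields
    its first model.
    """
    atoms: list[Atom] = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6]
            if record in ("ATOM  ", "HETATM"):
                atom = _parse_pdb_atom_line(line, lineno)
                if atom is not None:
                    atoms.append(atom)
            elif record.strip() == "ENDMDL":
                break
    if not atoms:
        raise ParseError(f"{path}: no ATOM/HETATM records found")
    return Structure(atoms)


def _format_pdb_atom(atom: Atom, serial: int, bfactor: float) -> str:
    name = atom.name
    # element-aligned name layout: 1-letter elements start in column 14
    if len(name) < 4 and len(atom.element) == 1:
        name = f" {name}"
    bfactor = float(np.clip(bfactor, -9.99, 999.99))
    return (
        f"ATOM  {serial:>5d} {name:<4s}{'':1s}{atom.residue_name:>3s} "
        f"{atom.chain_id:1s}{atom.residue_seq:>4d}{atom.icode:1s}   "
        f"{atom.coords[0]:8.3f}{atom.coords[1]:8.3f}{atom.coords[2]:8.3f}"
        f"{1.00:6.2f}{bfactor:6.2f}          {atom.element.upper():>2s}"
    )


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write a structure as fixed-column ATOM records."""
    with open(path, "w") as handle:
        for i, atom in enumerate(structure, start=1):
            handle.write(_format_pdb_atom(atom, i, atom.bfactor) + "\n")
        handle.write("END\n")


def write_scored_pdb(
    structure: Structure, per_atom_scores: Sequence[float], path: str | Path
) -> None:
    """Write a PDB with one score per atom stored in the B-factor column.

    Scores are clipped to the numeric width of columns 61–66; re-reading
    the file recovers them to two decimals.
    """
    scores = np.asarray(per_atom_scores, dtype=float)
    if scores.shape != (len(structure),):
        raise ValueError(
            f"score count {scores.size} does not match atom count {len(structure)}"
        )
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    with open(path, "w") as handle:
        for i, atom in enumerate(structure):
            handle.write(_format_pdb_atom(atom, i + 1, scores[i]) + "\n")
        handle.write("END\n")


# ---------------------------------------------------------------------------
# GRO reading/writing
# ---------------------------------------------------------------------------

_NM_TO_A = 10.0


def read_gro(path: str | Path) -> Structure:
    """Read a GROMACS GRO file; coordinates are converted nm → Å.

    The box vector (last line) is retained in Å on the returned structure
    as the ``box`` attribute.  GRO has no chain column; all atoms land in
    chain ``'A'``.
    """
    with open(path) as handle:
        lines = handle.read().splitlines()
    if len(lines) < 3:
        raise ParseError(f"{path}: truncated GRO file")
    try:
        n_atoms = int(lines[1].strip())
    except ValueError as exc:
        raise ParseError(f"line 2: expected atom count, got {lines[1]!r}") from exc
    body = lines[2:]
    if len(body) < n_atoms + 1:
        raise ParseError(
            f"{path}: header declares {n_atoms} atoms but body has "
            f"{max(len(body) - 1, 0)}"
        )
    atoms: list[Atom] = []
    for i in range(n_atoms):
        line = body[i]
        lineno = i + 3
        try:
            resseq = int(line[0:5])
            resname = line[5:10].strip()
            name = line[10:15].strip()
            serial = int(line[15:20])
            x = float(line[20:28]) * _NM_TO_A
            y = float(line[28:36]) * _NM_TO_A
            z = float(line[36:44]) * _NM_TO_A
        except (ValueError, IndexError) as exc:
            raise ParseError(f"line {lineno}: malformed GRO atom line: {exc}") from exc
        element = guess_element(name)
        atoms.append(
            Atom(
                serial=serial,
                name=name,
                element=element,
                residue_name=resname,
                residue_seq=resseq,
                chain_id="A",
                coords=np.array([x, y, z]),
                mass=element_mass(element),
                vdw_radius=element_vdw_radius(element),
            )
        )
    box_fields = body[n_atoms].split()
    structure = Structure(atoms)
    structure.box = np.array([float(v) * _NM_TO_A for v in box_fields])
    return structure


def write_gro(structure: Structure, path: str | Path, box_nm=(10.0, 10.0, 10.0)) -> None:
    """Write a structure as a GRO file (Å → nm on write)."""
    with open(path, "w") as handle:
        handle.write("generated by aggroscan\n")
        handle.write(f"{len(structure):5d}\n")
        for atom in structure:
            x, y, z = atom.coords / _NM_TO_A
            handle.write(
                f"{atom.residue_seq % 100000:5d}{atom.residue_name:<5s}"
                f"{atom.name:>5s}{atom.serial % 100000:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        handle.write(f"{box_nm[0]:10.5f}{box_nm[1]:10.5f}{box_nm[2]:10.5f}\n")


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def _read_multimodel_pdb_frames(path: str | Path) -> list[np.ndarray]:
    frames: list[np.ndarray] = []
    current: list[np.ndarray] | None = None
    saw_model = False
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                saw_model = True
                current = []
            elif record == "ENDMDL":
                if current is not None:
                    frames.append(np.array(current, dtype=float))
                current = None
            elif line[:6] in ("ATOM  ", "HETATM"):
                atom = _parse_pdb_atom_line(line, lineno)
                if atom is None:
                    continue
                if current is None:
                    if saw_model:
                        raise ParseError(
                            f"line {lineno}: ATOM record outside MODEL/ENDMDL"
                        )
                    current = []
                    saw_model = False
                current.append(atom.coords)
    if current:
        frames.append(np.array(current, dtype=float))
    if not frames:
        raise ParseError(f"{path}: no coordinate frames found")
    return frames


def read_trajectory(
    source: str | Path | Sequence[str | Path],
    topology: Structure,
    dt_ns: float | None = None,
) -> Trajectory:
    """Read frames from a multi-model PDB or an ordered list of GRO files.

    Atom order must match ``topology`` in every frame; a mismatch raises an
    error naming the offending frame index.  When ``dt_ns`` is given,
    frame times 0, dt, 2·dt, … are attached.
    """
    if isinstance(source, (str, Path)):
        raw_frames = _read_multimodel_pdb_frames(source)
    else:
        raw_frames = [read_gro(p).coords for p in source]
    n_atoms = len(topology)
    for idx, frame in enumerate(raw_frames):
        if frame.shape != (n_atoms, 3):
            raise ParseError(
                f"frame {idx}: has {frame.shape[0]} atoms, topology has {n_atoms}"
            )
    frames = np.stack(raw_frames)
    times = None
    if dt_ns is not None:
        times = np.arange(len(raw_frames)) * dt_ns
    return Trajectory(topology=topology, frames=frames, times=times)


def write_multimodel_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB (MODEL/ENDMDL blocks)."""
    with open(path, "w") as handle:
        for f in range(trajectory.n_frames):
            handle.write(f"MODEL     {f + 1:4d}\n")
            structure = trajectory.frame_structure(f)
            for i, atom in enumerate(structure, start=1):
                handle.write(_format_pdb_atom(atom, i, atom.bfactor) + "\n")
            handle.write("ENDMDL\n")
        handle.write("END\n")
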