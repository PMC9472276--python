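"""Structure and index-group I/O for end-state snapshot post-processing.

Reads multi-frame PDB snapshots (single file with MODEL/ENDMDL records, a
directory of per-frame PDB files, or a multi-frame XYZ), Gromacs-style
``.ndx`` index groups, extracts named atom subsets (protein, ligand,
solvent, ...) and serializes them as XYZ clusters for single-point-energy
calculators.

Conventions: coordinates are Angstrom throughout; atom indices in index
files are 1-based (Gromacs convention) and refer to atom *serials*, so
selections remain valid on frames that were filtered (ion stripping,
solvent reduction) while keeping their original serials.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Elements this package knows how to name. Covers organic chemistry, halogens
# and the common biological ions; extend as needed.
KNOWN_ELEMENTS = {
    "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne",
    "Na", "Mg", "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca",
    "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Se", "Br", "Kr", "I",
}

STANDARD_AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "HID", "HIE", "HIP", "CYX",
}

WATER_RESIDUE_NAMES = {"HOH", "SOL", "WAT", "TIP3"}


class StructureError(ValueError):
    """Malformed or inconsistent structural input."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom of one snapshot (coordinates in Angstrom)."""

    serial: int
    element: str
    atom_name: str
    residue_name: str
    residue_id: int
    mol_id: int
    coords: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.serial < 1:
            raise StructureError(f"atom serial must be positive, got {self.serial}")
        if self.element not in KNOWN_ELEMENTS:
            raise StructureError(
                f"unknown element {self.element!r} for atom "
                f"{self.atom_name!r} (serial {self.serial})"
            )
        if not all(np.isfinite(self.coords)):
            raise StructureError(f"non-finite coordinates for atom serial {self.serial}")


@dataclass
class StructureFrame:
    """One MD snapshot: an ordered list of atoms plus frame bookkeeping."""

    atoms: list[AtomRecord]
    time_ps: float = 0.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError("a frame must contain at least one atom")
        serials = [a.serial for a in self.atoms]
        if any(b <= a for a, b in zip(serials, serials[1:])):
            raise StructureError("atom serials must be strictly increasing")
        if self.time_ps < 0:
            raise StructureError("frame time must be non-negative")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def coords(self) -> np.ndarray:
        """N x 3 coordinate array (Angstrom)."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def water_mol_ids(self) -> list[int]:
        """mol_ids of water molecules, in first-appearance order."""
        seen: dict[int, None] = {}
        for a in self.atoms:
            if a.residue_name in WATER_RESIDUE_NAMES:
                seen.setdefault(a.mol_id, None)
        return list(seen)


@dataclass
class Trajectory:
    """An ordered sequence of snapshots with constant composition."""

    frames: list[StructureFrame]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("trajectory must contain at least one frame")
        ref = self.frames[0]
        for fr in self.frames[1:]:
            if fr.n_atoms != ref.n_atoms:
                raise StructureError(
                    f"frame {fr.frame_index} has {fr.n_atoms} atoms, "
                    f"expected {ref.n_atoms} (source {self.source!r})"
                )
            if fr.elements != ref.elements:
                raise StructureError(
                    f"frame {fr.frame_index} has a different element sequence "
                    f"than frame {ref.frame_index} (source {self.source!r})"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class GroupSelection:
    """Named sets of 1-based atom indices, as read from a Gromacs ndx file."""

    groups: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, idx in self.groups.items():
            if any(i < 1 for i in idx):
                raise StructureError(f"group {name!r} contains an index < 1")
            if len(set(idx)) != len(idx):
                raise StructureError(f"group {name!r} contains duplicate indices")
            self.groups[name] = sorted(idx)

    def __getitem__(self, name: str) -> list[int]:
        return self.groups[name]

    def __contains__(self, name: str) -> bool:
        return name in self.groups

    def union(self, names: Iterable[str]) -> list[int]:
        """Sorted union of the named groups' indices."""
        out: set[int] = set()
        for name in names:
            if name not in self.groups:
                raise KeyError(f"no group named {name!r} in selection")
            out.update(self.groups[name])
        return sorted(out)


@dataclass
class AtomSubset:
    """A component cluster (e.g. PL, P, L, LS, S) extracted from one frame."""

    elements: list[str]
    coords: np.ndarray
    label: str = ""
    frame_index: int = 0
    time_ps: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if len(self.elements) != self.coords.shape[0]:
            raise StructureError(
                f"{len(self.elements)} elements but {self.coords.shape[0]} coordinate rows"
            )

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


_SYMBOL_RE = re.compile(r"[A-Za-z]+")


def infer_element(atom_name: str, residue_name: str = "") -> str:
    """Infer a chemical element from a PDB atom name.

    Digits and primes are stripped; a 2-letter match is preferred except in
    standard amino-acid residues, where ambiguous names like ``HG`` (a gamma
    hydrogen, not mercury) resolve to the 1-letter symbol.
    """
    m = _SYMBOL_RE.search(atom_name)
    if not m:
        raise StructureError(f"cannot infer element from atom name {atom_name!r}")
    letters = m.group(0)
    two = letters[:2].capitalize() if len(letters) >= 2 else None
    one = letters[0].upper()
    prefer_one = residue_name.upper() in STANDARD_AMINO_ACIDS | WATER_RESIDUE_NAMES
    candidates = [one, two] if prefer_one else [two, one]
    for cand in candidates:
        if cand and cand in KNOWN_ELEMENTS:
            return cand
    raise StructureError(
        f"cannot infer element from atom name {atom_name!r} (residue {residue_name!r})"
    )


def _normalize_element(token: str, atom_name: str) -> str:
    sym = token.strip().capitalize()
    if sym not in KNOWN_ELEMENTS:
        raise StructureError(
            f"unknown element token {token!r} for atom {atom_name!r}"
        )
    return sym


def assign_mol_ids(residue_ids: Sequence[int], residue_names: Sequence[str]) -> list[int]:
    """Label contiguous runs of identical (residue_id, residue_name) as molecules."""
    mol_ids: list[int] = []
    current = 0
    prev: tuple[int, str] | None = None
    for rid, rname in zip(residue_ids, residue_names):
        key = (rid, rname)
        if prev is not None and key != prev:
            current += 1
        mol_ids.append(current)
        prev = key
    return mol_ids


# ---------------------------------------------------------------------------
# Gromacs index files


def read_ndx(path: str | Path) -> GroupSelection:
    """Parse a Gromacs-format index file into named 1-based index groups.

    Duplicate group names: the last definition wins (a warning is logged).
    Empty groups are retained but flagged with a warning.
    """
    path = Path(path)
    groups: dict[str, list[int]] = {}
    current: str | None = None
    header_re = re.compile(r"^\[\s*(.+?)\s*\]$")
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split(";", 1)[0].strip()
            if not line:
                continue
            m = header_re.match(line)
            if m:
                current = m.group(1)
                if current in groups:
                    logger.warning(
                        "duplicate group %r at %s:%d; last definition wins",
                        current, path, lineno,
                    )
                groups[current] = []
                continue
            if current is None:
                raise StructureError(
                    f"{path}:{lineno}: indices before any [ group ] header"
                )
            for tok in line.split():
                try:
                    groups[current].append(int(tok))
                except ValueError:
                    raise StructureError(
                        f"{path}:{lineno}: non-integer token {tok!r} in group {current!r}"
                    ) from None
    if not groups:
        raise StructureError(f"{path}: no [ group ] header found")
    for name, idx in groups.items():
        if not idx:
            logger.warning("group %r in %s is empty", name, path)
        groups[name] = sorted(set(idx))
    return GroupSelection(groups=groups)


def write_ndx(selection: GroupSelection, path: str | Path, per_line: int = 15) -> None:
    """Write a GroupSelection as a Gromacs-format index file."""
    path = Path(path)
    with open(path, "w") as fh:
        for name, idx in selection.groups.items():
            fh.write(f"[ {name} ]\n")
            for start in range(0, len(idx), per_line):
                fh.write(" ".join(str(i) for i in idx[start:start + per_line]) + "\n")


# ---------------------------------------------------------------------------
# Structure readers


def read_structure_frames(
    path: str | Path, time_per_frame_ps: float = 1.0
) -> Trajectory:
    """Read a trajectory of snapshots.

    Accepts a multi-model PDB file, a directory of single-frame PDB files
    (frames ordered lexicographically by file name), or a multi-frame XYZ
    file. Elements come from the PDB element column when present, otherwise
    they are inferred from the atom name. PDB exports carry no time
    metadata, so frame times are ``frame_index * time_per_frame_ps``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(path.glob("*.pdb"))
        if not files:
            raise StructureError(f"no .pdb files found in directory {path}")
        frames: list[StructureFrame] = []
        for f in files:
            frames.extend(_read_pdb_frames(f))
        frames = _reindex(frames, time_per_frame_ps)
        return Trajectory(frames=frames, source=str(path))
    if path.suffix.lower() == ".xyz":
        frames = _reindex(list(_read_xyz_frames(path)), time_per_frame_ps)
        return Trajectory(frames=frames, source=str(path))
    frames = _reindex(_read_pdb_frames(path), time_per_frame_ps)
    return Trajectory(frames=frames, source=str(path))


def _reindex(frames: list[StructureFrame], time_per_frame_ps: float) -> list[StructureFrame]:
    for i, fr in enumerate(frames):
        fr.frame_index = i
        fr.time_ps = i * time_per_frame_ps
    if frames:
        _warn_on_stretched_molecules(frames[0])
    return frames


def _read_pdb_frames(path: Path) -> list[StructureFrame]:
    """Read all MODEL frames of one PDB file via MDAnalysis."""
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # toy PDBs lack masses/charges
        u = mda.Universe(str(path))
    ag = u.atoms
    names = [str(n) for n in ag.names]
    resnames = [str(r) for r in ag.resnames]
    resids = [int(r) for r in ag.resids]
    try:
        col = [str(e).strip() for e in ag.elements]
    except Exception:
        col = [""] * len(names)
    elements = [
        _normalize_element(tok, nm) if tok else infer_element(nm, rn)
        for tok, nm, rn in zip(col, names, resnames)
    ]
    mol_ids = assign_mol_ids(resids, resnames)
    frames = []
    for ts in u.trajectory:
        xyz = ts.positions.astype(float)
        atoms = [
            AtomRecord(
                serial=i + 1,
                element=elements[i],
                atom_name=names[i],
                residue_name=resnames[i],
                residue_id=resids[i],
                mol_id=mol_ids[i],
                coords=(float(xyz[i, 0]), float(xyz[i, 1]), float(xyz[i, 2])),
            )
            for i in range(len(names))
        ]
        frames.append(StructureFrame(atoms=atoms, frame_index=int(ts.frame)))
    return frames


def _read_xyz_frames(path: Path):
    """Parse a (possibly multi-frame) standard XYZ file."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise StructureError(f"{path}: expected atom count at line {pos + 1}")
        body = lines[pos + 2: pos + 2 + n]
        if len(body) < n:
            raise StructureError(f"{path}: truncated frame at line {pos + 1}")
        atoms = []
        for i, row in enumerate(body):
            parts = row.split()
            if len(parts) < 4:
                raise StructureError(f"{path}: malformed XYZ row {row!r}")
            el = _normalize_element(parts[0], parts[0])
            x, y, z = (float(p) for p in parts[1:4])
            atoms.append(
                AtomRecord(
                    serial=i + 1, element=el, atom_name=el, residue_name="UNK",
                    residue_id=1, mol_id=0, coords=(x, y, z),
                )
            )
        yield StructureFrame(atoms=atoms, frame_index=frame_idx)
        frame_idx += 1
        pos += 2 + n


def _warn_on_stretched_molecules(frame: StructureFrame, threshold: float = 5.0) -> None:
    """Warn if any atom sits > threshold from all other atoms of its molecule.

    Frames are expected PBC-whole; a stretched molecule is the signature of
    an un-imaged periodic box.
    """
    by_mol: dict[int, list[AtomRecord]] = {}
    for a in frame.atoms:
        by_mol.setdefault(a.mol_id, []).append(a)
    for mol_id, atoms in by_mol.items():
        if len(atoms) < 2:
            continue
        xyz = np.array([a.coords for a in atoms])
        d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        nearest = d.min(axis=1)
        if (nearest > threshold).any():
            logger.warning(
                "molecule %d (%s) has an atom > %.1f A from its nearest "
                "intramolecular neighbour; frames are assumed PBC-whole",
                mol_id, atoms[0].residue_name, threshold,
            )


# ---------------------------------------------------------------------------
# Group extraction and XYZ output


def extract_group(
    frame: StructureFrame,
    selection: GroupSelection,
    names: Sequence[str],
    label: str | None = None,
    missing: str = "error",
) -> AtomSubset:
    """Extract the union of the named index groups as an atom subset.

    Atoms are matched by serial and returned in ascending serial order, so
    PL = union(P, L) regardless of the order of ``names``. With
    ``missing="ignore"``, indices whose atoms were removed from the frame
    (e.g. waters dropped by solvent reduction) are silently skipped.
    """
    if missing not in ("error", "ignore"):
        raise ValueError("missing must be 'error' or 'ignore'")
    wanted = selection.union(names)
    by_serial = {a.serial: a for a in frame.atoms}
    picked: list[AtomRecord] = []
    for idx in wanted:
        atom = by_serial.get(idx)
        if atom is None:
            if missing == "ignore":
                continue
            raise StructureError(
                f"index {idx} from group(s) {list(names)} is out of range for a "
                f"frame with atom serials up to {frame.atoms[-1].serial}"
            )
        picked.append(atom)
    if label is None:
        label = "".join(names)
    return AtomSubset(
        elements=[a.element for a in picked],
        coords=np.array([a.coords for a in picked], dtype=float),
        label=label,
        frame_index=frame.frame_index,
        time_ps=frame.time_ps,
    )


def write_xyz(subset: AtomSubset, path: str | Path) -> None:
    """Write an atom subset as a standard XYZ file (coordinates in Angstrom)."""
    if subset.n_atoms == 0:
        raise StructureError("refusing to write an empty subset")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"{subset.n_atoms}\n")
        fh.write(
            f"label={subset.label} frame={subset.frame_index} "
            f"time_ps={subset.time_ps:g}\n"
        )
        for el, (x, y, z) in zip(subset.elements, subset.coords):
            fh.write(f"{el:<2s} {x:16.8f} {y:16.8f} {z:16.8f}\n")


def read_xyz(path: str | Path) -> AtomSubset:
    """Read a single-frame XYZ file back into an atom subset."""
    path = Path(path)
    frames = list(_read_xyz_frames(path))
    if len(frames) != 1:
        raise StructureError(f"{path}: expected exactly one XYZ frame, got {len(frames)}")
    frame = frames[0]
    label = ""
    with open(path) as fh:
        fh.readline()
        comment = fh.readline()
    m = re.search(r"label=(\S+)", comment)
    if m:
        label = m.group(1)
    return AtomSubset(
        elements=frame.elements, coords=frame.coords, label=label,
        frame_index=frame.frame_index,
    )
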