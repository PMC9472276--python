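"""Deterministic synthetic systems and datasets.

Every pipeline stage — PDB/ndx parsing, group extraction, solvent
reduction, mock energies, LIE fitting — can be exercised offline with the
generators here. The toy complexes are geometric, not chemical: a rigid
receptor cluster, a small ligand cluster parked 3-5 Angstrom away in a
"pocket", a shell of three-site waters, and optional sodium counter-ions.
They validate plumbing and arithmetic, not chemistry.

All randomness flows from the seed in :class:`ToySystemSpec`; the same
spec produces byte-identical PDB/ndx output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_structures import (
    AtomRecord,
    GroupSelection,
    StructureFrame,
    Trajectory,
    write_ndx,
)

_RECEPTOR_ELEMENTS = ("C", "C", "N", "C", "O", "H")
_LIGAND_ELEMENTS = ("C", "H", "O", "C", "H")

_MAX_PLACEMENT_TRIES = 2000


@dataclass(frozen=True)
class ToySystemSpec:
    """Composition of a synthetic solvated receptor-ligand system."""

    n_receptor_atoms: int = 12
    n_ligand_atoms: int = 5
    n_waters: int = 20
    n_ions: int = 0
    box_edge: float = 24.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_receptor_atoms, self.n_ligand_atoms) < 1:
            raise ValueError("receptor and ligand need at least one atom each")
        if self.n_waters < 0 or self.n_ions < 0:
            raise ValueError("counts must be non-negative")
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")


class PlacementError(RuntimeError):
    """Could not place atoms without overlap within the retry bound."""


def _place_cluster(
    rng: np.random.Generator,
    n: int,
    center: np.ndarray,
    radius: float,
    existing: list[np.ndarray],
    min_dist: float = 0.9,
) -> list[np.ndarray]:
    placed: list[np.ndarray] = []
    for _ in range(n):
        for _try in range(_MAX_PLACEMENT_TRIES):
            p = center + rng.uniform(-radius, radius, size=3)
            if np.linalg.norm(p - center) > radius:
                continue
            others = placed + existing
            if all(np.linalg.norm(p - q) >= min_dist for q in others):
                placed.append(p)
                break
        else:
            raise PlacementError(
                f"could not place atom {len(placed) + 1}/{n} without overlap"
            )
    return placed


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix (quaternion method)."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _build_base_system(spec: ToySystemSpec):
    """Elements, base coordinates, residue bookkeeping and group indices."""
    rng = np.random.default_rng(spec.seed)
    r_rec = 1.2 + 1.1 * spec.n_receptor_atoms ** (1.0 / 3.0)
    rec_xyz = _place_cluster(rng, spec.n_receptor_atoms, np.zeros(3), r_rec, [])
    r_lig = 0.8 + 0.9 * spec.n_ligand_atoms ** (1.0 / 3.0)
    lig_center = np.array([r_rec + 4.0, 0.0, 0.0])
    lig_xyz = _place_cluster(rng, spec.n_ligand_atoms, lig_center, r_lig, rec_xyz,
                             min_dist=0.9)
    solute = rec_xyz + lig_xyz
    solute_arr = np.array(solute)
    centroid = solute_arr.mean(axis=0)
    extent = float(np.linalg.norm(solute_arr - centroid, axis=1).max())
    shell_hi = max(extent + 4.0, spec.box_edge / 2.0)

    # three-site waters: O + two H at ~0.96 A, randomly oriented; oxygens
    # scattered from near-contact out to the box edge so distance-ordered
    # selections see a realistic spread
    h1 = np.array([0.9572, 0.0, 0.0])
    h2 = np.array([-0.2399872, 0.9266272, 0.0])
    water_sites: list[list[np.ndarray]] = []
    placed_o: list[np.ndarray] = []
    for _ in range(spec.n_waters):
        for _try in range(_MAX_PLACEMENT_TRIES):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            o = centroid + direction * rng.uniform(0.0, shell_hi)
            if all(np.linalg.norm(o - q) >= 2.4 for q in placed_o) and all(
                np.linalg.norm(o - q) >= 2.4 for q in solute
            ):
                break
        else:
            raise PlacementError("could not place water oxygen without overlap")
        rot = _random_rotation(rng)
        water_sites.append([o, o + rot @ h1, o + rot @ h2])
        placed_o.append(o)

    ion_xyz: list[np.ndarray] = []
    for _ in range(spec.n_ions):
        for _try in range(_MAX_PLACEMENT_TRIES):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            p = centroid + direction * rng.uniform(extent + 3.0, shell_hi + 2.0)
            if all(np.linalg.norm(p - q) >= 3.0 for q in solute + placed_o + ion_xyz):
                break
        else:
            raise PlacementError("could not place ion without overlap")
        ion_xyz.append(p)

    elements, coords, names, resnames, resids, molids = [], [], [], [], [], []

    def _add(el, xyz, name, resname, resid, molid):
        elements.append(el)
        coords.append(np.asarray(xyz, dtype=float))
        names.append(name)
        resnames.append(resname)
        resids.append(resid)
        molids.append(molid)

    for i, p in enumerate(rec_xyz):
        el = _RECEPTOR_ELEMENTS[i % len(_RECEPTOR_ELEMENTS)]
        _add(el, p, f"{el}{i + 1}", "REC", 1, 0)
    for i, p in enumerate(lig_xyz):
        el = _LIGAND_ELEMENTS[i % len(_LIGAND_ELEMENTS)]
        _add(el, p, f"{el}{i + 1}", "LIG", 2, 1)
    resid = 3
    molid = 2
    for sites in water_sites:
        for el, name, p in zip(("O", "H", "H"), ("OW", "HW1", "HW2"), sites):
            _add(el, p, name, "SOL", resid, molid)
        resid += 1
        molid += 1
    for p in ion_xyz:
        _add("Na", p, "NA", "NA", resid, molid)
        resid += 1
        molid += 1

    n_rec, n_lig = spec.n_receptor_atoms, spec.n_ligand_atoms
    n_wat_atoms = 3 * spec.n_waters
    groups = {
        "P": list(range(1, n_rec + 1)),
        "L": list(range(n_rec + 1, n_rec + n_lig + 1)),
        "SOL": list(range(n_rec + n_lig + 1, n_rec + n_lig + n_wat_atoms + 1)),
        "ION": list(
            range(n_rec + n_lig + n_wat_atoms + 1,
                  n_rec + n_lig + n_wat_atoms + spec.n_ions + 1)
        ),
    }
    selection = GroupSelection(groups={k: v for k, v in groups.items() if v})
    base = np.array(coords)
    meta = list(zip(elements, names, resnames, resids, molids))
    return rng, base, meta, selection


def make_toy_trajectory(
    spec: ToySystemSpec, n_frames: int = 1, jitter: float = 0.05
) -> tuple[Trajectory, GroupSelection]:
    """Build a jittered multi-frame toy system.

    Each frame applies independent Gaussian coordinate jitter (stdev
    ``jitter`` Angstrom) to the base geometry; frames with any atom pair
    closer than 0.5 Angstrom are redrawn, with a retry bound.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng, base, meta, selection = _build_base_system(spec)
    frames = []
    for fi in range(n_frames):
        for _try in range(50):
            xyz = base + rng.normal(0.0, jitter, size=base.shape) if jitter else base
            d = np.linalg.norm(xyz[:, None, :] - xyz[None, :, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() >= 0.5:
                break
        else:
            raise PlacementError(f"frame {fi}: jitter produced persistent overlaps")
        atoms = [
            AtomRecord(
                serial=i + 1, element=el, atom_name=name, residue_name=resname,
                residue_id=resid, mol_id=molid,
                coords=(float(xyz[i, 0]), float(xyz[i, 1]), float(xyz[i, 2])),
            )
            for i, (el, name, resname, resid, molid) in enumerate(meta)
        ]
        frames.append(StructureFrame(atoms=atoms, time_ps=float(fi), frame_index=fi))
    return Trajectory(frames=frames, source=f"toy(seed={spec.seed})"), selection


def write_pdb(trajectory: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB with a filled element column."""
    path = Path(path)
    with open(path, "w") as fh:
        for fr in trajectory.frames:
            fh.write(f"MODEL     {fr.frame_index + 1:>4d}\n")
            for a in fr.atoms:
                x, y, z = a.coords
                fh.write(
                    f"ATOM  {a.serial:>5d} {a.atom_name:<4s} {a.residue_name:<3s} "
                    f"A{a.residue_id:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          {a.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def write_toy_system(
    spec: ToySystemSpec,
    outdir: str | Path,
    n_frames: int = 1,
    jitter: float = 0.05,
    per_frame_files: bool = False,
) -> tuple[Path, Path]:
    """Emit a toy system as PDB + Gromacs ndx; returns (pdb_path, ndx_path).

    With ``per_frame_files`` the trajectory is written as a directory of
    single-frame PDB files instead of one multi-model file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traj, selection = make_toy_trajectory(spec, n_frames=n_frames, jitter=jitter)
    ndx_path = outdir / "system.ndx"
    write_ndx(selection, ndx_path)
    if per_frame_files:
        frames_dir = outdir / "frames"
        frames_dir.mkdir(exist_ok=True)
        for fr in traj.frames:
            single = Trajectory(frames=[fr], source=traj.source)
            write_pdb(single, frames_dir / f"frame_{fr.frame_index:04d}.pdb")
        return frames_dir, ndx_path
    pdb_path = outdir / "trajectory.pdb"
    write_pdb(traj, pdb_path)
    return pdb_path, ndx_path


def make_synthetic_lie_dataset(
    beta_true: float = 0.106,
    gamma_true: float = -5.0,
    n: int = 54,
    noise_sd: float = 1.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic single-predictor LIE dataset for parameter-recovery studies.

    Predictors are ensemble-mean interaction energies drawn uniformly from
    the realistic range [-90, -20] kcal/mol; responses are the linear form
    plus Gaussian noise of stdev ``noise_sd`` kcal/mol.
    """
    if n < 3:
        raise ValueError("need at least 3 points")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    x = rng.uniform(-90.0, -20.0, size=n)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    y = beta_true * x + gamma_true + noise
    return pd.DataFrame(
        {
            "complex_id": [f"SYN{i:03d}" for i in range(n)],
            "x_kcal": x,
            "dg_exp_kcal": y,
        }
    )
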