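"""Solvation-shell reduction and ion stripping.

Explicit-solvent single-point evaluations on a full simulation box are
memory-bound, but a ligand buried in a binding pocket only feels nearby
waters. This module orders water molecules by their minimum atom-atom
distance to the solute and keeps whole waters within a cutoff (default
4 Angstrom), and removes backend-unsupported counter-ions — but only from
residues declared strippable, so an exotic element inside the ligand fails
loudly instead of being silently dropped.

Distances are plain Euclidean (no minimum-image convention): frames are
assumed PBC-whole and centred by the upstream trajectory tooling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .calculators import CalculatorSpec
from .io_structures import (
    GroupSelection,
    StructureFrame,
    StructureError,
    WATER_RESIDUE_NAMES,
)

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF_A = 4.0

#: Residue names whose atoms may be stripped when the backend cannot
#: evaluate them (monatomic counter-ions in Gromacs/Amber/CHARMM naming).
DEFAULT_STRIPPABLE_RESIDUES = frozenset({"NA", "CL", "K", "SOD", "CLA", "POT"})


@dataclass(frozen=True)
class SolventReductionReport:
    """Bookkeeping for one solvent-reduction pass."""

    n_waters_in: int
    n_waters_kept: int
    cutoff: float
    n_ions_stripped: int = 0

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.n_waters_kept > self.n_waters_in:
            raise ValueError("kept more waters than present")

    def to_json(self) -> str:
        return json.dumps(asdict(self))


def _solute_coords(frame: StructureFrame, selection: GroupSelection,
                   solute_names: Sequence[str]) -> np.ndarray:
    serials = set(selection.union(solute_names))
    coords = [a.coords for a in frame.atoms if a.serial in serials]
    if not coords:
        raise StructureError(f"solute groups {list(solute_names)} select no atoms")
    return np.asarray(coords, dtype=float)


def water_min_distances(
    frame: StructureFrame, selection: GroupSelection, solute_names: Sequence[str]
) -> dict[int, float]:
    """Minimum atom-atom distance from each water molecule to the solute.

    All atoms (heavy and hydrogen) participate on both sides. Returns
    ``{mol_id: distance}`` for every water in the frame.
    """
    solute = _solute_coords(frame, selection, solute_names)
    tree = cKDTree(solute)
    dists: dict[int, float] = {}
    for a in frame.atoms:
        if a.residue_name not in WATER_RESIDUE_NAMES:
            continue
        d, _ = tree.query(np.asarray(a.coords))
        prev = dists.get(a.mol_id)
        if prev is None or d < prev:
            dists[a.mol_id] = float(d)
    return dists


def order_waters(
    frame: StructureFrame, selection: GroupSelection, solute_names: Sequence[str]
) -> list[int]:
    """Water mol_ids sorted by ascending min distance to the solute.

    Ties break by ascending mol_id; no waters present yields an empty list.
    """
    dists = water_min_distances(frame, selection, solute_names)
    return sorted(dists, key=lambda m: (dists[m], m))


def reduce_solvation(
    frame: StructureFrame,
    selection: GroupSelection,
    solute_names: Sequence[str],
    cutoff: float = DEFAULT_CUTOFF_A,
) -> tuple[StructureFrame, SolventReductionReport]:
    """Keep the solute plus whole waters within ``cutoff`` of it.

    Waters are kept or dropped as whole molecules, never split. Atoms that
    are neither solute nor water (counter-ions, co-solvents) are dropped and
    counted in the report. Atom order and original serials are preserved, so
    the input GroupSelection still addresses the surviving atoms.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    dists = water_min_distances(frame, selection, solute_names)
    kept_waters = {m for m, d in dists.items() if d <= cutoff}
    solute_serials = set(selection.union(solute_names))
    kept_atoms = []
    n_dropped_other = 0
    for a in frame.atoms:
        if a.serial in solute_serials:
            kept_atoms.append(a)
        elif a.residue_name in WATER_RESIDUE_NAMES:
            if a.mol_id in kept_waters:
                kept_atoms.append(a)
        else:
            n_dropped_other += 1
    report = SolventReductionReport(
        n_waters_in=len(dists),
        n_waters_kept=len(kept_waters),
        cutoff=cutoff,
        n_ions_stripped=n_dropped_other,
    )
    logger.info("solvent reduction: %s", report.to_json())
    out = StructureFrame(
        atoms=kept_atoms, time_ps=frame.time_ps, frame_index=frame.frame_index
    )
    return out, report


def strip_unsupported(
    frame: StructureFrame,
    spec: CalculatorSpec,
    strippable_residues: Iterable[str] = DEFAULT_STRIPPABLE_RESIDUES,
) -> StructureFrame:
    """Remove backend-unsupported atoms from strippable (ion) residues.

    An unsupported element in any other residue — a bromine in the ligand,
    say — raises, because silently dropping ligand atoms would corrupt the
    interaction energy.
    """
    strippable = {r.upper() for r in strippable_residues}
    supported = spec.supported_elements
    kept = []
    n_stripped = 0
    for a in frame.atoms:
        if a.element in supported:
            kept.append(a)
        elif a.residue_name.upper() in strippable:
            n_stripped += 1
        else:
            raise StructureError(
                f"element {a.element!r} (atom {a.atom_name!r}, serial {a.serial}, "
                f"residue {a.residue_name!r}) is unsupported by backend "
                f"{spec.backend} and its residue is not strippable"
            )
    if n_stripped:
        logger.info("stripped %d unsupported ion atom(s)", n_stripped)
    if not kept:
        raise StructureError("stripping removed every atom of the frame")
    return StructureFrame(atoms=kept, time_ps=frame.time_ps, frame_index=frame.frame_index)
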