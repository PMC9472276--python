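"""Per-frame interaction energies, ensemble statistics and convergence.

The central quantity is the pairwise interaction energy of two atom groups
in one snapshot,

    dE_int = E(A u B) - E(A) - E(B),

evaluated with three single-point energies per frame. The absolute cluster
energies are in the hundreds of thousands of eV while the interaction is a
few eV; the large bias cancels in the subtraction, which is why the
difference — not the absolute energy — is the meaningful output of any
backend. Ensemble averages over frames feed the free-energy estimators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import constants
from .calculators import CalculatorSpec, single_point_energy
from .io_structures import GroupSelection, StructureFrame, extract_group

ev_to_kcalmol = constants.ev_to_kcalmol


@dataclass
class InteractionSeries:
    """Per-frame interaction energies (eV) for one component pair and backend."""

    values: list[tuple[int, float]]
    pair: tuple[str, str] = ("A", "B")
    backend: str = "MOCK_PAIRWISE"

    def __post_init__(self) -> None:
        idx = [i for i, _ in self.values]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def energies(self) -> np.ndarray:
        return np.array([v for _, v in self.values], dtype=float)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class EnsembleStat:
    """Mean and standard error of a per-frame quantity (eV)."""

    mean: float
    sem: float
    n_frames: int

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.sem < 0:
            raise ValueError("sem must be non-negative")


def interaction_energy(e_ab: float, e_a: float, e_b: float) -> float:
    """dE_int = E(AB) - E(A) - E(B), all in eV."""
    for name, v in (("e_ab", e_ab), ("e_a", e_a), ("e_b", e_b)):
        if not math.isfinite(v):
            raise ValueError(f"{name} is not finite: {v}")
    return e_ab - e_a - e_b


def frame_interaction(
    spec: CalculatorSpec,
    frame: StructureFrame,
    selection: GroupSelection,
    group_a: str,
    group_b: str,
    missing: str = "error",
) -> float:
    """Interaction energy (eV) between two disjoint index groups in one frame."""
    idx_a = set(selection[group_a])
    idx_b = set(selection[group_b])
    overlap = idx_a & idx_b
    if overlap:
        raise ValueError(
            f"groups {group_a!r} and {group_b!r} overlap on indices "
            f"{sorted(overlap)[:5]}{'...' if len(overlap) > 5 else ''}"
        )
    sub_a = extract_group(frame, selection, [group_a], label=group_a, missing=missing)
    sub_b = extract_group(frame, selection, [group_b], label=group_b, missing=missing)
    sub_ab = extract_group(
        frame, selection, [group_a, group_b],
        label=f"{group_a}{group_b}", missing=missing,
    )
    e_ab = single_point_energy(spec, sub_ab).value
    e_a = single_point_energy(spec, sub_a).value
    e_b = single_point_energy(spec, sub_b).value
    return interaction_energy(e_ab, e_a, e_b)


def trajectory_interactions(
    spec: CalculatorSpec,
    frames: Sequence[StructureFrame],
    selection: GroupSelection,
    group_a: str,
    group_b: str,
    missing: str = "error",
) -> InteractionSeries:
    """frame_interaction over a sequence of frames, as an InteractionSeries."""
    values = [
        (fr.frame_index, frame_interaction(spec, fr, selection, group_a, group_b, missing))
        for fr in frames
    ]
    return InteractionSeries(values=values, pair=(group_a, group_b), backend=spec.backend)


def ensemble_average(series: InteractionSeries, spread: str = "sem") -> EnsembleStat:
    """Ensemble mean of a per-frame series.

    ``spread="sem"`` (default) reports the standard error of the mean
    (sample stdev / sqrt(n), zero for a single frame); ``spread="stdev"``
    reports the sample standard deviation instead.
    """
    if len(series) == 0:
        raise ValueError("cannot average an empty series")
    e = series.energies
    n = len(e)
    mean = float(e.mean())
    if n == 1:
        width = 0.0
    else:
        sd = float(e.std(ddof=1))
        width = sd if spread == "stdev" else sd / math.sqrt(n)
    return EnsembleStat(mean=mean, sem=width, n_frames=n)


def stride_indices(n: int, reference_count: int) -> list[int]:
    """Positions of the first frame of each of ``n`` equal intervals in [0, reference_count)."""
    if n <= 0:
        raise ValueError("frame count must be positive")
    if n > reference_count:
        raise ValueError(f"n={n} exceeds reference window {reference_count}")
    return [(i * reference_count) // n for i in range(n)]


def convergence_profile(
    series: InteractionSeries,
    frame_counts: Sequence[int],
    reference_count: int | None = None,
) -> list[tuple[int, float]]:
    """Deviation of the n-frame stride mean from the reference mean.

    For each n, frames are subsampled deterministically as the first frame
    of each of n equal intervals over the reference window; the profile is
    ``(n, |mean_n - mean_ref|)`` in eV. No randomness is involved, so the
    profile is exactly reproducible.
    """
    if reference_count is None:
        reference_count = len(series)
    if reference_count > len(series):
        raise ValueError("reference_count exceeds series length")
    e = series.energies[:reference_count]
    ref_mean = e.mean()
    out = []
    for n in frame_counts:
        sel = stride_indices(n, reference_count)
        out.append((n, float(abs(e[sel].mean() - ref_mean))))
    return out


# ---------------------------------------------------------------------------
# Per-frame energy tables

ENERGY_TABLE_COLUMNS = ["frame_index", "E_AB", "E_A", "E_B", "dE_int", "backend", "pair"]


def energy_table(
    frame_indices: Sequence[int],
    e_ab: Sequence[float],
    e_a: Sequence[float],
    e_b: Sequence[float],
    backend: str,
    pair: tuple[str, str],
) -> pd.DataFrame:
    """Assemble the per-frame energy table (one row per frame, energies in eV)."""
    de = [interaction_energy(ab, a, b) for ab, a, b in zip(e_ab, e_a, e_b)]
    return pd.DataFrame(
        {
            "frame_index": list(frame_indices),
            "E_AB": list(e_ab),
            "E_A": list(e_a),
            "E_B": list(e_b),
            "dE_int": de,
            "backend": backend,
            "pair": f"{pair[0]}-{pair[1]}",
        }
    )


def write_energy_table(table: pd.DataFrame, path: str | Path) -> None:
    # %.17g round-trips IEEE doubles exactly, so a resumed run reproduces
    # the original report bit for bit
    table.to_csv(path, index=False, float_format="%.17g")


def read_energy_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(ENERGY_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: energy table missing columns {sorted(missing)}")
    return df


def series_from_table(table: pd.DataFrame) -> InteractionSeries:
    """Rebuild an InteractionSeries from a per-frame energy table."""
    pair = tuple(str(table["pair"].iloc[0]).split("-", 1)) if len(table) else ("A", "B")
    return InteractionSeries(
        values=[(int(i), float(v)) for i, v in zip(table["frame_index"], table["dE_int"])],
        pair=pair,  # type: ignore[arg-type]
        backend=str(table["backend"].iloc[0]) if len(table) else "",
    )
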