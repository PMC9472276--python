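"""End-to-end binding free energy workflows.

The bound workflow mirrors the standard end-state post-processing chain:
read snapshots, strip backend-unsupported ions, optionally reduce the
solvation shell, extract the PL/P/L clusters, evaluate single-point
energies per backend, form per-frame interaction energies, average, and
apply the chosen LIE estimator. The free-ligand workflow produces the
ligand-solvent (LS ensemble) terms needed by the solvent-included
estimators, stored so they can be merged with a bound run without
recomputation.

For the deterministic backends the outputs are a pure function of
(inputs, config, seed); per-frame energy tables are written to disk and a
completed run can be resumed from them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .calculators import CalculatorSpec, batch_energies
from .interaction import (
    EnsembleStat,
    ensemble_average,
    energy_table,
    read_energy_table,
    series_from_table,
    write_energy_table,
)
from .io_structures import extract_group, read_ndx, read_structure_frames
from .lie import ESTIMATORS, LIECoefficients, LIEInputs
from .solvent import (
    DEFAULT_STRIPPABLE_RESIDUES,
    reduce_solvation,
    strip_unsupported,
)

logger = logging.getLogger(__name__)


class WorkflowError(RuntimeError):
    """A pipeline stage failed; the message names the stage and frame."""


@dataclass
class RunConfig:
    """Configuration of one workflow run."""

    trajectory: str
    ndx: str
    protein_group: str = "P"
    ligand_group: str = "L"
    solvent_group: str = "SOL"
    ion_group: str | None = None
    backends: list[str] = field(default_factory=lambda: ["MOCK_PAIRWISE"])
    calculator_params: dict = field(default_factory=dict)
    frame_stride: int = 1
    max_frames: int | None = None
    solvent_cutoff: float | None = None
    equation: str = "eq4"
    coefficients: dict = field(default_factory=lambda: {"alpha": 0.0, "beta": 1.0, "gamma": 0.0})
    experimental_table: str | None = None
    seed: int = 0
    outdir: str = "endlie_out"

    def __post_init__(self) -> None:
        if self.equation not in ESTIMATORS:
            raise ValueError(
                f"unknown equation tag {self.equation!r}; choose from {sorted(ESTIMATORS)}"
            )
        if self.frame_stride < 1:
            raise ValueError("frame_stride must be >= 1")


def _nnp_channel(backend: str) -> str:
    """Which LIEInputs channel a backend's interaction terms feed."""
    return "d3" if backend == "DISP_D3" else "nnp"


def _select_frames(config: RunConfig):
    traj = read_structure_frames(config.trajectory)
    frames = traj.frames[:: config.frame_stride]
    if config.max_frames is not None:
        frames = frames[: config.max_frames]
    if not frames:
        raise WorkflowError("stage read: no frames selected")
    return frames


def _stat_to_dict(stat: EnsembleStat) -> dict:
    return {"mean_ev": stat.mean, "sem_ev": stat.sem, "n_frames": stat.n_frames}


def _pair_energies(
    spec: CalculatorSpec, frames, selection, group_a: str, group_b: str,
    out_csv: Path, resume: bool,
):
    """Per-frame E(AB), E(A), E(B) table for one backend and pair.

    If a complete table already exists at ``out_csv`` and ``resume`` is on,
    it is loaded instead of recomputed (restartability contract).
    """
    if resume and out_csv.exists():
        table = read_energy_table(out_csv)
        if len(table) == len(frames):
            logger.info("resuming from %s", out_csv)
            return table
    subsets_ab, subsets_a, subsets_b = [], [], []
    for fr in frames:
        subsets_a.append(extract_group(fr, selection, [group_a], label=group_a,
                                       missing="ignore"))
        subsets_b.append(extract_group(fr, selection, [group_b], label=group_b,
                                       missing="ignore"))
        subsets_ab.append(
            extract_group(fr, selection, [group_a, group_b],
                          label=f"{group_a}{group_b}", missing="ignore")
        )
    def _energies(subsets):
        # a group emptied by solvent reduction contributes zero energy
        vals = []
        nonempty = [s for s in subsets if s.n_atoms]
        computed = iter(batch_energies(spec, nonempty))
        for s in subsets:
            vals.append(next(computed).value if s.n_atoms else 0.0)
        return vals

    e_ab = _energies(subsets_ab)
    e_a = _energies(subsets_a)
    e_b = _energies(subsets_b)
    table = energy_table(
        [fr.frame_index for fr in frames], e_ab, e_a, e_b,
        backend=spec.backend, pair=(group_a, group_b),
    )
    write_energy_table(table, out_csv)
    return table


def _prepare_frames(config: RunConfig, frames, selection, spec: CalculatorSpec,
                    solute_names, with_solvent: bool):
    """Ion stripping + optional solvent reduction, per frame."""
    prepared = []
    report = None
    for fr in frames:
        try:
            fr2 = strip_unsupported(fr, spec, DEFAULT_STRIPPABLE_RESIDUES)
        except Exception as exc:
            raise WorkflowError(f"stage strip_ions, frame {fr.frame_index}: {exc}") from exc
        if with_solvent and config.solvent_cutoff is not None:
            try:
                fr2, report = reduce_solvation(
                    fr2, selection, solute_names, cutoff=config.solvent_cutoff
                )
            except Exception as exc:
                raise WorkflowError(
                    f"stage reduce_solvation, frame {fr.frame_index}: {exc}"
                ) from exc
        prepared.append(fr2)
    return prepared, report


def _write_manifest(outdir: Path, status: str, files: list[str]) -> None:
    (outdir / "MANIFEST.json").write_text(
        json.dumps({"status": status, "files": sorted(files)}, indent=2)
    )


def run_bound_workflow(config: RunConfig, resume: bool = False) -> dict:
    """Run the bound-state (PLS) pipeline and return the JSON-able summary.

    Writes per-frame energy tables (one per backend and component pair),
    a MANIFEST marking completeness, and ``summary.json`` in the output
    directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    _write_manifest(outdir, "incomplete", written)

    frames = _select_frames(config)
    selection = read_ndx(config.ndx)
    for g in (config.protein_group, config.ligand_group):
        if g not in selection:
            raise WorkflowError(f"stage read_ndx: group {g!r} not in {config.ndx}")
    p, l, s = config.protein_group, config.ligand_group, config.solvent_group
    want_solvent = config.equation in ("eq6", "eq7")
    if want_solvent and s not in selection:
        raise WorkflowError(
            f"stage read_ndx: solvent group {s!r} required by {config.equation} "
            f"is not in {config.ndx}"
        )

    inputs = LIEInputs()
    stats_out: dict = {}
    reduction_report = None
    for backend in config.backends:
        spec = CalculatorSpec(backend=backend, params=dict(config.calculator_params))
        prepared, reduction_report = _prepare_frames(
            config, frames, selection, spec, [p, l], with_solvent=True
        )
        lp_csv = outdir / f"energies_{backend}_{l}-{p}.csv"
        table_lp = _pair_energies(spec, prepared, selection, l, p, lp_csv, resume)
        written.append(lp_csv.name)
        series_lp = series_from_table(table_lp)
        stat_lp = ensemble_average(series_lp)
        channel = _nnp_channel(backend)
        setattr(inputs, f"dE_{channel}_LP", stat_lp)
        stats_out[f"{backend}.L-P"] = _stat_to_dict(stat_lp)
        if want_solvent:
            ls_csv = outdir / f"energies_{backend}_{l}-{s}.csv"
            table_ls = _pair_energies(spec, prepared, selection, l, s, ls_csv, resume)
            written.append(ls_csv.name)
            stat_ls = ensemble_average(series_from_table(table_ls))
            setattr(inputs, f"dE_{channel}_LS_bound", stat_ls)
            stats_out[f"{backend}.L-S(bound)"] = _stat_to_dict(stat_ls)

    coeffs = LIECoefficients(**config.coefficients)
    free_terms_path = outdir / "ls_free_terms.json"
    if want_solvent and free_terms_path.exists():
        merge_free_ligand_terms(inputs, json.loads(free_terms_path.read_text()))
    dg = None
    if not want_solvent or inputs.dE_nnp_LS_free is not None:
        est = ESTIMATORS[config.equation](inputs, coeffs)
        dg = {"value_kcalmol": est.value, "uncertainty_kcalmol": est.uncertainty,
              "equation": est.equation}

    summary = {
        "version": __version__,
        "config": dataclasses.asdict(config),
        "n_frames": len(frames),
        "solvent_reduction": dataclasses.asdict(reduction_report) if reduction_report else None,
        "ensemble_stats": stats_out,
        "dg": dg,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    written.append("summary.json")
    _write_manifest(outdir, "complete", written)
    return summary


def run_free_ligand_workflow(config: RunConfig, resume: bool = False) -> dict:
    """Run the free-ligand (LS) pipeline: ligand-solvent terms per backend.

    The result is written to ``ls_free_terms.json`` in the output directory,
    in the shape :func:`merge_free_ligand_terms` consumes, so a later bound
    run (or :func:`combine_bound_and_free`) can apply the solvent-included
    estimators without recomputation.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = _select_frames(config)
    selection = read_ndx(config.ndx)
    l, s = config.ligand_group, config.solvent_group
    if s not in selection:
        raise WorkflowError(
            f"stage read_ndx: solvent group {s!r} not found in {config.ndx}"
        )
    if not frames[0].water_mol_ids():
        raise WorkflowError(
            f"stage read: no water molecules in the trajectory; the free-ligand "
            f"workflow needs solvent group {s!r} populated"
        )
    terms: dict = {}
    for backend in config.backends:
        spec = CalculatorSpec(backend=backend, params=dict(config.calculator_params))
        prepared, _ = _prepare_frames(config, frames, selection, spec, [l],
                                      with_solvent=True)
        ls_csv = outdir / f"energies_free_{backend}_{l}-{s}.csv"
        table = _pair_energies(spec, prepared, selection, l, s, ls_csv, resume)
        stat = ensemble_average(series_from_table(table))
        terms[backend] = _stat_to_dict(stat)
    out = {"ensemble": "LS", "pair": f"{l}-{s}", "terms": terms}
    (outdir / "ls_free_terms.json").write_text(json.dumps(out, indent=2))
    return out


def merge_free_ligand_terms(inputs: LIEInputs, free_terms: dict) -> LIEInputs:
    """Fold free-ligand (LS) ensemble terms into a LIEInputs in place."""
    for backend, stat in free_terms.get("terms", {}).items():
        channel = _nnp_channel(backend)
        setattr(
            inputs,
            f"dE_{channel}_LS_free",
            EnsembleStat(mean=stat["mean_ev"], sem=stat["sem_ev"],
                         n_frames=stat["n_frames"]),
        )
    return inputs


def combine_bound_and_free(
    bound_summary: dict, free_terms: dict, coefficients: dict, equation: str = "eq6"
) -> dict:
    """Apply a solvent-included estimator to stored bound + free results."""
    inputs = LIEInputs()
    for key, stat in bound_summary["ensemble_stats"].items():
        backend, pair = key.split(".", 1)
        channel = _nnp_channel(backend)
        es = EnsembleStat(mean=stat["mean_ev"], sem=stat["sem_ev"],
                          n_frames=stat["n_frames"])
        if pair.endswith("(bound)"):
            setattr(inputs, f"dE_{channel}_LS_bound", es)
        else:
            setattr(inputs, f"dE_{channel}_LP", es)
    merge_free_ligand_terms(inputs, free_terms)
    est = ESTIMATORS[equation](inputs, LIECoefficients(**coefficients))
    return {"value_kcalmol": est.value, "uncertainty_kcalmol": est.uncertainty,
            "equation": est.equation}
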