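"""Single-point-energy backends behind one uniform contract.

Three backends share the same interface:

* ``NNP_ANI2X`` — the ANI-2x neural-network potential (via torchani/ASE),
  trained to reproduce wb97x/6-31G* energies for H, C, N, O, F, S, Cl.
* ``DISP_D3`` — Grimme's D3 dispersion correction with the wB97X parameter
  set (via the simple-dftd3 python API), standing in for van der Waals
  attraction.
* ``MOCK_PAIRWISE`` — a deterministic Lennard-Jones + Coulomb pair
  potential with a fixed per-element parameter table. It has no chemical
  pretensions; it exists because pairwise additivity makes every
  interaction-energy identity exact, which turns the whole pipeline into
  something that can be verified against closed forms offline.

All backends treat a subset as an isolated cluster (no periodic boundary
conditions) and return energies in eV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constants import COULOMB_EV_ANGSTROM, HARTREE_TO_EV
from .io_structures import AtomSubset

ANI2X_ELEMENTS = frozenset({"H", "C", "N", "O", "F", "S", "Cl"})

# D3 parameters exist for essentially the whole periodic table; cap at the
# elements this package can name.
_D3_ELEMENTS_UNSUPPORTED: frozenset[str] = frozenset()

#: Mock pair-potential table: element -> (epsilon eV, sigma Angstrom, charge e).
#: Charges default to zero for the organic elements so the potential decays as
#: r^-6 and cluster energies converge quickly with distance cutoffs; monatomic
#: ions carry their formal charge. Override via CalculatorSpec.params["table"].
MOCK_TABLE: dict[str, tuple[float, float, float]] = {
    "H":  (0.0008, 1.20, 0.0),
    "C":  (0.0030, 3.40, 0.0),
    "N":  (0.0074, 3.30, 0.0),
    "O":  (0.0090, 3.10, 0.0),
    "F":  (0.0067, 2.90, 0.0),
    "S":  (0.0109, 3.60, 0.0),
    "Cl": (0.0118, 3.50, 0.0),
    "Br": (0.0130, 3.70, 0.0),
    "Na": (0.0061, 2.30, 1.0),
    "K":  (0.0045, 2.80, 1.0),
}

BACKENDS = ("MOCK_PAIRWISE", "NNP_ANI2X", "DISP_D3")


class CalculatorError(RuntimeError):
    """A backend could not evaluate the requested subset."""


class BackendUnavailableError(CalculatorError):
    """The backend's optional dependency is not installed."""


class UnsupportedElementError(CalculatorError):
    """The subset contains elements outside the backend's element set."""


@dataclass
class CalculatorSpec:
    """Backend choice plus backend-specific parameters.

    Recognised params: ``table`` (mock pair-potential table), ``damping``
    (``"bj"`` or ``"zero"`` for D3), ``model_version`` (NNP), ``device``
    (opaque hint passed to the NNP backend).
    """

    backend: str = "MOCK_PAIRWISE"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"unknown backend {self.backend!r}; choose from {BACKENDS}")

    @property
    def supported_elements(self) -> frozenset[str]:
        if self.backend == "NNP_ANI2X":
            return ANI2X_ELEMENTS
        if self.backend == "MOCK_PAIRWISE":
            return frozenset(self.params.get("table", MOCK_TABLE))
        from .io_structures import KNOWN_ELEMENTS

        return frozenset(KNOWN_ELEMENTS) - _D3_ELEMENTS_UNSUPPORTED

    @property
    def mock_table(self) -> Mapping[str, tuple[float, float, float]]:
        return self.params.get("table", MOCK_TABLE)


@dataclass(frozen=True)
class EnergyValue:
    """A single-point energy (eV) tagged with its provenance."""

    value: float
    backend: str
    component: str = ""
    frame_index: int = 0

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise CalculatorError(
                f"non-finite energy from backend {self.backend} "
                f"(component {self.component!r}, frame {self.frame_index})"
            )


def check_supported(spec: CalculatorSpec, subset: AtomSubset) -> list[str]:
    """List the elements of ``subset`` the backend cannot evaluate (may be empty)."""
    supported = spec.supported_elements
    out: list[str] = []
    for el in subset.elements:
        if el not in supported and el not in out:
            out.append(el)
    return out


def mock_pair_potential(
    el_i: str, el_j: str, r: float,
    table: Mapping[str, tuple[float, float, float]] | None = None,
) -> float:
    """Lennard-Jones + Coulomb pair energy (eV) at separation ``r`` (Angstrom).

    u(r) = 4 eps_ij [(sig_ij/r)^12 - (sig_ij/r)^6] + k_e q_i q_j / r with
    Lorentz-Berthelot combination rules.
    """
    if r <= 0:
        raise ValueError(f"pair distance must be positive, got {r}")
    table = MOCK_TABLE if table is None else table
    try:
        eps_i, sig_i, q_i = table[el_i]
        eps_j, sig_j, q_j = table[el_j]
    except KeyError as exc:
        raise UnsupportedElementError(f"element {exc.args[0]!r} not in mock table") from None
    eps = math.sqrt(eps_i * eps_j)
    sig = 0.5 * (sig_i + sig_j)
    sr6 = (sig / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6) + COULOMB_EV_ANGSTROM * q_i * q_j / r


def _mock_energy(spec: CalculatorSpec, subset: AtomSubset) -> float:
    table = spec.mock_table
    els = subset.elements
    xyz = subset.coords
    n = len(els)
    if n < 2:
        return 0.0
    params = np.array([table[el] for el in els], dtype=float)
    eps, sig, q = params[:, 0], params[:, 1], params[:, 2]
    diff = xyz[:, None, :] - xyz[None, :, :]
    r = np.sqrt((diff * diff).sum(axis=-1))
    iu = np.triu_indices(n, k=1)
    rij = r[iu]
    if (rij <= 0).any():
        raise CalculatorError("coincident atoms in subset (zero pair distance)")
    eps_ij = np.sqrt(eps[iu[0]] * eps[iu[1]])
    sig_ij = 0.5 * (sig[iu[0]] + sig[iu[1]])
    sr6 = (sig_ij / rij) ** 6
    lj = 4.0 * eps_ij * (sr6 * sr6 - sr6)
    coul = COULOMB_EV_ANGSTROM * q[iu[0]] * q[iu[1]] / rij
    return float((lj + coul).sum())


_ANI_MODEL_CACHE: dict = {}


def _ani_energy(spec: CalculatorSpec, subset: AtomSubset) -> float:
    try:
        import torch  # noqa: F401
        import torchani
    except ImportError as exc:
        raise BackendUnavailableError(
            "NNP_ANI2X requires the optional 'torchani' dependency "
            "(pip install endstate-lie[nnp])"
        ) from exc
    import torch

    version = spec.params.get("model_version", "ANI2x")
    device = spec.params.get("device", "cpu")
    key = (version, device)
    if key not in _ANI_MODEL_CACHE:
        model = getattr(torchani.models, version)(periodic_table_index=False)
        _ANI_MODEL_CACHE[key] = model.to(device).double()
    model = _ANI_MODEL_CACHE[key]
    species = model.species_to_tensor("".join(subset.elements)).unsqueeze(0).to(device)
    coords = torch.tensor(subset.coords[None, :, :], dtype=torch.float64, device=device)
    energy_ha = model((species, coords)).energies.item()
    return energy_ha * HARTREE_TO_EV


def _d3_energy(spec: CalculatorSpec, subset: AtomSubset) -> float:
    try:
        from dftd3.interface import (
            DispersionModel,
            RationalDampingParam,
            ZeroDampingParam,
        )
    except ImportError as exc:
        raise BackendUnavailableError(
            "DISP_D3 requires the optional 'dftd3' dependency "
            "(pip install endstate-lie[d3])"
        ) from exc

    ANGSTROM_TO_BOHR = 1.0 / 0.529177210903
    numbers = np.array([_atomic_number(el) for el in subset.elements])
    positions = subset.coords * ANGSTROM_TO_BOHR
    model = DispersionModel(numbers, positions)
    damping = spec.params.get("damping", "bj")
    method = spec.params.get("method", "wb97x")
    if damping == "bj":
        param = RationalDampingParam(method=method)
    elif damping == "zero":
        param = ZeroDampingParam(method=method)
    else:
        raise ValueError(f"unknown D3 damping variant {damping!r}")
    res = model.get_dispersion(param, grad=False)
    return float(res["energy"]) * HARTREE_TO_EV


def _atomic_number(el: str) -> int:
    order = (
        "H He Li Be B C N O F Ne Na Mg Al Si P S Cl Ar K Ca Sc Ti V Cr Mn Fe "
        "Co Ni Cu Zn Ga Ge As Se Br Kr"
    ).split()
    try:
        return order.index(el) + 1
    except ValueError:
        raise UnsupportedElementError(f"no atomic number for element {el!r}") from None


def single_point_energy(spec: CalculatorSpec, subset: AtomSubset) -> EnergyValue:
    """Potential energy (eV) of a subset treated as an isolated cluster."""
    if subset.n_atoms == 0:
        raise CalculatorError("cannot evaluate an empty subset")
    bad = check_supported(spec, subset)
    if bad:
        raise UnsupportedElementError(
            f"backend {spec.backend} does not support element(s) {bad} "
            f"in component {subset.label!r}"
        )
    if spec.backend == "MOCK_PAIRWISE":
        value = _mock_energy(spec, subset)
    elif spec.backend == "NNP_ANI2X":
        value = _ani_energy(spec, subset)
    else:
        value = _d3_energy(spec, subset)
    return EnergyValue(
        value=value, backend=spec.backend, component=subset.label,
        frame_index=subset.frame_index,
    )


def batch_energies(
    spec: CalculatorSpec, subsets: Sequence[AtomSubset], batch_size: int = 8
) -> list[EnergyValue]:
    """Evaluate many subsets, preserving order.

    Batching is a throughput detail: the result is defined to equal the
    per-item ``single_point_energy`` loop. Errors carry the frame index of
    the offending subset.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    out: list[EnergyValue] = []
    for start in range(0, len(subsets), batch_size):
        for sub in subsets[start:start + batch_size]:
            try:
                out.append(single_point_energy(spec, sub))
            except CalculatorError as exc:
                raise CalculatorError(
                    f"frame {sub.frame_index} ({sub.label!r}): {exc}"
                ) from exc
    return out
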