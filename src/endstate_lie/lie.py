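"""Linear-interaction-energy binding free energy estimators.

The LIE family writes the binding free energy as a linear combination of
ensemble-averaged ligand-surroundings interaction energies with empirical
coefficients alpha (van der Waals / dispersion), beta (electrostatic /
total-potential) and an intercept gamma:

* classical MM form:
  dG = alpha * (<E_vdw^L-surr>_PLS - <E_vdw^L-S>_LS)
     + beta  * (<E_el^L-surr>_PLS  - <E_el^L-S>_LS) + gamma
* solvent-ignored neural-potential forms:
  dG = beta * <dE_nnp^L-P>_PLS + gamma                          (nnp)
  dG = alpha * <dE_d3^L-P>_PLS + beta * <dE_nnp^L-P>_PLS + gamma (nnp+d3)
* solvent-included forms replace each <.^L-P> by
  <dE^L-P>_PLS + <dE^L-S>_PLS - <E^L-S>_LS, the bound-state ligand-protein
  and ligand-solvent terms minus the free-ligand solvation term.

Energies from the NNP/D3 backends arrive in eV and are converted to
kcal/mol before the linear form is applied, so fitted gamma is always in
kcal/mol. Coefficients are fitted by ordinary least squares against
experimental free energies derived from IC50/Ki via dG = RT ln(c/1M).

Uncertainty on an estimate is first-order: |coef| * sem for each term,
summed in quadrature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import (
    DEFAULT_TEMPERATURE_K,
    EV_TO_KCALMOL,
    R_KCAL_PER_MOL_K,
    ev_to_kcalmol,
)
from .interaction import EnsembleStat

#: Gromacs default classical-LIE coefficients (charged-ligand electrostatics).
MM_LIE_DEFAULTS = dict(alpha=0.181, beta=0.5, gamma=0.0)

EQUATION_TAGS = ("eq2", "eq3", "eq4", "eq5", "eq6", "eq7")


class MissingTermError(ValueError):
    """A required ensemble term is absent from the inputs."""


def _stat(x: EnsembleStat | float | None, name: str, hint: str = "") -> EnsembleStat:
    if x is None:
        msg = f"required ensemble term {name!r} is missing"
        if hint:
            msg += f"; {hint}"
        raise MissingTermError(msg)
    if isinstance(x, EnsembleStat):
        return x
    return EnsembleStat(mean=float(x), sem=0.0, n_frames=1)


@dataclass
class LIEInputs:
    """Ensemble-averaged interaction terms feeding the estimators.

    NNP/D3 terms are in eV (backend-native); the MM benchmarking terms are
    in kcal/mol as exported by classical MD energy groups. ``*_bound`` terms
    come from the protein+ligand+solvent (PLS) trajectory, ``*_free`` from
    the ligand-in-water (LS) trajectory.
    """

    dE_nnp_LP: EnsembleStat | float | None = None
    dE_d3_LP: EnsembleStat | float | None = None
    dE_nnp_LS_bound: EnsembleStat | float | None = None
    dE_d3_LS_bound: EnsembleStat | float | None = None
    dE_nnp_LS_free: EnsembleStat | float | None = None
    dE_d3_LS_free: EnsembleStat | float | None = None
    # MM terms, kcal/mol
    e_el_Lsurr_bound: EnsembleStat | float | None = None
    e_el_LS_free: EnsembleStat | float | None = None
    e_vdw_Lsurr_bound: EnsembleStat | float | None = None
    e_vdw_LS_free: EnsembleStat | float | None = None


@dataclass
class LIECoefficients:
    """Empirical LIE coefficients, optionally with OLS standard errors."""

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0
    se_alpha: float | None = None
    se_beta: float | None = None
    se_gamma: float | None = None
    units_in: str = "kcal/mol"

    def __post_init__(self) -> None:
        for se in (self.se_alpha, self.se_beta, self.se_gamma):
            if se is not None and se < 0:
                raise ValueError("standard errors must be non-negative")


@dataclass(frozen=True)
class FitDiagnostics:
    """Goodness-of-fit summary on the fitted values."""

    r: float
    mae: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if not (-1.0 - 1e-12 <= self.r <= 1.0 + 1e-12):
            raise ValueError(f"Pearson r out of range: {self.r}")
        if self.mae < 0 or self.rmse < 0:
            raise ValueError("mae/rmse must be non-negative")


@dataclass(frozen=True)
class DGEstimate:
    """A binding free energy estimate (kcal/mol) with propagated uncertainty."""

    value: float
    uncertainty: float
    equation: str


@dataclass(frozen=True)
class ExperimentRecord:
    """Experimental affinity for one complex: dG directly, or Ki/IC50 (molar)."""

    complex_id: str
    ic50: float | None = None
    ki: float | None = None
    dg_exp: float | None = None

    def __post_init__(self) -> None:
        if self.ic50 is None and self.ki is None and self.dg_exp is None:
            raise ValueError(f"{self.complex_id}: need one of ic50, ki, dg_exp")
        for name, c in (("ic50", self.ic50), ("ki", self.ki)):
            if c is not None and c <= 0:
                raise ValueError(f"{self.complex_id}: {name} must be positive, got {c}")


def dg_exp(record: ExperimentRecord, temperature_K: float = DEFAULT_TEMPERATURE_K) -> float:
    """Experimental binding free energy (kcal/mol).

    A stated dG takes precedence; otherwise dG = RT ln(c) with c the molar
    Ki (preferred) or IC50 — the competitive-inhibition approximation.
    """
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")
    if record.dg_exp is not None:
        return record.dg_exp
    conc = record.ki if record.ki is not None else record.ic50
    return R_KCAL_PER_MOL_K * temperature_K * math.log(conc)


# ---------------------------------------------------------------------------
# Estimators


def _linear(terms: list[tuple[float, EnsembleStat, bool]], gamma: float, tag: str) -> DGEstimate:
    """Evaluate sum(coef * mean) + gamma with quadrature error propagation.

    Each term is (coef, stat, in_ev); eV terms are converted to kcal/mol.
    """
    total = gamma
    var = 0.0
    for coef, stat, in_ev, in terms:
        scale = EV_TO_KCALMOL if in_ev else 1.0
        total += coef * stat.mean * scale
        var += (abs(coef) * stat.sem * scale) ** 2
    return DGEstimate(value=total, uncertainty=math.sqrt(var), equation=tag)


def dg_eq4(inputs: LIEInputs, coeffs: LIECoefficients) -> DGEstimate:
    """Solvent-ignored, NNP-only estimator: dG = beta * <dE_nnp^L-P> + gamma."""
    lp = _stat(inputs.dE_nnp_LP, "dE_nnp_LP")
    return _linear([(coeffs.beta, lp, True)], coeffs.gamma, "eq4")


def dg_eq5(inputs: LIEInputs, coeffs: LIECoefficients) -> DGEstimate:
    """Solvent-ignored NNP+D3 estimator:
    dG = alpha * <dE_d3^L-P> + beta * <dE_nnp^L-P> + gamma."""
    lp_n = _stat(inputs.dE_nnp_LP, "dE_nnp_LP")
    lp_d = _stat(inputs.dE_d3_LP, "dE_d3_LP")
    return _linear(
        [(coeffs.alpha, lp_d, True), (coeffs.beta, lp_n, True)], coeffs.gamma, "eq5"
    )


_LS_HINT = "run the free-ligand (LS) workflow to produce the ligand-solvent terms"


def _solvated_stat(lp, ls_bound, ls_free, names: tuple[str, str, str]) -> EnsembleStat:
    """Combine L-P and L-S terms into the solvent-included bracket
    <dE^L-P>_PLS + <dE^L-S>_PLS - <E^L-S>_LS (sems in quadrature)."""
    a = _stat(lp, names[0])
    b = _stat(ls_bound, names[1], _LS_HINT)
    c = _stat(ls_free, names[2], _LS_HINT)
    return EnsembleStat(
        mean=a.mean + b.mean - c.mean,
        sem=math.sqrt(a.sem**2 + b.sem**2 + c.sem**2),
        n_frames=min(a.n_frames, b.n_frames, c.n_frames),
    )


def dg_eq6(inputs: LIEInputs, coeffs: LIECoefficients) -> DGEstimate:
    """Solvent-included NNP estimator:
    dG = beta * (<dE_nnp^L-P>_PLS + <dE_nnp^L-S>_PLS - <E_nnp^L-S>_LS) + gamma."""
    nnp = _solvated_stat(
        inputs.dE_nnp_LP, inputs.dE_nnp_LS_bound, inputs.dE_nnp_LS_free,
        ("dE_nnp_LP", "dE_nnp_LS_bound", "dE_nnp_LS_free"),
    )
    est = _linear([(coeffs.beta, nnp, True)], coeffs.gamma, "eq6")
    return est


def dg_eq7(inputs: LIEInputs, coeffs: LIECoefficients) -> DGEstimate:
    """Solvent-included NNP+D3 estimator: the eq6 bracket for both the D3
    (alpha) and NNP (beta) channels."""
    nnp = _solvated_stat(
        inputs.dE_nnp_LP, inputs.dE_nnp_LS_bound, inputs.dE_nnp_LS_free,
        ("dE_nnp_LP", "dE_nnp_LS_bound", "dE_nnp_LS_free"),
    )
    d3 = _solvated_stat(
        inputs.dE_d3_LP, inputs.dE_d3_LS_bound, inputs.dE_d3_LS_free,
        ("dE_d3_LP", "dE_d3_LS_bound", "dE_d3_LS_free"),
    )
    return _linear([(coeffs.alpha, d3, True), (coeffs.beta, nnp, True)], coeffs.gamma, "eq7")


def dg_mm_lie(inputs: LIEInputs, coeffs: LIECoefficients) -> DGEstimate:
    """Classical LIE on MM energy-group terms (already kcal/mol):
    dG = alpha * (<E_vdw^L-surr>_PLS - <E_vdw^L-S>_LS)
       + beta  * (<E_el^L-surr>_PLS  - <E_el^L-S>_LS) + gamma."""
    vb = _stat(inputs.e_vdw_Lsurr_bound, "e_vdw_Lsurr_bound")
    vf = _stat(inputs.e_vdw_LS_free, "e_vdw_LS_free")
    eb = _stat(inputs.e_el_Lsurr_bound, "e_el_Lsurr_bound")
    ef = _stat(inputs.e_el_LS_free, "e_el_LS_free")
    vdw = EnsembleStat(vb.mean - vf.mean, math.sqrt(vb.sem**2 + vf.sem**2),
                       min(vb.n_frames, vf.n_frames))
    el = EnsembleStat(eb.mean - ef.mean, math.sqrt(eb.sem**2 + ef.sem**2),
                      min(eb.n_frames, ef.n_frames))
    return _linear([(coeffs.alpha, vdw, False), (coeffs.beta, el, False)],
                   coeffs.gamma, "eq3")


ESTIMATORS = {"eq3": dg_mm_lie, "eq4": dg_eq4, "eq5": dg_eq5, "eq6": dg_eq6, "eq7": dg_eq7}
# eq2 is eq3 with alpha fixed to zero
ESTIMATORS["eq2"] = dg_mm_lie


# ---------------------------------------------------------------------------
# Fitting and cross-validation


def _diagnostics(y: np.ndarray, yhat: np.ndarray) -> FitDiagnostics:
    resid = y - yhat
    if np.allclose(yhat, yhat[0]) or np.allclose(y, y[0]):
        r = 0.0
    else:
        r = float(np.corrcoef(y, yhat)[0, 1])
    return FitDiagnostics(
        r=r,
        mae=float(np.abs(resid).mean()),
        rmse=float(np.sqrt((resid**2).mean())),
        n=len(y),
    )


def fit_coefficients(
    x_terms: np.ndarray, y: Sequence[float], model: str = "eq4"
) -> tuple[LIECoefficients, FitDiagnostics]:
    """Ordinary least squares fit of the LIE coefficients.

    ``x_terms`` is (n, k) in kcal/mol: k=1 fits (beta, gamma); k=2 fits
    (alpha, beta, gamma) with column 0 the alpha-channel (D3 / van der
    Waals) and column 1 the beta-channel (NNP / electrostatic). gamma is
    the intercept. Standard errors come from the OLS covariance.
    """
    X = np.asarray(x_terms, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if k not in (1, 2):
        raise ValueError(f"expected 1 or 2 predictor columns, got {k}")
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} points to fit {k + 1} coefficients")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design matrix (collinear predictors)")
    res = sm.OLS(y, design).fit()
    params, ses = res.params, res.bse
    if k == 1:
        coeffs = LIECoefficients(
            alpha=0.0, beta=float(params[1]), gamma=float(params[0]),
            se_alpha=None, se_beta=float(ses[1]), se_gamma=float(ses[0]),
        )
    else:
        coeffs = LIECoefficients(
            alpha=float(params[1]), beta=float(params[2]), gamma=float(params[0]),
            se_alpha=float(ses[1]), se_beta=float(ses[2]), se_gamma=float(ses[0]),
        )
    return coeffs, _diagnostics(y, np.asarray(res.fittedvalues))


def predict(x_terms: np.ndarray, coeffs: LIECoefficients) -> np.ndarray:
    """Evaluate the fitted linear form on predictor rows (kcal/mol)."""
    X = np.asarray(x_terms, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[1] == 1:
        return coeffs.beta * X[:, 0] + coeffs.gamma
    return coeffs.alpha * X[:, 0] + coeffs.beta * X[:, 1] + coeffs.gamma


@dataclass
class CrossValidationResult:
    """Per-split refits plus a mean +/- stdev summary."""

    splits: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)


def cross_validate(
    x_terms: np.ndarray,
    y: Sequence[float],
    n_splits: int = 100,
    test_fraction: float = 0.1,
    seed: int = 0,
) -> CrossValidationResult:
    """Random train/test refitting of the coefficients.

    Each split draws ceil(n * test_fraction) test points without
    replacement (seeded), fits on the remainder, and records coefficients
    plus train/test RMSE. Defaults mirror the common 90/10 x 100 protocol;
    for n=54 that is 48 training and 6 test points per split.
    """
    if n_splits < 1:
        raise ValueError("n_splits must be >= 1")
    if not (0 < test_fraction < 1):
        raise ValueError("test_fraction must be in (0, 1)")
    X = np.asarray(x_terms, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n = len(y)
    n_test = math.ceil(n * test_fraction)
    if n_test < 1:
        raise ValueError("test set smaller than 1 point")
    if n - n_test < X.shape[1] + 2:
        raise ValueError("training set too small to fit the coefficients")
    rng = np.random.default_rng(seed)
    result = CrossValidationResult()
    for split_i in range(n_splits):
        test_idx = np.sort(rng.choice(n, size=n_test, replace=False))
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        coeffs, diag_train = fit_coefficients(X[train_mask], y[train_mask])
        yhat_test = predict(X[test_idx], coeffs)
        rmse_test = float(np.sqrt(((y[test_idx] - yhat_test) ** 2).mean()))
        result.splits.append(
            {
                "split": split_i,
                "test_idx": test_idx.tolist(),
                "n_train": int(train_mask.sum()),
                "n_test": int(n_test),
                "alpha": coeffs.alpha,
                "beta": coeffs.beta,
                "gamma": coeffs.gamma,
                "rmse_train": diag_train.rmse,
                "rmse_test": rmse_test,
            }
        )
    df = pd.DataFrame(result.splits)
    result.summary = {
        key: {"mean": float(df[key].mean()), "stdev": float(df[key].std(ddof=1)) if n_splits > 1 else 0.0}
        for key in ("alpha", "beta", "gamma", "rmse_train", "rmse_test")
    }
    result.summary["n_train"] = int(df["n_train"].iloc[0])
    result.summary["n_test"] = int(df["n_test"].iloc[0])
    return result


# ---------------------------------------------------------------------------
# Experimental tables


def read_experiment_table(path: str | Path) -> list[ExperimentRecord]:
    """Read a delimited table of experimental affinities.

    Expected header: ``complex_id`` plus any of ``ic50_nM``, ``ki_nM``,
    ``dg_exp_kcal``. Concentrations are nanomolar in the file and converted
    to molar here.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if "complex_id" not in df.columns:
        raise ValueError(f"{path}: missing 'complex_id' column")
    records = []
    for _, row in df.iterrows():
        def _get(col: str) -> float | None:
            if col in df.columns and pd.notna(row[col]):
                return float(row[col])
            return None

        ic50_nM = _get("ic50_nM")
        ki_nM = _get("ki_nM")
        records.append(
            ExperimentRecord(
                complex_id=str(row["complex_id"]),
                ic50=ic50_nM * 1e-9 if ic50_nM is not None else None,
                ki=ki_nM * 1e-9 if ki_nM is not None else None,
                dg_exp=_get("dg_exp_kcal"),
            )
        )
    return records
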