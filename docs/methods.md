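# Methods

## The model

`endstate_lie` estimates absolute protein–ligand binding free energies from
*end-state* molecular dynamics trajectories: only the bound complex in water
(PLS — protein + ligand + solvent) and, for the solvent-included variants,
the free ligand in water (LS) are simulated. No alchemical intermediates are
involved; the trade-off is that the estimators carry empirical coefficients.

The central per-frame quantity is the interaction energy of two atom groups

    ΔE_int = E(A ∪ B) − E(A) − E(B),

three single-point energies on the same snapshot geometry. Cluster energies
of a truncated protein–ligand system are of order 10⁵ eV while ΔE_int is a
few eV; any constant bias of the backend (a neural potential's systematic
offset, for instance) cancels in the subtraction, which is what makes the
difference — not the absolute energy — the meaningful observable.

Ensemble averages ⟨·⟩ over frames feed linear estimators of the binding
free energy. With all x-terms converted to kcal/mol before the linear form
is applied (so γ is always in kcal/mol):

| tag | form | ensembles needed |
|-----|------|-----------------|
| eq3 | α(⟨E_vdw^L-surr⟩_PLS − ⟨E_vdw^L-S⟩_LS) + β(⟨E_el^L-surr⟩_PLS − ⟨E_el^L-S⟩_LS) + γ | classical MM energy groups, PLS + LS |
| eq4 | β⟨ΔE_nnp^L-P⟩_PLS + γ | PLS only, solvent ignored |
| eq5 | α⟨ΔE_d3^L-P⟩ + β⟨ΔE_nnp^L-P⟩ + γ | PLS only |
| eq6 | β(⟨ΔE_nnp^L-P⟩ + ⟨ΔE_nnp^L-S⟩_PLS − ⟨E_nnp^L-S⟩_LS) + γ | PLS + LS |
| eq7 | the eq6 bracket for both the D3 (α) and NNP (β) channels | PLS + LS |

Nesting identities hold by construction and are tested: eq5 with α = 0 is
eq4, and eq6/eq7 collapse to eq4/eq5 when the bound and free
ligand–solvent terms cancel. The splitting of the ligand–surroundings term
into protein and solvent channels assumes interaction additivity; for a
pairwise potential the identity ΔE(L, P∪S) = ΔE(L,P) + ΔE(L,S) is exact
(asserted to 1e-9 eV on the mock backend), for a many-body neural potential
it is only approximate and is documented rather than asserted numerically.

Conformational entropy changes and the linear-response "preorganization"
term are deliberately outside the formalism, as is any implicit-solvent
(PB/GBSA) replacement for the explicit ligand–solvent terms.

## Backends

All backends share one contract: a scalar potential energy in eV for an
isolated cluster (no periodic boundary conditions, mirroring stripped-water
single-point evaluation), deterministic for the mock and D3 backends and
reproducible to 1e-4 eV for the NNP.

* **NNP_ANI2X** — ANI-2x via torchani (optional extra `nnp`), covering
  exactly {H, C, N, O, F, S, Cl}. Sodium counter-ions therefore cannot be
  evaluated and are stripped (see below). Energies arrive in Hartree and
  are converted with 1 Ha = 27.211386245988 eV.
* **DISP_D3** — Grimme D3 dispersion via simple-dftd3 (optional extra
  `d3`), ωB97X parameter set. Becke–Johnson damping is the default;
  zero-damping is selectable via `params={"damping": "zero"}` since the
  historical parameterization is ambiguous, and the choice is logged.
* **MOCK_PAIRWISE** — Lennard-Jones + Coulomb with a fixed per-element
  (ε, σ, q) table and Lorentz–Berthelot combination,
  k_e = 14.399645 eV·Å·e⁻². The default charges are zero for the organic
  elements and +1 for Na/K: with a neutral pure-LJ default the potential
  decays as r⁻⁶, so distance-cutoff constructions converge quickly and
  every interaction identity can be checked against closed forms; charges
  remain exercisable through an explicit table override. The mock backend
  exists to make the pipeline exactly verifiable, not to model chemistry.

## Units and constants

Internal energy unit is eV everywhere; free energies are reported in
kcal/mol with 1 eV = 23.060548 kcal/mol, fixed once (printed conversions in
the literature round inconsistently, so a single frozen constant matters).
Experimental affinities convert via ΔG = RT ln(c/1 M) with
R = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹, default T = 298.15 K (configurable —
note production MD for such datasets is often run at 310 K).

## Statistics

* Ensemble spread is the plain iid standard error of the mean
  (sample stdev / √n, zero for n = 1); sample stdev is available via a
  flag. Autocorrelation/block averaging is out of scope.
* Estimator uncertainty is first-order: |coef|·sem per term, combined in
  quadrature.
* Coefficients are fitted by ordinary least squares with intercept
  (statsmodels); standard errors come from the OLS covariance, and the
  diagnostics (Pearson r, MAE, RMSE on fitted values) are checked against
  direct recomputation to 1e-12.
* Cross-validation draws ⌈n·test_fraction⌉ test points without replacement
  from a seeded generator, refits on the remainder, and summarizes
  coefficients and train/test RMSE as mean ± stdev. The defaults
  (100 splits, fraction 0.1) give 48 training / 6 test points at n = 54.
* Convergence profiles subsample deterministically — the first frame of
  each of n equal intervals over the reference window, indices
  ⌊i·N/n⌋ — so they are exactly reproducible; no RNG is involved.

## Solvent reduction and ion stripping

Waters are ordered by their minimum atom–atom distance (heavy atoms and
hydrogens on both sides — the most conservative reading of "nearest") to
the solute, ties broken by molecule id. Reduction keeps whole water
molecules with distance ≤ cutoff, default 4.0 Å measured from the whole
protein–ligand complex (a ligand-only reference is available by passing
only the ligand group as solute). Distances are plain Euclidean: frames
are assumed PBC-whole and centred upstream; the reader validates molecule
compactness (warning when an atom sits > 5 Å from the rest of its
molecule) instead of re-imaging.

Ion stripping removes backend-unsupported elements only from residues
declared strippable (default NA/CL/K/SOD/CLA/POT). An unsupported element
anywhere else — e.g. a brominated ligand under the ANI element set — is a
hard error, never a silent drop, because losing ligand atoms would corrupt
ΔE_int. Neglecting the ligand–ion interaction is justified when the few
counter-ions stay far from a pocket-buried ligand.

## Synthetic fixtures

The toy complexes are geometric stand-ins for solvated protein–ligand
systems: a rigid C/N/O/H receptor cluster, a small C/H/O ligand cluster
3–5 Å away, three-site waters scattered from near-contact to the box
boundary, optional Na⁺ ions, per-frame Gaussian jitter, all derived from a
single seed (byte-identical files on regeneration). Default test systems
use ~10 receptor atoms, ~4 ligand atoms, 15–25 waters and ≤ 2 ions over
≤ 5 frames — sizes chosen so every oracle (O(N²) brute force, closed-form
pair energies) runs in milliseconds while exercising every code path,
including ion stripping and solvent reduction.

The synthetic calibration dataset draws ensemble means uniformly from
[−90, −20] kcal/mol (the realistic magnitude range for ligand–protein
interaction energies) and adds Gaussian noise, default σ = 1.5 kcal/mol at
n = 54, matching the scale of a multi-family benchmark set.

What the fixtures do **not** emulate: real conformational sampling,
chemistry-driven energy landscapes, water structure, or correlated frames.
Passing tests demonstrate that the plumbing and the arithmetic are exact
and that the statistical machinery recovers known coefficients — not that
the method is accurate on real complexes.

## Scope of the offline validation

The headline benchmark-scale result for this family of methods — a
correlation of R = 0.87–0.88 and MAE of 1.76 (NNP-only) / 0.76 (NNP+D3)
kcal/mol against experimental affinities over 54 complexes — requires the
original production MD trajectories (~100 frames × 54 systems) and full
neural-potential evaluations. It cannot be recomputed from this
repository and is intentionally not asserted anywhere in the test suite.
Users with their own trajectories reproduce that pipeline directly through
the `endlie bound` / `endlie free-ligand` / `endlie fit` commands; offline,
the property suite above is the evidence that each stage computes what it
claims. Likewise the fitted calibration coefficients
(β = 0.10639, γ = −4.9875 for the single-channel form; the classical-LIE
refit α = 0.25, β = −0.06, γ = −3.09) are consumed as published inputs,
with the unit convention recorded (`units_in`), since a coefficient fitted
in one unit system does not transfer to another.

## Numerical choices

* Energy tables are written with `%.17g` and parsed with round-trip float
  precision, so resuming from per-frame files reproduces the original
  report bit for bit.
* OLS rank deficiency raises rather than silently pseudo-inverting.
* Pearson r is defined as 0 when either side is constant.
* `extract_group` matches atoms by serial, so index groups survive
  ion-stripping and solvent-reduction (which preserve original serials);
  indices pointing at removed waters are skippable with `missing="ignore"`.
* Gromacs ndx parsing: duplicate group names — last definition wins with a
  warning; empty groups are kept but flagged; non-integer tokens name the
  offending line.

## Known limitations

* Binary trajectory formats (XTC/TRR/DCD) are not read; convert to
  multi-model PDB (or per-frame PDBs, or XYZ) first.
* Sampling is inherited from the classical force field that generated the
  frames; the backends only re-evaluate energies.
* The iid error bars underestimate uncertainty for correlated frames.
* The D3 and NNP backends require optional dependencies; without them the
  corresponding calculators raise a clear `BackendUnavailableError` and
  everything else (including the full mock pipeline) works.
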