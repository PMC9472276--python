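import math

import numpy as np
import pytest

from endstate_lie.constants import EV_TO_KCALMOL
from endstate_lie.fixtures import make_synthetic_lie_dataset
from endstate_lie.interaction import EnsembleStat
from endstate_lie.lie import (
    ExperimentRecord,
    LIECoefficients,
    LIEInputs,
    MissingTermError,
    cross_validate,
    dg_eq4,
    dg_eq5,
    dg_eq6,
    dg_eq7,
    dg_exp,
    dg_mm_lie,
    fit_coefficients,
    predict,
    read_experiment_table,
)

# fitted single-channel coefficients from a 54-complex calibration
BETA_FIT = 0.10639
GAMMA_FIT = -4.9875


def _stat(mean, sem=0.0, n=100):
    return EnsembleStat(mean=mean, sem=sem, n_frames=n)


class TestDgEq4:
    def test_intercept_only(self):
        inputs = LIEInputs(dE_nnp_LP=_stat(0.0))
        coeffs = LIECoefficients(beta=BETA_FIT, gamma=GAMMA_FIT)
        assert dg_eq4(inputs, coeffs).value == pytest.approx(GAMMA_FIT)

    def test_fitted_coefficients_on_mean_interaction(self):
        # beta * (-2.183 eV in kcal/mol) + gamma = -10.343 kcal/mol
        inputs = LIEInputs(dE_nnp_LP=_stat(-2.183))
        coeffs = LIECoefficients(beta=BETA_FIT, gamma=GAMMA_FIT)
        assert dg_eq4(inputs, coeffs).value == pytest.approx(-10.343, abs=2e-3)

    def test_identity_coefficients(self):
        inputs = LIEInputs(dE_nnp_LP=_stat(-2.0))
        coeffs = LIECoefficients(beta=1.0, gamma=0.0)
        assert dg_eq4(inputs, coeffs).value == pytest.approx(-2.0 * EV_TO_KCALMOL)

    def test_uncertainty_is_beta_times_sem(self):
        inputs = LIEInputs(dE_nnp_LP=_stat(-2.0, sem=0.05))
        coeffs = LIECoefficients(beta=-0.5, gamma=0.0)
        est = dg_eq4(inputs, coeffs)
        assert est.uncertainty == pytest.approx(0.5 * 0.05 * EV_TO_KCALMOL)

    def test_missing_term_named(self):
        with pytest.raises(MissingTermError, match="dE_nnp_LP"):
            dg_eq4(LIEInputs(), LIECoefficients(beta=1.0))


class TestDgEq5:
    def test_alpha_zero_reduces_to_eq4(self):
        inputs = LIEInputs(dE_nnp_LP=_stat(-2.2), dE_d3_LP=_stat(-1.1))
        c5 = LIECoefficients(alpha=0.0, beta=0.3, gamma=-2.0)
        assert dg_eq5(inputs, c5).value == pytest.approx(dg_eq4(inputs, c5).value)

    def test_all_means_zero_gives_gamma(self):
        inputs = LIEInputs(dE_nnp_LP=_stat(0.0), dE_d3_LP=_stat(0.0))
        assert dg_eq5(inputs, LIECoefficients(alpha=0.4, beta=0.2, gamma=-3.3)
                      ).value == pytest.approx(-3.3)

    def test_linear_form_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            nnp, d3 = rng.normal(-2, 1), rng.normal(-1, 0.5)
            a, b, g = rng.normal(size=3)
            inputs = LIEInputs(dE_nnp_LP=_stat(nnp), dE_d3_LP=_stat(d3))
            want = a * d3 * EV_TO_KCALMOL + b * nnp * EV_TO_KCALMOL + g
            got = dg_eq5(inputs, LIECoefficients(alpha=a, beta=b, gamma=g)).value
            assert got == pytest.approx(want, abs=1e-10)


class TestDgEq6Eq7:
    def test_solvent_cancellation_reduces_eq6_to_eq4(self):
        ls = _stat(-0.8)
        inputs = LIEInputs(dE_nnp_LP=_stat(-2.1), dE_nnp_LS_bound=ls,
                           dE_nnp_LS_free=ls)
        coeffs = LIECoefficients(beta=0.11, gamma=-5.0)
        assert dg_eq6(inputs, coeffs).value == pytest.approx(
            dg_eq4(inputs, coeffs).value
        )

    def test_all_zero_gives_gamma(self):
        z = _stat(0.0)
        inputs = LIEInputs(dE_nnp_LP=z, dE_nnp_LS_bound=z, dE_nnp_LS_free=z,
                           dE_d3_LP=z, dE_d3_LS_bound=z, dE_d3_LS_free=z)
        coeffs = LIECoefficients(alpha=0.3, beta=0.2, gamma=-4.0)
        assert dg_eq6(inputs, coeffs).value == pytest.approx(-4.0)
        assert dg_eq7(inputs, coeffs).value == pytest.approx(-4.0)

    def test_eq7_reduces_to_eq5_on_cancellation(self):
        ls_n, ls_d = _stat(-0.8), _stat(-0.4)
        inputs = LIEInputs(
            dE_nnp_LP=_stat(-2.1), dE_nnp_LS_bound=ls_n, dE_nnp_LS_free=ls_n,
            dE_d3_LP=_stat(-1.0), dE_d3_LS_bound=ls_d, dE_d3_LS_free=ls_d,
        )
        coeffs = LIECoefficients(alpha=0.25, beta=0.11, gamma=-5.0)
        assert dg_eq7(inputs, coeffs).value == pytest.approx(
            dg_eq5(inputs, coeffs).value
        )

    def test_linear_form_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            lp, lsb, lsf = rng.normal(-2, 1, size=3)
            b, g = rng.normal(size=2)
            inputs = LIEInputs(dE_nnp_LP=_stat(lp), dE_nnp_LS_bound=_stat(lsb),
                               dE_nnp_LS_free=_stat(lsf))
            want = b * (lp + lsb - lsf) * EV_TO_KCALMOL + g
            got = dg_eq6(inputs, LIECoefficients(beta=b, gamma=g)).value
            assert got == pytest.approx(want, abs=1e-10)

    def test_missing_ls_terms_direct_user_to_ls_workflow(self):
        inputs = LIEInputs(dE_nnp_LP=_stat(-2.0))
        with pytest.raises(MissingTermError, match="free-ligand"):
            dg_eq6(inputs, LIECoefficients(beta=1.0))


class TestDgMmLie:
    def test_gromacs_defaults_with_zero_differences(self):
        z = _stat(0.0)
        inputs = LIEInputs(e_el_Lsurr_bound=z, e_el_LS_free=z,
                           e_vdw_Lsurr_bound=z, e_vdw_LS_free=z)
        coeffs = LIECoefficients(alpha=0.181, beta=0.5, gamma=0.0)
        assert dg_mm_lie(inputs, coeffs).value == 0.0

    def test_refit_coefficients_intercept(self):
        # a neutral-ligand refit lands near alpha=0.25, beta=-0.06, gamma=-3.09;
        # with vanishing energy differences only the intercept survives
        z = _stat(0.0)
        inputs = LIEInputs(e_el_Lsurr_bound=z, e_el_LS_free=z,
                           e_vdw_Lsurr_bound=z, e_vdw_LS_free=z)
        coeffs = LIECoefficients(alpha=0.25, beta=-0.06, gamma=-3.09)
        assert dg_mm_lie(inputs, coeffs).value == pytest.approx(-3.09)

    def test_linear_form_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            vb, vf, eb, ef = rng.normal(-20, 10, size=4)
            a, b, g = rng.normal(size=3)
            inputs = LIEInputs(e_vdw_Lsurr_bound=_stat(vb), e_vdw_LS_free=_stat(vf),
                               e_el_Lsurr_bound=_stat(eb), e_el_LS_free=_stat(ef))
            want = a * (vb - vf) + b * (eb - ef) + g
            got = dg_mm_lie(inputs, LIECoefficients(alpha=a, beta=b, gamma=g)).value
            assert got == pytest.approx(want, abs=1e-10)

    def test_missing_term(self):
        with pytest.raises(MissingTermError):
            dg_mm_lie(LIEInputs(), LIECoefficients())


class TestLinearity:
    def test_scaling_means_scales_dg_minus_gamma(self):
        coeffs = LIECoefficients(alpha=0.2, beta=0.1, gamma=-5.0)
        inputs = LIEInputs(dE_nnp_LP=_stat(-2.0), dE_d3_LP=_stat(-1.0))
        base = dg_eq5(inputs, coeffs).value - coeffs.gamma
        for c in (0.5, 2.0, -3.0):
            scaled = LIEInputs(dE_nnp_LP=_stat(-2.0 * c), dE_d3_LP=_stat(-1.0 * c))
            assert dg_eq5(scaled, coeffs).value - coeffs.gamma == pytest.approx(
                c * base, abs=1e-9
            )


class TestDgExp:
    def test_ki_one_molar_is_zero_at_any_temperature(self):
        rec = ExperimentRecord(complex_id="X", ki=1.0)
        for t in (100.0, 298.15, 310.0):
            assert dg_exp(rec, temperature_K=t) == 0.0

    def test_ic50_one_micromolar(self):
        rec = ExperimentRecord(complex_id="X", ic50=1e-6)
        want = 1.987204e-3 * 298.15 * math.log(1e-6)
        assert dg_exp(rec) == pytest.approx(want, abs=1e-12)
        assert dg_exp(rec) == pytest.approx(-8.186, abs=1e-3)

    def test_stated_dg_takes_precedence(self):
        rec = ExperimentRecord(complex_id="X", ic50=1e-6, dg_exp=-12.3)
        assert dg_exp(rec) == -12.3

    def test_ki_preferred_over_ic50(self):
        rec = ExperimentRecord(complex_id="X", ic50=1e-6, ki=1e-9)
        assert dg_exp(rec) == pytest.approx(1.987204e-3 * 298.15 * math.log(1e-9))

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            ExperimentRecord(complex_id="X", ic50=-1.0)

    def test_record_needs_some_affinity(self):
        with pytest.raises(ValueError):
            ExperimentRecord(complex_id="X")


class TestFitCoefficients:
    def test_noiseless_recovery_to_1e10(self):
        df = make_synthetic_lie_dataset(beta_true=0.106, gamma_true=-5.0, n=30,
                                        noise_sd=0.0, seed=2)
        coeffs, diag = fit_coefficients(df["x_kcal"].to_numpy(),
                                        df["dg_exp_kcal"].to_numpy())
        assert coeffs.beta == pytest.approx(0.106, abs=1e-10)
        assert coeffs.gamma == pytest.approx(-5.0, abs=1e-10)
        assert diag.r == pytest.approx(1.0, abs=1e-12)
        assert diag.mae == pytest.approx(0.0, abs=1e-10)

    def test_single_predictor_matches_closed_form_regression(self):
        df = make_synthetic_lie_dataset(n=54, noise_sd=1.5, seed=9)
        x = df["x_kcal"].to_numpy()
        y = df["dg_exp_kcal"].to_numpy()
        coeffs, _ = fit_coefficients(x, y)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        intercept = y.mean() - slope * x.mean()
        assert coeffs.beta == pytest.approx(slope, rel=1e-10)
        assert coeffs.gamma == pytest.approx(intercept, rel=1e-10)

    def test_beta_within_two_se_in_most_replicates(self):
        hits = 0
        for seed in range(100):
            df = make_synthetic_lie_dataset(beta_true=0.106, gamma_true=-5.0,
                                            n=54, noise_sd=1.5, seed=seed)
            coeffs, _ = fit_coefficients(df["x_kcal"].to_numpy(),
                                         df["dg_exp_kcal"].to_numpy())
            if abs(coeffs.beta - 0.106) < 2 * coeffs.se_beta:
                hits += 1
        assert hits >= 90

    def test_two_predictor_fit_recovers_generating_plane(self):
        rng = np.random.default_rng(1)
        X = rng.uniform(-60, -10, size=(40, 2))
        y = 0.25 * X[:, 0] - 0.06 * X[:, 1] - 3.09
        coeffs, diag = fit_coefficients(X, y)
        assert coeffs.alpha == pytest.approx(0.25, abs=1e-10)
        assert coeffs.beta == pytest.approx(-0.06, abs=1e-10)
        assert coeffs.gamma == pytest.approx(-3.09, abs=1e-9)
        assert predict(X, coeffs) == pytest.approx(y, abs=1e-9)

    def test_diagnostics_match_brute_force(self):
        df = make_synthetic_lie_dataset(n=54, noise_sd=1.5, seed=33)
        x = df["x_kcal"].to_numpy()
        y = df["dg_exp_kcal"].to_numpy()
        coeffs, diag = fit_coefficients(x, y)
        yhat = coeffs.beta * x + coeffs.gamma
        r = float(np.corrcoef(y, yhat)[0, 1])
        assert diag.r == pytest.approx(r, abs=1e-12)
        assert diag.mae == pytest.approx(float(np.abs(y - yhat).mean()), abs=1e-12)
        assert diag.rmse == pytest.approx(
            float(np.sqrt(((y - yhat) ** 2).mean())), abs=1e-12
        )

    def test_rank_deficient_design_rejected(self):
        X = np.ones((10, 2))
        X[:, 1] = 2 * X[:, 0]
        with pytest.raises(ValueError, match="rank"):
            fit_coefficients(X, np.arange(10.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_coefficients(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestCrossValidate:
    def test_split_sizes_for_n54_fraction_01(self):
        df = make_synthetic_lie_dataset(n=54, noise_sd=1.5, seed=0)
        result = cross_validate(df["x_kcal"].to_numpy(),
                                df["dg_exp_kcal"].to_numpy(),
                                n_splits=5, test_fraction=0.1, seed=1)
        assert result.summary["n_train"] == 48
        assert result.summary["n_test"] == 6

    def test_same_seed_identical_splits_and_results(self):
        df = make_synthetic_lie_dataset(n=54, noise_sd=1.5, seed=0)
        x, y = df["x_kcal"].to_numpy(), df["dg_exp_kcal"].to_numpy()
        a = cross_validate(x, y, n_splits=10, seed=7)
        b = cross_validate(x, y, n_splits=10, seed=7)
        assert [s["test_idx"] for s in a.splits] == [s["test_idx"] for s in b.splits]
        assert a.summary == b.summary

    def test_noiseless_data_zero_test_rmse(self):
        df = make_synthetic_lie_dataset(n=30, noise_sd=0.0, seed=5)
        result = cross_validate(df["x_kcal"].to_numpy(),
                                df["dg_exp_kcal"].to_numpy(), n_splits=20, seed=3)
        assert all(s["rmse_test"] < 1e-9 for s in result.splits)

    def test_invalid_fraction(self):
        df = make_synthetic_lie_dataset(n=20, seed=0)
        with pytest.raises(ValueError):
            cross_validate(df["x_kcal"].to_numpy(), df["dg_exp_kcal"].to_numpy(),
                           test_fraction=1.5)


class TestExperimentTable:
    def test_read_mixed_table(self, tmp_path):
        p = tmp_path / "exp.csv"
        p.write_text(
            "complex_id,ic50_nM,ki_nM,dg_exp_kcal\n"
            "5IVS,1000,,\n"
            "XYZ1,,50,\n"
            "XYZ2,,,-9.5\n"
        )
        records = read_experiment_table(p)
        assert [r.complex_id for r in records] == ["5IVS", "XYZ1", "XYZ2"]
        assert records[0].ic50 == pytest.approx(1e-6)
        assert records[1].ki == pytest.approx(5e-8)
        assert dg_exp(records[2]) == -9.5

    def test_missing_id_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("name,ic50_nM\nA,5\n")
        with pytest.raises(ValueError, match="complex_id"):
            read_experiment_table(p)
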