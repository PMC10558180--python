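"""Contralateral normalization, correlate tables, standardized OLS and
partial-regression (Frisch-Waugh-Lovell) identities."""

import numpy as np
import pandas as pd
import pytest

from tumorburden.core import ContractError
from tumorburden.correlates import (
    build_tumor_table,
    build_voxel_table,
    fit_multivariate,
    log_standardize,
    normalize_to_contralateral,
    partial_regression,
    records_to_frame,
)
from tumorburden.phantom import PhantomSpec, generate_phantom, simulate_regression_table


@pytest.fixture(scope="module")
def clean_flat_phantom():
    """No noise, no PSF: uptake ratios equal the generative contrasts."""
    spec = PhantomSpec(noise_sd_mri=0.0, noise_sd_pet=0.0, noise_sd_fluor=0.0,
                       pet_psf_fwhm=0.0, gd_status=False, pet_visible=True,
                       cellularity=1.0, seed=31)
    return generate_phantom(spec, case_id="flat")


class TestNormalize:
    def test_trivial_ratios(self):
        assert normalize_to_contralateral(2.0, 1.0) == 2.0
        assert normalize_to_contralateral(1.7, 1.7) == 1.0

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(ContractError):
            normalize_to_contralateral(1.0, 0.0)

    def test_phantom_generative_contrast_recovered(self, clean_flat_phantom):
        """Tumor:background 3:1, noiseless, unblurred -> max-uptake ratio 3."""
        records = build_tumor_table([clean_flat_phantom])
        assert records[0].pet_uptake == pytest.approx(3.0, rel=1e-6)

    def test_scale_invariance(self, clean_flat_phantom):
        """Scaling a whole image by a positive constant leaves records unchanged."""
        import copy
        from tumorburden.core import ScalarVolume
        case = copy.copy(clean_flat_phantom)
        case.pet = ScalarVolume(case.pet.geometry, case.pet.values * 37.5)
        case.tdtomato = ScalarVolume(case.tdtomato.geometry, case.tdtomato.values * 0.04)
        a = build_tumor_table([clean_flat_phantom])[0]
        b = build_tumor_table([case])[0]
        assert b.pet_uptake == pytest.approx(a.pet_uptake, rel=1e-12)
        assert b.tdtomato == pytest.approx(a.tdtomato, rel=1e-12)


class TestTumorTable:
    def test_record_fields_from_generator(self, clean_flat_phantom):
        rec = build_tumor_table([clean_flat_phantom])[0]
        assert rec.gd_status == 0
        assert rec.tumor_volume > 0
        for value in (rec.tdtomato, rec.asct2, rec.lectin):
            assert value > 1.0  # tumor fluorescence exceeds contralateral brain

    def test_missing_lectin_marked_absent(self):
        spec = PhantomSpec(has_lectin=False, seed=32)
        rec = build_tumor_table([generate_phantom(spec, case_id="nolec")])[0]
        assert rec.lectin is None
        frame = records_to_frame([rec])
        assert np.isnan(frame.loc["nolec", "lectin"])

    def test_max_dominates_mean_summary(self, cohort):
        for case in cohort[:4]:
            pet_vals = case.pet.values[case.truth_pet.values]
            assert pet_vals.max() >= pet_vals.mean()


class TestVoxelTable:
    def test_record_count_equals_tumor_voxels(self, clean_flat_phantom):
        table = build_voxel_table(clean_flat_phantom)
        assert len(table) == clean_flat_phantom.truth_pet.count

    def test_noiseless_voxel_dependency(self, clean_flat_phantom):
        """Unblurred, noiseless: voxel PET and tdTomato are both affine in
        cell density, so their correlation is ~1 wherever density varies."""
        table = build_voxel_table(clean_flat_phantom)
        r = np.corrcoef(table["pet_uptake"], table["tdtomato"])[0, 1]
        assert r > 0.99

    def test_empty_tumor_rejected(self, clean_flat_phantom):
        import copy
        from tumorburden.core import BinaryMask
        case = copy.copy(clean_flat_phantom)
        case.truth_pet = BinaryMask(case.truth_pet.geometry,
                                    np.zeros(case.truth_pet.geometry.shape, bool))
        with pytest.raises(ContractError):
            build_voxel_table(case)


class TestLogStandardize:
    def test_zero_mean_unit_sd(self):
        table = simulate_regression_table(n=20, seed=1)
        out = log_standardize(table)
        for col in ("pet_uptake", "tdtomato", "asct2", "lectin", "tumor_volume", "gd_status"):
            assert abs(out[col].mean()) < 1e-12
            assert out[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_two_point_hand_arithmetic(self):
        table = pd.DataFrame({"pet_uptake": [np.e, np.e**3]})
        out = log_standardize(table)
        np.testing.assert_allclose(out["pet_uptake"], [-np.sqrt(0.5), np.sqrt(0.5)], atol=1e-12)

    def test_nonpositive_value_names_record(self):
        table = pd.DataFrame({"pet_uptake": [1.0, -2.0]}, index=["ok", "bad"])
        with pytest.raises(ContractError, match="bad"):
            log_standardize(table)

    def test_constant_column_rejected(self):
        table = pd.DataFrame({"pet_uptake": [1.0, 1.0, 1.0]})
        with pytest.raises(ContractError, match="zero variance"):
            log_standardize(table)

    def test_gd_status_not_logged(self):
        table = simulate_regression_table(n=15, seed=2)
        out = log_standardize(table)
        gd = table["gd_status"].astype(float)
        expected = (gd - gd.mean()) / gd.std(ddof=1)
        np.testing.assert_allclose(out["gd_status"], expected, atol=1e-12)

    def test_response_unscaled_option(self):
        table = simulate_regression_table(n=15, seed=3)
        out = log_standardize(table, standardize_response=False)
        np.testing.assert_allclose(out["pet_uptake"], np.log(table["pet_uptake"]), atol=1e-12)


class TestFitMultivariate:
    def test_exact_linear_combination_recovered(self):
        rng = np.random.default_rng(60)
        n = 30
        table = pd.DataFrame(rng.standard_normal((n, 3)), columns=["tdtomato", "asct2", "gd_status"])
        table["pet_uptake"] = 1.5 * table["tdtomato"] - 0.5 * table["asct2"] + 0.25 * table["gd_status"]
        fit = fit_multivariate(table)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.params["tdtomato"] == pytest.approx(1.5, abs=1e-9)
        assert fit.params["asct2"] == pytest.approx(-0.5, abs=1e-9)

    def test_pure_noise_null_level(self):
        rng = np.random.default_rng(61)
        n, k = 200, 4
        table = pd.DataFrame(rng.standard_normal((n, k)),
                             columns=["tdtomato", "asct2", "lectin", "tumor_volume"])
        table["pet_uptake"] = rng.standard_normal(n)
        fit = fit_multivariate(table)
        assert np.all(np.abs(fit.coefficients) < 0.25)
        # E[R^2] = k/(n-1) under the null
        assert fit.r_squared < 5 * k / (n - 1)

    def test_residuals_sum_to_zero(self):
        table = simulate_regression_table(n=13, seed=4)
        fit = fit_multivariate(log_standardize(table))
        assert abs(fit.residuals.sum()) < 1e-9
        assert 0.0 <= fit.r_squared <= 1.0

    def test_rank_deficiency_names_columns(self):
        rng = np.random.default_rng(62)
        table = pd.DataFrame({"tdtomato": rng.standard_normal(20)})
        table["asct2"] = 2.0 * table["tdtomato"]
        table["pet_uptake"] = rng.standard_normal(20)
        with pytest.raises(ContractError, match="collinear"):
            fit_multivariate(table)

    def test_missing_lectin_dual_models(self):
        table = simulate_regression_table(n=13, seed=5, lectin_missing=2)
        std = log_standardize(table.drop(columns="lectin")).join(
            np.log(table["lectin"]).pipe(lambda s: (s - s.mean()) / s.std(ddof=1)))
        full = fit_multivariate(std)
        assert full.n == 11  # complete cases only
        free = fit_multivariate(std, regressors=["tdtomato", "asct2", "tumor_volume", "gd_status"])
        assert free.n == 13


class TestPartialRegression:
    def test_fwl_identity_every_regressor(self):
        """Partial-regression slope equals the multivariate coefficient."""
        rng = np.random.default_rng(63)
        n, k = 40, 8
        cols = [f"x{j}" for j in range(k)]
        table = pd.DataFrame(rng.standard_normal((n, k)), columns=cols)
        table["pet_uptake"] = table @ rng.standard_normal(k + 1)[:-1] + rng.standard_normal(n)
        fit = fit_multivariate(table, regressors=cols)
        for col in cols:
            _, _, slope = partial_regression(table, col, regressors=cols)
            assert slope == pytest.approx(fit.params[col], abs=1e-10)

    def test_single_regressor_degenerates_to_simple_regression(self):
        rng = np.random.default_rng(64)
        table = pd.DataFrame({"tdtomato": rng.standard_normal(25)})
        table["pet_uptake"] = 0.8 * table["tdtomato"] + rng.normal(0, 0.1, 25)
        _, _, slope = partial_regression(table, "tdtomato", regressors=["tdtomato"])
        simple = fit_multivariate(table, regressors=["tdtomato"])
        assert slope == pytest.approx(simple.params["tdtomato"], abs=1e-12)

    def test_residual_coordinates_centered(self):
        table = log_standardize(simulate_regression_table(n=13, seed=6))
        x_res, y_res, _ = partial_regression(table, "tdtomato")
        assert abs(x_res.mean()) < 1e-9 and abs(y_res.mean()) < 1e-9


class TestParameterRecovery:
    def test_unbiased_over_replicates(self):
        """Fitted standardized coefficients are unbiased within Monte-Carlo
        error over 200 simulated cohorts at the study's n = 13."""
        effects = {"tdtomato": 1.2, "asct2": 0.3, "lectin": 0.15,
                   "tumor_volume": 0.2, "gd_status": 0.4}
        betas = []
        for rep in range(200):
            table = simulate_regression_table(n=13, effects=effects, noise_sd=0.3,
                                              seed=1000 + rep)
            # fit on the generative log scale (regressor logs are standard
            # normal by construction, so coefficients are already standardized)
            logt = table.copy()
            for col in ("pet_uptake", "tdtomato", "asct2", "lectin", "tumor_volume"):
                logt[col] = np.log(logt[col])
            fit = fit_multivariate(logt, response="pet_uptake",
                                   regressors=list(effects))
            betas.append(fit.coefficients[list(effects)])
        betas = pd.DataFrame(betas)
        for name, true_beta in effects.items():
            mc_err = betas[name].std(ddof=1) / np.sqrt(len(betas))
            assert abs(betas[name].mean() - true_beta) < 4 * mc_err + 1e-3, name

    def test_tdtomato_dominant_model_recovered(self):
        """A tdTomato-dominant generative model yields tdTomato as the largest
        fitted coefficient."""
        table = simulate_regression_table(n=13, seed=7)
        fit = fit_multivariate(log_standardize(table))
        coefs = fit.coefficients.abs()
        assert coefs.idxmax() == "tdtomato"
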