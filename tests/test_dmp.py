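import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from ewaskit import dmp
from ewaskit.io import SampleSheet, ValidationError
from ewaskit.stats import bh_adjust
from conftest import make_beta


def _sheet(n=20, seed=0):
    rng = np.random.default_rng(seed)
    return SampleSheet(
        pd.DataFrame(
            {"group": ["control"] * n + ["case"] * n,
             "age": rng.uniform(60, 87, 2 * n).round(1),
             "sex": ["M", "F"] * n},
            index=pd.Index([f"S{i:03d}" for i in range(2 * n)],
                           name="sample_id"),
        )
    )


def _group_design(sheet):
    X = pd.DataFrame(index=sheet.sample_ids)
    X["intercept"] = 1.0
    X["group"] = sheet.case_mask().astype(float)
    return X


class TestFitProbeModels:
    def test_equal_group_means_give_zero_coefficient(self):
        sheet = _sheet()
        betas = make_beta(np.full((3, 40), 0.4),
                          sample_ids=list(sheet.sample_ids))
        fits = dmp.fit_probe_models(betas, _group_design(sheet))
        np.testing.assert_allclose(fits.coef, 0.0, atol=1e-14)

    def test_noiseless_group_difference_recovered_exactly(self):
        sheet = _sheet()
        vals = np.full((1, 40), 0.40)
        vals[0, sheet.case_mask()] = 0.52
        betas = make_beta(vals, sample_ids=list(sheet.sample_ids))
        fits = dmp.fit_probe_models(betas, _group_design(sheet))
        assert fits.coef.iloc[0] == pytest.approx(0.12, abs=1e-14)

    def test_matches_closed_form_ols_oracle(self):
        # 3-probe toy vs an independent lstsq-based oracle
        sheet = _sheet(seed=2)
        rng = np.random.default_rng(2)
        vals = np.clip(rng.normal(0.5, 0.05, (3, 40)), 0, 1)
        X = pd.DataFrame(index=sheet.sample_ids)
        X["intercept"] = 1.0
        X["group"] = sheet.case_mask().astype(float)
        X["age"] = sheet.data["age"].astype(float)
        betas = make_beta(vals, sample_ids=list(sheet.sample_ids))
        fits = dmp.fit_probe_models(betas, X)
        Xm = X.to_numpy()
        for i in range(3):
            b, res, *_ = np.linalg.lstsq(Xm, vals[i], rcond=None)
            resid = vals[i] - Xm @ b
            s2 = resid @ resid / (40 - 3)
            cov = s2 * np.linalg.inv(Xm.T @ Xm)
            assert fits.coef.iloc[i] == pytest.approx(b[1], abs=1e-10)
            assert fits.se.iloc[i] == pytest.approx(np.sqrt(cov[1, 1]),
                                                    abs=1e-10)

    def test_missing_values_fitted_on_complete_rows(self):
        sheet = _sheet(seed=3)
        vals = np.full((1, 40), 0.40)
        vals[0, sheet.case_mask()] = 0.52
        vals[0, 0] = np.nan
        betas = make_beta(vals, sample_ids=list(sheet.sample_ids))
        fits = dmp.fit_probe_models(betas, _group_design(sheet))
        assert fits.coef.iloc[0] == pytest.approx(0.12, abs=1e-12)
        assert fits.df.iloc[0] == 37  # 39 obs - 2 params

    def test_rank_deficient_design_rejected_naming_column(self):
        sheet = _sheet()
        X = _group_design(sheet)
        X["group_copy"] = X["group"]
        betas = make_beta(np.full((2, 40), 0.5),
                          sample_ids=list(sheet.sample_ids))
        with pytest.raises(ValidationError, match="group_copy"):
            dmp.fit_probe_models(betas, X)


class TestModeration:
    def _fits(self, s2, df=36.0):
        n = len(s2)
        return dmp.ProbeModelFit(
            coef=pd.Series(np.ones(n)),
            se=pd.Series(np.sqrt(np.asarray(s2))),
            unscaled_se=pd.Series(np.ones(n)),
            s2=pd.Series(np.asarray(s2, dtype=float)),
            df=pd.Series(np.full(n, df)),
        )

    def test_identical_variances_leave_t_ordinary(self):
        fits = self._fits(np.full(50, 0.04))
        mod = dmp.moderate_variances(fits)
        assert mod.no_shrinkage
        np.testing.assert_allclose(mod.s2_post, 0.04)
        np.testing.assert_allclose(mod.t, 1.0 / np.sqrt(0.04))

    def test_posterior_variance_between_sample_and_prior(self):
        rng = np.random.default_rng(1)
        s2 = 0.02 * rng.chisquare(10, 500) / 10
        mod = dmp.moderate_variances(self._fits(s2))
        lo = np.minimum(s2, mod.s0_2)
        hi = np.maximum(s2, mod.s0_2)
        assert ((mod.s2_post >= lo - 1e-12) & (mod.s2_post <= hi + 1e-12)).all()

    def test_prior_parameters_recovered_from_simulation(self):
        # s2 ~ s0^2 * d0/chi2_d0 * chi2_df/df with d0=4, s0^2=1
        rng = np.random.default_rng(7)
        n, d0, dfree = 10_000, 4.0, 36
        var_g = d0 / rng.chisquare(d0, n)
        s2 = var_g * rng.chisquare(dfree, n) / dfree
        mod = dmp.moderate_variances(self._fits(s2, df=float(dfree)))
        assert 3.0 <= mod.d0 <= 5.0
        assert 0.9 <= mod.s0_2 <= 1.1

    def test_total_df_is_residual_plus_prior(self):
        rng = np.random.default_rng(2)
        s2 = 0.02 * rng.chisquare(10, 300) / 10
        mod = dmp.moderate_variances(self._fits(s2, df=30.0))
        np.testing.assert_allclose(mod.df_total, 30.0 + mod.d0)


class TestEmpiricalNull:
    def test_standard_normal_recovered(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=50_000)
        nf = dmp.empirical_null_adjust(z, seed=1, n_iter=1200, burn_in=400)
        assert abs(nf.bias) < 0.02
        assert abs(nf.inflation - 1.0) < 0.02

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        z = rng.normal(0.0, 1.0, 30_000)
        nf0 = dmp.empirical_null_adjust(z, seed=2, n_iter=800, burn_in=300)
        nf5 = dmp.empirical_null_adjust(z + 5.0, seed=2, n_iter=800,
                                        burn_in=300)
        assert nf5.bias - nf0.bias == pytest.approx(5.0, abs=0.05)

    def test_center_maps_to_zero(self):
        rng = np.random.default_rng(3)
        z = rng.normal(0.3, 1.2, 20_000)
        nf = dmp.empirical_null_adjust(z, seed=3, n_iter=800, burn_in=300)
        centered = (np.array([nf.bias]) - nf.bias) / nf.inflation
        assert centered[0] == 0.0
        # and the adjusted z of values near the bias are near zero
        i = int(np.argmin(np.abs(z - nf.bias)))
        assert abs(nf.z_adjusted.iloc[i] if hasattr(nf.z_adjusted, "iloc")
                   else nf.z_adjusted[i]) < 0.01

    def test_non_finite_z_rejected(self):
        with pytest.raises(ValidationError, match="finite"):
            dmp.empirical_null_adjust(np.array([0.0, np.inf] * 600))


class TestGenomicInflation:
    def test_chi2_median_value_gives_lambda_one(self):
        z = np.full(1000, np.sqrt(dmp.CHI2_1_MEDIAN))
        assert dmp.genomic_inflation(z) == pytest.approx(1.0, abs=1e-12)

    def test_quadratic_scaling(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=10_000)
        lam = dmp.genomic_inflation(z)
        assert dmp.genomic_inflation(2 * z) == pytest.approx(4 * lam, rel=1e-12)

    def test_null_z_gives_lambda_near_one(self):
        rng = np.random.default_rng(2)
        z = rng.normal(size=100_000)
        assert 0.98 <= dmp.genomic_inflation(z) <= 1.02


class TestBHAdjust:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])),
            [0.04, 0.04, 0.04, 0.04],
        )

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_matches_statsmodels_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = rng.random(rng.integers(1, 200))
            expect = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(bh_adjust(p), expect, atol=1e-12)

    def test_monotone_step_up(self):
        rng = np.random.default_rng(6)
        p = rng.random(500)
        q = bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(q[order]) >= -1e-15).all()


class TestCallDmps:
    @pytest.mark.parametrize("q,db,tier", [
        (0.0005, 0.12, "stringent"),
        (0.0005, -0.12, "stringent"),
        (0.04, 0.06, "relaxed"),
        (0.04, 0.04, "none"),
        (0.2, 0.5, "none"),
        (0.0005, 0.08, "relaxed"),  # passes relaxed but not stringent delta
    ])
    def test_tier_assignment(self, q, db, tier):
        out = dmp.call_dmps(pd.Series([q]), pd.Series([db]))
        assert out.iloc[0] == tier


class TestRunDmp:
    def test_injected_dmps_recovered_with_controlled_fdp(self, small_cohort):
        betas, _, sheet, _, truth = small_cohort
        table, diag = dmp.run_dmp(betas, sheet, seed=5, n_iter=800,
                                  burn_in=300)
        hits = set(table.index[table["tier"] != "none"])
        injected = set(truth.dmp_probes)
        for iv in truth.dmr_intervals:
            injected |= set(iv["probes"])
        recall = len(hits & set(truth.dmp_probes)) / len(truth.dmp_probes)
        fdp = len(hits - injected) / max(len(hits), 1)
        assert recall >= 0.95
        assert fdp <= 0.10
        assert 0.8 <= diag["lambda_after"] <= 1.25

    def test_null_cohort_calibrated(self, null_cohort):
        betas, _, sheet, _, _ = null_cohort
        table, diag = dmp.run_dmp(betas, sheet, seed=6, n_iter=800,
                                  burn_in=300)
        assert (table["q"] < 0.05).mean() <= 0.05
        assert (table["tier"] == "none").all()
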