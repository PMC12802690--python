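import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cortexmeth import linear_modelling as lm
from cortexmeth.io_formats import BetaMatrix
from cortexmeth.synthetic_data import simulate_dataset


def _sheet(ages, sex=None, batch=None, donor=None, fraction="bulk"):
    n = len(ages)
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(n)],
            "age_value": ages,
            "age_unit": "pcw",
            "sex": sex if sex is not None else ["M"] * n,
            "batch": batch if batch is not None else ["b1"] * n,
            "donor_id": donor if donor is not None else [f"d{i}" for i in range(n)],
            "fraction": fraction if not isinstance(fraction, str) else [fraction] * n,
            "stage": "prenatal",
        }
    )


class TestFitSiteLinear:
    def test_matches_closed_form_ols_on_five_points(self):
        ages = np.array([6.0, 9.0, 12.0, 17.0, 21.0])
        y = np.array([0.21, 0.25, 0.28, 0.40, 0.45])
        beta = BetaMatrix(["cg1"], [f"s{i}" for i in range(5)], y[None, :])
        res = lm.fit_site_linear(beta, _sheet(ages), covariates=(), min_complete=5)
        X = np.column_stack([np.ones(5), ages])
        XtXi = np.linalg.inv(X.T @ X)
        b = XtXi @ X.T @ y
        resid = y - X @ b
        se = np.sqrt(resid @ resid / 3 * XtXi[1, 1])
        assert res.loc[0, "effect"] == pytest.approx(100 * b[1], abs=1e-10)
        assert res.loc[0, "se"] == pytest.approx(100 * se, abs=1e-10)
        assert res.loc[0, "df"] == 3

    def test_noiseless_line_is_flagged_dmp(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(6, 23, 30)
        y = 0.2 + 0.01 * (ages - 6)
        beta = BetaMatrix(["cg1"], [f"s{i}" for i in range(30)], y[None, :])
        res = lm.fit_site_linear(beta, _sheet(ages), covariates=())
        assert res.loc[0, "effect"] == pytest.approx(1.0, abs=1e-8)
        assert res.loc[0, "dmp"]
        assert res.loc[0, "log10_p"] < -100
        assert res.loc[0, "direction"] == "hyper"

    def test_covariate_adjustment_removes_sex_offset(self):
        rng = np.random.default_rng(2)
        n = 60
        ages = rng.uniform(6, 23, n)
        sex = rng.integers(0, 2, n)
        y = 0.4 + 0.1 * sex + rng.normal(0, 0.01, n)
        beta = BetaMatrix(["cg1"], [f"s{i}" for i in range(n)], y[None, :])
        sheet = _sheet(ages, sex=np.where(sex == 1, "M", "F"))
        res = lm.fit_site_linear(beta, sheet, covariates=("sex",))
        assert abs(res.loc[0, "effect"]) < 0.05
        assert not res.loc[0, "dmp"]

    def test_permuted_age_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(3)
        n_sites, n = 1000, 50
        vals = np.clip(0.5 + 0.05 * rng.standard_normal((n_sites, n)), 0.001, 0.999)
        beta = BetaMatrix([f"cg{i}" for i in range(n_sites)],
                          [f"s{i}" for i in range(n)], vals)
        ages = rng.permutation(np.linspace(6, 23, n))
        res = lm.fit_site_linear(beta, _sheet(ages), covariates=())
        rate = (res["p"] < 0.05).mean()
        assert 0.035 <= rate <= 0.065

    def test_missing_values_complete_case_per_site(self):
        rng = np.random.default_rng(4)
        ages = rng.uniform(6, 23, 30)
        y = 0.2 + 0.01 * (ages - 6)
        y2 = y.copy()
        y2[:5] = np.nan
        beta = BetaMatrix(["cg1", "cg2"], [f"s{i}" for i in range(30)],
                          np.vstack([y, y2]))
        res = lm.fit_site_linear(beta, _sheet(ages), covariates=())
        assert res.loc[0, "n_used"] == 30
        assert res.loc[1, "n_used"] == 25
        assert res.loc[1, "effect"] == pytest.approx(1.0, abs=1e-8)

    def test_rank_deficient_design_names_columns(self):
        ages = np.linspace(6, 23, 20)
        sheet = _sheet(ages, sex=["M"] * 10 + ["F"] * 10,
                       batch=["b1"] * 10 + ["b2"] * 10)  # batch == sex
        beta = BetaMatrix(["cg1"], [f"s{i}" for i in range(20)],
                          np.full((1, 20), 0.5))
        with pytest.raises(ValueError, match="collinear"):
            lm.fit_site_linear(beta, sheet)


class TestDirectionBinomial:
    def test_exact_tail_for_ten_trials(self):
        res = lm.direction_binomial(10, 5, 0.5)
        assert res["p_one_tailed"] == pytest.approx(638 / 1024, rel=1e-12)

    def test_all_successes_closed_form(self):
        res = lm.direction_binomial(12, 12, 0.3)
        assert res["p_one_tailed"] == pytest.approx(0.3**12, rel=1e-10)

    @pytest.mark.parametrize("n,k,p0", [(20, 13, 0.5), (15, 4, 0.25), (18, 18, 0.6)])
    def test_agrees_with_exact_enumeration(self, n, k, p0):
        oracle = sum(
            stats.binom.pmf(i, n, p0) for i in range(k, n + 1)
        )
        assert lm.direction_binomial(n, k, p0)["p_one_tailed"] == pytest.approx(
            oracle, rel=1e-10
        )

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            lm.direction_binomial(10, 11, 0.5)


class TestEffectMagnitude:
    def test_identical_groups_give_zero_t(self):
        g = np.array([1.0, 1.2, 0.8, 1.1])
        res = lm.compare_effect_magnitude(g, g)
        assert res["t_abs"] == pytest.approx(0.0, abs=1e-12)

    def test_planted_difference_matches_welch_oracle(self, rng):
        a = rng.normal(1.0, 0.1, 500)
        b = rng.normal(1.5, 0.1, 500)
        res = lm.compare_effect_magnitude(a, -b)  # hypo effects carried signed
        # Welch formula computed directly
        va, vb = a.var(ddof=1) / 500, b.var(ddof=1) / 500
        t = (np.abs(a).mean() - np.abs(b).mean()) / np.sqrt(va + vb)
        assert res["t_abs"] == pytest.approx(t, rel=1e-6)
        assert res["p_abs"] < 1e-100

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            lm.compare_effect_magnitude([], [1.0])


class TestGlobalTrend:
    def test_constant_sites_no_trend(self):
        ages = np.linspace(6, 23, 30)
        beta = BetaMatrix(["cg1", "cg2"], [f"s{i}" for i in range(30)],
                          np.full((2, 30), 0.5))
        res = lm.global_trend(beta, _sheet(ages), covariates=())
        assert res["effect"] == pytest.approx(0.0, abs=1e-10)

    def test_symmetric_slopes_cancel(self):
        ages = np.linspace(6, 23, 30)
        up = 0.3 + 0.005 * (ages - 6)
        down = 0.7 - 0.005 * (ages - 6)
        beta = BetaMatrix(["cg1", "cg2"], [f"s{i}" for i in range(30)],
                          np.vstack([up, down]))
        res = lm.global_trend(beta, _sheet(ages), covariates=())
        assert res["effect"] == pytest.approx(0.0, abs=1e-10)

    def test_planted_global_drift_recovered(self):
        rng = np.random.default_rng(5)
        n_sites, n = 200, 60
        ages = rng.uniform(6, 23, n)
        drift = -0.0002  # proportion/week == -0.02 pp/week
        vals = np.clip(
            rng.uniform(0.3, 0.7, (n_sites, 1)) + drift * (ages - 6)
            + rng.normal(0, 0.02, (n_sites, n)),
            0.001, 0.999,
        )
        beta = BetaMatrix([f"cg{i}" for i in range(n_sites)],
                          [f"s{i}" for i in range(n)], vals)
        res = lm.global_trend(beta, _sheet(ages), covariates=())
        assert res["effect"] == pytest.approx(-0.02, abs=2 * res["se"] + 1e-3)


class TestInteraction:
    def _two_fraction_data(self, slope_pos, slope_neg, seed=6, n=40):
        rng = np.random.default_rng(seed)
        ages = np.tile(rng.uniform(8, 20, n // 2), 2)
        frac = ["SATB2+"] * (n // 2) + ["SATB2-"] * (n // 2)
        y = np.where(
            np.array(frac) == "SATB2+",
            0.6 + slope_pos / 100 * (ages - 8),
            0.6 + slope_neg / 100 * (ages - 8),
        ) + rng.normal(0, 0.01, n)
        beta = BetaMatrix(["cg1"], [f"s{i}" for i in range(n)],
                          np.clip(y, 0.001, 0.999)[None, :])
        sheet = _sheet(ages, fraction=frac)
        return beta, sheet

    def test_planted_interaction_recovered(self):
        beta, sheet = self._two_fraction_data(-4.0, 0.0)
        res = lm.fit_interaction(beta, sheet, covariates=())
        assert res.loc[0, "significant"]
        assert res.loc[0, "effect[SATB2+]"] == pytest.approx(-4.0, abs=0.3)
        assert res.loc[0, "effect[SATB2-]"] == pytest.approx(0.0, abs=0.3)

    def test_equal_slopes_no_interaction(self):
        beta, sheet = self._two_fraction_data(1.0, 1.0)
        res = lm.fit_interaction(beta, sheet, covariates=())
        assert abs(res.loc[0, "interaction_effect"]) < 0.5
        assert not res.loc[0, "significant"]

    def test_small_fraction_rejected(self):
        beta, sheet = self._two_fraction_data(1.0, 1.0)
        sheet = sheet.copy()
        sheet.loc[sheet["fraction"] == "SATB2-", "fraction"] = "SATB2+"
        sheet.loc[0, "fraction"] = "SATB2-"
        with pytest.raises(ValueError, match="< 3 samples"):
            lm.fit_interaction(beta, sheet, covariates=())


class TestMixedModel:
    def _paired_data(self, cell_effect, donor_sd, n_donors=20, seed=7, n_sites=1):
        rng = np.random.default_rng(seed)
        ages = np.repeat(rng.uniform(8, 20, n_donors), 2)
        donors = np.repeat([f"d{i}" for i in range(n_donors)], 2)
        frac = ["SATB2+", "SATB2-"] * n_donors
        donor_off = np.repeat(rng.normal(0, donor_sd, n_donors), 2)
        vals = []
        for _ in range(n_sites):
            y = (0.5 + donor_off + cell_effect * (np.array(frac) == "SATB2+")
                 + rng.normal(0, 0.02, 2 * n_donors))
            vals.append(np.clip(y, 0.001, 0.999))
        beta = BetaMatrix([f"cg{i}" for i in range(n_sites)],
                          [f"s{i}" for i in range(2 * n_donors)], np.array(vals))
        sheet = _sheet(ages, donor=donors, fraction=list(frac))
        return beta, sheet

    def test_zero_donor_variance_matches_ols(self):
        beta, sheet = self._paired_data(cell_effect=0.05, donor_sd=0.0)
        mixed = lm.fit_site_mixed(beta, sheet, covariates=())
        import statsmodels.api as sm

        sheet_o = sheet.set_index("sample_id").loc[beta.sample_ids].reset_index()
        X = pd.DataFrame(
            {
                "const": 1.0,
                "age": sheet_o["age_value"],
                "cell": (sheet_o["fraction"] == "SATB2-").astype(float),
            }
        )
        ols = sm.OLS(beta.values[0], X).fit()
        assert mixed.loc[0, "effect"] == pytest.approx(100 * ols.params["cell"], abs=1e-4)

    def test_mixed_more_powerful_than_ols_with_donor_offsets(self):
        beta, sheet = self._paired_data(cell_effect=0.02, donor_sd=0.08)
        mixed = lm.fit_site_mixed(beta, sheet, covariates=())
        assert not mixed.loc[0, "fallback_ols"]
        import statsmodels.api as sm

        sheet_o = sheet.set_index("sample_id").loc[beta.sample_ids].reset_index()
        X = pd.DataFrame(
            {
                "const": 1.0,
                "age": sheet_o["age_value"],
                "cell": (sheet_o["fraction"] == "SATB2-").astype(float),
            }
        )
        ols = sm.OLS(beta.values[0], X).fit()
        assert mixed.loc[0, "p"] < ols.pvalues["cell"]

    def test_null_lrt_p_approximately_uniform(self):
        beta, sheet = self._paired_data(cell_effect=0.0, donor_sd=0.05,
                                        n_donors=15, n_sites=120)
        mixed = lm.fit_site_mixed(beta, sheet, covariates=())
        ks = stats.kstest(mixed["p"], "uniform")
        assert ks.pvalue > 0.01


class TestCrossStage:
    def _results(self, effects, ps):
        return pd.DataFrame(
            {"site_id": [f"cg{i}" for i in range(len(effects))],
             "effect": effects, "p": ps}
        )

    def test_identical_tables_fully_consistent(self):
        pre = self._results([1.0, -2.0, 0.5], [1e-10, 1e-10, 1e-10])
        res = lm.crossstage_compare(pre, pre, alpha_post=1e-6)
        assert res["correlation"] == pytest.approx(1.0)
        assert (res["table"]["class"] == "consistent").all()

    def test_negated_tables_fully_opposite(self):
        pre = self._results([1.0, -2.0, 0.5], [1e-10, 1e-10, 1e-10])
        post = pre.copy()
        post["effect"] = -post["effect"]
        res = lm.crossstage_compare(pre, post, alpha_post=1e-6)
        assert res["correlation"] == pytest.approx(-1.0)
        assert (res["table"]["class"] == "opposite").all()

    def test_nonsignificant_sites_are_postnatal_null(self):
        pre = self._results([1.0, -2.0], [1e-10, 1e-10])
        post = self._results([1.0, -2.0], [0.5, 1e-10])
        res = lm.crossstage_compare(pre, post, alpha_post=1e-6)
        assert list(res["table"]["class"]) == ["postnatal-null", "consistent"]


class TestVarianceCompare:
    def test_identical_groups_zero_difference(self, rng):
        vals = np.clip(0.5 + 0.1 * rng.standard_normal((20, 30)), 0.001, 0.999)
        a = BetaMatrix([f"cg{i}" for i in range(20)], [f"s{i}" for i in range(30)], vals)
        b = BetaMatrix([f"cg{i}" for i in range(20)], [f"t{i}" for i in range(30)], vals)
        res = lm.variance_compare(a, b)
        assert res["mean_variance_a"] == pytest.approx(res["mean_variance_b"])
        assert res["t"] == pytest.approx(0.0, abs=1e-10)

    def test_planted_variance_ratio_recovered(self, rng):
        # fetal-like SD 11% vs adult-like SD ~6.46% on the percent scale
        n_sites = 300
        a_vals = np.clip(0.5 + 0.11 * rng.standard_normal((n_sites, 60)), 0.001, 0.999)
        b_vals = np.clip(0.5 + 0.0646 * rng.standard_normal((n_sites, 60)), 0.001, 0.999)
        ids = [f"cg{i}" for i in range(n_sites)]
        a = BetaMatrix(ids, [f"s{i}" for i in range(60)], a_vals)
        b = BetaMatrix(ids, [f"t{i}" for i in range(60)], b_vals)
        res = lm.variance_compare(a, b)
        assert res["mean_variance_a"] == pytest.approx(121.0, rel=0.05)
        assert res["mean_variance_b"] == pytest.approx(41.7, rel=0.05)
        assert res["p"] < 1e-50

    def test_single_sample_group_rejected(self):
        a = BetaMatrix(["cg1"], ["s1"], np.array([[0.5]]))
        b = BetaMatrix(["cg1"], ["t1", "t2"], np.array([[0.5, 0.6]]))
        with pytest.raises(ValueError, match=">= 2 samples"):
            lm.variance_compare(a, b)


class TestPercentArithmetic:
    @pytest.mark.parametrize(
        "k,n,expect",
        [
            (50913, 807806, 6.30),
            (50329, 50913, 98.9),
            (1003, 41518, 2.42),
            (275, 1003, 27.4),
            (1277, 807806, 0.158),
        ],
    )
    def test_three_significant_figure_rounding(self, k, n, expect):
        assert lm.percent(k, n) == expect

    def test_slope_recovery_bias_small(self):
        beta, sheet, truth = simulate_dataset(
            n_sites=100, n_samples=90, class_mix=(0.0, 1.0, 0.0),
            effect_grid=(1.0,), noise_sd=0.05, seed=12,
        )
        res = lm.fit_site_linear(beta, sheet)
        bias = (res["effect"].to_numpy() - truth["true_slope"].to_numpy()).mean()
        assert abs(bias) < 0.05
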