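"""Association layer: transforms, model fits, Box-Cox, residuals, permutation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from casam.stats import (
    boxcox,
    feature_residuals,
    fit_case_control_model,
    fit_genetic_model,
    permutation_global_test,
    qq_summary,
    read_cohort_table,
    summarize_cohort,
    transform_density,
)
from casam.synthetic import CohortConfig, generate_case_control_cohort, generate_cohort


class TestTransforms:
    def test_known_values(self):
        assert transform_density([25.0], "sqrt_area")[0] == pytest.approx(5.0)
        assert transform_density([np.e**2], "log_vol")[0] == pytest.approx(2.0)
        np.testing.assert_array_equal(transform_density([1.5, 2.5], "identity"),
                                      [1.5, 2.5])

    def test_nonpositive_log_reports_rows(self):
        with pytest.raises(ValueError, match="rows"):
            transform_density([1.0, 0.0, 2.0], "log_vol")


class TestCohortReader:
    def test_column_mapping_and_value_recode(self, tmp_path):
        df = generate_cohort(CohortConfig(n=50), seed=1)
        renamed = df.rename(columns={"genotype": "rs_geno", "status": "cc"})
        renamed["cc"] = (renamed["cc"] == "case").astype(int)
        path = tmp_path / "t.csv"
        renamed.to_csv(path, index=False)
        back = read_cohort_table(path, {
            "genotype": "rs_geno", "status": "cc",
            "values": {"status": {"1": "case", "0": "control"}},
        })
        np.testing.assert_array_equal(back["genotype"], df["genotype"])
        assert set(back["status"]) <= {"case", "control"}

    def test_bad_genotype_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"genotype": [0, 1, 3]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="genotype"):
            read_cohort_table(path)

    def test_summary_reproduces_table_exactly(self):
        tab = pd.DataFrame({
            "age": [50.0, 60.0], "bmi": [25.0, 27.0],
            "menopausal": ["pre", "post"], "status": ["control", "control"],
        })
        s = summarize_cohort(tab)
        age = s[(s.variable == "age")].iloc[0]
        assert age["mean"] == 55.0 and age["sd"] == pytest.approx(np.sqrt(50.0))
        meno = s[(s.variable == "menopausal") & (s.level == "pre")].iloc[0]
        assert meno["n"] == 1 and meno["percent"] == 50.0


class TestGeneticModel:
    def test_recovers_planted_effect_within_ci(self):
        tab = generate_cohort(CohortConfig(n=20_000), seed=2)
        r = fit_genetic_model(tab, "volpara_log")
        assert r.ci_low <= -0.138 <= r.ci_high
        assert r.p_wald < 1e-6
        assert r.n_used <= 20_000

    def test_constant_genotype_is_error(self):
        tab = generate_cohort(CohortConfig(n=200), seed=3)
        tab["genotype"] = 0
        with pytest.raises(ValueError, match="constant"):
            fit_genetic_model(tab, "volpara_log")

    def test_estimate_equivariant_under_outcome_rescaling(self):
        tab = generate_cohort(CohortConfig(n=2000), seed=4)
        r1 = fit_genetic_model(tab, "volpara_log")
        tab2 = tab.copy()
        tab2["volpara_log"] = 3.0 * tab2["volpara_log"]
        r2 = fit_genetic_model(tab2, "volpara_log")
        assert r2.estimate == pytest.approx(3.0 * r1.estimate, rel=1e-9)
        assert r2.ci_low == pytest.approx(3.0 * r1.ci_low, rel=1e-9)

    def test_missing_category_rows_dropped_and_reported(self):
        tab = generate_cohort(CohortConfig(n=2000), seed=5)
        r = fit_genetic_model(tab, "volpara_log")
        n_complete = ((tab.menopausal != "missing") & (tab.hrt != "missing")
                      & (tab.parity_afb != "missing")).sum()
        assert r.n_used == n_complete
        r2 = fit_genetic_model(tab, "volpara_log", include_missing_category=True)
        assert r2.n_used == 2000

    def test_extra_density_adjustment_attenuates(self):
        tab = generate_cohort(CohortConfig(n=20_000), seed=6)
        base = fit_genetic_model(tab, "casam_vol")
        adj = fit_genetic_model(tab, "casam_vol", extra_adjust="volpara_log")
        assert abs(adj.estimate) < abs(base.estimate)


class TestCaseControlModel:
    def test_all_control_table_is_error(self):
        tab = generate_cohort(CohortConfig(n=500), seed=7)
        tab["status"] = "control"
        with pytest.raises(ValueError, match="cases"):
            fit_case_control_model(tab, "volpara_log")

    def test_log_odds_recovered_at_scale(self):
        cc = generate_case_control_cohort(n_cases=400, n_controls=4000, seed=8)
        r = fit_case_control_model(cc, "volpara_log", "partial")
        assert r.ci_low <= 0.978 <= r.ci_high
        assert r.p_wald < 0.01

    def test_separation_is_detected(self):
        n = 200
        rng = np.random.default_rng(0)
        tab = generate_cohort(CohortConfig(n=n), seed=9)
        tab["status"] = np.where(tab["volpara_log"] > tab["volpara_log"].median(),
                                 "case", "control")
        with pytest.raises(ValueError, match="separation|fit failed"):
            fit_case_control_model(tab, "volpara_log", "partial")


class TestBoxCox:
    def test_lognormal_recovers_lambda_zero(self, rng):
        v = np.exp(rng.normal(0, 0.6, 5000))
        _, lam = boxcox(v)
        assert abs(lam) <= 0.1

    def test_normal_recovers_lambda_one(self, rng):
        # a coefficient of variation large enough to identify lambda
        v = rng.normal(10.0, 2.5, 5000)
        v = v[v > 0.5]
        _, lam = boxcox(v)
        assert abs(lam - 1.0) <= 0.2

    def test_constant_vector_is_error(self):
        with pytest.raises(ValueError, match="constant"):
            boxcox(np.full(100, 3.0))

    def test_nonpositive_values_shifted(self, rng):
        v = rng.normal(0, 1, 500)  # mixed sign
        t, lam = boxcox(v)
        assert np.isfinite(t).all()


class TestFeatureResiduals:
    def _table(self, rng, n=2000):
        return pd.DataFrame({
            "volpara_log": rng.normal(2, 0.5, n),
            "age": rng.normal(54, 9, n),
            "bmi": rng.normal(26, 4, n),
        })

    def test_exact_linear_feature_has_zero_residuals(self, rng):
        tab = self._table(rng)
        f = pd.DataFrame({"f": 2.0 + 3.0 * tab.volpara_log - 0.5 * tab.age})
        res = feature_residuals(f, tab)
        assert np.abs(res["f"]).max() < 1e-8

    def test_independent_feature_keeps_its_variance(self, rng):
        tab = self._table(rng, n=5000)
        f = pd.DataFrame({"f": rng.normal(size=5000)})
        res = feature_residuals(f, tab)
        ratio = res["f"].var() / f["f"].var()
        assert 0.95 <= ratio <= 1.05

    def test_residuals_orthogonal_to_adjusters(self, rng):
        tab = self._table(rng, n=500)
        f = pd.DataFrame({"f": rng.normal(size=500) + 0.4 * tab.bmi})
        res = feature_residuals(f, tab)["f"].to_numpy()
        for a in ("volpara_log", "age", "bmi"):
            z = tab[a].to_numpy()
            assert abs(res @ z) < 1e-6 * np.linalg.norm(res) * np.linalg.norm(z)


class TestPermutationTest:
    def test_extreme_observed_statistic_gives_minimal_p(self, rng):
        n, m = 300, 40
        g = rng.binomial(2, 0.3, n).astype(float)
        # every feature driven by genotype, with independent noise so the
        # permuted statistics stay near their binomial null level
        Y = np.outer(g, np.ones(m)) + 1.0 * rng.normal(size=(n, m))
        out = permutation_global_test(Y, g, n_perm=500, seed=1)
        assert out["observed_statistic"] == m
        assert out["p_global"] == pytest.approx(1.0 / 501.0)

    def test_small_n_perm_warns(self, rng):
        g = rng.binomial(2, 0.3, 100).astype(float)
        Y = rng.normal(size=(100, 5))
        with pytest.warns(UserWarning, match="n_perm"):
            permutation_global_test(Y, g, n_perm=50, seed=2)

    def test_seed_reproducible(self, rng):
        g = rng.binomial(2, 0.3, 200).astype(float)
        Y = rng.normal(size=(200, 20))
        a = permutation_global_test(Y, g, n_perm=300, seed=9)
        b = permutation_global_test(Y, g, n_perm=300, seed=9)
        assert a["p_global"] == b["p_global"]
        np.testing.assert_array_equal(a["perm_statistics"], b["perm_statistics"])


class TestQQ:
    def test_uniform_grid_on_diagonal(self):
        m = 200
        p = (np.arange(1, m + 1) - 0.5) / m
        qq = qq_summary(p)
        np.testing.assert_allclose(qq.observed, qq.expected, atol=1e-12)

    def test_all_ones_observed_zero(self):
        qq = qq_summary(np.ones(10))
        np.testing.assert_allclose(qq.observed, 0.0)

    def test_null_pvalues_close_to_diagonal(self, rng):
        # DKW bound at alpha=0.01 for the empirical CDF deviation
        m = 2000
        p = rng.uniform(size=m)
        qq = qq_summary(p)
        eps = np.sqrt(np.log(2 / 0.01) / (2 * m))
        # translate the CDF bound to the p-value scale away from the tail
        body = qq.expected < 2  # p > 0.01
        obs_p = 10 ** (-qq.observed[body])
        exp_p = 10 ** (-qq.expected[body])
        assert np.max(np.abs(obs_p - exp_p)) <= eps + 1e-12

    def test_empty_and_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qq_summary([])
        with pytest.raises(ValueError):
            qq_summary([0.0, 0.5])
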