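import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from legmuscle.association_stats import (association_tables, emmeans_by_sex,
                                         fit_standardized_lm, force_tables,
                                         hierarchical_lm, partial_pearson,
                                         residual_diagnostics)
from legmuscle.phantom import CohortSpec, simulate_cohort


def normal_equations_oracle(y, X):
    """Standardized OLS betas via explicit matrix inversion."""
    yz = (y - y.mean()) / y.std(ddof=1)
    Xz = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    Xd = np.column_stack([np.ones(len(y)), Xz])
    return np.linalg.inv(Xd.T @ Xd) @ Xd.T @ yz


FIXED_8ROW = pd.DataFrame({
    "age": [25.0, 31, 44, 52, 29, 38, 47, 60],
    "bmi": [21.0, 24, 27, 30, 22, 26, 23, 29],
    "sex": ["female", "male", "female", "male"] * 2,
})
FIXED_8ROW_Y = np.array([310.0, 420, 355, 470, 300, 405, 330, 455])


class TestStandardizedLM:
    def test_perfect_single_predictor(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(size=30)
        X = pd.DataFrame({"x1": x1, "x2": rng.normal(size=30)})
        fit = fit_standardized_lm(x1.copy(), X)
        assert fit.beta[0] == pytest.approx(1.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        Xn = FIXED_8ROW.copy()
        Xn["sex"] = Xn["sex"].map({"female": 0.0, "male": 1.0})
        expected = normal_equations_oracle(FIXED_8ROW_Y, Xn.to_numpy(float))
        fit = fit_standardized_lm(FIXED_8ROW_Y, FIXED_8ROW)
        np.testing.assert_allclose(fit.beta, expected[1:], atol=1e-10)

    def test_single_predictor_beta_is_pearson_r(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=50)
        y = 0.6 * x + rng.normal(size=50)
        fit = fit_standardized_lm(y, pd.DataFrame({"x": x}))
        r = np.corrcoef(x, y)[0, 1]
        assert fit.beta[0] == pytest.approx(r, abs=1e-10)

    def test_r2_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.normal(size=40), "b": rng.normal(size=40)})
        y = X.a + 0.5 * X.b + rng.normal(size=40)
        f1 = fit_standardized_lm(y, X)
        X2 = pd.DataFrame({"a": 100 * X.a - 7, "b": 0.01 * X.b + 3})
        f2 = fit_standardized_lm(y, X2)
        assert f1.r2 == pytest.approx(f2.r2, rel=1e-10)

    def test_constant_predictor_named_in_error(self):
        X = pd.DataFrame({"good": np.arange(10.0), "flat": np.ones(10)})
        with pytest.raises(ValueError, match="flat"):
            fit_standardized_lm(np.arange(10.0), X)

    def test_recovers_generating_effects(self):
        """Cohort simulated with known standardized effects: the fitted
        betas land near the truth."""
        cspec = CohortSpec(n=200, vol_age=0.4, vol_bmi=0.6, vol_sex=0.0, seed=3)
        cohort, truth, _ = simulate_cohort(cspec)
        sub = truth[(truth.muscle == "soleus") & (truth.side == "left")]
        df = sub.merge(cohort, on="participant_id")
        fit = fit_standardized_lm(df.volume_ml, df[["age", "bmi", "sex"]])
        got = dict(zip(fit.predictors, fit.beta))
        assert got["age"] == pytest.approx(0.4, abs=0.12)
        assert got["bmi"] == pytest.approx(0.6, abs=0.12)
        assert got["sex"] == pytest.approx(0.0, abs=0.15)

    def test_summary_table_shape(self):
        fit = fit_standardized_lm(FIXED_8ROW_Y, FIXED_8ROW)
        tab = fit.summary()
        assert list(tab.columns) == ["beta", "se", "t", "p"]
        assert list(tab.index) == ["age", "bmi", "sex"]


class TestPartialPearson:
    def test_reduces_to_plain_pearson_without_controls(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=30), rng.normal(size=30)
        r, p = partial_pearson(y, x)
        r_exp, p_exp = sps.pearsonr(
            x - x.mean(), y - y.mean())
        assert r == pytest.approx(r_exp, abs=1e-10)
        assert p == pytest.approx(p_exp, abs=1e-8)

    def test_fully_explained_outcome(self):
        rng = np.random.default_rng(7)
        Z = pd.DataFrame({"z1": rng.normal(size=60), "z2": rng.normal(size=60)})
        y = 2 * Z.z1 - Z.z2
        x = rng.normal(size=60)
        r, p = partial_pearson(y, x, Z)
        assert abs(r) < 1e-8

    def test_matches_precision_matrix_oracle(self):
        rng = np.random.default_rng(8)
        n = 10
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("yxab"))
        r, _ = partial_pearson(df.y, df.x, df[["a", "b"]])
        # oracle: partial correlation from the inverse correlation matrix
        P = np.linalg.inv(np.corrcoef(df.to_numpy().T))
        expected = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
        assert r == pytest.approx(expected, abs=1e-10)


class TestEMMeans:
    def test_null_sex_effect(self):
        cspec = CohortSpec(n=400, vol_sex=0.0, seed=9)
        cohort, truth, _ = simulate_cohort(cspec)
        sub = truth[(truth.muscle == "soleus") & (truth.side == "left")]
        df = sub.merge(cohort, on="participant_id")
        mm = emmeans_by_sex(df.volume_ml, df[["age", "bmi", "sex"]])
        se = np.hypot(mm.se_female, mm.se_male)
        assert abs(mm.emm_female - mm.emm_male) < 2 * se

    def test_orthogonal_design_equals_raw_means(self):
        # balanced sexes with identical age/bmi in both groups
        age = np.tile([30.0, 40, 50, 60], 2)
        bmi = np.tile([22.0, 24, 26, 28], 2)
        sex = ["female"] * 4 + ["male"] * 4
        y = np.r_[np.array([5.0, 6, 7, 8]), np.array([7.0, 8, 9, 10])]
        mm = emmeans_by_sex(y, pd.DataFrame({"age": age, "bmi": bmi, "sex": sex}))
        assert mm.emm_female == pytest.approx(6.5, abs=1e-8)
        assert mm.emm_male == pytest.approx(8.5, abs=1e-8)

    def test_matches_hand_prediction(self):
        import statsmodels.api as sm
        X = FIXED_8ROW.copy()
        X["sex"] = X["sex"].map({"female": 0.0, "male": 1.0})
        Xd = sm.add_constant(X[["age", "bmi", "sex"]].to_numpy())
        res = sm.OLS(FIXED_8ROW_Y, Xd).fit()
        b = res.params
        mm = emmeans_by_sex(FIXED_8ROW_Y, FIXED_8ROW)
        hand_f = b[0] + b[1] * X.age.mean() + b[2] * X.bmi.mean()
        assert mm.emm_female == pytest.approx(hand_f, abs=1e-8)
        assert mm.emm_male == pytest.approx(hand_f + b[3], abs=1e-8)

    def test_single_sex_rejected(self):
        X = pd.DataFrame({"age": np.arange(10.0) + 20, "bmi": np.arange(10.0) + 20,
                          "sex": ["female"] * 10})
        with pytest.raises(ValueError, match="both sexes"):
            emmeans_by_sex(np.arange(10.0), X)


class TestHierarchical:
    @staticmethod
    def _data(seed, effect=0.0, n=77):
        rng = np.random.default_rng(seed)
        base = pd.DataFrame({
            "age": rng.normal(34, 11, n), "bmi": rng.normal(25, 4.5, n),
            "sex": rng.choice(["female", "male"], size=n)})
        sexn = (base.sex == "male").astype(float)
        add = rng.normal(size=n)
        y = 0.3 * sexn + effect * add + rng.normal(size=n)
        return y, base, add

    def test_f_change_equals_t_squared(self):
        y, base, add = self._data(0, effect=0.4)
        hf = hierarchical_lm(y, base, add, addition_name="vol")
        i = hf.full.predictors.index("vol")
        assert hf.f_change == pytest.approx(hf.full.tvalues[i] ** 2, rel=1e-8)
        assert hf.p_change == pytest.approx(hf.full.pvalues[i], rel=1e-8)

    def test_delta_r2_nonnegative_and_consistent(self):
        y, base, add = self._data(1, effect=0.3)
        hf = hierarchical_lm(y, base, add)
        assert hf.delta_r2 >= 0
        assert hf.delta_r2 == pytest.approx(hf.full.r2 - hf.base.r2, abs=1e-12)

    def test_null_addition_p_uniform(self):
        """Under a null added predictor the F-change p-values are uniform
        (KS test over many replicates)."""
        ps = []
        for seed in range(300):
            y, base, add = self._data(seed, effect=0.0, n=50)
            ps.append(hierarchical_lm(y, base, add).p_change)
        ks = sps.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_recovers_soleus_delta_r2(self):
        """Cohort generated with a soleus-volume force effect whose unique
        contribution is about 6% of force variance at n=77."""
        deltas = []
        for seed in range(20):
            cspec = CohortSpec(n=77, seed=seed)
            cohort, truth, _ = simulate_cohort(cspec)
            sub = truth[(truth.muscle == "soleus") & (truth.side == "left")]
            df = sub.merge(cohort, on="participant_id")
            hf = hierarchical_lm(df.pf_left, df[["age", "bmi", "sex"]],
                                 df.volume_ml, addition_name="soleus_volume")
            deltas.append(hf.delta_r2)
        deltas = np.asarray(deltas)
        assert ((deltas >= 0.0) & (deltas <= 0.15)).all()
        assert abs(np.median(deltas) - 0.060) < 0.03


class TestResidualDiagnostics:
    def test_normal_residuals_pass(self):
        count = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=200)
            y = x + rng.normal(size=200)
            fit = fit_standardized_lm(y, pd.DataFrame({"x": x}))
            if residual_diagnostics(fit).shapiro_p > 0.05:
                count += 1
        assert count >= 0.9 * 60 * 0.9  # >= 90% less slack for 60 draws

    def test_exponential_residuals_fail(self):
        count = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=200)
            y = x + rng.exponential(size=200)
            fit = fit_standardized_lm(y, pd.DataFrame({"x": x}))
            if residual_diagnostics(fit).shapiro_p < 0.05:
                count += 1
        assert count >= 27  # >= 90% of replicates

    def test_heteroscedasticity_detected(self):
        rng = np.random.default_rng(1)
        x = np.sort(rng.normal(size=300))
        y = x + rng.normal(size=300) * (0.2 + 2.0 * (x - x.min()))
        fit = fit_standardized_lm(y, pd.DataFrame({"x": x}))
        assert residual_diagnostics(fit).scale_location_r > 0.2

    def test_constant_residuals_rejected(self):
        fit = fit_standardized_lm(np.arange(10.0),
                                  pd.DataFrame({"x": np.arange(10.0)}))
        with pytest.raises(ValueError, match="constant|degenerate"):
            residual_diagnostics(fit)


class TestTables:
    def test_association_and_force_tables_shapes(self):
        cspec = CohortSpec(n=60, seed=12)
        cohort, truth, _ = simulate_cohort(cspec)
        tab = association_tables(truth, cohort, measure_col="volume_ml")
        assert len(tab) == 10  # 5 muscles x 2 sides
        assert {"beta_age", "beta_bmi", "beta_sex", "r2"} <= set(tab.columns)
        ftab = force_tables(truth, cohort, measure_col="volume_ml")
        assert len(ftab) == 10
        assert (ftab.delta_r2 >= 0).all()
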