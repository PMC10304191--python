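"""OLS risk model: fitting, inference, influence decomposition, prediction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ocprisk import cohort as cohort_mod
from ocprisk.regression import (
    CRITICAL_T_GENETIC,
    CRITICAL_T_HEALTH,
    GENETIC_WEIGHTS,
    HEALTH_WEIGHTS,
    PREDICTOR_NAMES,
    RegressionFit,
    adjusted_r2,
    build_design,
    coefficient_significance,
    fit_ols,
    influence_shares,
    predict_risk,
    predict_risk_frame,
    predictive_ability,
)


def normal_equations_oracle(X: np.ndarray, y: np.ndarray):
    """Independent OLS recomputation straight from the normal equations."""
    design = np.column_stack([np.ones(len(y)), X])
    xtx = design.T @ design
    beta = np.linalg.solve(xtx, design.T @ y)
    resid = y - design @ beta
    dof = len(y) - design.shape[1]
    sigma2 = resid @ resid / dof
    se = np.sqrt(np.diag(np.linalg.inv(xtx)) * sigma2)
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - (resid @ resid) / tss
    return beta, se, r2


def random_design(rng: np.random.Generator, n=151, m=9) -> pd.DataFrame:
    X = rng.normal(size=(n, m)) @ rng.normal(size=(m, m)) * 0.3 + rng.normal(size=(n, m))
    return pd.DataFrame(X, columns=list(PREDICTOR_NAMES)[:m])


class TestFitOLS:
    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(10):
            X = random_design(rng)
            y = rng.normal(size=len(X))
            fit = fit_ols(X, y)
            beta, se, r2 = normal_equations_oracle(X.to_numpy(), y)
            np.testing.assert_allclose(fit.coef, beta, rtol=1e-8)
            np.testing.assert_allclose(fit.se, se, rtol=1e-8)
            np.testing.assert_allclose(fit.t, beta / se, rtol=1e-8)
            assert fit.r2 == pytest.approx(r2, rel=1e-8)
            assert fit.r2_adj == pytest.approx(
                1 - (1 - r2) * (fit.n - 1) / (fit.n - fit.m - 1), rel=1e-8
            )

    def test_noiseless_recovery_is_exact(self, rng):
        X = random_design(rng)
        truth = np.arange(1.0, 11.0)
        y = truth[0] + X.to_numpy() @ truth[1:]
        fit = fit_ols(X, y)
        np.testing.assert_allclose(fit.coef, truth, rtol=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_adjusted_r2_closed_form(self):
        assert round(adjusted_r2(0.3, n=151, m=9), 4) == 0.2553

    def test_adjusted_never_exceeds_r2(self, rng):
        X = random_design(rng, n=40, m=5)
        y = rng.normal(size=40)
        fit = fit_ols(X, y)
        assert fit.r2_adj <= fit.r2

    def test_univariate_closed_form(self):
        """5-point simple regression equals the textbook slope/intercept."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 4.1, 5.9, 8.2, 9.8])
        slope = ((x - x.mean()) * (y - y.mean())).sum() / ((x - x.mean()) ** 2).sum()
        intercept = y.mean() - slope * x.mean()
        fit = fit_ols(pd.DataFrame({"x": x}), y)
        assert fit.coef[0] == pytest.approx(intercept, rel=1e-12)
        assert fit.coef[1] == pytest.approx(slope, rel=1e-12)

    def test_rank_deficiency_names_columns(self, rng):
        X = random_design(rng, n=30, m=3)
        X["dup"] = X.iloc[:, 0] * 2.0
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols(X, rng.normal(size=30))

    def test_too_few_observations(self, rng):
        X = random_design(rng, n=5, m=9)
        with pytest.raises(ValueError, match="n > m\\+1"):
            fit_ols(X, rng.normal(size=5))


class TestSignificance:
    def test_printed_comparisons(self):
        fit = RegressionFit(
            names=("a", "b"), coef=np.array([1.0, 1.0]), se=np.array([1.0, 1.0]),
            t=np.array([2.562, 1.905]), r2=0.2, r2_adj=0.15, n=151, m=9,
            fitted=np.zeros(1), resid=np.zeros(1),
        )
        flags_health = coefficient_significance(fit, CRITICAL_T_HEALTH)
        assert bool(flags_health["a"]) is True  # 2.562 > 2.263
        flags_genetic = coefficient_significance(fit, CRITICAL_T_GENETIC)
        assert bool(flags_genetic["b"]) is False  # 1.905 < 2.693

    def test_zero_t_never_significant(self):
        fit = RegressionFit(
            names=("a",), coef=np.zeros(1), se=np.ones(1), t=np.zeros(1),
            r2=0.0, r2_adj=0.0, n=20, m=1, fitted=np.zeros(1), resid=np.zeros(1),
        )
        assert not coefficient_significance(fit, 0.001).any()


class TestInfluenceShares:
    def test_orthogonal_predictors_get_marginal_r2(self, rng):
        n = 4000
        x1 = np.repeat([1.0, -1.0], n // 2)
        x2 = np.tile([1.0, -1.0], n // 2)  # exactly orthogonal to x1
        y = 2.0 * x1 + 1.0 * x2 + rng.normal(size=n)
        X = pd.DataFrame({"x1": x1, "x2": x2})
        fit = fit_ols(X, y)
        shares = influence_shares(fit, X, y)
        r1 = np.corrcoef(x1, y)[0, 1] ** 2
        r2_ = np.corrcoef(x2, y)[0, 1] ** 2
        assert shares["x1"] == pytest.approx(100 * r1, rel=1e-6)
        assert shares["x2"] == pytest.approx(100 * r2_, rel=1e-6)

    def test_shares_sum_to_explained_variability(self, rng):
        X = random_design(rng, n=100, m=5)
        y = X.to_numpy() @ np.ones(5) + rng.normal(size=100)
        fit = fit_ols(X, y)
        shares = influence_shares(fit, X, y)
        assert shares.sum() == pytest.approx(100 * fit.r2, abs=1e-9)
        assert (shares >= 0).all()

    def test_null_factor_has_negligible_share(self, rng):
        n = 2000
        x1 = rng.normal(size=n)
        null = rng.normal(size=n)
        y = 3.0 * x1 + rng.normal(size=n) * 0.5
        X = pd.DataFrame({"x1": x1, "null": null})
        fit = fit_ols(X, y)
        shares = influence_shares(fit, X, y)
        assert shares["null"] < 0.5  # percent

    def test_single_predictor_gets_everything(self, rng):
        x = rng.normal(size=200)
        y = x + rng.normal(size=200)
        X = pd.DataFrame({"x": x})
        fit = fit_ols(X, y)
        shares = influence_shares(fit, X, y)
        assert shares["x"] == pytest.approx(100 * fit.r2, rel=1e-9)


class TestPredict:
    def test_published_intercepts(self):
        zeros = np.zeros(9)
        assert predict_risk(zeros, HEALTH_WEIGHTS) == 0.2975
        assert predict_risk(zeros, GENETIC_WEIGHTS) == 2.4756

    def test_single_factor_hand_sum(self):
        x = np.zeros(9)
        x[2] = 1.0  # X3, pesticide ADI fold-excess
        assert predict_risk(x, HEALTH_WEIGHTS) == pytest.approx(1.1576, abs=1e-12)

    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=9, max_size=9))
    def test_matches_fsum_oracle(self, values):
        x = np.array(values)
        expected = math.fsum([HEALTH_WEIGHTS[0]] + [w * v for w, v in zip(HEALTH_WEIGHTS[1:], x)])
        assert predict_risk(x, HEALTH_WEIGHTS) == pytest.approx(expected, abs=1e-12)

    def test_frame_prediction_consistent(self, rng):
        X = random_design(rng, n=20, m=9)
        scores = predict_risk_frame(X, HEALTH_WEIGHTS)
        for i in range(5):
            assert scores.iloc[i] == pytest.approx(
                predict_risk(X.iloc[i].to_numpy(), HEALTH_WEIGHTS), rel=1e-12
            )


class TestPredictiveAbility:
    def test_perfect_concordance(self):
        y = np.array([0.0, 1.0, 2.0, 3.0])
        assert predictive_ability(y, y) == 1.0

    def test_anti_concordance(self):
        y = np.array([-2.0, -1.0, 1.0, 2.0])
        assert predictive_ability(-y, y) == 0.0

    def test_six_point_hand_count(self):
        scores = np.array([0.1, 0.9, 0.4, 0.8, 0.2, 0.6])  # mean 0.5 -> F,T,F,T,F,T
        y = np.array([0.0, 2.0, 1.0, 0.0, 0.0, 3.0])  # mean 1 -> F,T,F,F,F,T
        # concordant: positions 1,2,3,5,6 -> 5 of 6
        assert predictive_ability(scores, y) == pytest.approx(5 / 6)

    @given(a=st.floats(0.01, 100), b=st.floats(-50, 50))
    def test_positive_affine_invariance(self, a, b):
        scores = np.array([0.1, 0.9, 0.4, 0.8, 0.2, 0.6])
        y = np.array([0.0, 2.0, 1.0, 0.0, 0.0, 3.0])
        assert predictive_ability(a * scores + b, y) == predictive_ability(scores, y)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="zero-variance"):
            predictive_ability(np.ones(5), np.arange(5.0))


class TestBuildDesign:
    def _clean_person(self, village="Kyzylkairat", age=40.0):
        row = {
            "id": "P-1", "village": village, "sex": "F", "age": age,
            "weight": 70.0, "smoking": 0, "alcohol": 0,
        }
        row.update({f"cons_{f}": 0.0 for f in cohort_mod.FOOD_ITEMS})
        for v in cohort_mod.genetics.DEFAULT_PANEL:
            row[v.rsid] = "+" if v.marker_model == "dominant_deletion" else 0
        return row

    def test_all_functional_zero_contamination_gives_age_only(self):
        people = pd.DataFrame([self._clean_person(age=43.0)])
        X = build_design(
            people,
            cohort_mod.default_contamination().scaled(0.0),
            cohort_mod.default_reference_doses(),
        )
        row = X.iloc[0]
        assert row["X1_age"] == 43.0
        assert (row.drop("X1_age") == 0.0).all()

    def test_permutation_equivariance(self):
        config = cohort_mod.SimulationConfig(seed=7)
        people = cohort_mod.generate_individuals(config).head(12)
        contamination = cohort_mod.village_contamination(config)
        X = build_design(people, contamination, config.doses)
        order = np.array([5, 2, 0, 1, 4, 3, 11, 7, 6, 10, 9, 8])
        X_perm = build_design(people.iloc[order], contamination, config.doses)
        np.testing.assert_allclose(X_perm.to_numpy(), X.to_numpy()[order])

    def test_missing_predictor_names_individual(self):
        person = self._clean_person()
        person["weight"] = np.nan
        people = pd.DataFrame([person])
        with pytest.raises(ValueError, match="P-1"):
            build_design(
                people,
                cohort_mod.default_contamination(),
                cohort_mod.default_reference_doses(),
            )

    def test_three_person_hand_computed_fold_excess(self):
        """Single contaminated food: X2/X3 match hand arithmetic."""
        import pandas as pd
        from ocprisk.exposure import CONTAMINANT_GROUPS, FOOD_ITEMS, ContaminationTable, ReferenceDoses

        mean = pd.DataFrame(0.0, index=list(FOOD_ITEMS), columns=list(CONTAMINANT_GROUPS))
        mean.loc["milk", "DDT"] = 0.2
        table = ContaminationTable(mean)
        mpc = pd.DataFrame(np.nan, index=list(FOOD_ITEMS), columns=list(CONTAMINANT_GROUPS))
        mpc["DDT"] = 0.1
        doses = ReferenceDoses(adi={"DDT": 0.01}, mpc=mpc)
        person = self._clean_person()
        person["cons_milk"] = 0.5
        X = build_design(pd.DataFrame([person]), table, doses)
        # X2: only DDT has a complete MPC column; diet weight of milk is 1,
        # C/MPC = 0.2/0.1 = 2
        assert X.iloc[0]["X2_pesticide_mpc_excess"] == pytest.approx(2.0)
        # X3: EDI = 0.2*0.5/70; only DDT has an ADI
        assert X.iloc[0]["X3_pesticide_adi_excess"] == pytest.approx(0.2 * 0.5 / 70 / 0.01)
        # X4: no metal MPCs -> 0
        assert X.iloc[0]["X4_metal_mpc_excess"] == 0.0
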