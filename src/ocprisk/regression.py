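"""Nine-factor multivariate risk model for health and genetic outcomes.

The model is an ordinary-least-squares multiple regression

    Y = b0 + b1*X1 + ... + b9*X9 + e

with predictors X1 age (years), X2 mean pesticide MPC fold-excess of
the individual diet, X3 mean pesticide ADI fold-excess of the
individual daily intakes, X4 mean heavy-metal MPC fold-excess, X5-X7
the DNA-repair / detoxification / antioxidant cluster susceptibility
scores in [0, 1], and X8/X9 smoking and alcohol indicators.  Outcomes
are the chronic-disease rank (health model) and the chromosomal
aberration frequency in percent (genetic model).

Besides fitting, the module evaluates the two published coefficient
vectors, per-coefficient t-statistics against fixed critical values,
adjusted R-squared, a variance decomposition into per-factor influence
shares (rescaled squared semipartial correlations summing to 100*R²),
and the mean-threshold predictive-ability score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import genetics
from .exposure import (
    CONTAMINANT_GROUPS,
    FOOD_ITEMS,
    HEAVY_METALS,
    PESTICIDE_GROUPS,
    ContaminationTable,
    ReferenceDoses,
    individual_group_edi,
)

__all__ = [
    "PREDICTOR_NAMES",
    "HEALTH_WEIGHTS",
    "GENETIC_WEIGHTS",
    "CRITICAL_T_HEALTH",
    "CRITICAL_T_GENETIC",
    "RegressionFit",
    "build_design",
    "fit_ols",
    "coefficient_significance",
    "influence_shares",
    "predict_risk",
    "predictive_ability",
]

PREDICTOR_NAMES: tuple[str, ...] = (
    "X1_age",
    "X2_pesticide_mpc_excess",
    "X3_pesticide_adi_excess",
    "X4_metal_mpc_excess",
    "X5_repair_score",
    "X6_detox_score",
    "X7_antioxidant_score",
    "X8_smoking",
    "X9_alcohol",
)

#: published health-risk coefficients (intercept, b1..b9)
HEALTH_WEIGHTS: np.ndarray = np.array(
    [0.2975, 0.0038, -0.0336, 0.8601, -0.282, 0.09607, 0.5485, 0.2119, -0.3557, 0.1533]
)
#: published genetic-risk (aberration) coefficients (intercept, b1..b9)
GENETIC_WEIGHTS: np.ndarray = np.array(
    [2.4756, -0.01415, 0.7166, -0.8569, -0.1146, 1.1351, 0.2174, -0.7496, 0.9268, 0.2767]
)

# critical t-values the published models used; taken as given constants
CRITICAL_T_HEALTH = 2.263
CRITICAL_T_GENETIC = 2.693

Summary = Literal["mean", "max", "count"]


@dataclass
class RegressionFit:
    """OLS fit summary: coefficients, inference and fit statistics."""

    names: tuple[str, ...]
    coef: np.ndarray
    se: np.ndarray
    t: np.ndarray
    r2: float
    r2_adj: float
    n: int
    m: int
    fitted: np.ndarray
    resid: np.ndarray

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "t": self.t}, index=list(self.names)
        )


def _summarize(values: Sequence[float], summary: Summary) -> float:
    if len(values) == 0:
        return 0.0
    if summary == "mean":
        return float(np.mean(values))
    if summary == "max":
        return float(np.max(values))
    if summary == "count":
        return float(np.sum(np.asarray(values) > 1.0))
    raise ValueError(f"unknown summary {summary!r}")


def _diet_weighted_mpc_excess(
    consumption: Mapping[str, float],
    contamination: ContaminationTable,
    doses: ReferenceDoses,
    groups: Iterable[str],
    summary: Summary,
) -> float:
    """Summary over groups of the diet-weighted mean C/MPC fold-excess."""
    total = sum(consumption.values())
    if total <= 0:
        return 0.0
    per_group: list[float] = []
    for group in groups:
        value = 0.0
        complete = True
        for food in FOOD_ITEMS:
            mpc = doses.mpc_for(food, group)
            if mpc is None:
                complete = False
                break
            weight = consumption.get(food, 0.0) / total
            if weight == 0.0:
                continue
            value += weight * contamination.concentration(food, group) / mpc
        if complete:
            per_group.append(value)
    return _summarize(per_group, summary)


def _adi_fold_excess(
    consumption: Mapping[str, float],
    body_weight: float,
    contamination: ContaminationTable,
    doses: ReferenceDoses,
    summary: Summary,
) -> float:
    """Summary over pesticide groups with an ADI of EDI/ADI."""
    edis = individual_group_edi(consumption, body_weight, contamination, PESTICIDE_GROUPS)
    ratios = [
        edis[group] / doses.adi[group]
        for group in PESTICIDE_GROUPS
        if doses.adi.get(group) is not None
    ]
    return _summarize(ratios, summary)


def build_design(
    individuals: pd.DataFrame,
    contamination: ContaminationTable | Mapping[str, ContaminationTable],
    doses: ReferenceDoses,
    panel: Sequence[genetics.VariantDefinition] = genetics.DEFAULT_PANEL,
    summary: Summary = "mean",
    coding: Literal["dominant", "additive"] = "dominant",
) -> pd.DataFrame:
    """Assemble the 9-column predictor matrix, one row per individual.

    Requires ``village``, ``age``, ``weight``, ``smoking``,
    ``alcohol``, the seven ``cons_<food>`` columns and the panel
    genotype columns.  Individuals with any missing required input are
    reported together by id.
    """
    required = (
        ["village", "age", "weight", "smoking", "alcohol"]
        + [f"cons_{food}" for food in FOOD_ITEMS]
    )
    missing_cols = [c for c in required if c not in individuals.columns]
    if missing_cols:
        raise ValueError(f"cohort table lacks required columns: {missing_cols}")
    bad = individuals.index[individuals[required].isna().any(axis=1)]
    if len(bad):
        ids = individuals.loc[bad, "id"].tolist() if "id" in individuals else list(bad)
        raise ValueError(f"individuals with missing predictors: {ids}")

    scores = genetics.individual_cluster_scores(individuals, panel, coding)
    rows = []
    for (idx, row), (_, score_row) in zip(individuals.iterrows(), scores.iterrows()):
        table = (
            contamination[row["village"]]
            if isinstance(contamination, Mapping)
            else contamination
        )
        consumption = {food: float(row[f"cons_{food}"]) for food in FOOD_ITEMS}
        rows.append(
            {
                "X1_age": float(row["age"]),
                "X2_pesticide_mpc_excess": _diet_weighted_mpc_excess(
                    consumption, table, doses, PESTICIDE_GROUPS, summary
                ),
                "X3_pesticide_adi_excess": _adi_fold_excess(
                    consumption, float(row["weight"]), table, doses, summary
                ),
                "X4_metal_mpc_excess": _diet_weighted_mpc_excess(
                    consumption, table, doses, HEAVY_METALS, summary
                ),
                "X5_repair_score": score_row["repair_score"],
                "X6_detox_score": score_row["detox_score"],
                "X7_antioxidant_score": score_row["antioxidant_score"],
                "X8_smoking": float(row["smoking"]),
                "X9_alcohol": float(row["alcohol"]),
            }
        )
    return pd.DataFrame(rows, index=individuals.index, columns=list(PREDICTOR_NAMES))


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Adjusted determination coefficient 1 - (1-R²)(n-1)/(n-m-1)."""
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _check_full_rank(X: pd.DataFrame) -> None:
    design = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # name the offending columns via QR with pivoting
        from scipy.linalg import qr

        _, r, piv = qr(design, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(design.shape) * np.finfo(float).eps
        names = ["intercept"] + list(X.columns)
        collinear = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        collinear += [names[p] for p in piv[len(diag):]]
        raise ValueError(f"design matrix is rank deficient; collinear columns: {collinear}")


def fit_ols(X: pd.DataFrame, y: Sequence[float]) -> RegressionFit:
    """Fit the linear risk model by ordinary least squares.

    Classical homoskedastic standard errors; t_i = b_i / SE_i;
    adjusted R² by the (n-1)/(n-m-1) correction.
    """
    y = np.asarray(y, dtype=float)
    n, m = len(X), X.shape[1]
    if n <= m + 1:
        raise ValueError(f"need n > m+1 observations, got n={n}, m={m}")
    _check_full_rank(X)
    model = sm.OLS(y, sm.add_constant(X.to_numpy(float), has_constant="add")).fit()
    names = ("intercept",) + tuple(X.columns)
    r2 = float(model.rsquared)
    return RegressionFit(
        names=names,
        coef=np.asarray(model.params),
        se=np.asarray(model.bse),
        t=np.asarray(model.tvalues),
        r2=r2,
        r2_adj=adjusted_r2(r2, n, m),
        n=n,
        m=m,
        fitted=np.asarray(model.fittedvalues),
        resid=np.asarray(model.resid),
    )


def coefficient_significance(
    fit: RegressionFit, critical_value: float = CRITICAL_T_HEALTH
) -> pd.Series:
    """Per-coefficient flag: significant iff |t_i| > critical value."""
    if critical_value <= 0:
        raise ValueError("critical value must be positive")
    return pd.Series(np.abs(fit.t) > critical_value, index=list(fit.names))


def _r2_of(X: np.ndarray, y: np.ndarray) -> float:
    design = np.column_stack([np.ones(len(y)), X]) if X.size else np.ones((len(y), 1))
    return float(sm.OLS(y, design).fit().rsquared)


def influence_shares(fit: RegressionFit, X: pd.DataFrame, y: Sequence[float]) -> pd.Series:
    """Per-factor influence shares in percent, summing to 100·R².

    Each predictor's raw weight is its squared semipartial correlation
    (R² of the full model minus R² without that predictor), rescaled so
    the shares total the explained variability 100·R².  For mutually
    orthogonal predictors this reduces to each predictor's marginal
    100·r².
    """
    y = np.asarray(y, dtype=float)
    full = X.to_numpy(float)
    raw = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        reduced = np.delete(full, j, axis=1)
        raw[j] = fit.r2 - _r2_of(reduced, y)
    raw = np.clip(raw, 0.0, None)
    total = raw.sum()
    if total == 0.0:
        shares = np.zeros_like(raw)
    else:
        shares = raw / total * (100.0 * fit.r2)
    return pd.Series(shares, index=list(X.columns), name="influence_pct")


def predict_risk(x: Sequence[float], weights: Sequence[float]) -> float:
    """Risk score b0 + b·x for a 9-element predictor vector."""
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (10,):
        raise ValueError(f"expected 10 coefficients (intercept + 9), got {weights.shape}")
    if x.shape != (9,):
        raise ValueError(f"expected 9 predictors, got {x.shape}")
    return float(weights[0] + weights[1:] @ x)


def predict_risk_frame(X: pd.DataFrame, weights: Sequence[float]) -> pd.Series:
    """Vectorized risk scores for a design-matrix frame."""
    weights = np.asarray(weights, dtype=float)
    return pd.Series(
        weights[0] + X.to_numpy(float) @ weights[1:], index=X.index, name="risk_score"
    )


def predictive_ability(scores: Sequence[float], observed: Sequence[float]) -> float:
    """Mean-threshold concordance between predicted scores and outcomes.

    Both vectors are binarized at their own arithmetic means ("above
    the mean" = higher risk); the result is the fraction of individuals
    with concordant binary labels.  Undefined (raises) when either
    vector has zero variance, since no threshold separates anything.
    """
    scores = np.asarray(scores, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if scores.shape != observed.shape or scores.ndim != 1:
        raise ValueError("scores and observed outcomes must be equal-length vectors")
    if len(scores) < 2:
        raise ValueError("need at least 2 individuals")
    if np.ptp(scores) == 0.0 or np.ptp(observed) == 0.0:
        raise ValueError("predictive ability undefined: zero-variance scores or outcomes")
    high_pred = scores > scores.mean()
    high_obs = observed > observed.mean()
    return float(np.mean(high_pred == high_obs))
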