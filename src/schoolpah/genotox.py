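"""DNA-damage (comet tail-moment) statistics.

Tail moments are log10-transformed before any test, since the raw comet
assay outcome is right-skewed.  The stage covers stratified group
comparisons (t-test / one-way ANOVA on the log scale), univariate
regression screening of candidate predictors, and stepwise multiple linear
regression with collinearity (VIF) reporting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "COHORT_COLUMNS",
    "GroupComparison",
    "RegressionModel",
    "load_cohort",
    "write_cohort",
    "log10_tail_moment",
    "compare_groups",
    "simple_lr_screen",
    "stepwise_mlr",
]

COHORT_COLUMNS = [
    "child_id", "site_id", "traffic_group", "age_band", "gender", "bmi_category",
    "dist_main_road", "dist_highway", "transport_mode", "grilled_food",
    "supplement", "fruit", "ets", "bw_kg", "indoor_tpah", "outdoor_tpah",
    "tail_moment",
]

#: Allowed levels per categorical column; order defines the numeric coding
#: used when a category enters a regression (reference level first).
CATEGORY_LEVELS = {
    "traffic_group": ["LT", "HT"],
    "age_band": ["7-9", "10-11"],
    "gender": ["boy", "girl"],
    "bmi_category": ["underweight", "normal", "overweight", "obese"],
    "dist_main_road": ["<500m", ">=500m"],
    "dist_highway": ["<500m", ">=500m"],
    "transport_mode": ["active", "motorized"],
    "grilled_food": ["no", "yes"],
    "supplement": ["no", "yes"],
    "fruit": ["no", "yes"],
    "ets": ["no", "yes"],
}

CONTINUOUS_PREDICTORS = ("bw_kg", "indoor_tpah", "outdoor_tpah")


def validate_cohort(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort missing column(s): {missing}")
    if not (df["tail_moment"] > 0).all():
        raise ValueError("all tail moments must be > 0 (log10 must exist)")
    for col, levels in CATEGORY_LEVELS.items():
        bad = set(df[col].unique()) - set(levels)
        if bad:
            raise ValueError(f"{col}: unknown level(s) {sorted(bad)}")
    if df["child_id"].duplicated().any():
        raise ValueError("duplicate child_id")
    return df


def load_cohort(path: str | Path) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path))


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(df)[COHORT_COLUMNS].to_csv(path, index=False)


def log10_tail_moment(df: pd.DataFrame) -> pd.Series:
    """Elementwise log10 of the comet tail moment."""
    tm = df["tail_moment"]
    if not (tm > 0).all():
        raise ValueError("tail moment must be > 0")
    return np.log10(tm)


@dataclass(frozen=True)
class GroupComparison:
    variable: str
    levels: dict[str, dict]  # level -> {"mean": .., "sd": .., "n": ..} on log10 scale
    test: str  # "t" or "anova"
    statistic: float
    p_value: float


def compare_groups(df: pd.DataFrame, variable: str, equal_var: bool = True) -> GroupComparison:
    """Compare log10 tail moment across the levels of a stratification variable.

    Two levels use the independent-samples t-test (pooled variance by
    default, Welch optional); more than two use one-way ANOVA.
    """
    y = log10_tail_moment(df)
    order = CATEGORY_LEVELS.get(variable)
    groups: dict[str, np.ndarray] = {}
    present = [lv for lv in order if lv in set(df[variable])] if order else sorted(df[variable].unique())
    for lv in present:
        vals = y[df[variable] == lv].to_numpy()
        if len(vals) < 2:
            raise ValueError(f"{variable}={lv}: needs >= 2 observations")
        groups[lv] = vals
    if len(groups) < 2:
        raise ValueError(f"{variable}: needs >= 2 levels, found {len(groups)}")
    summaries = {
        lv: {"mean": float(v.mean()), "sd": float(v.std(ddof=1)), "n": int(len(v))}
        for lv, v in groups.items()
    }
    vals = list(groups.values())
    if len(vals) == 2:
        res = stats.ttest_ind(vals[0], vals[1], equal_var=equal_var)
        test = "t"
    else:
        res = stats.f_oneway(*vals)
        test = "anova"
    return GroupComparison(
        variable=variable,
        levels=summaries,
        test=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
    )


def _numeric_predictor(df: pd.DataFrame, var: str) -> pd.Series:
    """Numeric encoding of a predictor (level index for categoricals)."""
    if var in CONTINUOUS_PREDICTORS or var not in CATEGORY_LEVELS:
        x = pd.to_numeric(df[var])
    else:
        codes = {lv: i for i, lv in enumerate(CATEGORY_LEVELS[var])}
        x = df[var].map(codes).astype(float)
    return x


def simple_lr_screen(
    df: pd.DataFrame, candidates: Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Univariate OLS of log10 tail moment on each candidate predictor.

    Returns a frame with slope, p-value and a significance flag at ``alpha``.
    """
    if len(df) <= 2:
        raise ValueError("need n > 2 for a univariate fit")
    y = log10_tail_moment(df).to_numpy()
    rows = []
    for var in candidates:
        x = _numeric_predictor(df, var).to_numpy()
        if np.ptp(x) == 0:
            raise ValueError(f"{var}: constant predictor")
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        rows.append(
            {"predictor": var, "slope": float(fit.params[1]),
             "p_value": float(fit.pvalues[1]), "significant": bool(fit.pvalues[1] < alpha)}
        )
    return pd.DataFrame(rows)


@dataclass
class RegressionModel:
    """Final stepwise OLS model on log10 tail moment."""

    outcome: str
    intercept: float
    intercept_ci: tuple[float, float]
    predictors: dict[str, dict] = field(default_factory=dict)
    adjusted_r2: float = float("nan")
    f_statistic: float = float("nan")
    df1: int = 0
    df2: int = 0
    n: int = 0
    intercept_only: bool = False

    def to_json(self, path: str | Path) -> dict:
        payload = {
            "outcome": self.outcome,
            "intercept": {"B": self.intercept, "ci95": list(self.intercept_ci)},
            "predictors": self.predictors,
            "adjusted_r2": self.adjusted_r2,
            "f_statistic": self.f_statistic,
            "df": [self.df1, self.df2],
            "n": self.n,
            "intercept_only": self.intercept_only,
        }
        Path(path).write_text(json.dumps(payload, indent=2))
        return payload


def _vif(X: np.ndarray, j: int) -> float:
    """Variance inflation factor via the auxiliary regression of column j."""
    if X.shape[1] == 1:
        return 1.0
    others = np.delete(X, j, axis=1)
    fit = sm.OLS(X[:, j], sm.add_constant(others)).fit()
    r2 = min(fit.rsquared, 1 - 1e-12)
    return float(1.0 / (1.0 - r2))


def stepwise_mlr(
    df: pd.DataFrame,
    candidates: Sequence[str],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> RegressionModel:
    """Forward-entry / backward-removal stepwise OLS on log10 tail moment.

    At each step the candidate with the smallest entry p-value below
    ``p_enter`` is added, then any retained predictor whose p-value exceeds
    ``p_remove`` is dropped (worst first).  Candidates whose tolerance
    (1 - R^2 against the already-selected set) falls below 1e-4 are barred
    from entry, mirroring the usual stepwise collinearity guard.  If nothing
    enters, an intercept-only model is returned with a flag.
    """
    if not candidates:
        raise ValueError("need >= 1 candidate predictor")
    y = log10_tail_moment(df).to_numpy()
    X = {var: _numeric_predictor(df, var).to_numpy() for var in candidates}
    selected: list[str] = []

    def fit_model(names: list[str]):
        mat = sm.add_constant(np.column_stack([X[v] for v in names])) if names else \
            np.ones((len(y), 1))
        return sm.OLS(y, mat).fit()

    while True:
        changed = False
        remaining = [v for v in candidates if v not in selected]
        if remaining:
            pvals = {}
            for var in remaining:
                if selected:
                    aux = sm.OLS(
                        X[var], sm.add_constant(np.column_stack([X[v] for v in selected]))
                    ).fit()
                    if 1.0 - aux.rsquared < 1e-4:  # tolerance guard
                        continue
                fit = fit_model(selected + [var])
                pvals[var] = fit.pvalues[-1]
        if remaining and pvals:
            best = min(pvals, key=pvals.get)
            if pvals[best] < p_enter:
                selected.append(best)
                changed = True
        while selected:
            fit = fit_model(selected)
            worst_i = int(np.argmax(fit.pvalues[1:]))
            if fit.pvalues[1 + worst_i] > p_remove:
                selected.pop(worst_i)
                changed = True
            else:
                break
        if not changed:
            break

    fit = fit_model(selected)
    n = len(y)
    if not selected:
        intercept = float(np.mean(y))
        se = float(np.std(y, ddof=1) / np.sqrt(n))
        tcrit = stats.t.ppf(0.975, n - 1)
        return RegressionModel(
            outcome="log10_tail_moment",
            intercept=intercept,
            intercept_ci=(intercept - tcrit * se, intercept + tcrit * se),
            adjusted_r2=0.0,
            n=n,
            intercept_only=True,
        )

    ci = fit.conf_int(alpha=0.05)
    mat = np.column_stack([X[v] for v in selected])
    sd_y = float(np.std(y, ddof=1))
    predictors = {}
    for j, var in enumerate(selected):
        predictors[var] = {
            "B": float(fit.params[1 + j]),
            "ci95": [float(ci[1 + j][0]), float(ci[1 + j][1])],
            "beta": float(fit.params[1 + j] * np.std(mat[:, j], ddof=1) / sd_y),
            "p_value": float(fit.pvalues[1 + j]),
            "vif": _vif(mat, j),
        }
    return RegressionModel(
        outcome="log10_tail_moment",
        intercept=float(fit.params[0]),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
        predictors=predictors,
        adjusted_r2=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        df1=int(fit.df_model),
        df2=int(fit.df_resid),
        n=n,
    )
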