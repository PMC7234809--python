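"""Reciprocal-latency regression and polynomial trend testing.

Promptness (1/RT) is regressed on standardized trial covariates with a
Gaussian-family, identity-link model (ordinary least squares).  Continuous
regressors are z-scored and binary regressors coded +/-0.5 so that betas
are comparable effect sizes.  Per-subject slope tables (with
all/correct-only/incorrect-only splits) and hierarchical orthogonal-
polynomial trend tests (linear -> quadratic -> cubic, each increment judged
after the lower-order terms) are built on top.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DegenerateDataError, InsufficientDataError
from .trial_data import TrialTable, add_derived_columns

__all__ = [
    "RegressionResult",
    "WITHIN_REGRESSORS",
    "ACROSS_REGRESSORS",
    "design_matrix",
    "reciprocal_latency_glm",
    "slope_test",
    "polynomial_trend_test",
]

#: binary columns and their two levels (coded -0.5 / +0.5 in listed order)
_BINARY = {
    "category": ("nonprimate", "primate"),
    "play_order": ("forward", "reverse"),
    "touch_side": ("left", "right"),
    "correct": (False, True),
}

#: the ten standard regressors; perceptual_similarity requires a precomputed column
WITHIN_REGRESSORS = [
    "category",
    "play_order",
    "exposure",
    "touch_side",
    "elapsed_time_s",
    "chosen_location",
    "temporal_similarity",
    "td_s",
    "correct",
]
ACROSS_REGRESSORS = WITHIN_REGRESSORS + ["perceptual_similarity"]


@dataclass
class RegressionResult:
    """Tidy coefficient table for one promptness regression."""

    table: pd.DataFrame  # index: regressor; columns beta, sem, t, p, ci_lo, ci_hi
    n_obs: int
    family: str = "gaussian"
    link: str = "identity"
    rsquared: float | None = None

    def beta(self, name: str) -> float:
        return float(self.table.loc[name, "beta"])

    def row(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def summary(self) -> str:
        head = f"Promptness regression ({self.family}/{self.link}), n = {self.n_obs}"
        return head + "\n" + self.table.to_string(float_format=lambda v: f"{v: .4f}")

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def _standardize(col: pd.Series, name: str) -> np.ndarray:
    if name in _BINARY:
        lo, hi = _BINARY[name]
        vals = col.map({lo: -0.5, hi: 0.5})
        if vals.isna().any():
            raise ValueError(f"unexpected level in binary regressor '{name}'")
        return vals.to_numpy(dtype=float)
    x = col.to_numpy(dtype=float)
    sd = x.std()
    if sd == 0:
        raise DegenerateDataError(f"regressor '{name}' is constant")
    return (x - x.mean()) / sd


def design_matrix(df: pd.DataFrame, regressors: Sequence[str]) -> pd.DataFrame:
    """Standardized design matrix (z-scored continuous, +/-0.5 binary) plus intercept."""
    cols = {"const": np.ones(len(df))}
    for name in regressors:
        if name not in df.columns:
            raise KeyError(f"regressor column '{name}' not present; derive it first")
        cols[name] = _standardize(df[name], name)
    X = pd.DataFrame(cols, index=df.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the columns whose removal restores full rank
        collinear = []
        for name in list(X.columns[1:]):
            if np.linalg.matrix_rank(X.drop(columns=[name]).to_numpy()) == rank:
                collinear.append(name)
        raise DegenerateDataError(f"rank-deficient design; collinear columns: {collinear}")
    return X


def reciprocal_latency_glm(
    table: TrialTable | pd.DataFrame,
    regressors: Sequence[str] = WITHIN_REGRESSORS,
) -> RegressionResult:
    """Gaussian identity-link fit of promptness (1/RT) on standardized regressors.

    Derived columns (chosen_location, temporal_similarity, td_s) are computed
    automatically when absent.
    """
    df = table.df if isinstance(table, TrialTable) else table
    derivable = ("chosen_location", "temporal_similarity", "td_s")
    if any(r in derivable and r not in df.columns for r in regressors):
        df = add_derived_columns(df)
    y = 1.0 / df["rt_s"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateDataError("constant outcome (zero promptness variance)")
    X = design_matrix(df, regressors)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    out = pd.DataFrame(
        {
            "beta": fit.params,
            "sem": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
            "ci_lo": ci[0],
            "ci_hi": ci[1],
        }
    )
    return RegressionResult(out, n_obs=len(df), rsquared=float(fit.rsquared))


def slope_test(
    tables_by_subject: Mapping[str, TrialTable] | TrialTable,
    regressor_of_interest: str = "chosen_location",
    nuisance: Sequence[str] | None = None,
    min_trials: int = 30,
) -> pd.DataFrame:
    """Per-subject slope of promptness on one regressor, with nuisance control.

    Returns one row per subject x split (all / correct / incorrect): beta,
    SEM, t, p and 95% CI of the regressor of interest.  Splits with fewer
    than ``min_trials`` trials are flagged (``fitted = False``) rather than
    fitted.
    """
    if isinstance(tables_by_subject, TrialTable):
        full = tables_by_subject
        tables_by_subject = {
            s: full.subset(full.df["subject_id"] == s) for s in full.subjects
        }
    if nuisance is None:
        nuisance = [r for r in WITHIN_REGRESSORS if r != regressor_of_interest]
    records = []
    for subject, table in tables_by_subject.items():
        df = add_derived_columns(table.df)
        splits = {
            "all": df,
            "correct": df.loc[df["correct"]],
            "incorrect": df.loc[~df["correct"]],
        }
        for split, sub in splits.items():
            rec = {"subject": subject, "split": split, "n": len(sub)}
            if len(sub) < min_trials:
                rec.update(fitted=False, beta=np.nan, sem=np.nan, t=np.nan, p=np.nan,
                           ci_lo=np.nan, ci_hi=np.nan)
            else:
                use_nuisance = [n for n in nuisance if n != "correct" or split == "all"]
                res = reciprocal_latency_glm(sub, [regressor_of_interest] + list(use_nuisance))
                row = res.row(regressor_of_interest)
                rec.update(fitted=True, beta=row["beta"], sem=row["sem"], t=row["t"],
                           p=row["p"], ci_lo=row["ci_lo"], ci_hi=row["ci_hi"])
            records.append(rec)
    return pd.DataFrame(records)


def _orthogonal_poly(x: np.ndarray, degree: int) -> np.ndarray:
    """Orthonormal polynomial basis (constant column excluded), R poly()-style."""
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) <= degree:
        raise InsufficientDataError(
            f"need more than {degree} distinct values for a degree-{degree} basis"
        )
    V = np.vander(x - x.mean(), degree + 1, increasing=True)
    Q, _ = np.linalg.qr(V)
    return Q[:, 1:]


def polynomial_trend_test(
    table: TrialTable | pd.DataFrame,
    trend_var: str = "chosen_location",
    max_degree: int = 3,
) -> pd.DataFrame:
    """Hierarchical (linear, quadratic, cubic) trend test on promptness.

    The trend variable enters through an orthogonal polynomial basis, so the
    t-test of each degree's coefficient is exactly the incremental test of
    that degree given all lower-order terms.  Degrees that are untestable
    (too few distinct values) are flagged.
    """
    df = table.df if isinstance(table, TrialTable) else table
    if trend_var not in df.columns:
        df = add_derived_columns(df)
    x = df[trend_var].to_numpy(dtype=float)
    y = 1.0 / df["rt_s"].to_numpy(dtype=float)
    n_distinct = len(np.unique(x))
    testable = min(max_degree, n_distinct - 1)
    records = []
    if testable >= 1:
        basis = _orthogonal_poly(x, testable)
        X = sm.add_constant(basis)
        fit = sm.OLS(y, X).fit()
        for d in range(1, testable + 1):
            records.append(
                {
                    "degree": d,
                    "beta": float(fit.params[d]),
                    "t": float(fit.tvalues[d]),
                    "p": float(fit.pvalues[d]),
                    "significant": bool(fit.pvalues[d] < 0.05),
                    "testable": True,
                }
            )
    for d in range(testable + 1, max_degree + 1):
        records.append(
            {"degree": d, "beta": np.nan, "t": np.nan, "p": np.nan,
             "significant": False, "testable": False}
        )
    return pd.DataFrame(records)
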