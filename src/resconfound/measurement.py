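"""Construction of the three analysis variables from raw survey columns.

Cognitive ability is scored as the first unrotated factor of the subtest
battery (regression-method factor scores), socioeconomic background as the
natural log of mean two-year parental income with zeros treated as missing,
and education as the ordinal highest degree treated as a continuous
standardized variable.  A fourth derived variable, the education-minus-ability
difference score, indexes how much more educated than able a subject is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.multivariate.factor import Factor

__all__ = [
    "MeasurementConfig",
    "first_factor_scores",
    "log_income_seb",
    "difference_score",
    "standardize",
    "derive_variables",
]

FACTOR_METHODS = ("principal_axis", "maximum_likelihood")
_SM_METHOD = {"principal_axis": "pa", "maximum_likelihood": "ml"}
MISSING_POLICIES = ("listwise", "pairwise")
INCOME_POLICIES = ("available_year", "both_years")


@dataclass(frozen=True)
class MeasurementConfig:
    factor_method: str = "principal_axis"
    score_method: str = "regression"
    standardize: bool = True
    missing_policy: str = "listwise"
    income_policy: str = "available_year"

    def __post_init__(self) -> None:
        if self.factor_method not in FACTOR_METHODS:
            raise ValueError(f"factor_method must be one of {FACTOR_METHODS}")
        if self.score_method != "regression":
            raise ValueError("only regression-method factor scores are supported")
        if self.missing_policy not in MISSING_POLICIES:
            raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
        if self.income_policy not in INCOME_POLICIES:
            raise ValueError(f"income_policy must be one of {INCOME_POLICIES}")


def standardize(x: np.ndarray) -> np.ndarray:
    """Center/scale to mean 0, SD 1 over the non-missing entries."""
    x = np.asarray(x, dtype=float)
    m = np.nanmean(x)
    s = np.nanstd(x)
    if s == 0 or np.isnan(s):
        raise ValueError("cannot standardize a constant (or empty) variable")
    return (x - m) / s


def first_factor_scores(battery: np.ndarray, method: str = "principal_axis") -> np.ndarray:
    """Standardized regression-method scores on the first unrotated factor.

    Fits a single-factor model to the complete rows of the n x k battery and
    scores them with the regression (Thurstone) weights ``R^{-1} lambda``
    computed from the subtest correlation matrix and the estimated loadings.
    Rows with any missing subtest get a missing score.  Scores are
    standardized on the scored subsample and signed to correlate positively
    with the subtest mean.

    Parameters
    ----------
    battery
        n x k matrix of subtest scores; NaN marks missing.
    method
        ``"principal_axis"`` (default) or ``"maximum_likelihood"``.
    """
    if method not in FACTOR_METHODS:
        raise ValueError(f"method must be one of {FACTOR_METHODS}")
    X = np.asarray(battery, dtype=float)
    if X.ndim != 2:
        raise ValueError("battery must be a 2-D matrix")
    n, k = X.shape
    complete = ~np.isnan(X).any(axis=1)

    if k == 1:
        warnings.warn("single-subtest battery: factor scoring degenerates to standardization")
        out = np.full(n, np.nan)
        out[complete] = standardize(X[complete, 0])
        return out

    if complete.sum() < k + 1:
        raise ValueError(
            f"need at least k+1 = {k + 1} complete rows to fit a factor model, "
            f"got {int(complete.sum())}"
        )
    Xc = X[complete]
    R = np.corrcoef(Xc, rowvar=False)
    cond = np.linalg.eigvalsh(R)
    if cond.min() < 1e-10:
        # rank-deficient battery (e.g. duplicated subtests): fall back to the
        # leading eigenvector of R, which spans the same first factor
        lam = np.linalg.eigh(R)[1][:, -1]
        weights = lam
    else:
        fit = Factor(Xc, n_factor=1, method=_SM_METHOD[method]).fit()
        lam = np.asarray(fit.loadings)[:, 0]
        weights = np.linalg.solve(R, lam)

    Z = (Xc - Xc.mean(axis=0)) / Xc.std(axis=0)
    raw = Z @ weights
    scores = standardize(raw)
    if np.corrcoef(scores, Xc.mean(axis=1))[0, 1] < 0:
        scores = -scores
    out = np.full(n, np.nan)
    out[complete] = scores
    return out


def log_income_seb(
    income_y1: np.ndarray,
    income_y2: np.ndarray,
    policy: str = "available_year",
) -> np.ndarray:
    """Standardized natural log of mean two-year income; zeros are missing.

    A year with zero income is treated as missing before averaging.  Under the
    default ``available_year`` policy, subjects with exactly one non-zero year
    keep that year's value; under ``both_years`` they are dropped.  Subjects
    with no non-zero year are always missing.
    """
    if policy not in INCOME_POLICIES:
        raise ValueError(f"policy must be one of {INCOME_POLICIES}")
    y1 = np.asarray(income_y1, dtype=float)
    y2 = np.asarray(income_y2, dtype=float)
    if y1.shape != y2.shape:
        raise ValueError("income columns must have equal length")
    if np.nanmin(y1, initial=0) < 0 or np.nanmin(y2, initial=0) < 0:
        raise ValueError("incomes must be non-negative")
    y1 = np.where(y1 == 0, np.nan, y1)
    y2 = np.where(y2 == 0, np.nan, y2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
        mean = np.nanmean(np.column_stack([y1, y2]), axis=1)
    if policy == "both_years":
        mean[np.isnan(y1) | np.isnan(y2)] = np.nan
    return standardize(np.log(mean))


def difference_score(edu_std: np.ndarray, ca_std: np.ndarray) -> np.ndarray:
    """Element-wise education minus ability, both already standardized.

    Not restandardized: the components are standardized, the difference keeps
    its natural variance 2 - 2*corr(edu, ca).
    """
    edu = np.asarray(edu_std, dtype=float)
    ca = np.asarray(ca_std, dtype=float)
    if edu.shape != ca.shape:
        raise ValueError("edu and ca vectors must have equal length")
    return edu - ca


def derive_variables(raw: pd.DataFrame, config: MeasurementConfig | None = None) -> pd.DataFrame:
    """Raw survey CSV -> derived-variables table (id, seb, ca, edu, diff).

    Accepts either raw columns (``subtest_*``, ``income_y1/income_y2``,
    ``degree``) or pre-derived standardized columns (``seb``/``ca``/``edu``,
    or the generator's ``*_obs`` aliases), which pass through standardization
    only.  ``diff`` is computed on the rows where both edu and ca exist.
    """
    config = config or MeasurementConfig()
    n = len(raw)
    out = pd.DataFrame({"id": raw["id"].to_numpy() if "id" in raw else np.arange(n)})

    subtests = [c for c in raw.columns if c.startswith("subtest_")]
    if subtests:
        ca = first_factor_scores(raw[subtests].to_numpy(), method=config.factor_method)
    elif "ca" in raw:
        ca = standardize(raw["ca"].to_numpy())
    elif "ca_obs" in raw:
        ca = standardize(raw["ca_obs"].to_numpy())
    else:
        raise ValueError("no cognitive-ability columns found (subtest_* or ca)")

    if "income_y1" in raw and "income_y2" in raw:
        seb = log_income_seb(
            raw["income_y1"].to_numpy(), raw["income_y2"].to_numpy(), policy=config.income_policy
        )
    elif "seb" in raw:
        seb = standardize(raw["seb"].to_numpy())
    elif "seb_obs" in raw:
        seb = standardize(raw["seb_obs"].to_numpy())
    else:
        raise ValueError("no SEB columns found (income_y1/income_y2 or seb)")

    if "degree" in raw:
        edu = standardize(raw["degree"].to_numpy())
    elif "edu" in raw:
        edu = standardize(raw["edu"].to_numpy())
    elif "edu_obs" in raw:
        edu = standardize(raw["edu_obs"].to_numpy())
    else:
        raise ValueError("no education columns found (degree or edu)")

    out["seb"] = seb
    out["ca"] = ca
    out["edu"] = edu
    out["diff"] = difference_score(edu, ca)
    return out
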