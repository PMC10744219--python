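"""Agreement and regression statistics: Pearson correlation, Bland-Altman
limits of agreement, covariate-adjusted OLS, and normative cohort tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm


@dataclass(frozen=True)
class AgreementResult:
    """Bland-Altman + correlation summary of two paired measurement sets."""

    pearson_r: float
    p_value: float
    bias: float
    loa_low: float
    loa_high: float
    n: int


@dataclass(frozen=True)
class AdjustedFit:
    """One predictor's covariate-adjusted OLS coefficient with 95 % CI."""

    coefficient: float
    ci_low: float
    ci_high: float
    p_value: float
    covariates: tuple[str, ...]
    n: int


def pearson_regression(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with its two-sided p value (t distribution, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("undefined correlation for a constant series")
    r, p = scipy.stats.pearsonr(x, y)
    return float(r), float(p)


def bland_altman(x: Sequence[float], y: Sequence[float], loa_z: float = 1.96) -> AgreementResult:
    """Bland-Altman agreement between paired measurements.

    Differences are ``y - x``; bias is their mean and the limits of
    agreement are bias +/- ``loa_z`` sample standard deviations (ddof 1).
    Correlation is reported alongside (NaN when either series is constant,
    e.g. identical inputs).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 2:
        raise ValueError("need at least 2 pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    try:
        r, p = pearson_regression(x, y)
    except ValueError:
        r, p = float("nan"), float("nan")
    return AgreementResult(
        pearson_r=r,
        p_value=p,
        bias=bias,
        loa_low=bias - loa_z * sd,
        loa_high=bias + loa_z * sd,
        n=len(x),
    )


def adjusted_ols(
    outcome: Sequence[float],
    predictor: Sequence[float],
    covariates: Mapping[str, Sequence[float]] | None = None,
    predictor_name: str = "predictor",
) -> AdjustedFit:
    """Least-squares coefficient of ``predictor`` on ``outcome``, adjusted
    for the given covariate columns, with a t-based 95 % CI."""
    covariates = dict(covariates or {})
    y = np.asarray(outcome, dtype=float)
    cols = {predictor_name: np.asarray(predictor, dtype=float)}
    for name, col in covariates.items():
        cols[name] = np.asarray(col, dtype=float)
    X = pd.DataFrame(cols)
    n, p = X.shape[0], X.shape[1] + 1
    if y.shape[0] != n:
        raise ValueError("outcome and design lengths differ")
    if n <= p + 1:
        raise ValueError("need n > number of parameters + 1")
    design = sm.add_constant(X)
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        bad = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(design.drop(columns=[c]).to_numpy()) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int(alpha=0.05)
    return AdjustedFit(
        coefficient=float(fit.params[predictor_name]),
        ci_low=float(ci.loc[predictor_name, 0]),
        ci_high=float(ci.loc[predictor_name, 1]),
        p_value=float(fit.pvalues[predictor_name]),
        covariates=tuple(covariates.keys()),
        n=n,
    )


DEFAULT_AGE_BANDS = ((20, 30), (30, 40), (40, 50), (50, 60), (60, 70), (70, 80))


def cohort_table(
    values: pd.DataFrame,
    age: Sequence[float],
    sex: Sequence[str] | None = None,
    age_bands: Sequence[tuple[float, float]] = DEFAULT_AGE_BANDS,
    min_per_cell: int = 2,
) -> pd.DataFrame:
    """Normative table of segmental values stratified by age decile.

    ``values`` holds one row per subject and one column per reported
    quantity (e.g. seg_1 .. seg_17). Per age band and column the table
    reports n, mean, SD, the 95 % CI of the mean (mean +/- 1.96 SD/sqrt n)
    and the 95 % reference interval (mean +/- 1.96 SD). Strata with fewer
    than ``min_per_cell`` subjects are omitted with a warning.
    """
    age = np.asarray(age, dtype=float)
    if len(age) != len(values):
        raise ValueError("age and values lengths differ")
    if sex is not None and len(sex) != len(values):
        raise ValueError("sex and values lengths differ")
    sex_arr = np.asarray(sex) if sex is not None else None
    strata: list[tuple[str, str, np.ndarray]] = []
    for lo, hi in age_bands:
        in_band = (age >= lo) & (age < hi)
        label = f"{lo:g}-{hi:g}"
        strata.append((label, "all", in_band))
        if sex_arr is not None:
            for s in np.unique(sex_arr):
                strata.append((label, str(s), in_band & (sex_arr == s)))
    rows = []
    for label, sex_label, mask in strata:
        n = int(mask.sum())
        if n < min_per_cell:
            warnings.warn(
                f"stratum age {label} / sex {sex_label} has {n} subjects; omitted",
                RuntimeWarning,
                stacklevel=2,
            )
            continue
        sub = values.loc[mask]
        for col in values.columns:
            m = float(sub[col].mean())
            sd = float(sub[col].std(ddof=1))
            half_ci = 1.96 * sd / np.sqrt(n)
            rows.append(
                {
                    "age_band": label,
                    "sex": sex_label,
                    "variable": col,
                    "n": n,
                    "mean": m,
                    "sd": sd,
                    "ci_low": m - half_ci,
                    "ci_high": m + half_ci,
                    "ri_low": m - 1.96 * sd,
                    "ri_high": m + 1.96 * sd,
                }
            )
    return pd.DataFrame(rows)
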