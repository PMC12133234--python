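"""Demographic and cognitive cohort statistics.

Two-sample pooled-variance t-tests (from raw data or from printed
mean/SD/n summaries), Pearson chi-square for 2x2 tables, Pearson and
partial correlations, Bonferroni adjustment, and the standard
sample-description and correlation-matrix report tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "StatResult",
    "two_sample_t_summary",
    "two_sample_t_raw",
    "chi2_2x2",
    "pearson_r",
    "partial_r",
    "bonferroni_alpha",
    "build_table1",
    "correlation_matrix",
]

#: default continuous variables of the sample-description table, in order
TABLE1_VARIABLES = [
    "age",
    "education_years",
    "mmse",
    "tmt_a",
    "tmt_b",
    "lm_immediate",
    "lm_delayed",
    "pp_1g",
    "pp_2g",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics (mean, SD, n) of one variable in one group."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group size must be >= 2, got {self.n}")
        if self.sd < 0:
            raise ValueError(f"SD must be >= 0, got {self.sd}")


@dataclass(frozen=True)
class StatResult:
    statistic: float
    df: float
    p: float
    method: str


def two_sample_t_summary(g1: GroupSummary, g2: GroupSummary) -> StatResult:
    """Pooled-variance (Student) two-sample t from group summaries.

    t = (m1 - m2) / (s_p * sqrt(1/n1 + 1/n2)) with
    s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2); two-sided p on
    df = n1 + n2 - 2.
    """
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
    se = math.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    if se == 0:
        raise ValueError("zero pooled variance: t undefined")
    t = (g1.mean - g2.mean) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return StatResult(statistic=t, df=df, p=p, method="pooled-t")


def two_sample_t_raw(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pooled two-sample t from raw observations (NaNs dropped)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs at least 2 observations")
    g1 = GroupSummary(float(x.mean()), float(x.std(ddof=1)), len(x))
    g2 = GroupSummary(float(y.mean()), float(y.std(ddof=1)), len(y))
    return two_sample_t_summary(g1, g2)


def chi2_2x2(table: Sequence[Sequence[float]], yates: bool = False) -> StatResult:
    """Pearson chi-square on a 2x2 contingency table (df = 1).

    Continuity correction off by default; enable with ``yates=True``.
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {obs.shape}")
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(obs, correction=yates)
    return StatResult(statistic=float(res.statistic), df=1, p=float(res.pvalue), method="chi2")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson correlation with its t-based two-sided p (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    r, p = stats.pearsonr(x, y)
    return StatResult(statistic=float(r), df=len(x) - 2, p=float(p), method="pearson")


def partial_r(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Sequence[Sequence[float]] | np.ndarray,
) -> StatResult:
    """Partial correlation of x and y given covariates.

    Computed as the Pearson correlation of the OLS residuals of x and y on
    the covariates (with intercept); df = n - 2 - n_covariates, with the
    t-based two-sided p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if z.shape[0] == len(x) and z.shape[1] != len(x):
        z = z.T  # accept (n, k) or (k, n)
    k = z.shape[0]
    keep = ~(np.isnan(x) | np.isnan(y) | np.isnan(z).any(axis=0))
    x, y, z = x[keep], y[keep], z[:, keep]
    n = len(x)
    if n <= k + 2:
        raise ValueError(f"need n > {k + 2} observations for {k} covariates")
    design = np.column_stack([np.ones(n), z.T])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    if np.allclose(rx, 0) or np.allclose(ry, 0):
        raise ValueError("a variable is fully explained by the covariates")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * math.sqrt(df) / math.sqrt(max(1.0 - r * r, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(abs(t), df)
    return StatResult(statistic=r, df=df, p=p, method="partial")


def bonferroni_alpha(alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test significance level alpha / m."""
    if m < 1:
        raise ValueError(f"number of tests must be >= 1, got {m}")
    return alpha / m


def _sex_counts(series: pd.Series) -> tuple[int, int]:
    male = int((series == 1).sum())
    female = int((series == 0).sum())
    return male, female


def build_table1(
    cohort: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    variables: Sequence[str] | None = None,
    alpha: float = 0.05,
    group_col: str = "group",
    groups: tuple[str, str] = ("HC", "MCI"),
) -> pd.DataFrame:
    """Sample-description table: per-group mean (SD), test statistic, p.

    Continuous variables get a pooled two-sample t (first group minus
    second); the sex row gets a chi-square on male/female counts.  NaNs are
    dropped per variable, reducing that row's df, and per-group N is
    reported.  The ``significant`` column flags rows surviving the
    Bonferroni-adjusted level alpha / (number of test rows).
    """
    if scores is not None:
        cohort = cohort.merge(scores, on="participant_id", how="left")
    if variables is None:
        variables = [v for v in TABLE1_VARIABLES if v in cohort.columns]
    missing = [v for v in variables if v not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table lacks columns: {missing}")

    g1 = cohort[cohort[group_col] == groups[0]]
    g2 = cohort[cohort[group_col] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 participants")

    rows = []
    # sex row (chi-square), then the continuous variables
    if "sex" in cohort.columns:
        m1, f1 = _sex_counts(g1["sex"])
        m2, f2 = _sex_counts(g2["sex"])
        res = chi2_2x2([[m1, f1], [m2, f2]])
        rows.append(
            {
                "variable": "sex_male_female",
                "all": f"{m1 + m2}/{f1 + f2}",
                groups[0]: f"{m1}/{f1}",
                groups[1]: f"{m2}/{f2}",
                "n_1": len(g1),
                "n_2": len(g2),
                "test": "chi2",
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p,
            }
        )
    for var in variables:
        x = g1[var].astype(float)
        y = g2[var].astype(float)
        res = two_sample_t_raw(x, y)
        overall = cohort[var].astype(float)
        rows.append(
            {
                "variable": var,
                "all": f"{overall.mean():.2f} ({overall.std(ddof=1):.2f})",
                groups[0]: f"{x.mean():.2f} ({x.std(ddof=1):.2f})",
                groups[1]: f"{y.mean():.2f} ({y.std(ddof=1):.2f})",
                "n_1": int(x.notna().sum()),
                "n_2": int(y.notna().sum()),
                "test": "t",
                "statistic": res.statistic,
                "df": res.df,
                "p": res.p,
            }
        )
    out = pd.DataFrame(rows)
    adj = bonferroni_alpha(alpha, len(out))
    out["bonferroni_alpha"] = adj
    out["significant"] = out["p"] < adj
    return out


def correlation_matrix(
    data: pd.DataFrame,
    variables: Sequence[str],
    covariates: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson (or partial, given covariates) correlation matrices.

    Returns (r, p) DataFrames over pairwise-complete observations.  The
    Bonferroni-adjusted level for the off-diagonal tests is attached as
    ``r.attrs['bonferroni_alpha']``.
    """
    k = len(variables)
    r = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    p = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    m = k * (k - 1) // 2
    for i in range(k):
        for j in range(i + 1, k):
            xi, xj = variables[i], variables[j]
            if covariates:
                res = partial_r(data[xi], data[xj], data[list(covariates)].T.to_numpy())
            else:
                res = pearson_r(data[xi], data[xj])
            r.iloc[i, j] = r.iloc[j, i] = res.statistic
            p.iloc[i, j] = p.iloc[j, i] = res.p
    r.attrs["bonferroni_alpha"] = bonferroni_alpha(alpha, max(m, 1))
    return r, p
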