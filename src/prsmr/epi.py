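"""Observational association models and descriptive statistics.

Mirrors the non-genetic analysis layer of the study design: Z-standardized
log-transformed exposure against each cardiometabolic outcome in partially
(age, sex, PC1-3) and fully (+ BMI, alcohol, smoking) adjusted linear or
logistic models, plus a characteristics table by weight status.

Sample-exclusion rules applied before modelling:

* lipid-lowering-medication users excluded from every analysis;
* T2D cases excluded from HOMA-IR analyses;
* SBP/DBP models additionally adjust for blood-pressure medication use.

HOMA-IR and triglycerides enter log-transformed; all continuous outcomes
are converted to Z scores so effects are per-SD.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

CONTINUOUS_OUTCOMES = ["homa_ir", "hdl", "ldl", "total_cholesterol",
                       "triglycerides", "sbp", "dbp"]
BINARY_OUTCOMES = ["t2d", "hypertension"]
LOG_OUTCOMES = {"homa_ir", "triglycerides"}
#: variables summarized as median (25th-75th pct) in descriptive tables
SKEWED_VARS = {"adiponectin", "homa_ir", "triglycerides"}

PARTIAL_COVARIATES = ["age", "sex"]  # + PCs, appended by callers
FULL_EXTRA = ["bmi", "alcohol", "smoking_current", "smoking_former"]

Z95 = 1.96


@dataclass
class AssocResult:
    outcome: str
    effect: float               # beta per 1 SD (continuous) or log-OR (binary)
    se: float
    p: float
    n: int
    adjustment: str
    binary: bool

    @property
    def ci95(self) -> tuple[float, float]:
        return self.effect - Z95 * self.se, self.effect + Z95 * self.se

    def to_row(self) -> dict:
        lo, hi = self.ci95
        row = {"outcome": self.outcome, "adjustment": self.adjustment,
               "effect": self.effect, "se": self.se, "ci_low": lo,
               "ci_high": hi, "p": self.p, "n": self.n}
        if self.binary:
            row.update(odds_ratio=math.exp(self.effect),
                       or_ci_low=math.exp(lo), or_ci_high=math.exp(hi))
        return row


def zstandardize(values: np.ndarray, log_first: bool = False) -> np.ndarray:
    """Optionally log-transform, then scale to mean 0 / SD 1 (NaN-aware)."""
    v = np.asarray(values, dtype=float)
    if log_first:
        if np.nanmin(v) <= 0:
            raise ValueError("log transform requires strictly positive values")
        v = np.log(v)
    mu = np.nanmean(v)
    sd = np.nanstd(v, ddof=0)
    if sd == 0 or np.isnan(sd):
        raise ValueError("cannot standardize a constant (or empty) vector")
    return (v - mu) / sd


def analysis_frame(df: pd.DataFrame, outcome: str, adjustment: str,
                   pc_cols: list[str]) -> tuple[pd.DataFrame, list[str], dict]:
    """Apply exclusions and assemble the covariate list for one model.

    Returns (subset, covariate column names, exclusion counts).
    """
    if outcome not in df.columns:
        raise KeyError(f"outcome {outcome!r} not in dataset")
    excl = {}
    sub = df
    if "lipid_med" in sub.columns:
        k = int((sub["lipid_med"] == 1).sum())
        sub = sub[sub["lipid_med"] != 1]
        excl["lipid_med"] = k
    if outcome == "homa_ir" and "t2d" in sub.columns:
        k = int((sub["t2d"] == 1).sum())
        sub = sub[sub["t2d"] != 1]
        excl["t2d_cases"] = k
    cols = PARTIAL_COVARIATES + pc_cols
    if adjustment == "full":
        cols = cols + FULL_EXTRA
    elif adjustment != "partial":
        raise ValueError(f"unknown adjustment {adjustment!r}")
    if outcome in ("sbp", "dbp") and "bp_med" in sub.columns:
        cols = cols + ["bp_med"]
    need = [outcome, "adiponectin"] + [c for c in cols if c in sub.columns]
    k = int(sub[need].isna().any(axis=1).sum())
    if k:
        excl["missing_values"] = k
        sub = sub.dropna(subset=need)
    if len(sub) == 0:
        raise ValueError(f"no samples left for {outcome} after exclusions")
    return sub, [c for c in cols if c in sub.columns], excl


def observational_assoc(df: pd.DataFrame, outcome: str,
                        adjustment: str = "partial",
                        pc_cols: list[str] | None = None) -> AssocResult:
    """Exposure-outcome association per 1 SD of Z-standardized log exposure."""
    import statsmodels.api as sm

    pc_cols = pc_cols if pc_cols is not None else [
        c for c in df.columns if c.startswith("pc")][:3]
    sub, cols, _ = analysis_frame(df, outcome, adjustment, pc_cols)
    expo = zstandardize(sub["adiponectin"].to_numpy(), log_first=True)
    X = sm.add_constant(np.column_stack(
        [expo] + [sub[c].to_numpy(dtype=float) for c in cols]))
    binary = outcome in BINARY_OUTCOMES
    if binary:
        y = sub[outcome].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, X).fit(disp=0)
    else:
        y = zstandardize(sub[outcome].to_numpy(),
                         log_first=outcome in LOG_OUTCOMES)
        res = sm.OLS(y, X).fit()
    return AssocResult(outcome=outcome, effect=float(res.params[1]),
                       se=float(res.bse[1]), p=float(res.pvalues[1]),
                       n=len(sub), adjustment=adjustment, binary=binary)


def _mean_ci(v: np.ndarray) -> tuple[float, tuple[float, float]]:
    m = float(np.mean(v))
    half = Z95 * float(np.std(v, ddof=1)) / math.sqrt(v.size) if v.size > 1 else 0.0
    return m, (m - half, m + half)


def _median_iqr(v: np.ndarray) -> tuple[float, tuple[float, float]]:
    return float(np.median(v)), (float(np.percentile(v, 25)),
                                 float(np.percentile(v, 75)))


def percent_ci(p_hat: float, n: int) -> tuple[float, float]:
    """Wald 95% CI for a proportion, on the percent scale."""
    half = Z95 * math.sqrt(p_hat * (1.0 - p_hat) / n)
    return 100.0 * (p_hat - half), 100.0 * (p_hat + half)


def descriptive_table(df: pd.DataFrame, variables: list[str],
                      binary_vars: set[str] | None = None,
                      group_col: str | None = None) -> pd.DataFrame:
    """Characteristics table with matched group-comparison tests.

    Normally distributed variables: mean (95% Wald CI), two-sample t-test;
    skewed variables (:data:`SKEWED_VARS`): median (25th-75th pct),
    Mann-Whitney U; categorical: percent (95% Wald CI), chi-square.
    ``group_col`` (e.g. a BMI < 25 indicator) adds per-group summaries and
    the comparison p-value.
    """
    binary_vars = binary_vars if binary_vars is not None else {
        v for v in variables if set(pd.unique(df[v].dropna())) <= {0, 1}}
    groups = ([("all", df)] if group_col is None else
              [("all", df)] + [(str(g), d) for g, d in df.groupby(group_col)])
    for name, d in groups:
        if len(d) == 0:
            raise ValueError(f"empty group {name!r}")
    rows = []
    for var in variables:
        kind = ("percent+CI" if var in binary_vars
                else "median+IQR" if var in SKEWED_VARS else "mean+CI")
        row: dict = {"variable": var, "summary": kind}
        for gname, d in groups:
            v = d[var].dropna().to_numpy(dtype=float)
            if kind == "percent+CI":
                p_hat = float(v.mean())
                lo, hi = percent_ci(p_hat, v.size)
                row[f"{gname}_value"] = 100.0 * p_hat
                row[f"{gname}_lo"], row[f"{gname}_hi"] = lo, hi
            elif kind == "median+IQR":
                med, (lo, hi) = _median_iqr(v)
                row[f"{gname}_value"], row[f"{gname}_lo"], row[f"{gname}_hi"] = med, lo, hi
            else:
                m, (lo, hi) = _mean_ci(v)
                row[f"{gname}_value"], row[f"{gname}_lo"], row[f"{gname}_hi"] = m, lo, hi
        if group_col is not None and len(groups) == 3:
            a = groups[1][1][var].dropna().to_numpy(dtype=float)
            b = groups[2][1][var].dropna().to_numpy(dtype=float)
            row["test"], row["p"] = _compare(a, b, kind)
        rows.append(row)
    return pd.DataFrame(rows)


def _compare(a: np.ndarray, b: np.ndarray, kind: str) -> tuple[str, float]:
    if kind == "percent+CI":
        tab = np.array([[(a == 1).sum(), (a == 0).sum()],
                        [(b == 1).sum(), (b == 0).sum()]])
        if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
            return "chi-square", float("nan")
        if np.array_equal(np.sort(a), np.sort(b)):
            return "chi-square", 1.0
        return "chi-square", float(sps.chi2_contingency(tab, correction=False)[1])
    if kind == "median+IQR":
        if np.array_equal(np.sort(a), np.sort(b)) and np.unique(a).size == 1:
            return "Mann-Whitney U", 1.0
        return "Mann-Whitney U", float(sps.mannwhitneyu(
            a, b, alternative="two-sided").pvalue)
    if np.std(a, ddof=1) == 0 and np.std(b, ddof=1) == 0:
        return "t-test", 1.0 if np.mean(a) == np.mean(b) else 0.0
    return "t-test", float(sps.ttest_ind(a, b, equal_var=False).pvalue)
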