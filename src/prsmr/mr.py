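"""Causal estimation: 2SLS, binary two-stage, GMM, and sensitivity checks.

All estimators treat a polygenic score as a single instrument z for a
standardized log-transformed exposure x, with covariate adjustment sets
``partial`` (age, sex, PCs) and ``full`` (+ BMI, alcohol, smoking).

* :func:`tsls` — two-stage least squares from its definition: the point
  estimate is the coefficient on first-stage-fitted exposure; the SE uses
  the *structural* residuals y - b*x - g'C, not second-stage residuals.
* :func:`two_stage_binary` — stage-1 linear fit of the exposure, stage-2
  logistic regression of the binary outcome on fitted values; reported as
  an odds ratio per 1 SD of log-exposure, with an optional nonparametric
  bootstrap SE.
* :func:`gmm_continuous` — just-identified two-step GMM with a
  heteroskedasticity-robust weight; the point estimate coincides with 2SLS
  by algebra, the SE is the robust sandwich.
* :func:`gmm_binary` — moment conditions E[(y - expit(a + b x + g'C)) *
  (1, z, C)'] = 0 solved by damped Newton iteration, with an explicit
  non-convergence diagnostic.

Weak instruments (first-stage F <= 10) are flagged on the estimate and
raised as a :class:`WeakInstrumentWarning`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

WEAK_F_THRESHOLD = 10.0


class WeakInstrumentWarning(UserWarning):
    """First-stage F statistic at or below the conventional bar of 10."""


class EstimationError(RuntimeError):
    """Degenerate input or failed estimation (reported, never silent)."""


@dataclass
class FirstStageDiagnostics:
    f_stat: float
    r2_partial: float
    coefficient: float
    se: float


@dataclass
class IVEstimate:
    estimate: float            # beta per 1 SD log-exposure, or log-OR if binary
    se: float
    p: float
    n: int
    method: str                # tsls | gmm | two_stage_logistic | gmm_logistic
    adjustment: str = "partial"
    stratum: str = "all"
    outcome: str = ""
    f_stat: float | None = None
    weak_instrument: bool = False
    converged: bool = True
    note: str = ""

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - 1.96 * self.se,
                self.estimate + 1.96 * self.se)

    @property
    def odds_ratio(self) -> float | None:
        if self.method in ("two_stage_logistic", "gmm_logistic"):
            return float(np.exp(self.estimate))
        return None

    def to_row(self) -> dict:
        lo, hi = self.ci95
        row = {"outcome": self.outcome, "stratum": self.stratum,
               "method": self.method, "adjustment": self.adjustment,
               "estimate": self.estimate, "se": self.se,
               "ci_low": lo, "ci_high": hi, "p": self.p, "n": self.n,
               "f_stat": self.f_stat, "weak_instrument": self.weak_instrument,
               "converged": self.converged, "note": self.note}
        if self.method in ("two_stage_logistic", "gmm_logistic"):
            with np.errstate(over="ignore"):
                row["odds_ratio"] = float(np.exp(self.estimate))
                row["or_ci_low"] = float(np.exp(lo))
                row["or_ci_high"] = float(np.exp(hi))
        return row


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None or getattr(covariates, "size", 0) == 0:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def _residualize(v: np.ndarray, C: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(C, v, rcond=None)
    return v - C @ coef


def _wald_p(est: float, se: float) -> float:
    if se == 0:
        return float("nan")
    return float(2.0 * sps.norm.sf(abs(est / se)))


def first_stage_f(exposure: np.ndarray, instrument: np.ndarray,
                  covariates: np.ndarray | None = None) -> FirstStageDiagnostics:
    """F = t^2 of the instrument in exposure ~ instrument + covariates."""
    n = exposure.size
    C = _design(covariates, n)
    X = np.column_stack([C, instrument])
    coef, _, rank, _ = np.linalg.lstsq(X, exposure, rcond=None)
    if rank < X.shape[1]:
        raise EstimationError("instrument collinear with covariates in first stage")
    resid = exposure - X @ coef
    dof = n - X.shape[1]
    if dof <= 0:
        raise EstimationError("not enough observations for the first stage")
    sigma2 = float(resid @ resid) / dof
    XtX_inv = np.linalg.inv(X.T @ X)
    se = math.sqrt(sigma2 * XtX_inv[-1, -1])
    if se == 0:
        raise EstimationError("instrument has zero variance after residualization")
    t = coef[-1] / se
    # incremental R^2 of the instrument over the covariate-only model
    resid0 = _residualize(exposure, C)
    ss0 = float(resid0 @ resid0)
    r2_partial = 0.0 if ss0 == 0 else 1.0 - float(resid @ resid) / ss0
    return FirstStageDiagnostics(f_stat=float(t * t), r2_partial=r2_partial,
                                 coefficient=float(coef[-1]), se=float(se))


def _flag_weak(est: IVEstimate, diag: FirstStageDiagnostics) -> IVEstimate:
    est.f_stat = diag.f_stat
    if diag.f_stat <= WEAK_F_THRESHOLD:
        est.weak_instrument = True
        warnings.warn(f"weak instrument: first-stage F = {diag.f_stat:.2f} <= 10",
                      WeakInstrumentWarning, stacklevel=3)
    return est


def tsls(y: np.ndarray, exposure: np.ndarray, instrument: np.ndarray,
         covariates: np.ndarray | None = None, **tags,
         ) -> tuple[IVEstimate, FirstStageDiagnostics]:
    """Two-stage least squares with structural-residual standard errors.

    Just-identified IV: regressors W = [x, C], instruments Z = [z, C];
    theta = (Z'W)^{-1} Z'y; Var(theta) = s^2 (Z'W)^{-1} Z'Z (W'Z)^{-1} with
    s^2 from the structural residuals y - W theta.  For a single instrument
    the slope equals cov(z~, y~)/cov(z~, x~) after residualizing on C.
    """
    y = np.asarray(y, float)
    x = np.asarray(exposure, float)
    z = np.asarray(instrument, float)
    n = y.size
    C = _design(covariates, n)
    z_res = _residualize(z, C)
    if float(z_res @ z_res) <= 1e-12 * n:
        raise EstimationError("instrument has zero variance after residualization")
    W = np.column_stack([x, C])
    Z = np.column_stack([z, C])
    ZtW = Z.T @ W
    try:
        theta = np.linalg.solve(ZtW, Z.T @ y)
        A = np.linalg.inv(ZtW)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"singular IV system (collinear covariates?): {exc}")
    u = y - W @ theta                      # structural residuals
    sigma2 = float(u @ u) / (n - W.shape[1])
    cov = sigma2 * (A @ (Z.T @ Z) @ A.T)
    se = math.sqrt(max(cov[0, 0], 0.0))
    diag = first_stage_f(x, z, covariates)
    est = IVEstimate(estimate=float(theta[0]), se=se, p=_wald_p(theta[0], se),
                     n=n, method="tsls", **tags)
    return _flag_weak(est, diag), diag


def gmm_continuous(y: np.ndarray, exposure: np.ndarray,
                   instrument: np.ndarray,
                   covariates: np.ndarray | None = None, **tags,
                   ) -> tuple[IVEstimate, FirstStageDiagnostics]:
    """Two-step GMM for the linear structural model.

    Moments E[(y - b x - g'C) (1, z, C')'] = 0.  Just-identified, so the
    point estimate solves the moments exactly and equals 2SLS; the two-step
    (heteroskedasticity-robust) weight matters only for the sandwich SE
    V = G^{-1} S G^{-T} / n with G = Z'W/n and S = sum z_i z_i' u_i^2 / n.
    """
    y = np.asarray(y, float)
    x = np.asarray(exposure, float)
    z = np.asarray(instrument, float)
    n = y.size
    C = _design(covariates, n)
    W = np.column_stack([x, C])
    Z = np.column_stack([z, C])
    try:
        theta = np.linalg.solve(Z.T @ W, Z.T @ y)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(f"singular GMM system: {exc}")
    u = y - W @ theta
    G = Z.T @ W / n
    S = (Z * (u ** 2)[:, None]).T @ Z / n
    Ginv = np.linalg.inv(G)
    V = Ginv @ S @ Ginv.T / n
    se = math.sqrt(max(V[0, 0], 0.0))
    diag = first_stage_f(x, z, covariates)
    est = IVEstimate(estimate=float(theta[0]), se=se, p=_wald_p(theta[0], se),
                     n=n, method="gmm", **tags)
    return _flag_weak(est, diag), diag


def two_stage_binary(y: np.ndarray, exposure: np.ndarray,
                     instrument: np.ndarray,
                     covariates: np.ndarray | None = None,
                     bootstrap: int = 0, seed: int = 0, **tags,
                     ) -> IVEstimate:
    """Two-stage estimator for a binary outcome.

    Stage 1: linear regression of the exposure on instrument + covariates
    over the full analysis sample; stage 2: logistic regression of the
    outcome on the stage-1 fitted values + covariates.  The estimate is the
    log-odds ratio per 1 SD log-exposure.  Model-based SEs by default;
    ``bootstrap`` > 0 switches to a nonparametric bootstrap over
    individuals (two-stage model SEs understate uncertainty).
    """
    import statsmodels.api as sm

    y = np.asarray(y, float)
    x = np.asarray(exposure, float)
    z = np.asarray(instrument, float)
    n = y.size
    classes = np.unique(y[~np.isnan(y)])
    if not np.isin(classes, [0.0, 1.0]).all() or classes.size < 2:
        raise EstimationError("binary outcome must contain both classes")

    def fit_once(idx: np.ndarray) -> tuple[float, float]:
        C = _design(None if covariates is None else
                    np.asarray(covariates, float)[idx], idx.size)
        X1 = np.column_stack([C, z[idx]])
        coef, *_ = np.linalg.lstsq(X1, x[idx], rcond=None)
        xhat = X1 @ coef
        if xhat.std() < 1e-12:
            raise EstimationError("fitted exposure is constant "
                                  "(zero-weight or degenerate instrument)")
        X2 = np.column_stack([xhat, C])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.Logit(y[idx], X2).fit(disp=0, maxiter=100)
            except Exception as exc:  # PerfectSeparation and friends
                raise EstimationError(f"second-stage logistic fit failed: {exc}")
        if not res.mle_retvals.get("converged", True):
            raise EstimationError("second-stage logistic did not converge "
                                  "(possible separation)")
        return float(res.params[0]), float(res.bse[0])

    beta, se_model = fit_once(np.arange(n))
    se = se_model
    note = "model-based SE"
    if bootstrap > 0:
        rng = np.random.default_rng(seed)
        draws = []
        for _ in range(bootstrap):
            idx = rng.integers(0, n, size=n)
            try:
                draws.append(fit_once(idx)[0])
            except EstimationError:
                continue
        if len(draws) >= max(50, bootstrap // 2):
            se = float(np.std(draws, ddof=1))
            note = f"bootstrap SE ({len(draws)}/{bootstrap} resamples)"
        else:
            note = "bootstrap failed, model-based SE"
    diag = first_stage_f(x, z, covariates)
    est = IVEstimate(estimate=beta, se=se, p=_wald_p(beta, se), n=n,
                     method="two_stage_logistic", note=note, **tags)
    return _flag_weak(est, diag)


def gmm_binary(y: np.ndarray, exposure: np.ndarray,
               instrument: np.ndarray,
               covariates: np.ndarray | None = None,
               max_iter: int = 200, tol: float = 1e-10, **tags,
               ) -> IVEstimate:
    """GMM for a binary outcome with a logistic structural mean.

    Solves E[(y - expit(a + b x + g'C)) (1, z, C')'] = 0 (just-identified)
    by Newton iteration from the naive logistic starting point, with a
    root-finder fallback; reports exp(b) as the odds ratio with the GMM
    sandwich SE.  Covariate and instrument columns are standardized
    internally (the coefficient on x is invariant to that affine
    reparametrization).  Non-convergence is flagged on the returned
    estimate, never silently ignored.
    """
    y = np.asarray(y, float)
    x = np.asarray(exposure, float)
    z = np.asarray(instrument, float)
    n = y.size
    classes = np.unique(y[~np.isnan(y)])
    if not np.isin(classes, [0.0, 1.0]).all() or classes.size < 2:
        raise EstimationError("binary outcome must contain both classes")
    C = _design(covariates, n)

    def standardize(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v

    Cs = np.column_stack([standardize(C[:, j]) for j in range(1, C.shape[1])]) \
        if C.shape[1] > 1 else np.empty((n, 0))
    X = np.column_stack([np.ones(n), x, Cs])         # regressors
    Z = np.column_stack([np.ones(n), standardize(z), Cs])  # instruments
    k = X.shape[1]

    # start from the naive logistic fit (robust, always defined)
    import statsmodels.api as sm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            theta = np.asarray(sm.Logit(y, X).fit(disp=0, maxiter=50).params)
        except Exception:
            theta = np.zeros(k)
            theta[0] = math.log(max(y.mean(), 1e-6) / max(1 - y.mean(), 1e-6))

    def moments(t: np.ndarray) -> np.ndarray:
        return Z.T @ (y - expit(X @ t)) / n

    def jac(t: np.ndarray) -> np.ndarray:
        p = expit(X @ t)
        return -(Z * (p * (1 - p))[:, None]).T @ X / n

    converged = False
    for _ in range(max_iter):
        g = moments(theta)
        if not np.all(np.isfinite(g)):
            raise EstimationError("GMM moments diverged (separation?)")
        if np.max(np.abs(g)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(jac(theta), g)
        except np.linalg.LinAlgError:
            break
        # full Newton steps (affine-invariant); halve only to stay finite
        lam = 1.0
        for _ in range(30):
            cand = theta - lam * step
            if np.all(np.isfinite(moments(cand))):
                theta = cand
                break
            lam *= 0.5
        else:
            break
    if not converged:
        from scipy.optimize import root
        sol = root(moments, theta, jac=jac, method="hybr",
                   options={"xtol": 1e-12})
        if np.max(np.abs(moments(sol.x))) < max(tol, 1e-8):
            theta, converged = sol.x, True
    # a "root" at a saturated linear predictor is separation, not a solution
    if converged and np.max(np.abs(X @ theta)) > 30:
        converged = False

    p = expit(X @ theta)
    u = y - p
    Gj = -(Z * (p * (1 - p))[:, None]).T @ X / n
    S = (Z * (u ** 2)[:, None]).T @ Z / n
    try:
        Ginv = np.linalg.inv(Gj)
        V = Ginv @ S @ Ginv.T / n
        se = math.sqrt(max(V[1, 1], 0.0))
    except np.linalg.LinAlgError:
        se = float("nan")
        converged = False
    diag = first_stage_f(x, z, covariates)
    note = "" if converged else "GMM iteration did not converge"
    est = IVEstimate(estimate=float(theta[1]), se=se,
                     p=_wald_p(theta[1], se) if se == se else float("nan"),
                     n=n, method="gmm_logistic", converged=converged,
                     note=note, **tags)
    return _flag_weak(est, diag)


# ---------------------------------------------------------------------------
# stratified runs, confounder balance, pleiotropy scatter
# ---------------------------------------------------------------------------

STRATA = ("all", "normal_weight", "overweight_obese", "men", "women")


def stratum_mask(df: pd.DataFrame, stratum: str) -> np.ndarray:
    if stratum == "all":
        return np.ones(len(df), dtype=bool)
    if stratum == "normal_weight":
        return (df["bmi"] < 25).to_numpy()
    if stratum == "overweight_obese":
        return (df["bmi"] >= 25).to_numpy()
    if stratum == "men":
        return (df["sex"] == 0).to_numpy()
    if stratum == "women":
        return (df["sex"] == 1).to_numpy()
    raise ValueError(f"unknown stratum {stratum!r}")


def run_stratified(df: pd.DataFrame, y: np.ndarray, exposure: np.ndarray,
                   instrument: np.ndarray, covariate_cols: list[str],
                   estimator, strata: tuple[str, ...] = STRATA,
                   outcome: str = "", adjustment: str = "partial",
                   estimator_kwargs: dict | None = None,
                   ) -> list[IVEstimate]:
    """Run an estimator within each stratum.

    Sex strata drop ``sex`` from the covariates; exposure/outcome
    standardization is whatever the caller already applied on the full
    sample, so stratum effects stay on a common per-SD scale.  An empty or
    degenerate stratum yields an estimate marked unavailable rather than
    aborting the rest.
    """
    out = []
    estimator_kwargs = estimator_kwargs or {}
    for stratum in strata:
        mask = stratum_mask(df, stratum)
        cols = [c for c in covariate_cols
                if not (stratum in ("men", "women") and c == "sex")]
        tags = {"outcome": outcome, "adjustment": adjustment,
                "stratum": stratum}
        if mask.sum() < len(cols) + 5:
            est = IVEstimate(estimate=float("nan"), se=float("nan"),
                             p=float("nan"), n=int(mask.sum()),
                             method=getattr(estimator, "__name__", "?"),
                             converged=False, note="stratum unavailable "
                             f"(n={int(mask.sum())})", **tags)
        else:
            C = df.loc[mask, cols].to_numpy(dtype=float) if cols else None
            try:
                res = estimator(y[mask], exposure[mask], instrument[mask],
                                C, **estimator_kwargs, **tags)
                est = res[0] if isinstance(res, tuple) else res
            except EstimationError as exc:
                est = IVEstimate(estimate=float("nan"), se=float("nan"),
                                 p=float("nan"), n=int(mask.sum()),
                                 method=getattr(estimator, "__name__", "?"),
                                 converged=False, note=str(exc), **tags)
        out.append(est)
    return out


def confounder_balance(prs: np.ndarray, covariates: pd.DataFrame,
                       ) -> pd.DataFrame:
    """Per-covariate regression of the score on the covariate.

    One row per covariate with the regression coefficient and p-value
    (binary covariates reduce to the two-group mean comparison); no
    multiplicity adjustment.  Constant covariates give an NA row.
    """
    rows = []
    y = np.asarray(prs, float)
    n = y.size
    for name in covariates.columns:
        v = covariates[name].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        if v[ok].std() == 0 or ok.sum() < 3:
            rows.append({"covariate": name, "coefficient": np.nan, "p": np.nan})
            continue
        res = sps.linregress(v[ok], y[ok])
        rows.append({"covariate": name, "coefficient": res.slope,
                     "p": res.pvalue})
    return pd.DataFrame(rows)


def _single_snp_betas(dosages: np.ndarray, trait: np.ndarray,
                      pcs: np.ndarray | None) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP slope and SE from trait ~ dosage + PCs (PC-adjusted OLS)."""
    n, m = dosages.shape
    C = _design(pcs, n)
    t_res = _residualize(trait, C)
    betas = np.full(m, np.nan)
    ses = np.full(m, np.nan)
    dof = n - C.shape[1] - 1
    for j in range(m):
        d = dosages[:, j]
        ok = ~np.isnan(d)
        dj = d.copy()
        dj[~ok] = d[ok].mean() if ok.any() else np.nan
        d_res = _residualize(dj, C)
        denom = float(d_res @ d_res)
        if denom < 1e-12:
            continue  # monomorphic after adjustment
        b = float(d_res @ t_res) / denom
        resid = t_res - b * d_res
        sigma2 = float(resid @ resid) / dof
        betas[j] = b
        ses[j] = math.sqrt(sigma2 / denom)
    return betas, ses


def pleiotropy_scatter(model, dosages: np.ndarray, exposure: np.ndarray,
                       outcome: np.ndarray, pcs: np.ndarray | None,
                       variant_index: dict[str, int],
                       outlier_t: float = 3.0) -> pd.DataFrame:
    """SNP-exposure vs SNP-outcome effect table with outlier flags.

    Per model SNP, PC-adjusted single-SNP regressions give
    (beta_exposure, beta_outcome) with SEs; a through-origin
    inverse-variance-weighted fit of beta_outcome on beta_exposure is the
    reference line, and points whose standardized residual exceeds
    ``outlier_t`` in absolute value are flagged.  Monomorphic SNPs are
    dropped with a warning.
    """
    if model.n_snps == 0:
        raise ValueError("empty score model: no SNPs to plot")
    cols = np.array([variant_index[s] for s in model.weights["snp_id"]])
    G = dosages[:, cols]
    bx, sx = _single_snp_betas(G, exposure, pcs)
    by, sy = _single_snp_betas(G, outcome, pcs)
    ok = ~(np.isnan(bx) | np.isnan(by))
    if (~ok).any():
        warnings.warn(f"dropping {int((~ok).sum())} monomorphic/degenerate "
                      "SNPs from the scatter", UserWarning)
    w = 1.0 / sy[ok] ** 2
    slope = float((w * bx[ok] * by[ok]).sum() / (w * bx[ok] ** 2).sum())
    # studentized residual: both axes' sampling errors propagate into the
    # vertical deviation from the fitted line
    stud = (by - slope * bx) / np.sqrt(sy ** 2 + slope ** 2 * sx ** 2)
    table = pd.DataFrame({
        "snp_id": model.weights["snp_id"].values,
        "beta_exposure": bx, "se_exposure": sx,
        "beta_outcome": by, "se_outcome": sy,
        "studentized_residual": stud,
        "outlier": np.abs(stud) > outlier_t,
        "ivw_slope": slope,
    })
    return table[ok.tolist()].reset_index(drop=True)
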