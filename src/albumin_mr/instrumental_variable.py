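"""Instrumental-variable estimators for the albumin -> blood-pressure and
albumin -> hypertension-hazard effects.

Linear side: ordinary least squares, two-stage least squares with a
genotype instrument (dominant coding by convention), the first-stage
Wald F, and the Durbin-Wu-Hausman endogeneity test in its augmented-
regression (control-function) form, with the classical contrast form
retained as a cross-check.

Survival side: the two-stage residual-inclusion (2SRI / control function)
Cox estimator — first-stage OLS of the exposure on instrument plus
covariates, then a Cox model including the first-stage residual — whose
exposure coefficient is the causal log hazard ratio per g/dL.  Confidence
intervals default to the naive stage-2 Wald interval; a subject-level
bootstrap re-running both stages is available and labelled as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .survival_models import SurvivalData, CoxFit, fit_cox, Z975

__all__ = [
    "IVEstimate",
    "TSRIFit",
    "WeakInstrumentWarning",
    "fit_ols",
    "fit_2sls",
    "dwh_test",
    "dwh_contrast_test",
    "fit_2sri_cox",
    "tsri_bootstrap_ci",
]

WEAK_F_THRESHOLD = 10.0


class WeakInstrumentWarning(UserWarning):
    pass


class RankError(ValueError):
    pass


@dataclass
class IVEstimate:
    beta: float
    se: float
    p: float
    estimator: str                 # "ols" | "tsls"
    n: int
    first_stage_F: float | None = None
    dwh_p: float | None = None
    covariate_set: str = ""

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("standard error must be positive")


@dataclass
class TSRIFit:
    log_hr: float
    se: float
    hr: float
    ci: tuple[float, float]
    p: float
    resid_coef: float
    resid_p: float
    first_stage_F: float
    n: int
    ci_method: str = "wald-naive"
    cox_fit: CoxFit | None = None


def _design(n: int, covariates) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    return np.column_stack([np.ones(n), C])


def _check_rank(M: np.ndarray, what: str) -> None:
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise RankError(f"collinear design in {what}")


def _ols_core(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least squares with classical covariance; returns (beta, vcov, rss)."""
    _check_rank(X, "least squares")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    dof = X.shape[0] - X.shape[1]
    if dof <= 0:
        raise ValueError("more parameters than observations")
    sigma2 = resid @ resid / dof
    vcov = sigma2 * np.linalg.inv(X.T @ X)
    return beta, vcov, float(resid @ resid)


def fit_ols(outcome, exposure, covariates=None, covariate_set: str = "") -> IVEstimate:
    """OLS slope of the outcome on the exposure, adjusted for covariates."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    W = _design(len(y), covariates)
    X = np.column_stack([W, x])
    beta, vcov, _ = _ols_core(y, X)
    dof = len(y) - X.shape[1]
    b, se = beta[-1], np.sqrt(vcov[-1, -1])
    p = 2.0 * stats.t.sf(abs(b / se), dof)
    return IVEstimate(
        beta=float(b), se=float(se), p=float(p),
        estimator="ols", n=len(y), covariate_set=covariate_set,
    )


def _first_stage(
    x: np.ndarray, z: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Stage-1 regression x ~ W + z; returns (fitted, residuals, Wald F)."""
    Z = z if z.ndim == 2 else z[:, None]
    if np.all(Z.std(axis=0) == 0):
        raise ValueError("instrument is constant; cannot identify the effect")
    X1 = np.column_stack([W, Z])
    beta1, _, rss_u = _ols_core(x, X1)
    _, _, rss_r = _ols_core(x, W)
    q = Z.shape[1]
    dof = len(x) - X1.shape[1]
    F = ((rss_r - rss_u) / q) / (rss_u / dof) if rss_u > 0 else np.inf
    fitted = X1 @ beta1
    return fitted, x - fitted, float(F)


def fit_2sls(
    outcome, exposure, instrument, covariates=None, covariate_set: str = ""
) -> IVEstimate:
    """Two-stage least squares with a genotype instrument.

    Stage 1 regresses the exposure on instrument + covariates; stage 2
    regresses the outcome on the fitted exposure + covariates.  The
    standard error uses residuals evaluated at the *observed* exposure
    (the proper 2SLS variance).  A first-stage F below 10 triggers a
    weak-instrument warning but the estimate is still returned.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    W = _design(len(y), covariates)
    fitted, _, F = _first_stage(x, z, W)
    if F < WEAK_F_THRESHOLD:
        warnings.warn(
            f"weak instrument: first-stage F = {F:.2f} < {WEAK_F_THRESHOLD}",
            WeakInstrumentWarning,
        )
    X2 = np.column_stack([W, fitted])
    _check_rank(X2, "second stage")
    beta2 = np.linalg.lstsq(X2, y, rcond=None)[0]
    # variance from residuals at the observed exposure
    X_obs = np.column_stack([W, x])
    resid = y - X_obs @ beta2
    dof = len(y) - X2.shape[1]
    sigma2 = resid @ resid / dof
    vcov = sigma2 * np.linalg.inv(X2.T @ X2)
    b, se = beta2[-1], np.sqrt(vcov[-1, -1])
    p = 2.0 * stats.t.sf(abs(b / se), dof)
    return IVEstimate(
        beta=float(b), se=float(se), p=float(p),
        estimator="tsls", n=len(y), first_stage_F=F, covariate_set=covariate_set,
    )


def dwh_test(outcome, exposure, instrument, covariates=None) -> tuple[float, float]:
    """Durbin-Wu-Hausman endogeneity test, augmented-regression form.

    Adds the first-stage residual to the outcome OLS and t-tests its
    coefficient; a small p indicates the exposure is endogenous and the
    OLS and IV estimands differ.  Returns (t statistic, two-sided p);
    (nan, nan) when the first-stage residuals are identically zero.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    W = _design(len(y), covariates)
    _, vhat, _ = _first_stage(x, z, W)
    if np.allclose(vhat, 0.0, atol=1e-12):
        return np.nan, np.nan
    X = np.column_stack([W, x, vhat])
    beta, vcov, _ = _ols_core(y, X)
    dof = len(y) - X.shape[1]
    t = beta[-1] / np.sqrt(vcov[-1, -1])
    return float(t), float(2.0 * stats.t.sf(abs(t), dof))


def dwh_contrast_test(outcome, exposure, instrument, covariates=None):
    """Classical Hausman contrast (b_IV - b_OLS)^2 / (V_IV - V_OLS).

    Cross-check for the augmented-regression form.  The two exposure-slope
    variances are evaluated at a common error-variance estimate (the one
    from the augmented regression), which makes the contrast algebraically
    identical to the squared augmented-regression t statistic.  Returns
    (chi2, p), or (nan, nan) when the variance difference is non-positive.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    W = _design(len(y), covariates)
    fitted, vhat, _ = _first_stage(x, z, W)
    if np.allclose(vhat, 0.0, atol=1e-12):
        return np.nan, np.nan
    # common sigma^2 from the augmented (control-function) regression
    _, _, rss_aug = _ols_core(y, np.column_stack([W, x, vhat]))
    sigma2 = rss_aug / (len(y) - W.shape[1] - 2)

    b_ols = _ols_core(y, np.column_stack([W, x]))[0][-1]
    b_iv = _ols_core(y, np.column_stack([W, fitted]))[0][-1]

    def slope_var(col):
        M = np.column_stack([W, col])
        return sigma2 * np.linalg.inv(M.T @ M)[-1, -1]

    dv = slope_var(fitted) - slope_var(x)
    if dv <= 0:
        return np.nan, np.nan
    stat = (b_iv - b_ols) ** 2 / dv
    return float(stat), float(stats.chi2.sf(stat, 1))


def fit_2sri_cox(
    time,
    event,
    exposure,
    instrument,
    covariates: pd.DataFrame | np.ndarray | None = None,
    covariate_names: list[str] | None = None,
    ties: str = "breslow",
) -> TSRIFit:
    """Two-stage residual inclusion: causal hazard ratio per g/dL albumin.

    Stage 1: OLS of the exposure on instrument + covariates, keeping the
    residual.  Stage 2: Cox model on exposure + residual + covariates; the
    exposure coefficient is the causal log-HR and the residual term's p
    serves as an endogeneity diagnostic.  The default CI is the naive
    stage-2 Wald interval (ignoring first-stage uncertainty); see
    ``tsri_bootstrap_ci`` for the subject-level bootstrap alternative.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    if covariates is None:
        C = np.empty((len(t), 0))
        names = []
    elif isinstance(covariates, pd.DataFrame):
        C = covariates.to_numpy(dtype=float)
        names = list(covariates.columns)
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        names = covariate_names or [f"cov{i}" for i in range(C.shape[1])]
    W = np.column_stack([np.ones(len(t)), C]) if C.size else np.ones((len(t), 1))
    _, vhat, F = _first_stage(x, z, W)
    if np.allclose(vhat, vhat * 0, atol=1e-12) or np.corrcoef(x, vhat)[0, 1] > 1 - 1e-12:
        raise RankError("first-stage residuals collinear with exposure")

    cols = {"albumin_exposure": x, "stage1_residual": vhat}
    for i, nm in enumerate(names):
        cols[nm] = C[:, i]
    frame = pd.DataFrame(cols)
    data = SurvivalData(time=t, event=e, covariates=frame)
    fit = fit_cox(data, ties=ties)
    idx = fit.names.index("albumin_exposure")
    ridx = fit.names.index("stage1_residual")
    b, se = float(fit.coef[idx]), float(fit.se[idx])
    ci = (np.exp(b - Z975 * se), np.exp(b + Z975 * se))
    return TSRIFit(
        log_hr=b,
        se=se,
        hr=float(np.exp(b)),
        ci=(float(ci[0]), float(ci[1])),
        p=float(fit.p[idx]),
        resid_coef=float(fit.coef[ridx]),
        resid_p=float(fit.p[ridx]),
        first_stage_F=F,
        n=len(t),
        ci_method="wald-naive",
        cox_fit=fit,
    )


def tsri_bootstrap_ci(
    time,
    event,
    exposure,
    instrument,
    covariates=None,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Subject-level bootstrap percentile CI for the 2SRI hazard ratio.

    Re-runs both stages on each resample; deterministic under a fixed
    seed.  Raises if more than 20% of replicates fail to converge.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be at least 100")
    rng = np.random.default_rng(seed)
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    x = np.asarray(exposure, dtype=float)
    z = np.asarray(instrument, dtype=float)
    C = None
    if covariates is not None:
        C = (
            covariates.to_numpy(dtype=float)
            if isinstance(covariates, pd.DataFrame)
            else np.asarray(covariates, dtype=float)
        )
        if C.ndim == 1:
            C = C[:, None]
    n = len(t)
    draws = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = fit_2sri_cox(
                    t[idx], e[idx], x[idx], z[idx],
                    C[idx] if C is not None else None,
                )
            draws.append(fit.log_hr)
        except Exception:
            failures += 1
    if failures > 0.2 * n_boot:
        raise RuntimeError(
            f"{failures}/{n_boot} bootstrap replicates failed to converge"
        )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [alpha, 1.0 - alpha])
    return float(np.exp(lo)), float(np.exp(hi))
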