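"""Restricted cubic splines for the albumin dose-response curves.

Harrell's restricted truncated-power basis: with knots t1 < ... < tk the
model uses the linear term plus k-2 cubic terms that are constrained to be
linear beyond the boundary knots; terms are scaled by (tk - t1)^2 for
numerical conditioning.  Two fits are provided: an OLS spline for the
blood-pressure-change outcome and a Cox spline for the hypertension
hazard, both reported as curves relative to a reference exposure value
(4.0 g/dL by convention here) with pointwise delta-method confidence
intervals, plus a Wald test that all nonlinear coefficients vanish.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .survival_models import SurvivalData, fit_cox, Z975

__all__ = [
    "RCSBasis",
    "RCSCurve",
    "default_knots",
    "rcs_basis",
    "fit_rcs_linear",
    "fit_rcs_cox",
    "nonlinearity_test",
]


@dataclass
class RCSBasis:
    knots: np.ndarray
    matrix: np.ndarray     # (n, k-1): linear column then k-2 restricted terms
    scale: float           # (tk - t1)^2


@dataclass
class RCSCurve:
    grid: np.ndarray
    effect: np.ndarray         # difference (linear) or hazard ratio (cox)
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    reference: float
    scale: str                 # "difference" | "hazard-ratio"
    knots: np.ndarray
    spline_coef: np.ndarray
    spline_vcov: np.ndarray
    nonlinear_wald: tuple[float, int, float]  # (statistic, df, p)


def default_knots(x: np.ndarray, n_knots: int = 4) -> np.ndarray:
    """Knots at outer 5th/95th and equally spaced inner percentiles."""
    x = np.asarray(x, dtype=float)
    if n_knots == 4:
        q = [5, 35, 65, 95]
    elif n_knots == 3:
        q = [10, 50, 90]
    elif n_knots == 5:
        q = [5, 27.5, 50, 72.5, 95]
    else:
        q = np.linspace(5, 95, n_knots)
    knots = np.percentile(x[np.isfinite(x)], q)
    if len(np.unique(knots)) != len(knots):
        raise ValueError("duplicate knots; exposure distribution too coarse")
    return knots


def _rcs_columns(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    k = len(knots)
    scale = (knots[-1] - knots[0]) ** 2

    def cube(u):
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    denom = knots[-1] - knots[-2]
    for j in range(k - 2):
        tj = knots[j]
        term = (
            cube(x - tj)
            - cube(x - knots[-2]) * (knots[-1] - tj) / denom
            + cube(x - knots[-1]) * (knots[-2] - tj) / denom
        )
        cols.append(term / scale)
    return np.column_stack(cols)


def rcs_basis(x, knots) -> RCSBasis:
    """Restricted cubic basis: x plus k-2 scaled restricted cubic terms."""
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    if len(knots) < 3:
        raise ValueError("at least three knots are required")
    if len(np.unique(knots)) != len(knots):
        raise ValueError("knots must be distinct")
    return RCSBasis(
        knots=knots,
        matrix=_rcs_columns(x, knots),
        scale=float((knots[-1] - knots[0]) ** 2),
    )


def _wald_nonlinear(coef: np.ndarray, vcov: np.ndarray) -> tuple[float, int, float]:
    """Wald test that the k-2 nonlinear spline coefficients are all zero."""
    nl = coef[1:]
    V = vcov[1:, 1:]
    df = len(nl)
    if df == 0:
        return np.nan, 0, np.nan
    try:
        stat = float(nl @ np.linalg.solve(V, nl))
    except np.linalg.LinAlgError:
        return np.nan, df, np.nan
    return stat, df, float(stats.chi2.sf(stat, df))


def _curve_ci(basis_grid, basis_ref, coef, vcov):
    contrast = basis_grid - basis_ref
    effect = contrast @ coef
    var = np.einsum("ij,jk,ik->i", contrast, vcov, contrast)
    sd = np.sqrt(np.maximum(var, 0.0))
    return effect, effect - Z975 * sd, effect + Z975 * sd


def _resolve_grid_ref(x, knots, reference, grid):
    x = np.asarray(x, dtype=float)
    if grid is None:
        lo, hi = np.percentile(x, [1, 99])
        grid = np.linspace(lo, hi, 101)
        if not (grid[0] <= reference <= grid[-1]):
            grid = np.sort(np.append(grid, reference))
    grid = np.asarray(grid, dtype=float)
    if reference < knots[0] or reference > knots[-1]:
        warnings.warn(
            f"reference {reference} lies outside the knot span; extrapolating"
        )
    return grid


def fit_rcs_linear(
    outcome,
    exposure,
    covariates=None,
    knots=None,
    reference: float = 4.0,
    grid=None,
) -> RCSCurve:
    """OLS restricted-cubic-spline curve of the outcome versus exposure.

    Returns the fitted spline effect minus its value at the reference
    exposure, with pointwise delta-method 95% CIs; the curve is exactly 0
    with zero-width CI at the reference.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float)) if knots is not None else default_knots(x)
    basis = rcs_basis(x, knots)
    n = len(y)
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    X = np.column_stack([np.ones(n), C, basis.matrix])
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    resid = y - X @ beta
    dof = n - X.shape[1]
    sigma2 = resid @ resid / dof
    vcov = sigma2 * np.linalg.inv(X.T @ X)
    s = 1 + C.shape[1]
    coef = beta[s:]
    V = vcov[s:, s:]

    grid = _resolve_grid_ref(x, knots, reference, grid)
    bg = _rcs_columns(grid, knots)
    br = _rcs_columns(np.asarray([reference]), knots)
    effect, lo, hi = _curve_ci(bg, br, coef, V)
    return RCSCurve(
        grid=grid, effect=effect, ci_lower=lo, ci_upper=hi,
        reference=reference, scale="difference", knots=knots,
        spline_coef=coef, spline_vcov=V,
        nonlinear_wald=_wald_nonlinear(coef, V),
    )


def fit_rcs_cox(
    time,
    event,
    exposure,
    covariates: pd.DataFrame | np.ndarray | None = None,
    knots=None,
    reference: float = 4.0,
    grid=None,
    ties: str = "breslow",
) -> RCSCurve:
    """Cox restricted-cubic-spline hazard-ratio curve versus exposure.

    HR(x) = exp(spline(x) - spline(reference)); exactly 1 at the
    reference, pointwise delta-method CI on the log scale.
    """
    x = np.asarray(exposure, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float)) if knots is not None else default_knots(x)
    basis = rcs_basis(x, knots)
    cols = {f"rcs_{j}": basis.matrix[:, j] for j in range(basis.matrix.shape[1])}
    if covariates is not None:
        if isinstance(covariates, pd.DataFrame):
            for nm in covariates.columns:
                cols[nm] = covariates[nm].to_numpy(dtype=float)
        else:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            for i in range(C.shape[1]):
                cols[f"cov{i}"] = C[:, i]
    frame = pd.DataFrame(cols)
    data = SurvivalData(
        time=np.asarray(time, dtype=float),
        event=np.asarray(event, dtype=bool),
        covariates=frame,
    )
    fit = fit_cox(data, ties=ties)
    ns = basis.matrix.shape[1]
    coef = fit.coef[:ns]
    V = fit.vcov[:ns, :ns]

    grid = _resolve_grid_ref(x, knots, reference, grid)
    bg = _rcs_columns(grid, knots)
    br = _rcs_columns(np.asarray([reference]), knots)
    log_hr, lo, hi = _curve_ci(bg, br, coef, V)
    return RCSCurve(
        grid=grid,
        effect=np.exp(log_hr),
        ci_lower=np.exp(lo),
        ci_upper=np.exp(hi),
        reference=reference,
        scale="hazard-ratio",
        knots=knots,
        spline_coef=coef,
        spline_vcov=V,
        nonlinear_wald=_wald_nonlinear(coef, V),
    )


def nonlinearity_test(curve: RCSCurve) -> tuple[float, int, float]:
    """Wald test that the spline's nonlinear coefficients are all zero.

    Returns (statistic, df, p) with df = k - 2.
    """
    return curve.nonlinear_wald


def curve_frame(curve: RCSCurve) -> pd.DataFrame:
    col = "delta_bp" if curve.scale == "difference" else "hazard_ratio"
    return pd.DataFrame(
        {
            "albumin": curve.grid,
            col: curve.effect,
            "ci_lower": curve.ci_lower,
            "ci_upper": curve.ci_upper,
        }
    )
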