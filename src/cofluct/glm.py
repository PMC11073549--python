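"""Mass-univariate OLS with optional AR(1) prewhitening and contrasts.

This is the estimator shared by the node-activation, edge and gPPI
analyses: many target series (regions, edges, or one seed-pair series)
regressed on one design matrix.  Prewhitening follows the classical
Cochrane-Orcutt one-step scheme: the lag-1 autocorrelation of each
target's OLS residuals is estimated, then both sides of the regression
are transformed (first row scaled by sqrt(1 - rho^2), subsequent rows
differenced with weight rho) and the model is refitted.  Degrees of
freedom are frames minus design rank; the small additional loss induced
by estimating rho is ignored, as is standard practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import stats

from .regressors import DesignMatrix

__all__ = [
    "GLMFit",
    "ContrastResult",
    "RankDeficientError",
    "ar1_prewhiten",
    "ols_fit",
    "fit_glm",
    "contrast",
]

_RHO_CLIP = 0.999


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is rank deficient; names the collinear columns."""


def _as_matrix(X: Union[DesignMatrix, np.ndarray]) -> Tuple[np.ndarray, Optional[Sequence[str]]]:
    if isinstance(X, DesignMatrix):
        return X.values, X.names
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, None


def _check_rank(Xv: np.ndarray, names: Optional[Sequence[str]]) -> int:
    rank = np.linalg.matrix_rank(Xv)
    if rank < Xv.shape[1]:
        # identify dependent columns from the pivoted QR diagonal
        _, R = np.linalg.qr(Xv)
        diag = np.abs(np.diag(R))
        tol = diag.max() * max(Xv.shape) * np.finfo(float).eps if diag.size else 0.0
        bad = np.where(diag <= tol)[0]
        labels = [names[i] if names is not None else str(i) for i in bad]
        raise RankDeficientError(
            f"design matrix is rank deficient (rank {rank} < {Xv.shape[1]}); "
            f"suspect columns: {labels}"
        )
    return rank


def _as_targets(y: np.ndarray) -> Tuple[np.ndarray, bool]:
    y = np.asarray(y, dtype=float)
    was_1d = y.ndim == 1
    if was_1d:
        y = y[:, None]
    return y, was_1d


@dataclass
class GLMFit:
    """Fitted mass-univariate GLM.

    Attributes
    ----------
    betas : ndarray, (n_regressors, n_targets)
    sigma2 : ndarray, (n_targets,)
        Residual variance, RSS / dof.
    dof : float
        Residual degrees of freedom, usable frames minus design rank.
    rho : ndarray, (n_targets,)
        Estimated AR(1) coefficient per target (0 when prewhitening is off).
    design_rank : int
    xtx_inv : ndarray, (n_regressors, n_regressors) or (n_targets, p, p)
        Inverse normal-equations matrix; per-target when prewhitening made
        the effective design target specific.
    names : column names of the design, when available.
    """

    betas: np.ndarray
    sigma2: np.ndarray
    dof: float
    rho: np.ndarray
    design_rank: int
    xtx_inv: np.ndarray
    names: Optional[Sequence[str]] = None

    @property
    def n_targets(self) -> int:
        return self.betas.shape[1]


@dataclass
class ContrastResult:
    """Contrast estimate with t and two-sided p per target."""

    effect: np.ndarray
    t: np.ndarray
    p: np.ndarray
    dof: float

    def __post_init__(self) -> None:
        self.effect = np.atleast_1d(np.asarray(self.effect, dtype=float))
        self.t = np.atleast_1d(np.asarray(self.t, dtype=float))
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))


def _standardize_inputs(y: np.ndarray, Xv: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Z-score targets and non-constant design columns (ddof=1)."""
    y = (y - y.mean(axis=0)) / y.std(axis=0, ddof=1)
    Xv = Xv.copy()
    for j in range(Xv.shape[1]):
        col = Xv[:, j]
        sd = col.std(ddof=1)
        if sd > 0:
            Xv[:, j] = (col - col.mean()) / sd
    return y, Xv


def ar1_prewhiten(
    y: np.ndarray,
    X: Union[DesignMatrix, np.ndarray],
    pool_rho: bool = False,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Estimate AR(1) residual autocorrelation and whiten both sides.

    rho is the lag-1 autocorrelation of each target's OLS residuals
    (clipped to (-0.999, 0.999)); with ``pool_rho`` a single rho (the mean
    across targets) is applied everywhere.  The transform scales row 0 by
    sqrt(1 - rho^2) and replaces row t by row_t - rho * row_{t-1}, applied
    to both the targets and the design.

    Returns
    -------
    y_white : ndarray (n_frames, n_targets)
    X_white : ndarray (n_frames, p) if y was 1-D or rho is pooled,
        else (n_targets, n_frames, p).
    rho : ndarray (n_targets,)
    """
    y, was_1d = _as_targets(y)
    Xv, names = _as_matrix(X)
    if y.shape[0] < 3:
        raise ValueError("prewhitening needs at least 3 frames")
    _check_rank(Xv, names)

    beta, *_ = np.linalg.lstsq(Xv, y, rcond=None)
    resid = y - Xv @ beta
    num = np.sum(resid[1:] * resid[:-1], axis=0)
    den = np.sum(resid * resid, axis=0)
    # residuals at rounding-noise level mean an exact fit: rho is 0 there
    tol = np.finfo(float).eps ** 1.5 * (np.sum(y * y, axis=0) + 1.0)
    ok = den > tol
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(ok, num / np.where(ok, den, 1.0), 0.0)
    rho = np.clip(rho, -_RHO_CLIP, _RHO_CLIP)
    if pool_rho:
        rho = np.full_like(rho, rho.mean())

    scale0 = np.sqrt(1.0 - rho**2)
    yw = np.empty_like(y)
    yw[0] = y[0] * scale0
    yw[1:] = y[1:] - rho[None, :] * y[:-1]

    if was_1d or np.allclose(rho, rho[0]):
        r = rho[0]
        Xw = np.empty_like(Xv)
        Xw[0] = Xv[0] * np.sqrt(1.0 - r**2)
        Xw[1:] = Xv[1:] - r * Xv[:-1]
        if was_1d:
            return yw[:, 0][:, None], Xw, rho
        return yw, Xw, rho

    k = y.shape[1]
    Xw = np.empty((k, Xv.shape[0], Xv.shape[1]))
    Xw[:, 0, :] = Xv[0][None, :] * scale0[:, None]
    Xw[:, 1:, :] = Xv[None, 1:, :] - rho[:, None, None] * Xv[None, :-1, :]
    return yw, Xw, rho


def _zero_tiny_rss(rss: np.ndarray, yv: np.ndarray) -> np.ndarray:
    """Clamp residual sums at rounding-noise level to exactly zero."""
    tol = np.finfo(float).eps ** 1.5 * (np.sum(yv * yv, axis=0) + 1.0)
    return np.where(rss <= tol, 0.0, rss)


def _solve_shared(yv: np.ndarray, Xv: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    beta, *_ = np.linalg.lstsq(Xv, yv, rcond=None)
    resid = yv - Xv @ beta
    rss = _zero_tiny_rss(np.sum(resid**2, axis=0), yv)
    xtx_inv = np.linalg.inv(Xv.T @ Xv)
    return beta, rss, xtx_inv


def ols_fit(
    y: np.ndarray,
    X: Union[DesignMatrix, np.ndarray],
    standardize: bool = False,
) -> GLMFit:
    """Ordinary least squares of many targets on one shared design."""
    y, _ = _as_targets(y)
    Xv, names = _as_matrix(X)
    if y.shape[0] != Xv.shape[0]:
        raise ValueError("y and X disagree on frame count")
    if Xv.shape[0] < Xv.shape[1]:
        raise ValueError("fewer frames than design columns")
    rank = _check_rank(Xv, names)
    if standardize:
        y, Xv = _standardize_inputs(y, Xv)
    beta, rss, xtx_inv = _solve_shared(y, Xv)
    dof = y.shape[0] - rank
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    sigma2 = rss / dof
    return GLMFit(
        betas=beta,
        sigma2=sigma2,
        dof=float(dof),
        rho=np.zeros(y.shape[1]),
        design_rank=rank,
        xtx_inv=xtx_inv,
        names=names,
    )


def fit_glm(
    y: np.ndarray,
    X: Union[DesignMatrix, np.ndarray],
    prewhiten: bool = True,
    standardize: bool = False,
    pool_rho: bool = False,
) -> GLMFit:
    """Fit the GLM with the pipeline defaults (AR(1) prewhitening on).

    When prewhitening is on, rho generally differs across targets, so the
    whitened design is target specific and the normal equations are
    solved in a batched pass.
    """
    y, _ = _as_targets(y)
    Xv, names = _as_matrix(X)
    if y.shape[0] != Xv.shape[0]:
        raise ValueError("y and X disagree on frame count")
    rank = _check_rank(Xv, names)
    if standardize:
        y, Xv = _standardize_inputs(y, Xv)
    if not prewhiten:
        fit = ols_fit(y, Xv, standardize=False)
        fit.names = names
        return fit

    yw, Xw, rho = ar1_prewhiten(y, Xv, pool_rho=pool_rho)
    dof = y.shape[0] - rank
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    if Xw.ndim == 2:
        beta, rss, xtx_inv = _solve_shared(yw, Xw)
    else:
        # batched per-target normal equations: G_k b_k = X_k' y_k
        G = np.einsum("ktp,ktq->kpq", Xw, Xw)
        b = np.einsum("ktp,tk->kp", Xw, yw)
        xtx_inv = np.linalg.inv(G)
        beta = np.einsum("kpq,kq->kp", xtx_inv, b).T  # (p, k)
        fitted = np.einsum("ktp,pk->tk", Xw, beta)
        rss = _zero_tiny_rss(np.sum((yw - fitted) ** 2, axis=0), yw)
    sigma2 = rss / dof
    return GLMFit(
        betas=beta,
        sigma2=sigma2,
        dof=float(dof),
        rho=rho,
        design_rank=rank,
        xtx_inv=xtx_inv,
        names=names,
    )


def contrast(fit: GLMFit, c: Union[np.ndarray, Dict[str, float]], X: Optional[DesignMatrix] = None) -> ContrastResult:
    """Estimate c'beta with its t-statistic and two-sided p per target.

    ``c`` may be a weight vector or a {column_name: weight} mapping (the
    latter requires column names on the fit or an explicit DesignMatrix).
    Targets with zero residual variance get a +/-inf t sentinel with
    p = 0 (or t = 0, p = 1 when the effect is itself zero) and a warning.
    """
    if isinstance(c, dict):
        names = X.names if X is not None else fit.names
        if names is None:
            raise ValueError("named contrast requires design column names")
        vec = np.zeros(fit.betas.shape[0])
        for name, w in c.items():
            vec[list(names).index(name)] = w
        c = vec
    c = np.asarray(c, dtype=float)
    if c.shape[0] != fit.betas.shape[0]:
        raise ValueError("contrast length does not match regressor count")
    if not np.any(c):
        raise ValueError("contrast vector is all zero")

    effect = c @ fit.betas
    if fit.xtx_inv.ndim == 2:
        quad = float(c @ fit.xtx_inv @ c)
        var = fit.sigma2 * quad
    else:
        quad = np.einsum("p,kpq,q->k", c, fit.xtx_inv, c)
        var = fit.sigma2 * quad

    var = np.atleast_1d(np.asarray(var, dtype=float))
    effect = np.atleast_1d(effect)
    t = np.zeros_like(effect)
    ok = var > 0
    t[ok] = effect[ok] / np.sqrt(var[ok])
    if np.any(~ok):
        warnings.warn("zero residual variance for some targets; t set to sentinel values")
        degenerate = ~ok & (effect != 0)
        t[degenerate] = np.sign(effect[degenerate]) * np.inf
    p = np.ones_like(t)
    finite = np.isfinite(t)
    p[finite] = 2.0 * stats.t.sf(np.abs(t[finite]), fit.dof)
    p[~finite] = 0.0
    return ContrastResult(effect=effect, t=t, p=p, dof=fit.dof)
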