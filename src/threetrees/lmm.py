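"""Gaussian linear mixed model with a single random intercept per cluster.

The model is ``y = W b + u_cluster + e`` with ``u_j ~ N(0, sigma_u^2)`` and
``e ~ N(0, sigma_e^2)``.  Writing ``theta = sigma_u^2 / sigma_e^2``, the
marginal covariance is ``sigma_e^2 (I + theta Z Z')`` with Z the cluster
indicator matrix, whose inverse acts cluster-wise in closed form.  Both the
fixed effects (by GLS) and the residual variance profile out, leaving a
one-dimensional (restricted) likelihood in ``log theta`` that is maximised
by bounded scalar search.  Cluster random intercepts are recovered as
shrunken cluster-mean residuals (BLUPs):

    u_j = (n_j * theta / (1 + n_j * theta)) * mean residual of cluster j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

__all__ = ["MixedFit", "fit_mixed", "predict_mixed", "icc", "RankDeficientError"]

_LOG_THETA_BOUNDS = (-12.0, 12.0)


class RankDeficientError(ValueError):
    """Raised when the fixed-effect design is not of full column rank."""


@dataclass
class MixedFit:
    """A fitted random-intercept linear mixed model."""

    params: pd.Series  # fixed-effect estimates, indexed by column name
    se: pd.Series
    pvalues: pd.Series
    sigma_u2: float
    sigma_e2: float
    u: dict  # cluster label -> BLUP intercept
    criterion: float  # maximised (restricted) log-likelihood
    method: str = "reml"
    converged: bool = True
    n_obs: int = 0
    n_clusters: int = 0
    cov_params: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def theta(self) -> float:
        return self.sigma_u2 / self.sigma_e2

    def summary_frame(self) -> pd.DataFrame:
        """Coefficient table (term, estimate, SE, p)."""
        return pd.DataFrame(
            {"estimate": self.params, "se": self.se, "p_value": self.pvalues}
        )


def _check_rank(W: np.ndarray, names: Sequence[str]) -> None:
    _, R, piv = linalg.qr(W, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(W.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < W.shape[1]:
        bad = [names[i] for i in piv[rank:]]
        raise RankDeficientError(
            f"fixed-effect design is rank deficient; collinear columns: {bad}"
        )


def fit_mixed(
    W: np.ndarray,
    y: np.ndarray,
    cluster: np.ndarray,
    names: Optional[Sequence[str]] = None,
    method: str = "reml",
) -> MixedFit:
    """Fit the random-intercept model by REML (default) or ML.

    Parameters
    ----------
    W
        Fixed-effect design matrix including any intercept column.
    y
        Response vector.
    cluster
        Cluster label per row (any hashable labels).
    names
        Column names for ``W``; defaults to ``b0, b1, ...``.
    method
        ``"reml"`` (variance components corrected for fixed-effect
        estimation) or ``"ml"``.
    """
    W = np.asarray(W, dtype=float)
    y = np.asarray(y, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    n, p = W.shape
    if names is None:
        names = [f"b{i}" for i in range(p)]
    names = list(names)
    if method not in ("reml", "ml"):
        raise ValueError("method must be 'reml' or 'ml'")
    _check_rank(W, names)

    codes, labels = pd.factorize(np.asarray(cluster))
    J = len(labels)
    nj = np.bincount(codes, minlength=J).astype(float)

    def cluster_sums(M: np.ndarray) -> np.ndarray:
        if M.ndim == 1:
            return np.bincount(codes, weights=M, minlength=J)
        return np.column_stack(
            [np.bincount(codes, weights=M[:, k], minlength=J) for k in range(M.shape[1])]
        )

    Wc = cluster_sums(W)  # J x p cluster sums
    yc = cluster_sums(y)
    WtW = W.T @ W
    Wty = W.T @ y
    yty = float(y @ y)
    dof = n - p if method == "reml" else n

    def profile(theta: float):
        """GLS pieces at V* = I + theta*ZZ': returns (crit, beta, q, A)."""
        w = theta / (1.0 + nj * theta)  # per-cluster shrinkage weight
        A = WtW - (Wc * w[:, None]).T @ Wc  # W' V*^-1 W
        b = Wty - Wc.T @ (w * yc)  # W' V*^-1 y
        beta = np.linalg.solve(A, b)
        r = y - W @ beta
        rc = cluster_sums(r)
        q = float(r @ r - (w * rc * rc).sum())  # r' V*^-1 r
        logdet_v = float(np.log1p(nj * theta).sum())
        crit = logdet_v + dof * np.log(q)
        if method == "reml":
            sign, logdet_a = np.linalg.slogdet(A)
            crit += logdet_a
        return crit, beta, q, A

    def objective(log_theta: float) -> float:
        return profile(np.exp(log_theta))[0]

    res = optimize.minimize_scalar(
        objective, bounds=_LOG_THETA_BOUNDS, method="bounded",
        options={"xatol": 1e-9},
    )
    if not np.isfinite(res.fun):
        raise ValueError("non-finite mixed-model likelihood")
    log_theta = float(res.x)
    # boundary handling: variance component estimated at (numerical) zero
    at_zero = False
    if log_theta <= _LOG_THETA_BOUNDS[0] + 1e-6 or profile(0.0)[0] <= res.fun:
        at_zero = True
        log_theta = -np.inf
    theta = 0.0 if at_zero else float(np.exp(log_theta))
    if at_zero:
        warnings.warn(
            "between-cluster variance estimated at the boundary; sigma_u2 set to 0",
            stacklevel=2,
        )

    crit, beta, q, A = profile(theta)
    sigma_e2 = q / dof
    sigma_u2 = theta * sigma_e2

    # BLUPs: shrunken cluster-mean residuals
    r = y - W @ beta
    rc = cluster_sums(r)
    w = theta / (1.0 + nj * theta)
    u_vals = w * rc
    u = {lab: float(val) for lab, val in zip(labels, u_vals)}

    cov_beta = sigma_e2 * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov_beta))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    # full (restricted) log-likelihood at the optimum
    loglik = -0.5 * (crit + dof * (np.log(2.0 * np.pi) + 1.0 - np.log(dof)))

    return MixedFit(
        params=pd.Series(beta, index=names),
        se=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma_u2=float(sigma_u2),
        sigma_e2=float(sigma_e2),
        u=u,
        criterion=float(loglik),
        method=method,
        converged=True,
        n_obs=n,
        n_clusters=J,
        cov_params=cov_beta,
    )


def predict_mixed(
    fit: MixedFit,
    W: np.ndarray,
    cluster: Optional[np.ndarray] = None,
    include_random: bool = False,
) -> np.ndarray:
    """Predict from a fitted mixed model.

    With ``include_random`` the estimated random intercept of each row's
    cluster is added; clusters unseen at fit time fall back to ``u_j = 0``.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim == 1:
        W = W[:, None]
    if W.shape[1] != len(fit.params):
        raise ValueError(
            f"design has {W.shape[1]} columns, fit expects {len(fit.params)}"
        )
    pred = W @ fit.params.to_numpy()
    if include_random:
        if cluster is None:
            raise ValueError("cluster labels required when include_random is set")
        pred = pred + np.array([fit.u.get(c, 0.0) for c in np.asarray(cluster)])
    return pred


def icc(sigma_u2: float, sigma_e2: float) -> float:
    """Intraclass correlation: share of total variance between clusters."""
    if sigma_e2 <= 0 or sigma_u2 < 0:
        raise ValueError("need sigma_e2 > 0 and sigma_u2 >= 0")
    return sigma_u2 / (sigma_u2 + sigma_e2)
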