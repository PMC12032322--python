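"""Synthetic clustered data under three functional forms.

Three data-generating scenarios over a two-level design (J clusters of nj
rows each) share the same covariate machinery:

* level 1: X1..X3 jointly normal per row with equicorrelation ``rho``,
  X4 ~ Bernoulli(0.5) per row;
* level 2: Z1..Z2 jointly normal per cluster with correlation ``rho``,
  Z3 ~ Bernoulli(0.5) per cluster; all replicated over the cluster's rows.

The response adds a random intercept ``u_j ~ N(0, sigma_u^2)`` and noise
``e_ij ~ N(0, sigma_e^2)`` to a scenario-specific mean:

* M1 (linear):      X'beta + Z'gamma
* M2 (semilinear):  M1 + mu1*1{X1>0} + mu2*Z3 + mu3*1{X1>0}*Z3
* M3 (nonlinear):   M1 + mu1*X1^2 + mu2*Z2*ln|X3|

One noise coefficient per level (beta2 on X2, gamma2 on Z2) is identically
zero in every scenario, so the generators include irrelevant predictors by
construction.  The intraclass correlation is set through
``(sigma_u^2, sigma_e^2) = (3, 1)`` ("high", ICC 0.75) or ``(0.3, 0.5)``
("small", ICC 0.375); correlation levels are ``rho = 0.8`` ("high") or
``0.2`` ("small").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data import HierarchicalDataset

__all__ = [
    "ScenarioParams",
    "make_covariates",
    "simulate_response",
    "make_setting",
    "SIZE_GRID",
    "rep_seed",
]

# true fixed effects per scenario: beta = (b0..b4), gamma = (g1..g3), mu = (m1..m3)
_SCENARIO_COEFS = {
    "M1": ((5.0, 2.0, 0.0, 3.0, 1.0), (3.0, 0.0, 1.0), (0.0, 0.0, 0.0)),
    "M2": ((5.0, 2.0, 0.0, 3.0, 1.0), (2.0, 0.0, 1.0), (3.0, 2.0, -2.0)),
    "M3": ((5.0, 2.0, 0.0, 2.0, 2.0), (3.0, 0.0, 2.0), (2.0, 1.0, 0.0)),
}

_ICC_LEVELS = {"high": (3.0, 1.0), "small": (0.3, 0.5)}
_CORR_LEVELS = {"high": 0.8, "small": 0.2}

#: total-size grid: n_total -> (J clusters, nj rows per cluster)
SIZE_GRID = {
    750: (50, 15),
    1500: (50, 30),
    3500: (70, 50),
    5000: (100, 50),
    10000: (200, 50),
}

_X3_EPS = 1e-12  # guard for ln|X3| at the probability-zero event X3 == 0


@dataclass
class ScenarioParams:
    """True parameters of one simulation setting."""

    scenario: str
    beta: tuple  # (beta0, beta1, beta2, beta3, beta4)
    gamma: tuple  # (gamma1, gamma2, gamma3)
    mu: tuple  # (mu1, mu2, mu3)
    sigma_u2: float
    sigma_e2: float
    rho: float
    J: int
    nj: int
    seed: Optional[int] = None

    @classmethod
    def for_setting(
        cls,
        scenario: str,
        icc_level: str = "high",
        corr_level: str = "high",
        J: int = 70,
        nj: int = 50,
        seed: Optional[int] = None,
    ) -> "ScenarioParams":
        if scenario not in _SCENARIO_COEFS:
            raise ValueError(f"unknown scenario {scenario!r}; expected M1, M2 or M3")
        if icc_level not in _ICC_LEVELS:
            raise ValueError(f"unknown ICC level {icc_level!r}; expected high or small")
        if corr_level not in _CORR_LEVELS:
            raise ValueError(
                f"unknown correlation level {corr_level!r}; expected high or small"
            )
        beta, gamma, mu = _SCENARIO_COEFS[scenario]
        su2, se2 = _ICC_LEVELS[icc_level]
        return cls(
            scenario=scenario,
            beta=beta,
            gamma=gamma,
            mu=mu,
            sigma_u2=su2,
            sigma_e2=se2,
            rho=_CORR_LEVELS[corr_level],
            J=J,
            nj=nj,
            seed=seed,
        )


def _equicorr(dim: int, rho: float) -> np.ndarray:
    return np.full((dim, dim), rho) + (1.0 - rho) * np.eye(dim)


def make_covariates(
    J: int, nj: int, rho: float, seed=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Generate (X, Z, cluster) for a balanced two-level design.

    Returns the row-level matrix X (``J*nj x 4``), the cluster-constant
    matrix Z (``J*nj x 3``, drawn once per cluster and replicated) and the
    cluster label of every row.  ``seed`` may be an integer or a Generator.
    """
    if J < 1 or nj < 1:
        raise ValueError("J and nj must be >= 1")
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must be in (-1, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = J * nj
    X = np.empty((n, 4))
    X[:, :3] = rng.multivariate_normal(np.zeros(3), _equicorr(3, rho), size=n)
    X[:, 3] = rng.binomial(1, 0.5, size=n)
    Zc = np.empty((J, 3))
    Zc[:, :2] = rng.multivariate_normal(np.zeros(2), _equicorr(2, rho), size=J)
    Zc[:, 2] = rng.binomial(1, 0.5, size=J)
    cluster = np.repeat(np.arange(1, J + 1), nj)
    Z = np.repeat(Zc, nj, axis=0)
    return X, Z, cluster


def simulate_response(
    X: np.ndarray,
    Z: np.ndarray,
    cluster: np.ndarray,
    params: ScenarioParams,
    seed=None,
) -> np.ndarray:
    """Draw the response under the scenario's mean structure plus noise."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    b0, b1, b2, b3, b4 = params.beta
    g1, g2, g3 = params.gamma
    m1, m2, m3 = params.mu
    mean = (
        b0
        + b1 * X[:, 0]
        + b2 * X[:, 1]
        + b3 * X[:, 2]
        + b4 * X[:, 3]
        + g1 * Z[:, 0]
        + g2 * Z[:, 1]
        + g3 * Z[:, 2]
    )
    if params.scenario == "M2":
        ind_x1 = (X[:, 0] > 0).astype(float)
        ind_z3 = (Z[:, 2] > 0).astype(float)  # identity for a 0/1 draw
        mean = mean + m1 * ind_x1 + m2 * ind_z3 + m3 * ind_x1 * ind_z3
    elif params.scenario == "M3":
        abs_x3 = np.maximum(np.abs(X[:, 2]), _X3_EPS)
        mean = mean + m1 * X[:, 0] ** 2 + m2 * Z[:, 1] * np.log(abs_x3)
    elif params.scenario != "M1":
        raise ValueError(f"unknown scenario {params.scenario!r}")

    # map labels to 0..J-1 in sorted-unique order purely for the u draw
    _, inverse = np.unique(np.asarray(cluster), return_inverse=True)
    J = inverse.max() + 1
    u = rng.normal(0.0, np.sqrt(params.sigma_u2), size=J)
    eps = rng.normal(0.0, np.sqrt(params.sigma_e2), size=len(mean))
    return mean + u[inverse] + eps


def make_setting(
    scenario: str,
    icc_level: str = "high",
    corr_level: str = "high",
    J: int = 70,
    nj: int = 50,
    seed: Optional[int] = None,
) -> tuple[HierarchicalDataset, ScenarioParams]:
    """Instantiate one simulation setting and generate a dataset from it."""
    params = ScenarioParams.for_setting(scenario, icc_level, corr_level, J, nj, seed)
    rng = np.random.default_rng(seed)
    X, Z, cluster = make_covariates(J, nj, params.rho, rng)
    y = simulate_response(X, Z, cluster, params, rng)
    data = HierarchicalDataset(
        y=y,
        cluster=cluster,
        X=X,
        Z=Z,
        x_names=["x1", "x2", "x3", "x4"],
        z_names=["z1", "z2", "z3"],
    )
    return data, params


def rep_seed(master_seed: int, rep: int) -> int:
    """Per-replication seed derived from a master seed and the rep index.

    Uses a SeedSequence keyed on (master, rep) so any single replication can
    be regenerated in isolation; the result is kept below 2**31.
    """
    return int(
        np.random.SeedSequence([int(master_seed), int(rep)]).generate_state(1)[0]
        % (2**31)
    )
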