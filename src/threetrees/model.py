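"""The 3Trees estimator: a linear mixed model plus three regression trees.

The model for row i in cluster j is

    Y_ij = X_ij' beta + Z_j' gamma + T1(X_ij) + T2(Z_j) + T3(X_ij, Z_j)
           + u_j + e_ij,

a random-intercept mixed model whose fixed part is augmented by three
additive tree components: T1 over the level-1 covariates, T2 over the
cluster-constant level-2 covariates, and T3 over their union (cross-level
interactions).  Estimation has two stages:

1.  *Selection* — a backfitting loop that alternates a GLS/REML fit of the
    linear part (on the response minus the current tree contributions) with
    a refit of each tree on the partial residual that excludes it.  Tree
    contributions are mean-centred so the intercept stays identified.  The
    loop stops when the training MSE of the combined fit stabilises.
2.  *Estimation* — the terminal regions of the three selected trees are
    dummy-coded (reference region dropped), appended to the linear design,
    and the whole model is refitted jointly by REML, yielding coefficients,
    standard errors and p-values for linear and tree-region terms alike.

The tree engine is pluggable: greedy CART, conditional-inference, or
evolutionary search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Optional, Sequence

import numpy as np

from .cart import grow_cart
from .ctree import grow_ctree
from .data import HierarchicalDataset
from .evtree import EvolutionConfig, evolve
from .lmm import MixedFit, RankDeficientError, fit_mixed, predict_mixed
from .tree import TreeModel

__all__ = [
    "ThreeTreesConfig",
    "ThreeTreesFit",
    "select_trees",
    "encode_regions",
    "fit_3trees",
    "predict_3trees",
]

ENGINES = ("cart", "ctree", "evtree")


@dataclass
class ThreeTreesConfig:
    """Configuration of the 3Trees estimator.

    ``cp`` applies to the CART engine, ``alpha`` to the conditional-inference
    engine and ``evolution`` to the evolutionary engine; ``maxdepth`` and
    ``nmin`` are pushed into whichever engine is selected.  The backfitting
    loop stops when the relative change in training MSE between consecutive
    iterations falls below ``mse_tolerance`` or after
    ``max_backfit_iterations`` iterations.
    """

    engine: str = "cart"
    cp: float = 0.0
    alpha: float = 0.05
    evolution: Optional[EvolutionConfig] = None
    maxdepth: int = 3
    nmin: int = 10
    max_backfit_iterations: int = 50
    mse_tolerance: float = 1e-4
    method: str = "reml"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.engine not in ENGINES:
            raise ValueError(f"engine must be one of {ENGINES}")
        if self.mse_tolerance <= 0:
            raise ValueError("mse_tolerance must be > 0")


@dataclass
class ThreeTreesFit:
    """A fitted 3Trees model."""

    trees: tuple  # (T1, T2, T3)
    final_fit: MixedFit
    config: ThreeTreesConfig
    n_iterations: int
    converged: bool
    mse_trajectory: list[float]
    x_names: list[str]
    z_names: list[str]
    dropped_columns: list[str] = field(default_factory=list)

    def to_json(self, **kwargs) -> str:
        cfg = asdict(self.config)
        return json.dumps(
            {
                "config": cfg,
                "trees": [t.to_dict() for t in self.trees],
                "coefficients": {
                    "term": list(self.final_fit.params.index),
                    "estimate": self.final_fit.params.tolist(),
                    "se": self.final_fit.se.tolist(),
                    "p_value": self.final_fit.pvalues.tolist(),
                },
                "sigma_u2": self.final_fit.sigma_u2,
                "sigma_e2": self.final_fit.sigma_e2,
                "u": [[str(k), v] for k, v in self.final_fit.u.items()],
                "n_iterations": self.n_iterations,
                "converged": self.converged,
                "mse_trajectory": self.mse_trajectory,
                "x_names": self.x_names,
                "z_names": self.z_names,
                "dropped_columns": self.dropped_columns,
            },
            **kwargs,
        )


def _grow_engine(
    C: np.ndarray,
    target: np.ndarray,
    candidate_vars: Sequence[int],
    config: ThreeTreesConfig,
    names: Sequence[str],
    seed: Optional[int],
) -> TreeModel:
    if config.engine == "cart":
        return grow_cart(
            C, target, candidate_vars, config.maxdepth, config.nmin, config.cp,
            feature_names=names,
        )
    if config.engine == "ctree":
        return grow_ctree(
            C, target, candidate_vars, config.maxdepth, config.nmin, config.alpha,
            feature_names=names,
        )
    evo = config.evolution if config.evolution is not None else EvolutionConfig()
    evo = replace(evo, maxdepth=config.maxdepth, nmin=config.nmin, seed=seed)
    return evolve(C, target, candidate_vars, evo, feature_names=names)


def select_trees(
    train: HierarchicalDataset, config: ThreeTreesConfig
) -> tuple[TreeModel, TreeModel, TreeModel, list[float]]:
    """Backfitting selection of the three trees.

    Returns the three selected trees and the training-MSE trajectory of the
    combined fit (linear part + BLUPs + centred tree contributions), one
    entry per backfitting iteration.
    """
    y = train.y
    n = train.n_total
    C = np.column_stack([train.X, train.Z])
    c_names = list(train.x_names) + list(train.z_names)
    p1 = train.p1
    spaces = [
        list(range(p1)),  # T1: level-1 columns
        list(range(p1, p1 + train.p2)),  # T2: level-2 columns
        list(range(C.shape[1])),  # T3: all columns
    ]
    W = np.column_stack([np.ones(n), train.X, train.Z])
    w_names = ["(Intercept)", *train.x_names, *train.z_names]
    cluster = train.cluster

    base_seed = config.seed if config.seed is not None else 0
    seed_counter = [0]

    def next_seed() -> int:
        # one documented counter per engine call, so runs are reproducible
        s = int(
            np.random.SeedSequence([base_seed, seed_counter[0]]).generate_state(1)[0]
            % (2**31)
        )
        seed_counter[0] += 1
        return s

    contrib = np.zeros((3, n))
    trees: list[Optional[TreeModel]] = [None, None, None]
    trajectory: list[float] = []

    for iteration in range(1, config.max_backfit_iterations + 1):
        try:
            lin_fit = fit_mixed(
                W, y - contrib.sum(axis=0), cluster, w_names, method=config.method
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(
                f"linear-component fit failed at backfitting iteration {iteration}"
            ) from exc
        lin_pred = W @ lin_fit.params.to_numpy()
        u_row = np.array([lin_fit.u[c] for c in cluster])
        # residual of the combined fit at the current state; tree means
        # removed by centring are re-absorbed by the next intercept fit
        cur_resid = y - lin_pred - u_row - contrib.sum(axis=0)

        any_accepted = False
        for t in range(3):
            target = cur_resid + contrib[t]  # partial residual excluding T_t
            try:
                tree = _grow_engine(
                    C, target, spaces[t], config, c_names, next_seed()
                )
            except Exception as exc:
                raise RuntimeError(
                    f"tree engine failed for T{t + 1} at backfitting "
                    f"iteration {iteration}"
                ) from exc
            fitted = tree.predict(C)
            cand_resid = target - fitted
            # keep the previous tree when the refit does not improve the
            # combined training fit (stabilises the backfitting loop)
            if trees[t] is not None and float(np.mean(cand_resid**2)) >= float(
                np.mean(cur_resid**2)
            ):
                continue
            contrib[t] = fitted - fitted.mean()  # centred for identifiability
            trees[t] = tree
            cur_resid = cand_resid
            any_accepted = True

        mse = float(np.mean(cur_resid**2))
        if trajectory and (not any_accepted or mse >= trajectory[-1]):
            # no tree changed, or the refitted linear/BLUP state ended up
            # no better than the previous one: retain the previous trees
            # (this iteration cannot improve the combined fit further)
            if any_accepted:
                trees, contrib = prev_trees, prev_contrib
            trajectory.append(trajectory[-1])
        else:
            trajectory.append(mse)
        if _has_converged(trajectory, config.mse_tolerance):
            break
        prev_trees, prev_contrib = list(trees), contrib.copy()

    return trees[0], trees[1], trees[2], trajectory


def _has_converged(trajectory: Sequence[float], tolerance: float) -> bool:
    """True iff the last MSE step satisfies the relative-change criterion."""
    return (
        len(trajectory) >= 2
        and abs(trajectory[-1] - trajectory[-2]) < tolerance * trajectory[-2]
    )


def encode_regions(
    tree: TreeModel, C: np.ndarray, prefix: str = "R"
) -> tuple[np.ndarray, list[str]]:
    """Reference-coded terminal-region indicators for the rows of ``C``.

    One 0/1 column per terminal region except the first (the reference);
    a row has a single 1 in its region's column, or all zeros when it falls
    in the reference region.  A root-only tree emits no columns.
    """
    leaves = tree.leaves()
    m = len(leaves)
    if m <= 1:
        return np.empty((C.shape[0], 0)), []
    routed = tree.route(C)  # 0-based leaf index, left-to-right
    D = np.zeros((C.shape[0], m - 1))
    for k in range(1, m):
        D[routed == k, k - 1] = 1.0
    names = [f"{prefix}{leaf.region}" for leaf in leaves[1:]]
    return D, names


def _drop_collinear(
    design: np.ndarray, names: list[str], tol: float = 1e-8
) -> tuple[list[int], list[str]]:
    """Greedy left-to-right scan keeping a maximal independent column set."""
    n = design.shape[0]
    Q = np.empty((n, 0))
    kept: list[int] = []
    dropped: list[str] = []
    for k in range(design.shape[1]):
        col = design[:, k]
        norm = np.linalg.norm(col)
        if norm == 0:
            dropped.append(names[k])
            continue
        resid = col - Q @ (Q.T @ col)
        rnorm = np.linalg.norm(resid)
        if rnorm < tol * norm:
            dropped.append(names[k])
            continue
        Q = np.column_stack([Q, resid / rnorm])
        kept.append(k)
    return kept, dropped


def fit_3trees(train: HierarchicalDataset, config: ThreeTreesConfig) -> ThreeTreesFit:
    """Select the three trees by backfitting, then jointly refit by REML.

    The estimation-stage design is ``[1 | X | Z | region dummies of T1, T2,
    T3]`` with each tree's first region as the reference.  Exactly collinear
    columns are dropped (recorded in ``dropped_columns``) before the mixed
    fit; if the design is still singular the error advises a smaller
    ``maxdepth``.
    """
    t1, t2, t3, trajectory = select_trees(train, config)
    converged = _has_converged(trajectory, config.mse_tolerance)
    C = np.column_stack([train.X, train.Z])

    design_parts = [np.ones((train.n_total, 1)), train.X, train.Z]
    names = ["(Intercept)", *train.x_names, *train.z_names]
    for t, tree in enumerate((t1, t2, t3), start=1):
        D, dn = encode_regions(tree, C, prefix=f"T{t}.R")
        design_parts.append(D)
        names.extend(dn)
    design = np.column_stack(design_parts)

    kept, dropped = _drop_collinear(design, names)
    kept_names = [names[k] for k in kept]
    try:
        final = fit_mixed(
            design[:, kept], train.y, train.cluster, kept_names, method=config.method
        )
    except RankDeficientError as exc:
        raise RankDeficientError(
            "estimation-stage design is singular even after dropping "
            "collinear region dummies; consider a smaller maxdepth"
        ) from exc

    return ThreeTreesFit(
        trees=(t1, t2, t3),
        final_fit=final,
        config=config,
        n_iterations=len(trajectory),
        converged=converged,
        mse_trajectory=trajectory,
        x_names=list(train.x_names),
        z_names=list(train.z_names),
        dropped_columns=dropped,
    )


def _build_design(
    fit: ThreeTreesFit, X: np.ndarray, Z: np.ndarray
) -> np.ndarray:
    C = np.column_stack([X, Z])
    cols = {"(Intercept)": np.ones(C.shape[0])}
    for k, name in enumerate(fit.x_names):
        cols[name] = np.asarray(X, dtype=float)[:, k]
    for k, name in enumerate(fit.z_names):
        cols[name] = np.asarray(Z, dtype=float)[:, k]
    for t, tree in enumerate(fit.trees, start=1):
        D, dn = encode_regions(tree, C, prefix=f"T{t}.R")
        for k, name in enumerate(dn):
            cols[name] = D[:, k]
    return np.column_stack([cols[name] for name in fit.final_fit.params.index])


def predict_3trees(
    fit: ThreeTreesFit,
    data: HierarchicalDataset | None = None,
    X: Optional[np.ndarray] = None,
    Z: Optional[np.ndarray] = None,
    cluster: Optional[np.ndarray] = None,
    include_random: bool = False,
) -> np.ndarray:
    """Predict from a fitted 3Trees model.

    Accepts either a :class:`HierarchicalDataset` or raw ``(X, Z, cluster)``
    arrays.  With ``include_random`` the BLUP of each row's cluster is added
    (zero for clusters unseen at fit time).
    """
    if data is not None:
        X, Z, cluster = data.X, data.Z, data.cluster
    if X is None or Z is None:
        raise ValueError("either a dataset or X and Z arrays are required")
    design = _build_design(fit, X, Z)
    return predict_mixed(fit.final_fit, design, cluster, include_random)
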