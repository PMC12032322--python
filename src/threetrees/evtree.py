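"""Evolutionary search over regression-tree structures.

Instead of greedy recursive splitting, a population of trees is evolved:
each iteration every population member spawns an offspring through one of
five variation operators (split, prune, major split-rule mutation, minor
split-rule mutation, crossover) and replaces its parent only when its
penalised loss is strictly lower.  The loss trades training accuracy against
tree size,

    loss(T) = n * log(MSE(T)) + lambda * Mt * log(n),

a BIC-flavoured criterion (``Mt`` terminal nodes, ``n`` training rows).
Elitist parent-vs-offspring competition makes the best loss non-increasing,
and the search can escape the local optima greedy trees get stuck in (e.g.
XOR-type targets where no single split has positive gain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .tree import Node, SplitRule, TreeModel

__all__ = ["EvolutionConfig", "init_population", "apply_operator", "tree_loss", "evolve"]

OPERATORS = ("split", "prune", "major", "minor", "crossover")

_MSE_FLOOR = 1e-10


@dataclass
class EvolutionConfig:
    """Hyperparameters of the evolutionary tree search.

    Defaults are a reproducible, BIC-flavoured configuration: equal operator
    probabilities, strict parent-vs-offspring survivor selection and a
    stagnation-based stop.
    """

    population_size: int = 100
    max_iterations: int = 2000
    stagnation_window: int = 100
    operator_probabilities: dict = field(
        default_factory=lambda: {op: 0.2 for op in OPERATORS}
    )
    complexity_weight: float = 2.0
    maxdepth: int = 3
    nmin: int = 10
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        probs = np.array([self.operator_probabilities[op] for op in OPERATORS])
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("operator probabilities must be >= 0 and sum to 1")

    def _prob_vector(self) -> np.ndarray:
        return np.array([self.operator_probabilities[op] for op in OPERATORS])


def tree_loss(
    tree: TreeModel, X: np.ndarray, y: np.ndarray, complexity_weight: float = 2.0
) -> float:
    """Penalised loss ``n*log(MSE) + lambda*Mt*log(n)`` (lower is better)."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    mse = float(np.mean((y - tree.predict(X)) ** 2))
    return n * np.log(max(mse, _MSE_FLOOR)) + complexity_weight * tree.n_leaves * np.log(n)


def _loss_from_risk(tree: TreeModel, n: int, complexity_weight: float) -> float:
    # fast path: sum of leaf risks (normalised by n) IS the training MSE
    mse = tree.training_risk()
    return n * np.log(max(mse, _MSE_FLOOR)) + complexity_weight * tree.n_leaves * np.log(n)


def _node_candidates(x_node: np.ndarray, nmin: int) -> np.ndarray:
    """Admissible thresholds for one variable at a node (>= nmin per child)."""
    xs = np.sort(x_node)
    n = len(xs)
    if n < 2 * nmin:
        return np.empty(0)
    k = np.arange(1, n)
    valid = (xs[1:] > xs[:-1]) & (k >= nmin) & (n - k >= nmin)
    return 0.5 * (xs[:-1] + xs[1:])[valid]


def _random_split(
    X: np.ndarray,
    idx: np.ndarray,
    candidate_vars: Sequence[int],
    nmin: int,
    rng: np.random.Generator,
) -> Optional[SplitRule]:
    """A uniformly random admissible split of the rows ``idx``, or None."""
    variables = list(candidate_vars)
    order = rng.permutation(len(variables))
    for vi in order:
        var = int(variables[vi])
        cands = _node_candidates(X[idx, var], nmin)
        if len(cands):
            return SplitRule(var, float(rng.choice(cands)))
    return None


def _repair(
    tree: TreeModel,
    X: np.ndarray,
    y: np.ndarray,
    maxdepth: int,
    nmin: int,
) -> TreeModel:
    """Prune branches violating depth or minimum-node-size, refit all means."""

    def recurse(node: Node, idx: np.ndarray, depth: int) -> None:
        if node.is_leaf:
            return
        if depth >= maxdepth:
            node.make_leaf()
            return
        go_left = node.split.goes_left(X[idx])
        nl = int(go_left.sum())
        if nl < nmin or len(idx) - nl < nmin:
            node.make_leaf()
            return
        recurse(node.left, idx[go_left], depth + 1)
        recurse(node.right, idx[~go_left], depth + 1)

    recurse(tree.root, np.arange(len(y)), 0)
    tree.refit_leaves(X, y)
    tree.assign_regions()
    return tree


def init_population(
    X: np.ndarray,
    y: np.ndarray,
    candidate_vars: Sequence[int],
    config: EvolutionConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[TreeModel]:
    """Population of depth-1 trees, each with one random valid root split.

    If the data admit no valid split at all, root-only trees are returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    all_idx = np.arange(len(y))
    population = []
    for _ in range(config.population_size):
        root = Node()
        rule = _random_split(X, all_idx, candidate_vars, config.nmin, rng)
        if rule is not None and config.maxdepth >= 1:
            root.split = rule
            root.left = Node()
            root.right = Node()
        tree = TreeModel(root, engine="evtree")
        tree.refit_leaves(X, y)
        population.append(tree)
    return population


def apply_operator(
    parents: Sequence[TreeModel],
    operator: str,
    X: np.ndarray,
    y: np.ndarray,
    candidate_vars: Sequence[int],
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> list[TreeModel]:
    """Apply one variation operator, returning repaired, refitted offspring.

    Crossover takes two parents and yields two offspring; every other
    operator takes one parent and yields one.  If the chosen operator has no
    applicable node (e.g. prune on a root-only tree), the offspring is an
    unchanged copy of the parent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)

    def node_rows(tree: TreeModel) -> list[tuple[Node, np.ndarray, int]]:
        out = []

        def rec(node: Node, idx: np.ndarray, depth: int) -> None:
            out.append((node, idx, depth))
            if not node.is_leaf:
                go_left = node.split.goes_left(X[idx])
                rec(node.left, idx[go_left], depth + 1)
                rec(node.right, idx[~go_left], depth + 1)

        rec(tree.root, np.arange(len(y)), 0)
        return out

    if operator == "crossover":
        if len(parents) != 2:
            raise ValueError("crossover requires two parents")
        c1, c2 = parents[0].clone(), parents[1].clone()
        nodes1 = node_rows(c1)
        nodes2 = node_rows(c2)
        n1, _, _ = nodes1[rng.integers(len(nodes1))]
        n2, _, _ = nodes2[rng.integers(len(nodes2))]
        # swap subtree payloads in place
        n1.split, n2.split = n2.split, n1.split
        n1.left, n2.left = n2.left, n1.left
        n1.right, n2.right = n2.right, n1.right
        return [
            _repair(c1, X, y, config.maxdepth, config.nmin),
            _repair(c2, X, y, config.maxdepth, config.nmin),
        ]

    if len(parents) != 1:
        raise ValueError(f"{operator} takes one parent")
    child = parents[0].clone()
    nodes = node_rows(child)

    if operator == "split":
        eligible = [
            (nd, idx)
            for nd, idx, depth in nodes
            if nd.is_leaf and depth < config.maxdepth and len(idx) >= 2 * config.nmin
        ]
        if eligible:
            nd, idx = eligible[rng.integers(len(eligible))]
            rule = _random_split(X, idx, candidate_vars, config.nmin, rng)
            if rule is not None:
                nd.split = rule
                nd.left = Node()
                nd.right = Node()
    elif operator == "prune":
        internal = [nd for nd, _, _ in nodes if not nd.is_leaf]
        if internal:
            internal[rng.integers(len(internal))].make_leaf()
    elif operator == "major":
        internal = [(nd, idx) for nd, idx, _ in nodes if not nd.is_leaf]
        if internal:
            nd, idx = internal[rng.integers(len(internal))]
            rule = _random_split(X, idx, candidate_vars, config.nmin, rng)
            if rule is not None:
                nd.split = rule
    elif operator == "minor":
        internal = [(nd, idx) for nd, idx, _ in nodes if not nd.is_leaf]
        if internal:
            nd, idx = internal[rng.integers(len(internal))]
            cands = _node_candidates(X[idx, nd.split.variable], config.nmin)
            if len(cands) > 1:
                pos = int(np.searchsorted(cands, nd.split.threshold))
                pos = min(pos, len(cands) - 1)
                step = -1 if (pos == len(cands) - 1 or (pos > 0 and rng.random() < 0.5)) else 1
                nd.split = SplitRule(nd.split.variable, float(cands[pos + step]))
    else:
        raise ValueError(f"unknown operator {operator!r}")

    return [_repair(child, X, y, config.maxdepth, config.nmin)]


def evolve(
    X: np.ndarray,
    y: np.ndarray,
    candidate_vars: Optional[Sequence[int]] = None,
    config: Optional[EvolutionConfig] = None,
    feature_names: Optional[Sequence[str]] = None,
    return_info: bool = False,
):
    """Run the evolutionary tree search and return the best tree found.

    Each iteration every member of the population spawns offspring through a
    randomly chosen operator; an offspring replaces its parent only when its
    loss is strictly lower (elitist survivor selection).  The search stops at
    ``max_iterations`` or when the best loss has not improved for
    ``stagnation_window`` consecutive iterations.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if config is None:
        config = EvolutionConfig()
    if candidate_vars is None:
        candidate_vars = list(range(X.shape[1]))
    rng = np.random.default_rng(config.seed)
    n = len(y)
    lam = config.complexity_weight
    probs = config._prob_vector()

    population = init_population(X, y, candidate_vars, config, rng)
    losses = [_loss_from_risk(t, n, lam) for t in population]
    best_i = int(np.argmin(losses))
    best_tree, best_loss = population[best_i].clone(), losses[best_i]
    trajectory = [best_loss]
    stagnant = 0
    iterations_run = 0

    for _ in range(config.max_iterations):
        iterations_run += 1
        improved = False
        for i in range(config.population_size):
            op = OPERATORS[rng.choice(len(OPERATORS), p=probs)]
            if op == "crossover":
                j = int(rng.integers(config.population_size - 1))
                if j >= i:
                    j += 1
                offspring = apply_operator(
                    [population[i], population[j]], op, X, y, candidate_vars, config, rng
                )
                targets = [i, j]
            else:
                offspring = apply_operator(
                    [population[i]], op, X, y, candidate_vars, config, rng
                )
                targets = [i]
            for child, slot in zip(offspring, targets):
                child_loss = _loss_from_risk(child, n, lam)
                if child_loss < losses[slot]:
                    population[slot] = child
                    losses[slot] = child_loss
                    if child_loss < best_loss:
                        best_loss = child_loss
                        best_tree = child.clone()
                        improved = True
        trajectory.append(best_loss)
        stagnant = 0 if improved else stagnant + 1
        if stagnant >= config.stagnation_window:
            break

    best_tree.feature_names = list(feature_names) if feature_names is not None else None
    best_tree.engine = "evtree"
    if return_info:
        return best_tree, {
            "loss": best_loss,
            "iterations": iterations_run,
            "trajectory": trajectory,
        }
    return best_tree
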