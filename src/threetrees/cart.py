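"""Greedy CART regression trees with squared-error splitting.

The node risk is normalised by the *total* training size rather than the node
size, making risks additive across the nodes of any partition; the split gain
is then the parent risk minus the two child risks.  A relative-gain gate
(``cp``) applied against the root risk mirrors the standard recursive
partitioning control, and weakest-link cost-complexity pruning is available
separately.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .tree import Node, SplitRule, TreeModel

__all__ = [
    "node_risk",
    "best_split",
    "grow_cart",
    "prune_cost_complexity",
    "predict_tree",
]


def node_risk(y_node: np.ndarray, n_total: Optional[int] = None) -> float:
    """Squared-error risk of a node: ``sum((y - mean)^2) / n_total``.

    ``n_total`` is the total training-set size; when omitted, the node is
    taken to be the whole sample.  Normalising by the total size makes node
    risks additive across any partition of the data.
    """
    y_node = np.asarray(y_node, dtype=float)
    if y_node.size == 0:
        raise ValueError("node_risk of an empty node is undefined")
    if n_total is None:
        n_total = y_node.size
    return float(((y_node - y_node.mean()) ** 2).sum() / n_total)


def _scan_variable(
    x: np.ndarray, y: np.ndarray, nmin: int
) -> tuple[float, float] | None:
    """Best (gain*n_total, threshold) for one numeric variable, or None.

    The gain returned is the reduction in *sum of squares* (caller divides by
    the total training size).  Candidate thresholds are midpoints between
    consecutive distinct sorted values; both children must hold >= nmin rows.
    Among equal gains the smallest threshold wins.
    """
    n = len(y)
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    # split after position k (1-based count going left), k = nmin..n-nmin
    cum = np.cumsum(ys)
    cum2 = np.cumsum(ys**2)
    total, total2 = cum[-1], cum2[-1]
    k = np.arange(1, n)
    valid = (xs[1:] > xs[:-1]) & (k >= nmin) & (n - k >= nmin)
    if not valid.any():
        return None
    k = k[valid]
    sl, sl2 = cum[k - 1], cum2[k - 1]
    sse_left = sl2 - sl**2 / k
    sse_right = (total2 - sl2) - (total - sl) ** 2 / (n - k)
    sse_parent = total2 - total**2 / n
    gains = sse_parent - sse_left - sse_right
    best = int(np.argmax(gains))  # first occurrence = smallest threshold
    kb = k[best]
    threshold = 0.5 * (xs[kb - 1] + xs[kb])
    return float(gains[best]), float(threshold)


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    candidate_vars: Sequence[int],
    nmin: int = 10,
    n_total: Optional[int] = None,
) -> Optional[tuple[SplitRule, float]]:
    """Exhaustive best squared-error split of a node.

    Returns ``(rule, gain)`` maximising the risk reduction
    ``R(t) - R(tL) - R(tR)`` subject to both children holding at least
    ``nmin`` rows, or ``None`` if no admissible split has positive gain.
    Ties break to the lowest variable index, then the lowest threshold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if n_total is None:
        n_total = len(y)
    if len(y) < 2 * nmin:
        return None
    best_gain = 0.0
    best_rule: Optional[SplitRule] = None
    for var in candidate_vars:
        res = _scan_variable(X[:, var], y, nmin)
        if res is None:
            continue
        gain, threshold = res
        if gain > best_gain + 1e-12 * max(1.0, abs(best_gain)):
            best_gain = gain
            best_rule = SplitRule(int(var), threshold)
    if best_rule is None or best_gain <= 0:
        return None
    return best_rule, best_gain / n_total


def grow_cart(
    X: np.ndarray,
    y: np.ndarray,
    candidate_vars: Optional[Sequence[int]] = None,
    maxdepth: int = 3,
    nmin: int = 10,
    cp: float = 0.0,
    feature_names: Optional[Sequence[str]] = None,
) -> TreeModel:
    """Grow a greedy binary regression tree.

    Recursive binary splitting with :func:`best_split`; a split is kept only
    if its gain is at least ``cp`` times the root risk.  ``maxdepth=0``
    returns a root-only tree predicting the global mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if candidate_vars is None:
        candidate_vars = list(range(X.shape[1]))
    n_total = len(y)
    root_risk = node_risk(y)
    gate = cp * root_risk

    def build(idx: np.ndarray, depth: int) -> Node:
        sub_y = y[idx]
        node = Node(
            mean=float(sub_y.mean()),
            n=len(idx),
            risk=node_risk(sub_y, n_total),
        )
        if depth >= maxdepth or len(idx) < 2 * nmin:
            return node
        found = best_split(X[idx], sub_y, candidate_vars, nmin, n_total)
        if found is None:
            return node
        rule, gain = found
        if gain < gate:
            return node
        node.split = rule
        go_left = rule.goes_left(X[idx])
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    root = build(np.arange(n_total), 0)
    return TreeModel(root, engine="cart", feature_names=feature_names)


def prune_cost_complexity(tree: TreeModel, alpha: float) -> TreeModel:
    """Cost-complexity pruning: the subtree minimising ``R(T) + alpha*|T|``.

    Solved exactly by bottom-up dynamic programming over collapse decisions;
    ties prefer the smaller (collapsed) tree, which makes the pruned-tree
    sequence over increasing ``alpha`` nested.  Node risks stored at grow
    time are used, so no data is needed.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    pruned = tree.clone()

    def best(node: Node) -> float:
        leaf_cost = node.risk + alpha
        if node.is_leaf:
            return leaf_cost
        sub_cost = best(node.left) + best(node.right)
        if leaf_cost <= sub_cost + 1e-12:
            node.make_leaf()
            return leaf_cost
        return sub_cost

    best(pruned.root)
    pruned.assign_regions()
    return pruned


def predict_tree(tree: TreeModel, X: np.ndarray) -> np.ndarray:
    """Route rows through the tree and return terminal-node means."""
    return tree.predict(X)
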