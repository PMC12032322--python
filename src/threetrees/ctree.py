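"""Conditional-inference regression trees.

Splitting proceeds in two separated stages.  First, each candidate covariate
is tested for association with the node target (two-sided t-test of the
simple-regression slope); the per-variable p-values are Bonferroni-adjusted
for the number of candidates at the node.  Only if the smallest adjusted
p-value falls below the significance level ``alpha`` is the node split, and
then only on that variable — the split point itself is chosen by the
squared-error gain criterion restricted to the selected variable.  This
separation of variable selection from split-point search removes the bias of
exhaustive-search trees towards covariates with many distinct values, and
the test doubles as a statistical stopping rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cart import best_split
from .tree import Node, TreeModel

__all__ = ["AssociationTestResult", "association_test", "select_split_variable", "grow_ctree"]


@dataclass
class AssociationTestResult:
    variable: int
    statistic: float
    p_value: float
    adjusted_p: float


def association_test(
    target: np.ndarray, x: np.ndarray, variable: int = 0, n_candidates: int = 1
) -> AssociationTestResult:
    """Two-sided t-test of the simple-regression slope of ``target`` on ``x``.

    A constant covariate (or constant target) carries no information and
    yields statistic 0 with p-value 1, so it is never selected.
    """
    target = np.asarray(target, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3 or np.ptp(x) == 0 or np.ptp(target) == 0:
        return AssociationTestResult(variable, 0.0, 1.0, 1.0)
    r = np.corrcoef(x, target)[0, 1]
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    adj = min(1.0, p * n_candidates)
    return AssociationTestResult(variable, float(t), p, adj)


def select_split_variable(
    X: np.ndarray,
    target: np.ndarray,
    candidate_vars: Sequence[int],
    alpha: float = 0.05,
) -> Optional[AssociationTestResult]:
    """Bonferroni-adjusted variable selection at a node.

    Returns the test result of the winning variable if the minimum adjusted
    p-value is below ``alpha``, else ``None`` (the node becomes terminal).
    Ties in adjusted p break to the lowest variable index.
    """
    X = np.asarray(X, dtype=float)
    m = len(candidate_vars)
    if m == 0:
        return None
    results = [
        association_test(target, X[:, v], variable=int(v), n_candidates=m)
        for v in candidate_vars
    ]
    winner = min(results, key=lambda r: (r.adjusted_p, r.variable))
    if winner.adjusted_p < alpha:
        return winner
    return None


def grow_ctree(
    X: np.ndarray,
    y: np.ndarray,
    candidate_vars: Optional[Sequence[int]] = None,
    maxdepth: int = 3,
    nmin: int = 10,
    alpha: float = 0.05,
    feature_names: Optional[Sequence[str]] = None,
) -> TreeModel:
    """Grow a conditional-inference regression tree.

    Recursion stops when no candidate's adjusted association test rejects at
    level ``alpha``, when ``maxdepth`` is reached, or when a node is too
    small to split with ``nmin``-row children.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if candidate_vars is None:
        candidate_vars = list(range(X.shape[1]))
    n_total = len(y)

    def build(idx: np.ndarray, depth: int) -> Node:
        sub_y = y[idx]
        node = Node(
            mean=float(sub_y.mean()),
            n=len(idx),
            risk=float(((sub_y - sub_y.mean()) ** 2).sum() / n_total),
        )
        if depth >= maxdepth or len(idx) < max(2 * nmin, 3):
            return node
        test = select_split_variable(X[idx], sub_y, candidate_vars, alpha)
        if test is None:
            return node
        found = best_split(X[idx], sub_y, [test.variable], nmin, n_total)
        if found is None:
            return node
        rule, _ = found
        node.split = rule
        node.info["adjusted_p"] = test.adjusted_p
        go_left = rule.goes_left(X[idx])
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    root = build(np.arange(n_total), 0)
    return TreeModel(root, engine="ctree", feature_names=feature_names)
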