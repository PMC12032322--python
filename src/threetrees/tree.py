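"""Binary regression-tree structure shared by the CART, CTree and EvTree engines.

A tree is a recursive :class:`Node` structure wrapped in a :class:`TreeModel`.
Internal nodes carry a :class:`SplitRule` (variable index + threshold; rows
with ``x[var] <= threshold`` go left); terminal nodes carry the fitted node
mean and a region id.  Binary 0/1 covariates are handled as numerics with a
single admissible threshold at 0.5, so one routing rule covers all columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np

__all__ = ["SplitRule", "Node", "TreeModel"]


@dataclass
class SplitRule:
    """A binary split: rows with ``x[variable] <= threshold`` go left."""

    variable: int
    threshold: float

    def goes_left(self, X: np.ndarray) -> np.ndarray:
        return X[:, self.variable] <= self.threshold


@dataclass
class Node:
    """One node of a binary regression tree.

    A node is terminal iff ``split is None``.  ``mean`` is the fitted value of
    a terminal node; ``risk`` is the node's squared-error risk contribution
    (sum of squared deviations from the node mean divided by the *total*
    training size, so risks are additive across a tree level).
    """

    split: Optional[SplitRule] = None
    left: Optional["Node"] = None
    right: Optional["Node"] = None
    mean: float = 0.0
    n: int = 0
    risk: float = 0.0
    region: int = -1
    info: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.split is None

    def make_leaf(self) -> None:
        self.split = None
        self.left = None
        self.right = None

    def clone(self) -> "Node":
        node = Node(
            split=SplitRule(self.split.variable, self.split.threshold)
            if self.split
            else None,
            mean=self.mean,
            n=self.n,
            risk=self.risk,
            region=self.region,
            info=dict(self.info),
        )
        if self.left is not None:
            node.left = self.left.clone()
        if self.right is not None:
            node.right = self.right.clone()
        return node


class TreeModel:
    """A fitted binary regression tree.

    Parameters
    ----------
    root
        Root node of the tree.
    engine
        Tag of the engine that produced the tree: ``"cart"``, ``"ctree"`` or
        ``"evtree"``.
    feature_names
        Names of the columns of the covariate matrix the tree was grown on.
        The tree routes rows of that full matrix; its splits may be restricted
        to a subset of columns (candidate variables).
    """

    def __init__(
        self,
        root: Node,
        engine: str = "cart",
        feature_names: Optional[Sequence[str]] = None,
    ):
        self.root = root
        self.engine = engine
        self.feature_names = list(feature_names) if feature_names is not None else None
        self.assign_regions()

    # -- structure ---------------------------------------------------------

    def leaves(self) -> list[Node]:
        """Terminal nodes in left-to-right (pre-order) order."""
        return [n for n in self.iter_nodes() if n.is_leaf]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.iter_nodes() if not n.is_leaf]

    def iter_nodes(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            if not node.is_leaf:
                stack.append(node.right)
                stack.append(node.left)

    def iter_nodes_with_depth(self) -> Iterator[tuple[Node, int]]:
        stack = [(self.root, 0)]
        while stack:
            node, d = stack.pop()
            yield node, d
            if not node.is_leaf:
                stack.append((node.right, d + 1))
                stack.append((node.left, d + 1))

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def depth(self) -> int:
        return max(d for _, d in self.iter_nodes_with_depth())

    def split_variables(self) -> list[int]:
        return [n.split.variable for n in self.internal_nodes()]

    def assign_regions(self) -> None:
        """Number terminal regions 1..Mt in left-to-right order."""
        for r, leaf in enumerate(self.leaves(), start=1):
            leaf.region = r

    def clone(self) -> "TreeModel":
        return TreeModel(self.root.clone(), self.engine, self.feature_names)

    # -- routing and prediction -------------------------------------------

    def route(self, X: np.ndarray) -> np.ndarray:
        """Leaf index (0-based, left-to-right) for every row of ``X``."""
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0], dtype=np.intp)
        counter = [0]

        def recurse(node: Node, idx: np.ndarray) -> None:
            if node.is_leaf:
                out[idx] = counter[0]
                counter[0] += 1
                return
            go_left = node.split.goes_left(X[idx])
            recurse(node.left, idx[go_left])
            recurse(node.right, idx[~go_left])

        recurse(self.root, np.arange(X.shape[0]))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        means = np.array([leaf.mean for leaf in self.leaves()])
        return means[self.route(X)]

    # -- refitting (used by the evolutionary engine) -----------------------

    def refit_leaves(self, X: np.ndarray, y: np.ndarray) -> None:
        """Recompute node means, counts and risks for target ``y``.

        Risks are normalised by ``len(y)`` so they are additive across nodes.
        Empty nodes get ``n = 0`` and keep their previous mean; callers that
        edit tree structure should repair such nodes (see the evtree engine).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n_total = len(y)

        def recurse(node: Node, idx: np.ndarray) -> None:
            node.n = len(idx)
            if len(idx):
                sub = y[idx]
                node.mean = float(sub.mean())
                node.risk = float(((sub - node.mean) ** 2).sum() / n_total)
            else:
                node.risk = 0.0
            if not node.is_leaf:
                go_left = node.split.goes_left(X[idx])
                recurse(node.left, idx[go_left])
                recurse(node.right, idx[~go_left])

        recurse(self.root, np.arange(len(y)))

    def training_risk(self) -> float:
        """Sum of leaf risks: R(T) of the tree on its training data."""
        return sum(leaf.risk for leaf in self.leaves())

    # -- serialization -----------------------------------------------------

    def _node_to_dict(self, node: Node, next_id: list[int]) -> dict:
        d: dict = {"id": next_id[0], "n": node.n}
        next_id[0] += 1
        if node.is_leaf:
            d["mean"] = node.mean
            d["region"] = node.region
        else:
            d["variable"] = node.split.variable
            if self.feature_names is not None:
                d["variable_name"] = self.feature_names[node.split.variable]
            d["threshold"] = node.split.threshold
            if node.info:
                d.update({k: v for k, v in node.info.items()})
            d["left"] = self._node_to_dict(node.left, next_id)
            d["right"] = self._node_to_dict(node.right, next_id)
        return d

    def to_dict(self) -> dict:
        return {
            "engine": self.engine,
            "feature_names": self.feature_names,
            "n_leaves": self.n_leaves,
            "depth": self.depth,
            "root": self._node_to_dict(self.root, [0]),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @staticmethod
    def _node_from_dict(d: dict) -> Node:
        if "mean" in d:
            return Node(mean=d["mean"], n=d.get("n", 0), region=d.get("region", -1))
        node = Node(
            split=SplitRule(d["variable"], d["threshold"]),
            n=d.get("n", 0),
            info={
                k: v
                for k, v in d.items()
                if k not in {"id", "n", "variable", "variable_name", "threshold", "left", "right"}
            },
        )
        node.left = TreeModel._node_from_dict(d["left"])
        node.right = TreeModel._node_from_dict(d["right"])
        return node

    @classmethod
    def from_dict(cls, d: dict) -> "TreeModel":
        return cls(
            cls._node_from_dict(d["root"]),
            engine=d.get("engine", "cart"),
            feature_names=d.get("feature_names"),
        )

    @classmethod
    def from_json(cls, s: str) -> "TreeModel":
        return cls.from_dict(json.loads(s))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"TreeModel(engine={self.engine!r}, leaves={self.n_leaves}, "
            f"depth={self.depth})"
        )
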