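"""Hierarchical (two-level) dataset container, CSV I/O and train/test split.

Rows are individuals nested in clusters.  Level-1 covariates (X) vary per
row; level-2 covariates (Z) are constant within every cluster and replicated
over the cluster's rows.  Validation enforces that structure, so every
downstream module can rely on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["HierarchicalDataset", "load_dataset", "split_within_cluster"]


@dataclass
class HierarchicalDataset:
    """A clustered Gaussian-response table.

    Attributes
    ----------
    y
        Numeric response, length ``n_total``.
    cluster
        Cluster label per row (arbitrary hashables; mapped to codes 0..J-1
        in first-appearance order internally).
    X
        Level-1 covariate matrix, ``n_total x p1``.
    Z
        Level-2 covariate matrix, ``n_total x p2``; rows constant within a
        cluster.
    """

    y: np.ndarray
    cluster: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    x_names: list[str] = field(default_factory=list)
    z_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.cluster = np.asarray(self.cluster)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if self.X.shape[0] != len(self.y):
            self.X = self.X.T
        if self.Z.shape[0] != len(self.y):
            self.Z = self.Z.T
        if not self.x_names:
            self.x_names = [f"x{i + 1}" for i in range(self.X.shape[1])]
        if not self.z_names:
            self.z_names = [f"z{i + 1}" for i in range(self.Z.shape[1])]
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_total(self) -> int:
        return len(self.y)

    @property
    def p1(self) -> int:
        return self.X.shape[1]

    @property
    def p2(self) -> int:
        return self.Z.shape[1]

    @property
    def cluster_codes(self) -> np.ndarray:
        codes, _ = pd.factorize(self.cluster)
        return codes

    @property
    def cluster_labels(self) -> np.ndarray:
        _, labels = pd.factorize(self.cluster)
        return np.asarray(labels)

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_labels)

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.cluster_codes)

    def validate(self) -> None:
        n = len(self.y)
        if len(self.cluster) != n or self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("y, cluster, X and Z must have equal row counts")
        if not np.isfinite(self.y).all():
            raise ValueError("response contains missing or non-finite values")
        if not np.isfinite(self.X).all():
            raise ValueError("level-1 covariates contain missing or non-finite values")
        if not np.isfinite(self.Z).all():
            raise ValueError("level-2 covariates contain missing or non-finite values")
        codes = self.cluster_codes
        for k, name in enumerate(self.z_names):
            col = self.Z[:, k]
            mins = np.full(codes.max() + 1, np.inf)
            maxs = np.full(codes.max() + 1, -np.inf)
            np.minimum.at(mins, codes, col)
            np.maximum.at(maxs, codes, col)
            bad = np.nonzero(maxs - mins > 0)[0]
            if bad.size:
                label = self.cluster_labels[bad[0]]
                raise ValueError(
                    f"level-2 column {name!r} is not constant within "
                    f"cluster {label!r}"
                )

    # -- conversion --------------------------------------------------------

    def to_frame(
        self, response: str = "y", cluster: str = "cluster"
    ) -> pd.DataFrame:
        df = pd.DataFrame({response: self.y, cluster: self.cluster})
        for k, name in enumerate(self.x_names):
            df[name] = self.X[:, k]
        for k, name in enumerate(self.z_names):
            df[name] = self.Z[:, k]
        return df

    def to_csv(self, path, response: str = "y", cluster: str = "cluster") -> None:
        self.to_frame(response, cluster).to_csv(path, index=False)

    def subset(self, idx: np.ndarray) -> "HierarchicalDataset":
        return HierarchicalDataset(
            y=self.y[idx],
            cluster=self.cluster[idx],
            X=self.X[idx],
            Z=self.Z[idx],
            x_names=list(self.x_names),
            z_names=list(self.z_names),
        )


def load_dataset(
    path,
    response: str,
    cluster: str,
    level1: Sequence[str],
    level2: Sequence[str],
) -> HierarchicalDataset:
    """Load and validate a hierarchical dataset from a CSV file.

    Raises a schema error when a named column is absent and a validation
    error when a level-2 column varies within a cluster or values are
    missing.
    """
    df = pd.read_csv(path)
    level1 = list(level1)
    level2 = list(level2)
    missing = [c for c in [response, cluster, *level1, *level2] if c not in df.columns]
    if missing:
        raise KeyError(f"columns missing from {path}: {missing}")
    sub = df[[response, *level1, *level2]]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in columns {bad}")
    return HierarchicalDataset(
        y=df[response].to_numpy(dtype=float),
        cluster=df[cluster].to_numpy(),
        X=df[level1].to_numpy(dtype=float),
        Z=df[level2].to_numpy(dtype=float),
        x_names=level1,
        z_names=level2,
    )


def split_within_cluster(
    data: HierarchicalDataset, fraction: float = 0.5, seed: int | None = None
) -> tuple[HierarchicalDataset, HierarchicalDataset]:
    """Split every cluster's rows into train/test at the given fraction.

    Each cluster contributes ``round(fraction * n_j)`` rows (at least one,
    at most ``n_j - 1``) to the training set and the remainder to the test
    set, sampled without replacement.  Every cluster therefore appears in
    both sets, which is what allows test-set predictions to reuse the
    estimated random intercepts.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    codes = data.cluster_codes
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for j in range(codes.max() + 1):
        rows = np.nonzero(codes == j)[0]
        nj = len(rows)
        if nj < 2:
            raise ValueError(
                f"cluster {data.cluster_labels[j]!r} has a single row; "
                "cannot appear in both train and test"
            )
        k = int(np.rint(fraction * nj))
        k = min(max(k, 1), nj - 1)
        perm = rng.permutation(rows)
        train_idx.append(np.sort(perm[:k]))
        test_idx.append(np.sort(perm[k:]))
    train = data.subset(np.concatenate(train_idx))
    test = data.subset(np.concatenate(test_idx))
    return train, test
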