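"""Random-subspace ensemble of K-nearest-neighbour classifiers.

Each ensemble member owns a random subset of the latent feature
dimensions (sampled without replacement within a member, independently
across members) and a KNN classifier restricted to those coordinates.
Member votes are combined by majority; an ensemble-level tie goes to
the pathological class by default, reflecting the asymmetric clinical
cost of missing a pathological brain.

Determinism rules: neighbours are ordered by (distance, training
index) with a stable sort, so equal distances resolve to the smallest
training index; a tied neighbour vote (possible for even K) falls back
to the label of the single nearest neighbour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

PATHOLOGICAL = "pathological"


@dataclass
class KNNState:
    """Training set of one KNN member (already restricted to its subspace)."""

    train_points: np.ndarray
    train_labels: np.ndarray
    K: int

    def __post_init__(self) -> None:
        self.train_points = np.asarray(self.train_points, dtype=np.float64)
        self.train_labels = np.asarray(self.train_labels)
        if self.K < 1 or self.K > len(self.train_labels):
            raise ValueError(f"K={self.K} must lie in [1, n_train]")


def knn_predict(state: KNNState, Xq: np.ndarray) -> np.ndarray:
    """Majority label among the K nearest training points (Euclidean)."""
    Xq = np.atleast_2d(np.asarray(Xq, dtype=np.float64))
    if Xq.shape[1] != state.train_points.shape[1]:
        raise ValueError("query dimensionality does not match training data")
    d2 = ((Xq[:, None, :] - state.train_points[None, :, :]) ** 2).sum(axis=2)
    order = np.argsort(d2, axis=1, kind="stable")  # ties -> smallest index
    nearest = state.train_labels[order[:, : state.K]]
    out = np.empty(len(Xq), dtype=state.train_labels.dtype)
    for i, row in enumerate(nearest):
        labs, counts = np.unique(row, return_counts=True)
        top = counts.max()
        winners = labs[counts == top]
        out[i] = winners[0] if len(winners) == 1 else row[0]
    return out


@dataclass
class SubspaceEnsemble:
    members: list[tuple[np.ndarray, KNNState]]
    n_members: int
    subspace_dim: int
    K: int
    distance: str
    tie_rule: str
    seed: int
    classes: np.ndarray

    @property
    def d(self) -> int:
        return int(max(int(idx.max()) for idx, _ in self.members)) + 1


def fit_ensemble(
    X: np.ndarray,
    y: Sequence,
    n_members: int = 30,
    subspace_dim: int | None = None,
    K: int = 5,
    seed: int = 0,
    tie_rule: str = PATHOLOGICAL,
) -> SubspaceEnsemble:
    """Train the random-subspace KNN ensemble.

    ``subspace_dim`` defaults to ceil(d/2) (7 when d=13).  Requires both
    classes present and K <= n.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X must be n x d with one label per row")
    n, d = X.shape
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    if subspace_dim is None:
        subspace_dim = math.ceil(d / 2)
    if not 1 <= subspace_dim <= d:
        raise ValueError(f"subspace_dim={subspace_dim} must lie in [1, {d}]")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of training samples {n}")
    if tie_rule not in (PATHOLOGICAL, "lowest_label"):
        raise ValueError(f"unknown tie rule {tie_rule!r}")

    rng = np.random.default_rng(seed)
    members = []
    for _ in range(n_members):
        idx = np.sort(rng.choice(d, size=subspace_dim, replace=False))
        members.append((idx, KNNState(X[:, idx], y, K)))
    return SubspaceEnsemble(
        members=members, n_members=n_members, subspace_dim=subspace_dim,
        K=K, distance="euclidean", tie_rule=tie_rule, seed=seed, classes=classes,
    )


def predict_votes(ens: SubspaceEnsemble, Xq: np.ndarray) -> np.ndarray:
    """Per-member vote matrix of shape (n_queries, n_members)."""
    Xq = np.atleast_2d(np.asarray(Xq, dtype=np.float64))
    votes = np.empty((len(Xq), ens.n_members), dtype=ens.members[0][1].train_labels.dtype)
    for j, (idx, knn) in enumerate(ens.members):
        if idx.max() >= Xq.shape[1]:
            raise ValueError("query dimensionality does not match the ensemble")
        votes[:, j] = knn_predict(knn, Xq[:, idx])
    return votes


def _majority(ens: SubspaceEnsemble, vote_row: np.ndarray):
    labs, counts = np.unique(vote_row, return_counts=True)
    top = counts.max()
    winners = labs[counts == top]
    if len(winners) == 1:
        return winners[0]
    if ens.tie_rule == PATHOLOGICAL and PATHOLOGICAL in winners:
        return PATHOLOGICAL
    return np.sort(winners)[0]


def predict(ens: SubspaceEnsemble, Xq: np.ndarray) -> np.ndarray:
    """Ensemble decision: row-wise majority of the member votes."""
    votes = predict_votes(ens, Xq)
    return np.array([_majority(ens, row) for row in votes])


def vote_fraction(ens: SubspaceEnsemble, Xq: np.ndarray, label: str = PATHOLOGICAL) -> np.ndarray:
    """Fraction of members voting ``label`` — a confidence-like score."""
    votes = predict_votes(ens, Xq)
    return (votes == label).mean(axis=1)


def save_ensemble(ens: SubspaceEnsemble, path: Union[str, Path]) -> None:
    arrays = {
        "n_members": ens.n_members, "subspace_dim": ens.subspace_dim,
        "K": ens.K, "tie_rule": ens.tie_rule, "seed": ens.seed,
        "distance": ens.distance, "classes": ens.classes.astype(str),
    }
    for j, (idx, knn) in enumerate(ens.members):
        arrays[f"idx_{j}"] = idx
        arrays[f"X_{j}"] = knn.train_points
        arrays[f"y_{j}"] = knn.train_labels.astype(str)
    np.savez_compressed(path, **arrays)


def load_ensemble(path: Union[str, Path]) -> SubspaceEnsemble:
    with np.load(path, allow_pickle=False) as f:
        n_members = int(f["n_members"])
        K = int(f["K"])
        members = [
            (f[f"idx_{j}"], KNNState(f[f"X_{j}"], f[f"y_{j}"], K))
            for j in range(n_members)
        ]
        return SubspaceEnsemble(
            members=members, n_members=n_members,
            subspace_dim=int(f["subspace_dim"]), K=K,
            distance=str(f["distance"]), tie_rule=str(f["tie_rule"]),
            seed=int(f["seed"]), classes=f["classes"],
        )
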