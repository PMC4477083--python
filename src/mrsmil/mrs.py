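"""Minimum reference set (MRS) generation.

The MRS of a binary-labeled bag collection is the smallest-found subset of
labeled bags that, used as the labeled seeds of a manifold-ranking
classifier, classifies *all* labeled bags correctly (zero training error).
Starting from the empty set, each iteration adds the closest cross-class bag
pair with at least one member still outside the set, then re-runs the MR
classifier seeded by the current set; iteration stops at zero error or when
every bag is in the set (fallback, returned with its residual error).

The size of the resulting set is the selection criterion used upstream: a
smaller reference set means fewer labeled bags suffice to separate the
classes, i.e. better expected generalisation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .data_model import Bag
from .manifold_ranking import (
    MRParams,
    MRSolver,
    affinity_from_distances,
    pairwise_bag_distances,
)

__all__ = ["ReferenceSet", "generate_mrs", "generate_mrs_from_points", "mrs_size"]


@dataclass(frozen=True)
class ReferenceSet:
    """Indices (into positives-then-negatives order) of the reference bags."""

    bag_indices: tuple[int, ...]
    achieved_training_error: float
    iterations: int

    def __post_init__(self) -> None:
        if len(set(self.bag_indices)) != len(self.bag_indices):
            raise ValueError("reference set indices must be unique")


def mrs_size(refset: ReferenceSet) -> int:
    """Number of bags in the reference set — the selection criterion."""
    return len(refset.bag_indices)


def _generate_from_distance_matrix(
    D: np.ndarray,
    n_pos: int,
    params: MRParams,
    size_limit: int | None = None,
) -> ReferenceSet:
    """Core greedy loop on a precomputed bag-distance matrix.

    Nodes 0..n_pos-1 are positive, the rest negative. ``size_limit`` aborts
    the run once the set grows past the limit (used as an exact
    branch-and-bound prune when only the comparison of sizes matters).
    """
    n = D.shape[0]
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be non-empty")
    truth = np.concatenate([np.ones(n_pos, dtype=int), np.zeros(n_neg, dtype=int)])

    graph = affinity_from_distances(D, params)
    solver = MRSolver(graph, params)

    cross = D[:n_pos, n_pos:].copy()  # rows: positives, cols: negatives
    in_set = np.zeros(n, dtype=bool)
    error = 1.0
    iterations = 0
    while True:
        # minimum-distance cross-class pair with >= 1 member outside the set;
        # mask fully-included pairs, tie-break on lowest (pos, neg) index.
        masked = np.where(
            in_set[:n_pos, None] & in_set[None, n_pos:], np.inf, cross
        )
        flat = int(np.argmin(masked))
        i, j = divmod(flat, n_neg)
        if not np.isfinite(masked[i, j]):
            break  # every bag already in the set
        in_set[i] = True
        in_set[n_pos + j] = True
        iterations += 1

        seed_idx = np.flatnonzero(in_set)
        pred = solver.classify(seed_idx, truth[seed_idx])
        if len(set(truth[seed_idx].tolist())) == 1:
            pred = np.full(n, truth[seed_idx][0])
        error = float(np.mean(pred != truth))
        if error == 0.0 or in_set.all():
            break
        if size_limit is not None and int(in_set.sum()) > size_limit:
            break
    return ReferenceSet(tuple(np.flatnonzero(in_set).tolist()), error, iterations)


def generate_mrs(
    positive_bags: Sequence[Bag],
    negative_bags: Sequence[Bag],
    params: MRParams,
    size_limit: int | None = None,
) -> ReferenceSet:
    """Generate the MRS for a binary bag problem.

    Returned indices refer to the concatenation positives + negatives.
    ``achieved_training_error`` is 0.0 on success; if zero error is
    unreachable the full bag set is returned with its residual error.
    """
    bags = list(positive_bags) + list(negative_bags)
    D = pairwise_bag_distances(bags, params.bag_metric)
    return _generate_from_distance_matrix(D, len(positive_bags), params, size_limit)


def generate_mrs_from_points(
    X_pos: np.ndarray,
    X_neg: np.ndarray,
    params: MRParams,
    size_limit: int | None = None,
) -> ReferenceSet:
    """MRS over singleton bags given directly as point matrices (Euclidean)."""
    X_pos = np.atleast_2d(np.asarray(X_pos, dtype=float))
    X_neg = np.atleast_2d(np.asarray(X_neg, dtype=float))
    if X_pos.shape[0] == 0 or X_neg.shape[0] == 0:
        raise ValueError("both classes must be non-empty")
    X = np.vstack([X_pos, X_neg])
    D = cdist(X, X)
    return _generate_from_distance_matrix(D, X_pos.shape[0], params, size_limit)
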