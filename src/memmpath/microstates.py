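"""Microstate discretization and lagged transition counting.

Frames projected into IC space are clustered by k-means into microstates;
transitions between microstates at a fixed lag, counted separately per
thermodynamic ensemble and never across trajectory boundaries, are the raw
statistics for multi-ensemble Markov model estimation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .toysim import DiscreteTrajectorySet

__all__ = [
    "Discretization",
    "CountTensor",
    "kmeans_cluster",
    "assign",
    "count_transitions",
]


@dataclass
class Discretization:
    centers: np.ndarray         # (k, d)
    dtrajs: list                # per-trajectory state sequences
    k: int
    seed: int
    inertia: float


def assign(points, centers) -> np.ndarray:
    """Nearest-center state assignment; ties resolve to the lowest index."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    centers = getattr(centers, "centers", centers)
    centers = np.asarray(centers, dtype=float)
    if points.shape[1] != centers.shape[1]:
        raise ValueError(
            f"point dimension {points.shape[1]} != centers {centers.shape[1]}"
        )
    d = cdist(points, centers, metric="sqeuclidean")
    return np.argmin(d, axis=1).astype(np.int64)  # argmin takes first on ties


def kmeans_cluster(points, k: int, seed: int, max_iter: int = 300,
                   tol: float = 1e-6) -> Discretization:
    """k-means with k-means++ seeding, deterministic under ``seed``.

    ``points`` is a single (n, d) array or a list of per-trajectory arrays;
    with a list, the stored state sequences follow the trajectory split.
    """
    if isinstance(points, (list, tuple)):
        trajs = [np.atleast_2d(np.asarray(p, dtype=float)) for p in points]
    else:
        trajs = [np.atleast_2d(np.asarray(points, dtype=float))]
    pooled = np.concatenate(trajs)
    if len(pooled) == 0:
        raise ValueError("empty input")
    n_distinct = len(np.unique(pooled, axis=0))
    if k > n_distinct:
        raise ValueError(f"k={k} exceeds {n_distinct} distinct points")
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed,
                max_iter=max_iter, tol=tol, algorithm="lloyd")
    km.fit(pooled)
    centers = km.cluster_centers_
    # re-assign with our own tie rule so stored sequences and `assign` agree
    dtrajs = [assign(t, centers) for t in trajs]
    labels = np.concatenate(dtrajs)
    inertia = float(
        np.sum((pooled - centers[labels]) ** 2)
    )
    return Discretization(centers=centers, dtrajs=dtrajs, k=k, seed=seed,
                          inertia=inertia)


@dataclass
class CountTensor:
    counts: np.ndarray          # (n_ensembles, k, k) int
    lag: int
    mode: str                   # {"sliding", "strided"}
    state_counts: np.ndarray    # (n_ensembles, k) frames per (ensemble, state)

    @property
    def n_states(self):
        return self.counts.shape[1]

    @property
    def n_ensembles(self):
        return self.counts.shape[0]


def count_transitions(dtrajs: DiscreteTrajectorySet, lag: int,
                      mode: str = "sliding") -> CountTensor:
    """Transition counts at ``lag`` per ensemble.

    ``sliding`` counts every pair (t, t+lag); ``strided`` counts only
    non-overlapping pairs (t = 0, lag, 2*lag, ...), useful when statistically
    independent counts are wanted.  Pairs never span trajectories or
    ensembles.  Trajectories shorter than lag+1 contribute nothing; if a
    whole ensemble has no pairs its count matrix is all zero.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    if mode not in ("sliding", "strided"):
        raise ValueError("mode must be 'sliding' or 'strided'")
    n = dtrajs.n_states
    n_ens = max(dtrajs.ensembles) + 1
    counts = np.zeros((n_ens, n, n), dtype=np.int64)
    state_counts = np.zeros((n_ens, n), dtype=np.int64)
    for seq, ens in zip(dtrajs.dtrajs, dtrajs.ensembles):
        np.add.at(state_counts[ens], seq, 1)
        if len(seq) <= lag:
            continue
        if mode == "sliding":
            a, b = seq[:-lag], seq[lag:]
        else:
            sub = seq[::lag]
            a, b = sub[:-1], sub[1:]
        np.add.at(counts[ens], (a, b), 1)
    return CountTensor(counts=counts, lag=lag, mode=mode,
                       state_counts=state_counts)
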