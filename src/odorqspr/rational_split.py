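"""Rational train/test division via k-medoid clustering.

Compounds are clustered in autoscaled descriptor space with the PAM
(partitioning around medoids) algorithm — greedy BUILD initialization
followed by SWAP passes until no medoid exchange lowers the summed
Euclidean distance.  Roughly one compound in four, picked systematically
along the within-cluster distance ranking, forms the test set; medoids
always stay in the training set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClusterAssignment", "kmedoid", "assign_test"]


class SplitError(ValueError):
    pass


@dataclass
class ClusterAssignment:
    medoid_ids: list[str]
    labels: dict[str, int]
    total_cost: float
    #: distance of each compound to its assigned medoid
    distances: dict[str, float]
    #: total cost after each SWAP pass (cost is non-increasing)
    cost_history: list[float]

    def report_frame(self) -> pd.DataFrame:
        ids = list(self.labels)
        return pd.DataFrame(
            {
                "id": ids,
                "cluster": [self.labels[i] for i in ids],
                "distance_to_medoid": [self.distances[i] for i in ids],
            }
        )


def _pairwise_distances(X: np.ndarray) -> np.ndarray:
    sq = np.sum(X * X, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.maximum(d2, 0.0, out=d2)
    return np.sqrt(d2)


def kmedoid(Xs: pd.DataFrame, k: int, seed: int = 0) -> ClusterAssignment:
    """PAM k-medoid clustering on a scaled feature frame.

    BUILD greedily adds the medoid that most reduces the summed distance
    of every point to its nearest medoid; SWAP exhaustively tries every
    (medoid, non-medoid) exchange and applies the best strict improvement
    until none exists.  Ties are broken by row order, so the result is
    deterministic; ``seed`` is accepted for interface uniformity but no
    random draw is needed.
    """
    ids = [str(i) for i in Xs.index]
    n = len(ids)
    if k <= 0:
        raise SplitError("k must be positive")
    if k > n:
        raise SplitError(f"k={k} exceeds number of compounds n={n}")
    X = Xs.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise SplitError("missing values in feature matrix")
    D = _pairwise_distances(X)

    # BUILD
    medoids: list[int] = [int(np.argmin(D.sum(axis=1)))]
    nearest = D[medoids[0]].copy()
    while len(medoids) < k:
        # cost reduction of adding each candidate
        gains = np.sum(np.maximum(nearest[None, :] - D, 0.0), axis=1)
        gains[medoids] = -np.inf
        cand = int(np.argmax(gains))
        medoids.append(cand)
        nearest = np.minimum(nearest, D[cand])

    def assignment_cost(meds: list[int]) -> tuple[np.ndarray, np.ndarray, float]:
        sub = D[np.asarray(meds)]  # k x n
        lab = np.argmin(sub, axis=0)
        dist = sub[lab, np.arange(n)]
        return lab, dist, float(dist.sum())

    lab, dist, cost = assignment_cost(medoids)
    history = [cost]
    # SWAP: best-improvement passes
    while True:
        best = (0.0, None)
        non_medoids = [j for j in range(n) if j not in medoids]
        for mi, m in enumerate(medoids):
            for h in non_medoids:
                trial = list(medoids)
                trial[mi] = h
                _, _, c = assignment_cost(trial)
                delta = c - cost
                if delta < best[0] - 1e-12:
                    best = (delta, (mi, h))
        if best[1] is None:
            break
        mi, h = best[1]
        medoids[mi] = h
        lab, dist, cost = assignment_cost(medoids)
        history.append(cost)

    return ClusterAssignment(
        medoid_ids=[ids[m] for m in medoids],
        labels={ids[i]: int(lab[i]) for i in range(n)},
        total_cost=cost,
        distances={ids[i]: float(dist[i]) for i in range(n)},
        cost_history=history,
    )


def assign_test(clusters: ClusterAssignment, fraction: float = 0.25) -> tuple[list[str], list[str]]:
    """Systematic per-cluster test-set selection.

    Within each cluster, compounds are ranked by distance to the medoid
    (medoid first); ``round(fraction * size)`` members are drawn at
    evenly spaced positions along that ranking, so the test set samples
    the whole spread of each cluster.  Medoids always train; a singleton
    cluster contributes no test compound.
    """
    if not (0 < fraction < 1):
        raise SplitError("fraction must be in (0, 1)")
    test: list[str] = []
    train: list[str] = []
    k = len(clusters.medoid_ids)
    for c in range(k):
        members = [i for i, lab in clusters.labels.items() if lab == c]
        # medoid first, then by distance; id as deterministic tie-break
        members.sort(key=lambda i: (i != clusters.medoid_ids[c], clusters.distances[i], i))
        size = len(members)
        count = min(int(np.floor(size * fraction + 0.5)), size - 1)  # round half up
        picked: set[int] = set()
        for j in range(1, count + 1):
            pos = int(round(j * size / (count + 1)))  # 0-based; never 0 for j>=1
            pos = max(1, min(pos, size - 1))
            while pos in picked and pos < size - 1:
                pos += 1
            while pos in picked and pos > 1:
                pos -= 1
            picked.add(pos)
        for rank, cid in enumerate(members):
            (test if rank in picked else train).append(cid)
    return train, test


def split_frame(train: list[str], test: list[str]) -> pd.DataFrame:
    return pd.DataFrame(
        {"id": train + test, "set": ["train"] * len(train) + ["test"] * len(test)}
    )
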