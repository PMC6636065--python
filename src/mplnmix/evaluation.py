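"""Partition hardening and scoring, plus distance-based comparator methods."""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .model import CountMatrix, InputError

__all__ = ["map_classify", "adjusted_rand_index", "distance_comparators"]


def map_classify(z: np.ndarray) -> np.ndarray:
    """MAP hardening of responsibilities: per-row argmax, ties to the lowest index."""
    z = np.asarray(z, dtype=float)
    return z.argmax(axis=1)


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Hubert-Arabie adjusted Rand index between two partitions.

    1 for identical partitions (up to relabeling), ~0 for independent ones;
    can be negative for partitions that agree less than chance.
    """
    labels_a = np.asarray(labels_a).ravel()
    labels_b = np.asarray(labels_b).ravel()
    if labels_a.shape != labels_b.shape:
        raise InputError("partitions must have equal length")
    if labels_a.shape[0] < 2:
        raise InputError("need at least 2 observations")
    return float(adjusted_rand_score(labels_a, labels_b))


def _pam(X: np.ndarray, G: int, rng, max_iter: int = 100,
         n_restarts: int = 5) -> np.ndarray:
    """Partitioning around medoids (alternating assignment / medoid update).

    Restarted from several random medoid sets; the solution with the lowest
    total within-cluster distance wins.
    """
    n = X.shape[0]
    dist = cdist(X, X)
    best_labels, best_cost = None, np.inf
    for _ in range(n_restarts):
        medoids = rng.choice(n, size=G, replace=False)
        labels = dist[:, medoids].argmin(axis=1)
        for _ in range(max_iter):
            new_medoids = medoids.copy()
            for g in range(G):
                members = np.where(labels == g)[0]
                if members.size == 0:
                    new_medoids[g] = rng.integers(n)
                    continue
                within = dist[np.ix_(members, members)].sum(axis=1)
                new_medoids[g] = members[within.argmin()]
            new_labels = dist[:, new_medoids].argmin(axis=1)
            if (np.array_equal(new_medoids, medoids)
                    and np.array_equal(new_labels, labels)):
                break
            medoids, labels = new_medoids, new_labels
        cost = dist[np.arange(n), medoids[labels]].sum()
        if cost < best_cost:
            best_cost, best_labels = cost, labels
    return best_labels


def distance_comparators(y: CountMatrix, G: int, method: str = "kmeans",
                         seed: int = 0) -> np.ndarray:
    """Distance-based clustering baselines on log1p counts.

    method: "kmeans", "medoids" (PAM) or "hierarchical" (Ward linkage,
    Euclidean).  These are reference points for the model-based fit, not
    part of it.
    """
    if G > y.n:
        raise InputError("more clusters than observations")
    X = np.log1p(y.values.astype(float))
    if method == "kmeans":
        km = KMeans(n_clusters=G, n_init=3, random_state=int(seed) % (2**32))
        return km.fit_predict(X)
    if method == "medoids":
        return _pam(X, G, np.random.default_rng(seed))
    if method == "hierarchical":
        return fcluster(linkage(X, method="ward"), t=G, criterion="maxclust") - 1
    raise InputError(f"unsupported method {method!r}")
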