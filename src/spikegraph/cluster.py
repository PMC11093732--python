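"""Landmark-based bipartite modularity clustering.

Every point is a 'left' node; a fixed-size uniform subsample of points
('landmarks') is copied to the 'right' side, and each left node is
connected to its k exact nearest landmarks in Euclidean feature space.
Because edges only run left-right, all left labels can be updated in
parallel given fixed right labels (and vice versa) under the bipartite
modularity

    H = (1/2m) * sum_c ( e_c - gamma * K_c_left * K_c_right / (2m) )

where m is the edge count, e_c the number of within-cluster edges and
K_c_left / K_c_right the summed degrees of the cluster's left / right
nodes. Iterating the two parallel sweeps from a 200-cluster k-means++
initialization converges to a local minimum that is deliberately
oversplit — merges are decided later by the merging tree.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import kmeans_plusplus
from sklearn.neighbors import NearestNeighbors

__all__ = ["BipartiteGraph", "ClusterAssignment", "subsample_landmarks",
           "knn_bipartite", "kmeanspp_init", "bipartite_modularity",
           "iterate_reassignment", "cluster_features"]

N_SUB_DEFAULT = 25000       # landmarks per 40-um probe section
K_DEFAULT = 10              # neighbors per point (not stated upstream)
N_INIT_DEFAULT = 200        # k-means++ clusters at initialization
N_ITER_DEFAULT = 30         # maximum left+right sweeps


@dataclass
class BipartiteGraph:
    """kNN adjacency from all points (left) to landmark copies (right)."""

    neighbors: np.ndarray        # (N, k) indices into landmarks
    landmarks: np.ndarray        # (n_sub,) indices into the point set
    k: int

    @property
    def n_left(self) -> int:
        return self.neighbors.shape[0]

    @property
    def n_right(self) -> int:
        return len(self.landmarks)

    @property
    def m(self) -> int:
        """Total number of edges."""
        return self.neighbors.size

    @property
    def left_degree(self) -> np.ndarray:
        return np.full(self.n_left, self.k)

    @property
    def right_degree(self) -> np.ndarray:
        return np.bincount(self.neighbors.ravel(),
                           minlength=self.n_right)


@dataclass
class ClusterAssignment:
    left: np.ndarray             # label per point
    right: np.ndarray            # label per landmark copy (may differ)
    gamma: float = 1.0

    @property
    def n_clusters(self) -> int:
        labels = np.concatenate([self.left, self.right])
        return len(np.unique(labels))


def subsample_landmarks(n_points: int, n_sub: int = N_SUB_DEFAULT,
                        seed: int | np.random.Generator = 0) -> np.ndarray:
    """Uniformly random landmark subset of size min(n_points, n_sub)."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    if n_points <= n_sub:
        return np.arange(n_points)
    return np.sort(rng.choice(n_points, n_sub, replace=False))


def knn_bipartite(features: np.ndarray, landmarks: np.ndarray,
                  k: int = K_DEFAULT) -> BipartiteGraph:
    """Exact k-nearest-landmark graph (brute-force Euclidean search).

    A point that is itself a landmark is never linked to its own copy:
    self-edges carry no neighborhood information and make singleton
    clusters spurious local minima of the reassignment dynamics.
    """
    features = np.asarray(features, np.float32)
    landmarks = np.asarray(landmarks)
    if not np.isfinite(features).all():
        raise ValueError("non-finite features")
    n_lm = len(landmarks)
    k = min(k, max(n_lm - 1, 1))
    nn = NearestNeighbors(n_neighbors=min(k + 1, n_lm), algorithm="brute")
    nn.fit(features[landmarks])
    _, idx = nn.kneighbors(features)
    if idx.shape[1] > k:
        own = landmarks[idx] == np.arange(len(features))[:, None]
        order = np.argsort(own, axis=1, kind="stable")  # non-self first
        idx = np.take_along_axis(idx, order, axis=1)[:, :k]
    return BipartiteGraph(idx.astype(np.int32), landmarks, k)


def kmeanspp_init(features: np.ndarray, graph: BipartiteGraph,
                  n_init: int = N_INIT_DEFAULT,
                  seed: int | np.random.Generator = 0) -> ClusterAssignment:
    """k-means++ seeding (D^2 sampling); every point joins its nearest
    seed, landmarks inherit the label of the point they copy."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    features = np.asarray(features, np.float32)
    n = len(features)
    # preserve the full-scale seed occupancy (25,000 landmarks / 200
    # seeds = 125 spikes per seed) when a section holds fewer spikes
    n_init = max(2, min(n_init, n // 125, n))
    centers, _ = kmeans_plusplus(
        features, n_clusters=n_init,
        random_state=int(rng.integers(2**31 - 1)))
    labels = _nearest_center(features, centers)
    return ClusterAssignment(labels, labels[graph.landmarks].copy())


def _nearest_center(X: np.ndarray, centers: np.ndarray,
                    chunk: int = 4096) -> np.ndarray:
    out = np.empty(len(X), np.int32)
    c2 = (centers ** 2).sum(1)
    for i in range(0, len(X), chunk):
        d = c2[None, :] - 2.0 * X[i:i + chunk] @ centers.T
        out[i:i + chunk] = np.argmin(d, axis=1)
    return out


def bipartite_modularity(graph: BipartiteGraph, assign: ClusterAssignment
                         ) -> float:
    """Evaluate H for the given assignment."""
    m = graph.m
    if m == 0:
        return 0.0
    ll = assign.left[:, None]                      # (N, 1)
    rl = assign.right[graph.neighbors]             # (N, k)
    n_cl = max(assign.left.max(), assign.right.max()) + 1
    within = (rl == ll)
    e_c = np.bincount(ll.repeat(graph.k)[within.ravel()], minlength=n_cl)
    K_left = np.bincount(assign.left, weights=graph.left_degree,
                         minlength=n_cl)
    K_right = np.bincount(assign.right, weights=graph.right_degree,
                          minlength=n_cl)
    return float(np.sum(e_c - assign.gamma * K_left * K_right / (2 * m))
                 / (2 * m))


def _count_neighbor_labels(member_of: np.ndarray, labels: np.ndarray,
                           n_clusters: int) -> np.ndarray:
    """n_tc: for each row of ``member_of`` (neighbor lists), count the
    labels of the neighbors. Returns (n_nodes, n_clusters)."""
    n = member_of.shape[0]
    counts = np.zeros((n, n_clusters), np.float64)
    rows = np.repeat(np.arange(n), member_of.shape[1])
    np.add.at(counts, (rows, labels[member_of].ravel()), 1.0)
    return counts


def iterate_reassignment(graph: BipartiteGraph, assign: ClusterAssignment,
                         n_iter: int = N_ITER_DEFAULT,
                         check_monotone: bool = True) -> ClusterAssignment:
    """Alternate parallel left/right argmax sweeps until no label changes.

    Each left node t moves to argmax_c (n_tc - gamma * k_t * K_c_right /
    (2m)); ties go to the lowest cluster id (np.argmax), making runs
    bit-reproducible. The bipartite modularity is non-decreasing across
    full sweeps (asserted when ``check_monotone``). Empty clusters are
    dropped at the end.
    """
    gamma = assign.gamma
    m = graph.m
    left = assign.left.astype(np.int64).copy()
    right = assign.right.astype(np.int64).copy()
    n_cl = int(max(left.max(), right.max())) + 1
    k_left = graph.left_degree.astype(float)
    k_right = graph.right_degree.astype(float)
    # reverse adjacency: for each right node, its left neighbors
    order = np.argsort(graph.neighbors.ravel(), kind="stable")
    rev_left = np.repeat(np.arange(graph.n_left), graph.k)[order]
    rev_ptr = np.concatenate([[0], np.cumsum(
        np.bincount(graph.neighbors.ravel(), minlength=graph.n_right))])
    prev_H = bipartite_modularity(graph, ClusterAssignment(
        left, right, gamma)) if check_monotone else None
    for _ in range(n_iter):
        # left sweep
        n_tc = _count_neighbor_labels(graph.neighbors, right, n_cl)
        K_r = np.bincount(right, weights=k_right, minlength=n_cl)
        score = n_tc - gamma * np.outer(k_left, K_r) / (2 * m)
        new_left = np.argmax(score, axis=1)
        # right sweep (given updated left labels)
        n_sc = np.zeros((graph.n_right, n_cl))
        np.add.at(n_sc, (np.repeat(np.arange(graph.n_right),
                                   np.diff(rev_ptr)),
                         new_left[rev_left]), 1.0)
        K_l = np.bincount(new_left, weights=k_left, minlength=n_cl)
        score_r = n_sc - gamma * np.outer(k_right, K_l) / (2 * m)
        new_right = np.argmax(score_r, axis=1)
        changed = (new_left != left).any() or (new_right != right).any()
        left, right = new_left, new_right
        if check_monotone:
            H = bipartite_modularity(graph,
                                     ClusterAssignment(left, right, gamma))
            assert H >= prev_H - 1e-9, "modularity decreased during sweep"
            prev_H = H
        if not changed:
            break
    # drop empty clusters, relabel contiguously
    used = np.unique(np.concatenate([left, right]))
    remap = np.full(n_cl, -1, np.int64)
    remap[used] = np.arange(len(used))
    return ClusterAssignment(remap[left], remap[right], gamma)


def cluster_features(features: np.ndarray, n_sub: int = N_SUB_DEFAULT,
                     k: int = K_DEFAULT, n_init: int = N_INIT_DEFAULT,
                     n_iter: int = N_ITER_DEFAULT,
                     seed: int | np.random.Generator = 0
                     ) -> tuple[ClusterAssignment, BipartiteGraph]:
    """Landmarks -> kNN graph -> k-means++ init -> iterative reassignment."""
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    features = np.asarray(features, np.float32)
    landmarks = subsample_landmarks(len(features), n_sub, rng)
    graph = knn_bipartite(features, landmarks, k)
    init = kmeanspp_init(features, graph, n_init, rng)
    final = iterate_reassignment(graph, init, n_iter, check_monotone=False)
    return final, graph
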