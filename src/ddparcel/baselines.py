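"""Comparison parcellation methods, all constrained to the spatial graph.

Every method consumes the pairwise connectivity-fingerprint dissimilarity

    W_ij = sqrt( sum_{a != i,j} (D_ia - D_ja)^2 + sum_{a != i,j} (D_ai - D_aj)^2 )

and a target cluster count K, and returns a spatially contiguous
parcellation:

* ``local_similarity`` -- threshold neighbor edges (single linkage on the
  spatial graph);
* ``normalized_cut`` -- K-way spectral partitioning of the neighbor
  similarity graph S = 1/W;
* ``region_growing`` -- seeded growth followed by constrained Ward merging;
* ``ward`` -- spatially constrained agglomerative Ward linkage on the full W;
* ``random_parcellation`` -- iterative uniform merges of adjacent clusters,
  the chance baseline.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Set

import numpy as np
from sklearn.cluster import SpectralClustering

from .core import ConnectivityMatrix, Parcellation, SpatialGraph

__all__ = [
    "DissimilarityMatrix",
    "pairwise_dissimilarity",
    "WardTree",
    "ward",
    "local_similarity",
    "normalized_cut",
    "region_growing",
    "random_parcellation",
]

SIMILARITY_CAP = 1e12  # 1/W similarity when two fingerprints coincide


@dataclass
class DissimilarityMatrix:
    """Symmetric nonnegative N x N fingerprint dissimilarities, zero diagonal."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def pairwise_dissimilarity(D: ConnectivityMatrix) -> DissimilarityMatrix:
    """Connectivity-fingerprint distance between all element pairs.

    Both the row profile (outgoing connectivity) and the column profile
    (incoming) contribute; the entries involving i and j themselves are
    excluded from the sums.  For a symmetric matrix the two sums coincide, so
    W is sqrt(2) times the row-profile distance.
    """
    V = D.values.copy()
    if not D.diagonal_defined:
        np.fill_diagonal(V, 0.0)
    n = V.shape[0]
    if n < 3:
        raise ValueError("need at least 3 elements")

    def _profile_sq(M: np.ndarray) -> np.ndarray:
        sq = (M * M).sum(axis=1)
        G = M @ M.T
        full = sq[:, None] + sq[None, :] - 2.0 * G
        # remove the a = i and a = j terms
        dii = np.diag(M)
        corr = (dii[:, None] - M.T) ** 2 + (M - dii[None, :]) ** 2
        return full - corr

    W2 = _profile_sq(V) + _profile_sq(V.T)
    np.maximum(W2, 0.0, out=W2)
    W = np.sqrt(W2)
    np.fill_diagonal(W, 0.0)
    return DissimilarityMatrix(W)


# -- spatially constrained Ward --------------------------------------------


class WardTree:
    """Agglomerative Ward clustering restricted to merges of spatially
    adjacent clusters, built from a precomputed dissimilarity.

    ``W`` is treated as Euclidean distance between fingerprints; merge costs
    follow the Lance-Williams Ward update on squared distances, so on a
    complete graph the merge sequence reproduces classical Ward linkage.
    The full merge history is recorded once; ``labels(k)`` replays it.
    """

    def __init__(
        self,
        W: np.ndarray,
        graph: SpatialGraph,
        init_labels: Optional[np.ndarray] = None,
    ):
        W = np.asarray(W, dtype=float)
        n = graph.n_elements
        if W.shape != (n, n):
            raise ValueError("dissimilarity shape does not match graph")
        if init_labels is None:
            init_labels = np.arange(n)
        z0 = Parcellation.from_raw_labels(init_labels)
        self._init_labels = z0.labels.copy()
        members = z0.members()
        m = z0.k
        self.n_init = m

        sizes = np.array([len(x) for x in members], dtype=float)
        d2 = np.zeros((m, m))
        if m == n:
            d2 = W * W
        else:
            # cluster-level squared mean distances from pairwise W^2:
            # mean_{ij in AxB} d2 = V_A/n_A + V_B/n_B + |mu_A - mu_B|^2
            W2 = W * W
            v_over_n = np.array(
                [W2[np.ix_(mem, mem)].sum() / (2.0 * len(mem) ** 2) for mem in members]
            )
            for a in range(m):
                for b in range(a + 1, m):
                    cross = W2[np.ix_(members[a], members[b])].mean()
                    mu2 = max(cross - v_over_n[a] - v_over_n[b], 0.0)
                    lw = 2.0 * sizes[a] * sizes[b] / (sizes[a] + sizes[b]) * mu2
                    d2[a, b] = d2[b, a] = lw

        adj = np.zeros((m, m), dtype=bool)
        lab0 = z0.labels - 1
        for a, b in graph.edges:
            la, lb = lab0[a], lab0[b]
            if la != lb:
                adj[la, lb] = adj[lb, la] = True

        active = np.ones(m, dtype=bool)
        self.merges: List = []  # (slot_kept, slot_gone, cost)
        big = np.inf
        for _ in range(m - 1):
            masked = np.where(adj, d2, big)
            flat = int(np.argmin(masked))
            a, b = divmod(flat, m)
            if not np.isfinite(masked[a, b]):
                break  # graph disconnected at cluster level
            if a > b:
                a, b = b, a
            # Lance-Williams Ward update of distances from the merged cluster
            sa, sb = sizes[a], sizes[b]
            k = active.copy()
            k[a] = k[b] = False
            sk = sizes[k]
            d2[a, k] = ((sa + sk) * d2[a, k] + (sb + sk) * d2[b, k] - sk * d2[a, b]) / (
                sa + sb + sk
            )
            d2[k, a] = d2[a, k]
            adj[a] |= adj[b]
            adj[:, a] = adj[a]
            adj[a, a] = False
            adj[b, :] = adj[:, b] = False
            sizes[a] = sa + sb
            active[b] = False
            self.merges.append((a, b, float(masked[a, b] if a < b else masked[b, a])))

    def labels(self, k: int) -> Parcellation:
        """Cut the merge history at k clusters."""
        if k < 1 or k > self.n_init:
            raise ValueError(f"k must be in [1, {self.n_init}]")
        n_merges = self.n_init - k
        if n_merges > len(self.merges):
            raise ValueError(f"graph is disconnected; cannot reach k={k}")
        parent = np.arange(self.n_init)

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b, _ in self.merges[:n_merges]:
            parent[find(b)] = find(a)
        slot = np.array([find(s) for s in self._init_labels - 1])
        return Parcellation.from_raw_labels(slot)


def ward(W: DissimilarityMatrix, graph: SpatialGraph, K: int) -> Parcellation:
    """Spatially constrained Ward clustering of the full dissimilarity matrix."""
    return WardTree(W.values, graph).labels(K)


# -- helpers shared by threshold/spectral methods ---------------------------


def _cluster_adjacency(labels: np.ndarray, graph: SpatialGraph) -> Dict[int, Set[int]]:
    adj: Dict[int, Set[int]] = {int(l): set() for l in np.unique(labels)}
    for a, b in graph.edges:
        la, lb = int(labels[a]), int(labels[b])
        if la != lb:
            adj[la].add(lb)
            adj[lb].add(la)
    return adj


def _merge_smallest_down_to(labels: np.ndarray, graph: SpatialGraph, K: int) -> np.ndarray:
    """Repeatedly merge the smallest cluster into its smallest adjacent
    cluster until K remain.  Ties broken by cluster id."""
    labels = labels.copy()
    while len(np.unique(labels)) > K:
        ids, counts = np.unique(labels, return_counts=True)
        order = np.lexsort((ids, counts))
        adj = _cluster_adjacency(labels, graph)
        merged = False
        for idx in order:
            small = int(ids[idx])
            nbrs = sorted(adj[small])
            if not nbrs:
                continue
            sizes = {int(l): int(c) for l, c in zip(ids, counts)}
            target = min(nbrs, key=lambda l: (sizes[l], l))
            labels[labels == small] = target
            merged = True
            break
        if not merged:
            raise ValueError("disconnected spatial graph; cannot merge further")
    return labels


def _split_disconnected(labels: np.ndarray, graph: SpatialGraph) -> np.ndarray:
    """Give each spatially connected component of every cluster its own label."""
    from scipy.sparse.csgraph import connected_components as _cc

    labels = labels.copy()
    A = graph.adjacency_sparse
    next_label = labels.max() + 1
    for l in np.unique(labels):
        mem = np.where(labels == l)[0]
        if len(mem) == 1:
            continue
        ncomp, comp = _cc(A[mem][:, mem], directed=False)
        if ncomp > 1:
            for c in range(1, ncomp):
                labels[mem[comp == c]] = next_label
                next_label += 1
    return labels


# -- the four comparison methods --------------------------------------------


def local_similarity(W: DissimilarityMatrix, graph: SpatialGraph, K: int) -> Parcellation:
    """Threshold neighbor-edge dissimilarities so the retained-edge graph has
    K connected components (single linkage restricted to the spatial graph).

    The component count is a step function of the threshold, so an exact K
    can be skipped when tied edge weights enter together; in that case the
    closest achievable count >= K is taken and the smallest adjacent
    components are merged down to K, with a warning.
    """
    n = graph.n_elements
    if not 1 <= K <= n:
        raise ValueError("K out of range")
    edges = sorted(graph.edges, key=lambda e: (W.values[e[0], e[1]], e))
    weights = np.array([W.values[a, b] for a, b in edges])
    # group edges by tied weight; count components after each group
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    count = n
    stop_at = 0  # number of edges retained
    i = 0
    while i < len(edges) and count > K:
        j = i
        trial = count
        while j < len(edges) and weights[j] == weights[i]:
            a, b = edges[j]
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
                trial -= 1
            j += 1
        if trial >= K:
            count = trial
            stop_at = j
            i = j
        else:
            break
    # rebuild at the chosen threshold
    parent = np.arange(n)
    for a, b in edges[:stop_at]:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    labels = np.array([find(x) for x in range(n)])
    got = len(np.unique(labels))
    if got != K:
        warnings.warn(
            f"local_similarity: K={K} not reachable by thresholding "
            f"(closest {got}); merging smallest adjacent components"
        )
        labels = _merge_smallest_down_to(labels, graph, K)
    return Parcellation.from_raw_labels(labels)


def normalized_cut(
    W: DissimilarityMatrix, graph: SpatialGraph, K: int, seed: int = 0
) -> Parcellation:
    """K-way normalized cut of the neighbor similarity graph S = 1/W.

    Uses the spectral embedding + k-means discretization of the Shi-Malik
    relaxation.  Spectral clusters can come out spatially disconnected; they
    are split into their components and the count repaired by merging the
    smallest adjacent clusters back to K.
    """
    n = graph.n_elements
    if not 1 <= K <= n:
        raise ValueError("K out of range")
    if K == 1:
        return Parcellation.from_raw_labels(np.zeros(n, dtype=int))
    if K == n:
        return Parcellation.from_raw_labels(np.arange(n))
    S = np.zeros((n, n))
    for a, b in graph.edges:
        w = W.values[a, b]
        s = SIMILARITY_CAP if w <= 0 else min(1.0 / w, SIMILARITY_CAP)
        S[a, b] = S[b, a] = s
    sc = SpectralClustering(
        n_clusters=K,
        affinity="precomputed",
        assign_labels="kmeans",
        random_state=seed,
        n_init=10,
    )
    labels = sc.fit_predict(S)
    labels = _split_disconnected(labels, graph)
    got = len(np.unique(labels))
    if got > K:
        labels = _merge_smallest_down_to(labels, graph, K)
    while len(np.unique(labels)) < K:
        labels = _peel_leaf_from_largest(labels, graph)
    return Parcellation.from_raw_labels(labels)


def _peel_leaf_from_largest(labels: np.ndarray, graph: SpatialGraph) -> np.ndarray:
    """Detach one boundary element (a leaf of a BFS tree) of the largest
    cluster into a new singleton cluster; keeps every cluster contiguous."""
    labels = labels.copy()
    ids, counts = np.unique(labels, return_counts=True)
    big = int(ids[np.lexsort((ids, -counts))[0]])
    mem = [int(x) for x in np.where(labels == big)[0]]
    mset = set(mem)
    root = mem[0]
    seen = {root}
    order = [root]
    qi = 0
    while qi < len(order):
        u = order[qi]
        qi += 1
        for v in graph.neighbors[u]:
            v = int(v)
            if v in mset and v not in seen:
                seen.add(v)
                order.append(v)
    labels[order[-1]] = labels.max() + 1
    return labels


def region_growing(W: DissimilarityMatrix, graph: SpatialGraph, K: int) -> Parcellation:
    """Seeded region growing followed by constrained Ward merging.

    Seeds are elements whose worst (largest) neighbor dissimilarity is a
    local minimum over their neighborhood -- points likely to sit near parcel
    centers.  Regions grow by repeatedly attaching the unassigned neighbor
    with the smallest dissimilarity to its adjoining region's seed; grown
    regions are then merged by spatially constrained Ward linkage down to K.
    """
    n = graph.n_elements
    if not 1 <= K <= n:
        raise ValueError("K out of range")
    worst = np.array(
        [
            W.values[i, graph.neighbors[i]].max() if len(graph.neighbors[i]) else 0.0
            for i in range(n)
        ]
    )
    seeds = [
        i
        for i in range(n)
        if all(
            worst[i] < worst[j] or (worst[i] == worst[j] and i < j)
            for j in graph.neighbors[i]
        )
    ]
    if len(seeds) < K:
        taken = set(seeds)
        blocked = set(seeds)
        for s in seeds:
            blocked.update(int(v) for v in graph.neighbors[s])
        pool = sorted((i for i in range(n) if i not in taken), key=lambda i: (worst[i], i))
        for i in pool:
            if len(seeds) >= K:
                break
            if i in blocked:
                continue
            seeds.append(i)
            taken.add(i)
            blocked.add(i)
            blocked.update(int(v) for v in graph.neighbors[i])
        for i in pool:  # relax the non-adjacency preference if still short
            if len(seeds) >= K:
                break
            if i not in taken:
                seeds.append(i)
                taken.add(i)

    labels = np.full(n, -1, dtype=np.int64)
    heap = []
    for r, s in enumerate(seeds):
        labels[s] = r
        for v in graph.neighbors[s]:
            heapq.heappush(heap, (W.values[s, int(v)], int(v), r))
    seed_of = {r: s for r, s in enumerate(seeds)}
    while heap:
        _, elem, r = heapq.heappop(heap)
        if labels[elem] != -1:
            continue
        labels[elem] = r
        s = seed_of[r]
        for v in graph.neighbors[elem]:
            v = int(v)
            if labels[v] == -1:
                heapq.heappush(heap, (W.values[s, v], v, r))
    if len(seeds) == K:
        return Parcellation.from_raw_labels(labels)
    tree = WardTree(W.values, graph, init_labels=labels)
    return tree.labels(K)


def random_parcellation(
    graph: SpatialGraph, K: int, rng: np.random.Generator
) -> Parcellation:
    """Chance baseline: from singletons, repeatedly pick a cluster uniformly
    at random and merge it with a uniformly random neighboring cluster until
    K clusters remain.  Contiguous by construction."""
    n = graph.n_elements
    if not 1 <= K <= n:
        raise ValueError("K out of range")
    labels = np.arange(n)
    adj = {i: set(int(v) for v in graph.neighbors[i]) for i in range(n)}
    alive = sorted(adj)
    while len(alive) > K:
        c = alive[int(rng.integers(len(alive)))]
        nbrs = sorted(adj[c])
        if not nbrs:
            raise ValueError("disconnected spatial graph")
        d = nbrs[int(rng.integers(len(nbrs)))]
        keep, gone = (c, d) if c < d else (d, c)
        labels[labels == gone] = keep
        adj[keep] = (adj[keep] | adj[gone]) - {keep, gone}
        for e in adj[gone]:
            if e != keep:
                adj[e].discard(gone)
                adj[e].add(keep)
        adj[keep].discard(keep)
        del adj[gone]
        alive = sorted(adj)
    return Parcellation.from_raw_labels(labels)
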