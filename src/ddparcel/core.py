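"""Core spatial types: adjacency graphs, connectivity matrices, links, parcellations.

Conventions used throughout the package:

* Elements are indexed ``0..N-1``, in files as well as in memory.
* A symmetric connectivity matrix contributes each observation once: its
  "included entries" are the strict upper triangle.  For an asymmetric matrix
  every off-diagonal entry is included.
* Self-connectivity (the diagonal) is excluded from normalization and from all
  block statistics unless ``diagonal_defined`` is set.  The correlation
  diagonal of a functional connectivity matrix is trivially 1 and carries no
  information about parcel structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components as _sparse_cc

__all__ = [
    "SpatialGraph",
    "ConnectivityMatrix",
    "LinkState",
    "Parcellation",
    "connected_components",
    "normalize_matrix",
    "assert_contiguous",
]


@dataclass(frozen=True)
class SpatialGraph:
    """An undirected neighbor relation over ``n_elements`` spatial elements.

    Edges are stored as ``(min, max)`` index pairs.  The graph is the support
    of the distance-dependent CRP prior: element *i* may link only to itself
    or to one of its neighbors, which is what guarantees that every cluster
    is spatially connected.
    """

    n_elements: int
    edges: frozenset

    def __post_init__(self):
        if self.n_elements <= 0:
            raise ValueError("n_elements must be positive")
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-edge ({a},{a}) not allowed")
            if not (0 <= a < self.n_elements and 0 <= b < self.n_elements):
                raise ValueError(f"edge ({a},{b}) endpoint out of range")
            if a > b:
                raise ValueError("edges must be normalized as (min, max); use from_edges")

    @classmethod
    def from_edges(cls, n_elements: int, edges: Iterable) -> "SpatialGraph":
        return cls(n_elements, frozenset((min(a, b), max(a, b)) for a, b in edges))

    @classmethod
    def grid(cls, rows: int, cols: int) -> "SpatialGraph":
        """4-neighbor grid, elements numbered row-major."""
        edges = []
        for r in range(rows):
            for c in range(cols):
                i = r * cols + c
                if c + 1 < cols:
                    edges.append((i, i + 1))
                if r + 1 < rows:
                    edges.append((i, i + cols))
        return cls.from_edges(rows * cols, edges)

    @cached_property
    def neighbors(self) -> list:
        """Sorted neighbor index array for every element."""
        nbrs = [[] for _ in range(self.n_elements)]
        for a, b in self.edges:
            nbrs[a].append(b)
            nbrs[b].append(a)
        return [np.array(sorted(x), dtype=np.int64) for x in nbrs]

    @cached_property
    def degrees(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbors], dtype=np.int64)

    def are_neighbors(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self.edges

    @cached_property
    def adjacency_sparse(self) -> sparse.csr_matrix:
        if not self.edges:
            return sparse.csr_matrix((self.n_elements, self.n_elements))
        ab = np.array(sorted(self.edges), dtype=np.int64)
        data = np.ones(len(ab), dtype=np.int8)
        m = sparse.coo_matrix(
            (data, (ab[:, 0], ab[:, 1])), shape=(self.n_elements, self.n_elements)
        )
        m = m + m.T
        return m.tocsr()

    def is_connected(self) -> bool:
        ncomp, _ = _sparse_cc(self.adjacency_sparse, directed=False)
        return ncomp == 1


@dataclass
class ConnectivityMatrix:
    """An N x N real matrix of pairwise connectivity observations D."""

    values: np.ndarray
    symmetric: bool
    diagonal_defined: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if self.symmetric and not np.allclose(v, v.T, atol=1e-8, equal_nan=True):
            raise ValueError("matrix flagged symmetric but values are not")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def included_mask(self) -> np.ndarray:
        """Boolean mask of the entries that count as observations."""
        n = self.n
        if self.symmetric:
            return np.triu(np.ones((n, n), dtype=bool), k=0 if self.diagonal_defined else 1)
        mask = np.ones((n, n), dtype=bool)
        if not self.diagonal_defined:
            np.fill_diagonal(mask, False)
        return mask

    def included_values(self) -> np.ndarray:
        return self.values[self.included_mask()]


@dataclass
class LinkState:
    """Per-element link vector c: each element points at itself or a neighbor.

    The induced parcellation is the set of undirected connected components of
    the link graph ``{{i, c_i}}``.
    """

    links: np.ndarray

    def __post_init__(self):
        self.links = np.asarray(self.links, dtype=np.int64)
        if self.links.ndim != 1:
            raise ValueError("links must be a 1-d vector")

    def validate(self, graph: SpatialGraph) -> None:
        if len(self.links) != graph.n_elements:
            raise ValueError("link vector length does not match graph")
        for i, c in enumerate(self.links):
            if c != i and not graph.are_neighbors(i, int(c)):
                raise ValueError(f"link {i}->{c} is not a self-link or neighbor edge")


@dataclass
class Parcellation:
    """Cluster labels 1..k, canonicalized so clusters are ordered by their
    smallest member index."""

    labels: np.ndarray
    k: int

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        uniq = np.unique(self.labels)
        if len(uniq) != self.k or uniq[0] < 1 or uniq[-1] > self.k:
            raise ValueError("labels must cover 1..k with every cluster nonempty")

    @classmethod
    def from_raw_labels(cls, raw: np.ndarray) -> "Parcellation":
        """Canonicalize an arbitrary integer labeling to 1..k ordered by
        smallest contained element index."""
        raw = np.asarray(raw)
        _, first, inv = np.unique(raw, return_index=True, return_inverse=True)
        order = np.argsort(first, kind="stable")
        rank = np.empty(len(order), dtype=np.int64)
        rank[order] = np.arange(1, len(order) + 1)
        return cls(rank[inv], len(order))

    def members(self) -> list:
        """Member index arrays, position ``m`` holding cluster ``m+1``."""
        idx = np.argsort(self.labels, kind="stable")
        bounds = np.searchsorted(self.labels[idx], np.arange(1, self.k + 2))
        return [idx[bounds[m] : bounds[m + 1]] for m in range(self.k)]

    @property
    def n(self) -> int:
        return len(self.labels)


def connected_components(links: LinkState, graph: SpatialGraph, validate: bool = True) -> Parcellation:
    """Parcellation induced by a link state: undirected connected components of
    the link graph."""
    if validate:
        links.validate(graph)
    n = graph.n_elements
    rows = np.arange(n)
    adj = sparse.coo_matrix((np.ones(n, dtype=np.int8), (rows, links.links)), shape=(n, n))
    _, raw = _sparse_cc(adj, directed=False)
    return Parcellation.from_raw_labels(raw)


def normalize_matrix(D: ConnectivityMatrix) -> ConnectivityMatrix:
    """Standardize the included entries of D to zero mean and unit variance.

    Puts connectivity matrices from different problems on a common scale so
    the variance hyperparameter sigma0^2 is comparable across datasets.
    Raises for a (numerically) constant matrix.
    """
    vals = D.included_values()
    if vals.size < 2:
        raise ValueError("need at least two included entries to normalize")
    m = vals.mean()
    v = vals.var()
    if not np.isfinite(v) or v < 1e-300:
        raise ValueError("matrix is constant over its included entries; cannot normalize")
    out = (D.values - m) / np.sqrt(v)
    if not D.diagonal_defined:
        np.fill_diagonal(out, 0.0)
    return ConnectivityMatrix(out, D.symmetric, D.diagonal_defined)


def assert_contiguous(p: Parcellation, graph: SpatialGraph) -> bool:
    """True iff every cluster induces a connected subgraph of the spatial graph."""
    if len(p.labels) != graph.n_elements:
        raise ValueError("parcellation length does not match graph")
    A = graph.adjacency_sparse
    for members in p.members():
        if len(members) == 1:
            continue
        ncomp, _ = _sparse_cc(A[members][:, members], directed=False)
        if ncomp > 1:
            return False
    return True
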