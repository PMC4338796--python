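"""File formats: delimited matrices with JSON sidecars, edge lists, label TSVs.

All element ids are 0-based in files, matching the in-memory convention.
Matrices are dense delimited text (tab, or comma for ``.csv``) or a binary
``.npy`` container for large N; a ``<path>.json`` sidecar records the
symmetry flag and diagonal convention.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional

import numpy as np

from .core import ConnectivityMatrix, Parcellation, SpatialGraph

__all__ = [
    "load_matrix",
    "save_matrix",
    "load_adjacency",
    "save_adjacency",
    "load_labels",
    "save_labels",
    "parse_adjacency_spec",
]

_GRID_RE = re.compile(r"^grid:(\d+)x(\d+)$")


def save_matrix(path, D: ConnectivityMatrix) -> None:
    path = Path(path)
    if path.suffix == ".npy":
        np.save(path, D.values)
    else:
        delim = "," if path.suffix == ".csv" else "\t"
        np.savetxt(path, D.values, delimiter=delim)
    sidecar = {"symmetric": D.symmetric, "diagonal_defined": D.diagonal_defined}
    Path(str(path) + ".json").write_text(json.dumps(sidecar) + "\n")


def load_matrix(path) -> ConnectivityMatrix:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    if path.suffix == ".npy":
        values = np.load(path)
    else:
        delim = "," if path.suffix == ".csv" else None
        values = np.loadtxt(path, delimiter=delim)
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        symmetric = bool(meta.get("symmetric", False))
        diagonal_defined = bool(meta.get("diagonal_defined", False))
    else:
        symmetric = bool(np.allclose(values, values.T))
        diagonal_defined = False
    return ConnectivityMatrix(values, symmetric=symmetric, diagonal_defined=diagonal_defined)


def save_adjacency(path, graph: SpatialGraph) -> None:
    with open(path, "w") as fh:
        fh.write(f"# n_elements={graph.n_elements}\n")
        for a, b in sorted(graph.edges):
            fh.write(f"{a}\t{b}\n")


def load_adjacency(path, n_elements: Optional[int] = None) -> SpatialGraph:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"adjacency file not found: {path}")
    edges = []
    declared_n = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.search(r"n_elements=(\d+)", line)
            if m:
                declared_n = int(m.group(1))
            continue
        a, b = line.split("\t")[:2]
        edges.append((int(a), int(b)))
    n = n_elements or declared_n
    if n is None:
        n = max(max(a, b) for a, b in edges) + 1
    return SpatialGraph.from_edges(n, edges)


def parse_adjacency_spec(spec: str, n_elements: Optional[int] = None) -> SpatialGraph:
    """Either a path to an edge-list file or a ``grid:RxC`` shortcut."""
    m = _GRID_RE.match(str(spec))
    if m:
        return SpatialGraph.grid(int(m.group(1)), int(m.group(2)))
    return load_adjacency(spec, n_elements)


def save_labels(path, p: Parcellation) -> None:
    with open(path, "w") as fh:
        fh.write("element_id\tlabel\n")
        for i, l in enumerate(p.labels):
            fh.write(f"{i}\t{l}\n")


def load_labels(path) -> Parcellation:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"labels file not found: {path}")
    rows = []
    for line in path.read_text().splitlines()[1:]:
        if not line.strip():
            continue
        i, l = line.split("\t")
        rows.append((int(i), int(l)))
    rows.sort()
    return Parcellation.from_raw_labels(np.array([l for _, l in rows]))
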