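"""Synthetic connectivity generators: grid layouts, block-Normal sampling,
the three-spiral geometry, and the noise-sweep harness.

The generative model matches the model the sampler assumes: a K x K block
mean matrix A with iid standard-normal entries, and element-wise
connectivity D_ij drawn Normal(A_{z_i z_j}, sigma^2).  Three fixed
ground-truth layouts on an 18 x 18 grid probe different regimes:

* ``squares9``    -- 9 equal 6 x 6 squares (the equal-size case where
                     spectral methods are competitive);
* ``stripes6``    -- 6 horizontal stripes of unequal heights 6,4,3,2,2,1,
                     including two small adjacent stripes;
* ``nonuniform5`` -- one large L-shaped region plus four unequal rectangles.

The layouts are versioned constants of this package so that results are
reproducible; they are reconstructions of the qualitative designs (equal
squares / unequal stripes / nonuniform regions), not pixel-exact copies of
any published figure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import ConnectivityMatrix, Parcellation, SpatialGraph, normalize_matrix

__all__ = [
    "SyntheticDataset",
    "GRID_LAYOUTS",
    "make_grid_truth",
    "sample_connectivity",
    "make_spiral",
    "noise_sweep",
]

GRID_SIZE = 18
STRIPE_HEIGHTS = (6, 4, 3, 2, 2, 1)


@dataclass
class SyntheticDataset:
    graph: SpatialGraph
    truth: Parcellation
    block_means: np.ndarray
    noise_sd: float
    D: ConnectivityMatrix
    seed: Optional[int] = None


def _labels_squares9() -> np.ndarray:
    r, c = np.mgrid[0:GRID_SIZE, 0:GRID_SIZE]
    return (r // 6) * 3 + c // 6


def _labels_stripes6() -> np.ndarray:
    lab = np.empty((GRID_SIZE, GRID_SIZE), dtype=np.int64)
    row = 0
    for s, h in enumerate(STRIPE_HEIGHTS):
        lab[row : row + h, :] = s
        row += h
    return lab


def _labels_nonuniform5() -> np.ndarray:
    lab = np.empty((GRID_SIZE, GRID_SIZE), dtype=np.int64)
    lab[:12, :12] = 0  # with the block below: an L-shape of 180 elements
    lab[12:, :6] = 0
    lab[:12, 12:] = 1  # 72
    lab[12:, 6:12] = 2  # 36
    lab[12:, 12:16] = 3  # 24
    lab[12:, 16:] = 4  # 12
    return lab


GRID_LAYOUTS = {
    "squares9": _labels_squares9,
    "stripes6": _labels_stripes6,
    "nonuniform5": _labels_nonuniform5,
}


def make_grid_truth(layout: str) -> Tuple[SpatialGraph, Parcellation]:
    """Ground-truth parcellation of the 18 x 18 4-neighbor grid."""
    try:
        lab = GRID_LAYOUTS[layout]()
    except KeyError:
        raise ValueError(
            f"unknown layout {layout!r}; choose from {sorted(GRID_LAYOUTS)}"
        ) from None
    graph = SpatialGraph.grid(GRID_SIZE, GRID_SIZE)
    return graph, Parcellation.from_raw_labels(lab.ravel())


def sample_connectivity(
    graph: SpatialGraph,
    truth: Parcellation,
    sigma: float,
    rng,
    symmetric: bool = True,
) -> SyntheticDataset:
    """Draw a connectivity matrix from the block-Normal generative model.

    Block means A are iid standard normal (mirrored across the diagonal when
    a symmetric matrix is requested); each included entry of D is then
    Normal(A_{z_i z_j}, sigma^2).  sigma = 0 yields a block-piecewise-constant
    matrix.  ``rng`` may be an integer seed or a Generator.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    k = truth.k
    n = truth.n
    A = rng.standard_normal((k, k))
    if symmetric:
        A = np.triu(A) + np.triu(A, 1).T
    z0 = truth.labels - 1
    means = A[np.ix_(z0, z0)]
    noise = rng.standard_normal((n, n))
    if symmetric:
        noise = np.triu(noise, 1)
        noise = noise + noise.T
    D = means + sigma * noise
    np.fill_diagonal(D, 0.0)
    cm = ConnectivityMatrix(D, symmetric=symmetric, diagonal_defined=False)
    return SyntheticDataset(graph, truth, A, float(sigma), cm, seed)


def make_spiral(
    n_per_arm: int,
    turns: float = 1.5,
    noise: float = 0.0,
    rng=None,
) -> Tuple[SpatialGraph, Parcellation]:
    """Three interleaved Archimedean spiral arms.

    Each arm has ``n_per_arm`` points; consecutive points along an arm are
    adjacent, and every point is additionally adjacent to its nearest point
    on each of the other two arms.  ``noise`` jitters the point positions
    (Gaussian sd, in the same units as the unit inner radius) before
    adjacency is computed.  Truth is arm membership, K = 3.
    """
    if n_per_arm < 3:
        raise ValueError("n_per_arm must be >= 3")
    rng = np.random.default_rng(rng)
    t = np.linspace(0.0, 1.0, n_per_arm)
    theta = t * turns * 2.0 * np.pi
    radius = 1.0 + 2.0 * theta / (2.0 * np.pi)  # unit inner radius, pitch 2
    pts = []
    for arm in range(3):
        phi = theta + 2.0 * np.pi * arm / 3.0
        xy = np.column_stack([radius * np.cos(phi), radius * np.sin(phi)])
        pts.append(xy)
    pts = np.concatenate(pts)
    if noise > 0:
        pts = pts + noise * rng.standard_normal(pts.shape)
    edges = set()
    for arm in range(3):
        base = arm * n_per_arm
        for j in range(n_per_arm - 1):
            edges.add((base + j, base + j + 1))
    for arm in range(3):
        base = arm * n_per_arm
        for other in range(3):
            if other == arm:
                continue
            obase = other * n_per_arm
            opts = pts[obase : obase + n_per_arm]
            for j in range(n_per_arm):
                d = np.linalg.norm(opts - pts[base + j], axis=1)
                q = obase + int(np.argmin(d))
                edges.add((min(base + j, q), max(base + j, q)))
    graph = SpatialGraph.from_edges(3 * n_per_arm, edges)
    labels = np.repeat(np.arange(3), n_per_arm)
    return graph, Parcellation.from_raw_labels(labels)


def noise_sweep(
    layouts: Sequence[str],
    sigmas: Sequence[float],
    n_reps: int,
    methods: Sequence[str],
    seed: int,
    sigma0_sq: float = 0.01,
    n_passes: int = 30,
) -> pd.DataFrame:
    """Recovery experiment: for each (layout, sigma, rep) generate a dataset,
    run each method, and record NMI with the truth.

    The model runs first and its inferred K is handed to every baseline,
    mirroring the protocol where only the nonparametric model chooses K.
    Returns a tidy frame with columns layout, sigma, rep, method, k, nmi.
    """
    from .baselines import (
        local_similarity,
        normalized_cut,
        pairwise_dissimilarity,
        random_parcellation,
        region_growing,
        ward,
    )
    from .evaluation import nmi
    from .model import Hyperparams
    from .sampler import SamplerConfig, run_sampler

    baseline_fns = {
        "ward": lambda W, g, k, s: ward(W, g, k),
        "local": lambda W, g, k, s: local_similarity(W, g, k),
        "ncut": lambda W, g, k, s: normalized_cut(W, g, k, seed=s),
        "grow": lambda W, g, k, s: region_growing(W, g, k),
    }
    for m in methods:
        if m not in baseline_fns and m not in ("model", "random"):
            raise ValueError(f"unknown method {m!r}")

    root = np.random.default_rng(seed)
    rows = []
    for layout in layouts:
        graph, truth = make_grid_truth(layout)
        for sigma in sigmas:
            for rep in range(n_reps):
                data_seed = int(root.integers(2**31))
                ds = sample_connectivity(graph, truth, sigma, data_seed)
                Dn = normalize_matrix(ds.D)
                sol, _ = run_sampler(
                    Dn,
                    graph,
                    Hyperparams(sigma0_sq),
                    SamplerConfig(n_passes=n_passes, seed=data_seed),
                )
                k = sol.k
                W = pairwise_dissimilarity(Dn)
                for method in methods:
                    if method == "model":
                        z = sol.parcellation
                    elif method == "random":
                        z = random_parcellation(graph, k, np.random.default_rng(data_seed))
                    else:
                        z = baseline_fns[method](W, graph, k, data_seed)
                    rows.append(
                        {
                            "layout": layout,
                            "sigma": sigma,
                            "rep": rep,
                            "method": method,
                            "k": z.k,
                            # single-cluster solutions have undefined NMI
                            "nmi": nmi(z, truth) if z.k >= 2 else np.nan,
                        }
                    )
    return pd.DataFrame(rows)
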