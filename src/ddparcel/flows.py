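"""Origin-destination flow preprocessing and a synthetic flow generator.

A flow table holds spatial units (each with a population and a group id,
e.g. a county and its state), a sparse origin -> destination mover count, and
a unit adjacency graph.  Two preprocessing steps turn it into a connectivity
matrix the parcellation model can consume:

* ``merge_small_units`` -- iteratively merge the lowest-population unit with
  its lowest-population within-group neighbor until every unit reaches a
  minimum population, damping noisy estimates from tiny units;
* ``normalize_flows`` -- divide each mover count by the count expected under
  a chance model in which movers pick origins and destinations in proportion
  to population:

      D_ab = M_ab / [ (sum M) * P_a P_b / (sum P)^2 ].

  The result is a nonnegative asymmetric matrix in which 1 is chance level.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .core import ConnectivityMatrix, Parcellation, SpatialGraph
from .evaluation import nmi

__all__ = [
    "FlowTable",
    "merge_small_units",
    "normalize_flows",
    "simulate_flow_table",
    "border_alignment",
    "random_alignment_envelope",
]


@dataclass
class FlowTable:
    """Units with populations and group membership, mover counts, adjacency.

    ``movers`` maps (origin_index, destination_index) to annual mover counts;
    self-flows are tolerated but ignored (the diagonal convention).
    """

    unit_ids: List[str]
    populations: np.ndarray
    groups: np.ndarray
    movers: Dict[Tuple[int, int], float]
    graph: SpatialGraph

    def __post_init__(self):
        self.populations = np.asarray(self.populations, dtype=float)
        self.groups = np.asarray(self.groups)
        n = len(self.unit_ids)
        if len(self.populations) != n or len(self.groups) != n:
            raise ValueError("unit table lengths disagree")
        if self.graph.n_elements != n:
            raise ValueError("adjacency graph does not match unit count")
        if (self.populations <= 0).any():
            raise ValueError("populations must be positive")
        for (a, b), m in self.movers.items():
            if m < 0:
                raise ValueError("mover counts must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.unit_ids)


def merge_small_units(t: FlowTable, min_pop: float) -> FlowTable:
    """Merge units below ``min_pop`` into within-group neighbors.

    At each step the globally lowest-population unit below the threshold is
    merged with its lowest-population neighbor in the same group (ties broken
    by unit id; the merged unit keeps the lexicographically smaller id).
    Populations and flows are summed, adjacency is unioned, and flows
    internal to a merged unit drop onto the ignored diagonal.  Deterministic.
    """
    ids = list(t.unit_ids)
    pops = {i: float(p) for i, p in enumerate(t.populations)}
    groups = {i: t.groups[i] for i in range(t.n)}
    adj = {i: set(int(v) for v in t.graph.neighbors[i]) for i in range(t.n)}
    movers: Dict[Tuple[int, int], float] = dict(t.movers)
    uid = {i: str(ids[i]) for i in range(t.n)}
    alive = set(range(t.n))

    while True:
        below = [i for i in alive if pops[i] < min_pop]
        if not below:
            break
        i = min(below, key=lambda x: (pops[x], uid[x]))
        cands = [j for j in adj[i] if groups[j] == groups[i]]
        if not cands:
            raise ValueError(
                f"unit {uid[i]!r} is below min_pop but has no within-group neighbor"
            )
        j = min(cands, key=lambda x: (pops[x], uid[x]))
        keep, gone = (i, j) if uid[i] <= uid[j] else (j, i)
        pops[keep] += pops[gone]
        uid[keep] = min(uid[keep], uid[gone])
        # reroute flows
        for (a, b), m in list(movers.items()):
            if a == gone or b == gone:
                del movers[(a, b)]
                na = keep if a == gone else a
                nb = keep if b == gone else b
                movers[(na, nb)] = movers.get((na, nb), 0.0) + m
        adj[keep] = (adj[keep] | adj[gone]) - {keep, gone}
        for e in adj[gone]:
            if e != keep:
                adj[e].discard(gone)
                adj[e].add(keep)
        del adj[gone], pops[gone], groups[gone]
        alive.discard(gone)

    order = sorted(alive, key=lambda x: uid[x])
    remap = {old: new for new, old in enumerate(order)}
    edges = set()
    for a in order:
        for b in adj[a]:
            edges.add((min(remap[a], remap[b]), max(remap[a], remap[b])))
    return FlowTable(
        unit_ids=[uid[a] for a in order],
        populations=np.array([pops[a] for a in order]),
        groups=np.array([groups[a] for a in order]),
        movers={
            (remap[a], remap[b]): m for (a, b), m in movers.items() if a != b
        },
        graph=SpatialGraph.from_edges(len(order), edges),
    )


def normalize_flows(t: FlowTable) -> ConnectivityMatrix:
    """Chance-normalized flow matrix: mover counts divided by the flows a
    population-proportional chance model would produce."""
    total_m = sum(m for (a, b), m in t.movers.items() if a != b)
    if total_m <= 0:
        raise ValueError("total movers must be positive")
    P = t.populations
    total_p = P.sum()
    D = np.zeros((t.n, t.n))
    for (a, b), m in t.movers.items():
        if a == b:
            continue
        chance = total_m * P[a] * P[b] / total_p**2
        D[a, b] = m / chance
    return ConnectivityMatrix(D, symmetric=False, diagonal_defined=False)


def simulate_flow_table(
    n_units: int,
    n_groups: int,
    k_communities: int,
    effect: float,
    rng,
    mover_fraction: float = 0.03,
    mean_pop: float = 30000.0,
    align_with_groups: bool = True,
) -> Tuple[FlowTable, Parcellation]:
    """Synthetic flow table with planted migration communities.

    Units sit on a near-square planar grid; groups are contiguous column
    bands.  Communities are contiguous bands as well -- aligned with the
    group (column) axis by default, or orthogonal to it (row bands) when
    ``align_with_groups`` is False.  Populations are lognormal around
    ``mean_pop``; mover counts are Poisson with rate equal to the
    population-proportional chance rate times ``effect`` for within-community
    pairs and 1 otherwise, with a total budget of ``mover_fraction`` of the
    population.  ``effect`` = 1 is the null model in which normalized flows
    sit at chance.
    """
    if k_communities > n_units:
        raise ValueError("k_communities cannot exceed n_units")
    rng = np.random.default_rng(rng)
    cols = int(np.ceil(np.sqrt(n_units)))
    rows = int(np.ceil(n_units / cols))
    # grid positions for the first n_units cells, row-major
    edges = []
    for idx in range(n_units):
        r, c = divmod(idx, cols)
        if c + 1 < cols and idx + 1 < n_units and (idx + 1) // cols == r:
            edges.append((idx, idx + 1))
        if idx + cols < n_units:
            edges.append((idx, idx + cols))
    graph = SpatialGraph.from_edges(n_units, edges)

    pos_r = np.arange(n_units) // cols
    pos_c = np.arange(n_units) % cols
    groups = (pos_c * n_groups) // cols
    if align_with_groups:
        comm = (pos_c * k_communities) // cols
    else:
        comm = (pos_r * k_communities) // rows
    truth = Parcellation.from_raw_labels(comm)

    P = rng.lognormal(mean=np.log(mean_pop), sigma=0.5, size=n_units)
    total_p = P.sum()
    budget = mover_fraction * total_p
    movers: Dict[Tuple[int, int], float] = {}
    chance = budget * np.outer(P, P) / total_p**2
    mult = np.where(comm[:, None] == comm[None, :], effect, 1.0)
    lam = chance * mult
    np.fill_diagonal(lam, 0.0)
    counts = rng.poisson(lam)
    for a, b in zip(*np.nonzero(counts)):
        movers[(int(a), int(b))] = float(counts[a, b])
    table = FlowTable(
        unit_ids=[f"u{idx:04d}" for idx in range(n_units)],
        populations=P,
        groups=groups,
        movers=movers,
        graph=graph,
    )
    return table, truth


def border_alignment(p: Parcellation, groups) -> float:
    """NMI between a parcellation and a group (e.g. state) labeling."""
    gz = groups if isinstance(groups, Parcellation) else Parcellation.from_raw_labels(groups)
    return nmi(p, gz)


def random_alignment_envelope(
    graph: SpatialGraph,
    K: int,
    groups,
    n_draws: int = 100,
    rng=None,
) -> Dict[str, float]:
    """Null envelope of border alignment: NMI of random K-cluster
    parcellations against the group labeling (mean and 95% interval)."""
    from .baselines import random_parcellation

    rng = np.random.default_rng(rng)
    gz = groups if isinstance(groups, Parcellation) else Parcellation.from_raw_labels(groups)
    vals = []
    for _ in range(n_draws):
        z = random_parcellation(graph, K, rng)
        vals.append(nmi(z, gz))
    vals = np.array(vals)
    return {
        "mean": float(vals.mean()),
        "lo": float(np.percentile(vals, 2.5)),
        "hi": float(np.percentile(vals, 97.5)),
    }
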