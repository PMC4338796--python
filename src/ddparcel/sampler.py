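"""Collapsed Gibbs sampling over dd-CRP links, with incremental bookkeeping.

One Gibbs step resamples the link of a single element *i*:

1. remove the current link ``c_i``; this may split *i*'s parcel into the two
   connected components left behind (a link graph loses exactly one edge, so
   at most two components appear);
2. score every candidate link (self, or one of *i*'s spatial neighbors).
   Candidates that keep the removal-induced partition share a common baseline
   likelihood; candidates that merge two parcels are scored through the
   likelihood ratio of the merged versus split configuration, evaluated block
   by block with the O(1) pooled-statistics merge -- never by recomputing
   sufficient statistics from the data matrix;
3. draw the new link proportionally to prior weight (alpha for self, 1 for a
   neighbor) times likelihood, and apply it.

The sampler tracks the best-scoring visited state and reports it as the MAP
parcellation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Dict, List, Optional, Tuple

import numpy as np

from .core import (
    ConnectivityMatrix,
    LinkState,
    Parcellation,
    SpatialGraph,
    connected_components,
)
from .model import (
    EMPTY_BLOCK,
    BlockStats,
    Hyperparams,
    ModelScore,
    log_marginal_block,
    merge_block_stats,
)

__all__ = [
    "GibbsState",
    "SamplerConfig",
    "MapSolution",
    "initialize",
    "gibbs_step",
    "split_on_removal",
    "candidate_log_weights",
    "run_sampler",
]


@dataclass
class SamplerConfig:
    n_passes: int = 30
    seed: int = 0
    record_trace: bool = False

    def __post_init__(self):
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")


class GibbsState:
    """Mutable sampler state: links plus cached parcellation, block statistics
    and score terms.

    Parcels are identified by their smallest member index, so labels are
    stable under unrelated moves.  ``blocks`` maps parcel-id pairs (unordered
    for symmetric data, ordered including within-parcel pairs otherwise) to
    ``(BlockStats, log_marginal)`` tuples; the total log marginal is kept as a
    running sum.
    """

    def __init__(
        self,
        links: LinkState,
        D: ConnectivityMatrix,
        graph: SpatialGraph,
        hyper: Hyperparams,
        rng_seed: int = 0,
        validate: bool = True,
    ):
        if validate:
            links.validate(graph)
        self.D = D
        self.graph = graph
        self.hyper = hyper
        self.rng_seed = rng_seed
        self.links = np.asarray(links.links, dtype=np.int64).copy()
        self._log_z = float(np.log(hyper.alpha + graph.degrees).sum())
        self._log_alpha = math.log(hyper.alpha) if hyper.alpha > 0 else -math.inf
        self._rebuild_caches()

    # -- cache construction -------------------------------------------------

    def _rebuild_caches(self) -> None:
        from .model import block_stats as _grouped_stats

        parc = connected_components(LinkState(self.links), self.graph, validate=False)
        members = parc.members()
        # parcel id = smallest member element index
        self.labels = np.empty(self.graph.n_elements, dtype=np.int64)
        self.parcels: Dict[int, np.ndarray] = {}
        pid_of_label = {}
        for lab, mem in enumerate(members, start=1):
            pid = int(mem[0])
            self.parcels[pid] = mem
            self.labels[mem] = pid
            pid_of_label[lab] = pid
        self.blocks: Dict[Tuple[int, int], Tuple[BlockStats, float]] = {}
        self.ll = 0.0
        for (m, n), stats in _grouped_stats(self.D, parc).items():
            self._set_block(pid_of_label[m], pid_of_label[n], stats)
        self.n_self = int((self.links == np.arange(len(self.links))).sum())

    def _compute_block(self, a: int, b: int) -> BlockStats:
        V = self.D.values
        I = self.parcels[a]
        if a == b:
            sub = V[I[:, None], I]
            p = len(I)
            if self.D.symmetric:
                vals = sub[np.triu_indices(p, k=1)]
            else:
                vals = sub[~np.eye(p, dtype=bool)]
        else:
            vals = V[I[:, None], self.parcels[b]].ravel()
        L = vals.size
        if L == 0:
            return EMPTY_BLOCK
        mean = vals.sum() / L
        dev = vals - mean
        return BlockStats(L, float(mean), float(dev @ dev))

    def _key(self, a: int, b: int) -> Tuple[int, int]:
        if self.D.symmetric and a > b:
            return (b, a)
        return (a, b)

    def _set_block(self, a: int, b: int, stats: BlockStats) -> None:
        lp = log_marginal_block(stats, self.hyper)
        self.blocks[self._key(a, b)] = (stats, lp)
        self.ll += lp

    def _del_block(self, a: int, b: int) -> None:
        entry = self.blocks.pop(self._key(a, b), None)
        if entry is not None:
            self.ll -= entry[1]

    # -- public views -------------------------------------------------------

    @property
    def parcellation(self) -> Parcellation:
        return Parcellation.from_raw_labels(self.labels)

    @property
    def k(self) -> int:
        return len(self.parcels)

    @property
    def log_prior(self) -> float:
        if self.n_self > 0 and self.hyper.alpha == 0:
            return -math.inf
        return self.n_self * (self._log_alpha if self.n_self else 0.0) - self._log_z

    @property
    def score(self) -> ModelScore:
        return ModelScore(self.log_prior, self.ll)

    @property
    def log_posterior(self) -> float:
        return self.log_prior + self.ll

    def link_state(self) -> LinkState:
        return LinkState(self.links.copy())

    # -- structural moves ---------------------------------------------------

    def _split_components(self, i: int) -> Optional[Tuple[np.ndarray, np.ndarray]]:
        """Components of parcel(i) once the link out of i is removed, or None
        if the parcel stays connected.  At most two components can appear."""
        pid = int(self.labels[i])
        members = self.parcels[pid]
        if len(members) == 1:
            return None
        # local union-find; members is sorted so searchsorted is the index map
        targets = np.searchsorted(members, self.links[members])
        parent = list(range(len(members)))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        pos_i = int(np.searchsorted(members, i))
        for k in range(len(members)):
            if k == pos_i or targets[k] == k:
                continue
            ra, rb = find(k), find(int(targets[k]))
            if ra != rb:
                parent[ra] = rb
        roots = np.array([find(k) for k in range(len(members))])
        in_i = roots == roots[pos_i]
        if in_i.all():
            return None
        return members[in_i], members[~in_i]

    def _apply_split(self, comp_a: np.ndarray, comp_b: np.ndarray) -> None:
        """Replace the parcel covering comp_a | comp_b with the two components.

        Only the smaller fragment's blocks are recomputed from the data; the
        larger fragment's statistics are recovered by un-pooling them from
        the cached whole-parcel blocks (the exact inverse of the merge
        identity), so the work per split scales with the small side.
        """
        old = int(self.labels[comp_a[0]])
        if len(comp_b) < len(comp_a):
            comp_a, comp_b = comp_b, comp_a  # comp_a is now the small fragment
        ida, idb = int(comp_a[0]), int(comp_b[0])
        others = [p for p in self.parcels if p != old]
        old_blocks = {}
        for p in others:
            old_blocks[(old, p)] = self._get(old, p)[0]
            if not self.D.symmetric:
                old_blocks[(p, old)] = self._get(p, old)[0]
            self._del_block(old, p)
            if not self.D.symmetric:
                self._del_block(p, old)
        old_within = self._get(old, old)[0]
        self._del_block(old, old)
        del self.parcels[old]
        self.parcels[ida] = comp_a
        self.parcels[idb] = comp_b
        self.labels[comp_a] = ida
        self.labels[comp_b] = idb
        for p in others:
            small = self._compute_block(ida, p)
            self._set_block(ida, p, small)
            self._set_block(idb, p, _unmerge_block(old_blocks[(old, p)], small))
            if not self.D.symmetric:
                small = self._compute_block(p, ida)
                self._set_block(p, ida, small)
                self._set_block(p, idb, _unmerge_block(old_blocks[(p, old)], small))
        within_a = self._compute_block(ida, ida)
        cross_ab = self._compute_block(ida, idb)
        self._set_block(ida, ida, within_a)
        self._set_block(ida, idb, cross_ab)
        rem = _unmerge_block(_unmerge_block(old_within, within_a), cross_ab)
        if not self.D.symmetric:
            cross_ba = self._compute_block(idb, ida)
            self._set_block(idb, ida, cross_ba)
            rem = _unmerge_block(rem, cross_ba)
        self._set_block(idb, idb, rem)

    def _get(self, a: int, b: int) -> Tuple[BlockStats, float]:
        return self.blocks.get(self._key(a, b), (EMPTY_BLOCK, 0.0))

    def merge_delta(self, pa: int, pb: int) -> float:
        """Log-likelihood change from merging parcels pa and pb, computed via
        pooled block statistics only (the merge/split likelihood ratio)."""
        hyper = self.hyper
        delta = 0.0
        if self.D.symmetric:
            for p in self.parcels:
                if p == pa or p == pb:
                    continue
                sa, la = self._get(p, pa)
                sb, lb = self._get(p, pb)
                delta += log_marginal_block(merge_block_stats(sa, sb), hyper) - la - lb
            saa, laa = self._get(pa, pa)
            sbb, lbb = self._get(pb, pb)
            sab, lab = self._get(pa, pb)
            merged = merge_block_stats(merge_block_stats(saa, sbb), sab)
            delta += log_marginal_block(merged, hyper) - laa - lbb - lab
        else:
            for p in self.parcels:
                if p == pa or p == pb:
                    continue
                sa, la = self._get(p, pa)
                sb, lb = self._get(p, pb)
                delta += log_marginal_block(merge_block_stats(sa, sb), hyper) - la - lb
                sa, la = self._get(pa, p)
                sb, lb = self._get(pb, p)
                delta += log_marginal_block(merge_block_stats(sa, sb), hyper) - la - lb
            parts = [self._get(pa, pa), self._get(pb, pb), self._get(pa, pb), self._get(pb, pa)]
            merged = EMPTY_BLOCK
            for s, _ in parts:
                merged = merge_block_stats(merged, s)
            delta += log_marginal_block(merged, hyper) - sum(lp for _, lp in parts)
        return delta

    def _apply_merge(self, pa: int, pb: int) -> None:
        new = min(pa, pb)
        gone = max(pa, pb)
        hyper = self.hyper
        others = [p for p in self.parcels if p != pa and p != pb]
        for p in others:
            sa, _ = self._get(p, pa)
            sb, _ = self._get(p, pb)
            merged = merge_block_stats(sa, sb)
            self._del_block(p, pa)
            self._del_block(p, pb)
            self._set_block(p, new, merged)
            if not self.D.symmetric:
                sa, _ = self._get(pa, p)
                sb, _ = self._get(pb, p)
                merged = merge_block_stats(sa, sb)
                self._del_block(pa, p)
                self._del_block(pb, p)
                self._set_block(new, p, merged)
        if self.D.symmetric:
            keys = [(pa, pa), (pb, pb), (pa, pb)]
        else:
            keys = [(pa, pa), (pb, pb), (pa, pb), (pb, pa)]
        merged = EMPTY_BLOCK
        for a, b in keys:
            s, _ = self._get(a, b)
            merged = merge_block_stats(merged, s)
            self._del_block(a, b)
        mem = np.sort(np.concatenate([self.parcels[pa], self.parcels[pb]]))
        del self.parcels[gone]
        self.parcels[new] = mem
        self.labels[mem] = new
        self._set_block(new, new, merged)


def _unmerge_block(total: BlockStats, part: BlockStats) -> BlockStats:
    """Inverse of ``merge_block_stats``: statistics of ``total`` minus the
    disjoint sub-block ``part``."""
    if part.count == 0:
        return total
    nb = total.count - part.count
    if nb == 0:
        return EMPTY_BLOCK
    mb = (total.count * total.mean - part.count * part.mean) / nb
    sb = total.ss_dev - part.ss_dev - part.count * nb / total.count * (part.mean - mb) ** 2
    return BlockStats(nb, mb, max(sb, 0.0))


# ---------------------------------------------------------------------------


def split_on_removal(state: GibbsState, i: int) -> Tuple[Parcellation, Dict]:
    """Partition induced by removing the link out of element *i* (which may
    split i's parcel in two), together with the updated block map.

    Mutates ``state`` into the removal configuration (``c_i = i``) -- this is
    the first half of a Gibbs step.
    """
    _remove_link(state, i)
    return state.parcellation, state.blocks


def _remove_link(state: GibbsState, i: int) -> None:
    old = int(state.links[i])
    if old != i:
        comps = state._split_components(i)
        state.links[i] = i
        state.n_self += 1
        if comps is not None:
            state._apply_split(*comps)


def candidate_log_weights(state: GibbsState, i: int) -> Tuple[np.ndarray, np.ndarray]:
    """Candidate links for element *i* and their unnormalized log weights,
    relative to the removal-induced configuration.

    ``state`` must already be in the removal configuration (``c_i = i``).
    Weights omit the shared baseline likelihood; candidates that merge two
    parcels add the merge/split log ratio.
    """
    nbrs = state.graph.neighbors[i]
    cands = np.concatenate([[i], nbrs])
    logw = np.empty(len(cands))
    pi = int(state.labels[i])
    delta_cache: Dict[int, float] = {}
    for idx, j in enumerate(cands):
        base = state._log_alpha if j == i else 0.0
        pj = int(state.labels[j])
        if pj == pi:
            logw[idx] = base
        else:
            if pj not in delta_cache:
                delta_cache[pj] = state.merge_delta(pi, pj)
            logw[idx] = base + delta_cache[pj]
    return cands, logw


def gibbs_step(state: GibbsState, i: int, rng: np.random.Generator) -> GibbsState:
    """Resample the link of element *i* in place and return the state."""
    _remove_link(state, i)
    cands, logw = candidate_log_weights(state, i)
    w = np.exp(logw - logw.max())
    probs = w / w.sum()
    choice = int(cands[rng.choice(len(cands), p=probs)])
    pi = int(state.labels[i])
    if choice != i:
        state.links[i] = choice
        state.n_self -= 1
        pj = int(state.labels[choice])
        if pj != pi:
            state._apply_merge(pi, pj)
    return state


# -- initialization ---------------------------------------------------------


def _wilson_spanning_links(
    members: np.ndarray, graph: SpatialGraph, rng: np.random.Generator
) -> Dict[int, int]:
    """Uniform random spanning tree of the induced subgraph on ``members``
    (Wilson's loop-erased random walk), returned as child -> parent links with
    the root linking to itself."""
    mset = set(int(x) for x in members)
    members = [int(x) for x in members]
    root = members[int(rng.integers(len(members)))]
    in_tree = {root}
    succ: Dict[int, int] = {}
    parent: Dict[int, int] = {root: root}
    local_nbrs = {
        m: [int(v) for v in graph.neighbors[m] if int(v) in mset] for m in members
    }
    for start in members:
        if start in in_tree:
            continue
        u = start
        while u not in in_tree:
            nb = local_nbrs[u]
            if not nb:
                raise ValueError("cluster induces a disconnected subgraph")
            succ[u] = nb[int(rng.integers(len(nb)))]
            u = succ[u]
        u = start
        while u not in in_tree:
            in_tree.add(u)
            parent[u] = succ[u]
            u = succ[u]
    return parent


def _links_from_labels(
    z: Parcellation, graph: SpatialGraph, rng: np.random.Generator
) -> LinkState:
    links = np.arange(graph.n_elements, dtype=np.int64)
    for mem in z.members():
        parent = _wilson_spanning_links(mem, graph, rng)
        for child, par in parent.items():
            links[child] = par
    return LinkState(links)


def _ward_candidate_ks(n: int) -> List[int]:
    ks = []
    k = 2
    while k < n:
        ks.append(k)
        k *= 2
    ks.append(n)
    return ks


def initialize(
    D: ConnectivityMatrix,
    graph: SpatialGraph,
    hyper: Hyperparams,
    rng: np.random.Generator,
    mode: str = "ward-auto",
    k: Optional[int] = None,
    rng_seed: int = 0,
) -> GibbsState:
    """Build the starting state of the sampler.

    ``ward-auto`` (default, the standard scheme): cut the spatially
    constrained Ward tree at a geometric grid of candidate cluster counts
    (2, 4, 8, ... , N) refined by +/-25% steps around the running best, score
    each cut under the model, and keep the most likely; links are then set to
    a uniform random spanning tree within each cluster.  ``ward-k`` uses a
    fixed Ward cut; ``random`` draws every link uniformly from its support.
    """
    if not graph.is_connected():
        raise ValueError("spatial graph must be connected")
    from .baselines import WardTree, pairwise_dissimilarity
    from .model import log_model

    if mode == "random":
        links = np.empty(graph.n_elements, dtype=np.int64)
        for i in range(graph.n_elements):
            cand = np.concatenate([[i], graph.neighbors[i]])
            links[i] = cand[int(rng.integers(len(cand)))]
        return GibbsState(LinkState(links), D, graph, hyper, rng_seed=rng_seed)

    if mode == "ward-k":
        if k is None:
            raise ValueError("ward-k initialization requires k")
        if k == graph.n_elements:
            links = LinkState(np.arange(graph.n_elements))
            return GibbsState(links, D, graph, hyper, rng_seed=rng_seed)
        tree = WardTree(pairwise_dissimilarity(D).values, graph)
        z = tree.labels(k)
    elif mode == "ward-auto":
        tree = WardTree(pairwise_dissimilarity(D).values, graph)
        log_alpha = math.log(hyper.alpha) if hyper.alpha > 0 else -math.inf
        scores: Dict[int, float] = {}

        def score(kk: int) -> float:
            if kk not in scores:
                # spanning-tree links put one self-link per cluster
                scores[kk] = log_model(D, tree.labels(kk), hyper) + kk * log_alpha
            return scores[kk]

        candidates = _ward_candidate_ks(graph.n_elements)
        for kk in candidates:
            score(kk)
        for _ in range(10):
            best = max(scores, key=scores.get)
            extra = {
                max(1, int(round(best * 0.75))),
                min(graph.n_elements, int(round(best * 1.25))),
            } - set(scores)
            if not extra:
                break
            for kk in extra:
                score(kk)
        best = max(scores, key=scores.get)
        z = tree.labels(best)
    else:
        raise ValueError(f"unknown initialization mode: {mode}")

    links = _links_from_labels(z, graph, rng)
    return GibbsState(links, D, graph, hyper, rng_seed=rng_seed)


# -- main loop --------------------------------------------------------------


@dataclass
class MapSolution:
    """Best-scoring state visited by the sampler."""

    links: LinkState
    parcellation: Parcellation
    score: ModelScore
    k: int


def run_sampler(
    D: ConnectivityMatrix,
    graph: SpatialGraph,
    hyper: Hyperparams,
    config: SamplerConfig,
    init: str = "ward-auto",
    init_k: Optional[int] = None,
    pass_callback: Optional[Callable] = None,
) -> Tuple[MapSolution, List[Tuple[int, int, float]]]:
    """Run collapsed Gibbs sampling and return the MAP solution over the
    trajectory plus an optional per-step trace of (pass, K, log posterior).

    Sweeps use a fresh uniform random element order each pass.  All
    randomness flows from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    state = initialize(D, graph, hyper, rng, mode=init, k=init_k, rng_seed=config.seed)
    best_links = state.links.copy()
    best_score = state.log_posterior
    trace: List[Tuple[int, int, float]] = []
    for p in range(config.n_passes):
        for i in rng.permutation(graph.n_elements):
            gibbs_step(state, int(i), rng)
            lp = state.log_posterior
            if lp > best_score:
                best_score = lp
                best_links = state.links.copy()
            if config.record_trace:
                trace.append((p, state.k, lp))
        if pass_callback is not None:
            pass_callback(p, state, best_score)
    map_state = GibbsState(
        LinkState(best_links), D, graph, hyper, rng_seed=config.seed, validate=False
    )
    return (
        MapSolution(
            map_state.link_state(),
            map_state.parcellation,
            map_state.score,
            map_state.k,
        ),
        trace,
    )
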