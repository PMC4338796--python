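"""Scoring parcellations: normalized mutual information and variance explained.

NMI is mutual information normalized by the geometric mean of the two label
entropies,

    NMI(z, z_gt) = I(z, z_gt) / sqrt(H(z) H(z_gt)),

computed from the contingency table in natural logs (the ratio is base
invariant).  It ranges over [0, 1], is symmetric, needs no explicit matching
between parcels, and equals 1 iff the partitions coincide up to relabeling.

Variance explained is the fraction of the connectivity matrix's variance
captured by replacing every entry with its parcel-pair block mean -- the
summary used to judge how well a small set of parcels compresses a large
connectivity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .core import ConnectivityMatrix, Parcellation, SpatialGraph
from .model import block_stats

__all__ = ["EvaluationReport", "nmi", "variance_explained", "compare_methods"]


@dataclass
class EvaluationReport:
    method: str
    k: int
    seed: Optional[int] = None
    nmi: Optional[float] = None
    variance_explained: Optional[float] = None
    nmi_sd: Optional[float] = None


def nmi(z: Parcellation, z_gt: Parcellation) -> float:
    """Normalized mutual information between two parcellations.

    Raises for a single-cluster labeling (zero entropy leaves the ratio
    undefined); sweep code must handle that case explicitly rather than
    receive a silent zero.
    """
    if z.n != z_gt.n:
        raise ValueError("labelings have different lengths")
    if z.k < 2 or z_gt.k < 2:
        raise ValueError(
            "NMI is undefined for a single-cluster labeling (zero entropy)"
        )
    n = z.n
    cont = np.zeros((z.k, z_gt.k))
    np.add.at(cont, (z.labels - 1, z_gt.labels - 1), 1.0)
    nh = cont.sum(axis=1)
    nl = cont.sum(axis=0)
    nz = cont > 0
    info = (
        cont[nz] / n * (np.log(n * cont[nz]) - np.log(np.outer(nh, nl)[nz]))
    ).sum()
    h = -(nh / n * np.log(nh / n)).sum()
    h_gt = -(nl / n * np.log(nl / n)).sum()
    val = info / np.sqrt(h * h_gt)
    return float(min(max(val, 0.0), 1.0))


def variance_explained(D: ConnectivityMatrix, z: Parcellation) -> float:
    """1 - SS_residual / SS_total over the included entries of D, where the
    fitted value of every entry is its parcel-pair block mean."""
    vals = D.included_values()
    grand = vals.mean()
    ss_total = float(((vals - grand) ** 2).sum())
    if ss_total < 1e-300:
        raise ValueError("matrix is constant; variance explained undefined")
    ss_res = sum(b.ss_dev for b in block_stats(D, z).values())
    return 1.0 - ss_res / ss_total


def compare_methods(
    D: ConnectivityMatrix,
    graph: SpatialGraph,
    truth: Optional[Parcellation],
    methods: Sequence[str],
    K: Optional[int] = None,
    seeds: Sequence[int] = (0,),
    sigma0_sq: float = 0.01,
    n_passes: int = 30,
) -> List[EvaluationReport]:
    """Run each named method on one dataset and score it.

    ``model`` runs first; unless K is given explicitly, every baseline uses
    the model's inferred cluster count, matching the protocol in which only
    the nonparametric model chooses K.  For the ``random`` method an extra
    aggregate report (seed None) carries the Monte-Carlo mean and sd of NMI
    across seeds.
    """
    from .baselines import (
        local_similarity,
        normalized_cut,
        pairwise_dissimilarity,
        random_parcellation,
        region_growing,
        ward,
    )
    from .model import Hyperparams
    from .sampler import SamplerConfig, run_sampler

    reports: List[EvaluationReport] = []
    model_k = K
    if "model" in methods or K is None:
        for seed in seeds:
            sol, _ = run_sampler(
                D, graph, Hyperparams(sigma0_sq), SamplerConfig(n_passes=n_passes, seed=seed)
            )
            z = sol.parcellation
            if "model" in methods:
                reports.append(_score("model", z, D, truth, seed))
            if model_k is None:
                model_k = z.k
    W = None
    random_nmis = []
    for method in methods:
        if method == "model":
            continue
        if W is None:
            W = pairwise_dissimilarity(D)
        for seed in seeds:
            if method == "ward":
                z = ward(W, graph, model_k)
            elif method == "local":
                z = local_similarity(W, graph, model_k)
            elif method == "ncut":
                z = normalized_cut(W, graph, model_k, seed=seed)
            elif method == "grow":
                z = region_growing(W, graph, model_k)
            elif method == "random":
                z = random_parcellation(graph, model_k, np.random.default_rng(seed))
            else:
                raise ValueError(f"unknown method {method!r}")
            rep = _score(method, z, D, truth, seed)
            reports.append(rep)
            if method == "random" and rep.nmi is not None:
                random_nmis.append(rep.nmi)
    if random_nmis:
        reports.append(
            EvaluationReport(
                method="random",
                k=model_k,
                seed=None,
                nmi=float(np.mean(random_nmis)),
                nmi_sd=float(np.std(random_nmis, ddof=1)) if len(random_nmis) > 1 else 0.0,
            )
        )
    return reports


def _score(method, z, D, truth, seed) -> EvaluationReport:
    val = None
    if truth is not None and z.k >= 2 and truth.k >= 2:
        val = nmi(z, truth)
    return EvaluationReport(
        method=method,
        k=z.k,
        seed=seed,
        nmi=val,
        variance_explained=variance_explained(D, z),
    )
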