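"""The probabilistic model: dd-CRP prior and Normal-Inverse-chi^2 block likelihood.

Generative model
----------------
Links ``c ~ dd-CRP(alpha, f)`` with ``f_ij = 1`` iff *i* and *j* are spatial
neighbors, so every cluster (a connected component of the link graph) is
spatially contiguous.  For every pair of parcels *(m, n)* a connectivity
strength and variance are drawn from a conjugate Normal-Inverse-chi^2 prior,

    A_mn, s2_mn ~ NIchi2(mu0, kappa0, sigma0^2, nu0)
    D_ij ~ Normal(A_{z_i z_j}, s2_{z_i z_j})

Conjugacy lets us integrate A and s2 out analytically, leaving a closed-form
marginal likelihood per block that depends only on the block's sufficient
statistics (count L, mean dbar, sum of squared deviations s):

    p(D_mn) = Gamma(nu_mn/2)/Gamma(nu0/2) * sqrt(kappa0/kappa_mn)
              * (nu0 sigma0^2)^(nu0/2) / (nu_mn sigma2_mn)^(nu_mn/2)
              * pi^(-L/2)

with kappa_mn = kappa0 + L, nu_mn = nu0 + L and

    sigma2_mn = (nu0 sigma0^2 + s + L kappa0/(kappa0+L) (mu0 - dbar)^2) / nu_mn.

All computation is in the log domain via log-gamma; raw Gamma evaluation
overflows for the block sizes that arise in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Dict, NamedTuple, Tuple

import numpy as np

from .core import ConnectivityMatrix, LinkState, Parcellation, SpatialGraph

__all__ = [
    "Hyperparams",
    "BlockStats",
    "EMPTY_BLOCK",
    "ModelScore",
    "stats_of",
    "merge_block_stats",
    "block_stats",
    "log_marginal_block",
    "log_model",
    "log_ddcrp_prior",
]

_LOG_PI = math.log(math.pi)


@dataclass(frozen=True)
class Hyperparams:
    """Hyperparameters of the dd-CRP + NIchi2 model.

    ``sigma0_sq`` (the prior expected block variance) is the only hyperparameter
    that materially shapes the solution -- smaller values encourage smaller
    parcels -- so it has no default and must be chosen per run.  The remaining
    defaults are weakly informative: a diffuse prior on the block mean
    (kappa0 = 1e-4), a single pseudo-observation of variance (nu0 = 1), and a
    self-link concentration alpha = 10.
    """

    sigma0_sq: float
    alpha: float = 10.0
    mu0: float = 0.0
    kappa0: float = 1e-4
    nu0: float = 1.0

    def __post_init__(self):
        if self.sigma0_sq <= 0:
            raise ValueError("sigma0_sq must be positive")
        if self.kappa0 <= 0:
            raise ValueError("kappa0 must be positive")
        if self.nu0 <= 0:
            raise ValueError("nu0 must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be nonnegative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Hyperparams":
        return cls(**d)


class BlockStats(NamedTuple):
    """Sufficient statistics of one parcel-pair block of D."""

    count: int
    mean: float
    ss_dev: float


EMPTY_BLOCK = BlockStats(0, 0.0, 0.0)


@dataclass(frozen=True)
class ModelScore:
    log_prior: float
    log_marginal: float

    @property
    def log_posterior(self) -> float:
        return self.log_prior + self.log_marginal


def stats_of(values: np.ndarray) -> BlockStats:
    """Direct sufficient statistics of a flat array of block entries."""
    values = np.asarray(values, dtype=float).ravel()
    L = values.size
    if L == 0:
        return EMPTY_BLOCK
    m = values.mean()
    return BlockStats(L, float(m), float(((values - m) ** 2).sum()))


def merge_block_stats(b1: BlockStats, b2: BlockStats) -> BlockStats:
    """Pooled statistics of two disjoint blocks.

    Uses the exact pooling identity
    ``s = s1 + s2 + n1 n2 / (n1 + n2) * (m1 - m2)^2``,
    which is what makes merge moves O(1) per block during sampling.
    """
    if b1.count == 0:
        return b2
    if b2.count == 0:
        return b1
    n1, m1, s1 = b1
    n2, m2, s2 = b2
    n = n1 + n2
    mean = (n1 * m1 + n2 * m2) / n
    ss = s1 + s2 + n1 * n2 / n * (m1 - m2) ** 2
    return BlockStats(n, mean, ss)


def _pair_values(
    V: np.ndarray, I: np.ndarray, J: np.ndarray, same: bool, symmetric: bool
) -> np.ndarray:
    """Included entries of the block between element sets I and J.

    Within-parcel blocks exclude the diagonal; symmetric matrices count each
    unordered within-parcel pair once.  Cross blocks of a symmetric matrix use
    all I x J entries, which equals the strict-upper-triangle convention
    because D_ij = D_ji.
    """
    if same:
        sub = V[np.ix_(I, I)]
        p = len(I)
        if symmetric:
            return sub[np.triu_indices(p, k=1)]
        mask = ~np.eye(p, dtype=bool)
        return sub[mask]
    return V[np.ix_(I, J)].ravel()


def block_stats(D: ConnectivityMatrix, z: Parcellation) -> Dict[Tuple[int, int], BlockStats]:
    """Sufficient statistics for every parcel-pair block of D.

    Keys are 1-based label pairs: unordered ``(m, n)`` with ``m <= n`` for a
    symmetric matrix, all ordered pairs otherwise.  Computed in one grouped
    pass over the included entries (two-pass mean/ss for numerical accuracy).
    """
    if z.n != D.n:
        raise ValueError("parcellation length does not match matrix")
    k = z.k
    lab0 = z.labels - 1
    mask = D.included_mask()
    rows, cols = np.nonzero(mask)
    lm, ln = lab0[rows], lab0[cols]
    if D.symmetric:
        lm, ln = np.minimum(lm, ln), np.maximum(lm, ln)
    pid = lm * k + ln
    vals = D.values[rows, cols]
    nbin = k * k
    cnt = np.bincount(pid, minlength=nbin)
    tot = np.bincount(pid, weights=vals, minlength=nbin)
    mean = np.divide(tot, cnt, out=np.zeros(nbin), where=cnt > 0)
    dev = vals - mean[pid]
    ss = np.bincount(pid, weights=dev * dev, minlength=nbin)
    out: Dict[Tuple[int, int], BlockStats] = {}
    for m in range(1, k + 1):
        start = m if D.symmetric else 1
        for n in range(start, k + 1):
            b = (m - 1) * k + (n - 1)
            out[(m, n)] = (
                BlockStats(int(cnt[b]), float(mean[b]), float(ss[b]))
                if cnt[b] > 0
                else EMPTY_BLOCK
            )
    return out


def log_marginal_block(b: BlockStats, hyper: Hyperparams) -> float:
    """Closed-form log marginal likelihood of one block under the NIchi2 model.

    An empty block contributes log(1) = 0, so splitting a parcel never changes
    the score through blocks that do not exist.
    """
    L = b.count
    if L == 0:
        return 0.0
    k0, n0, s0, m0 = hyper.kappa0, hyper.nu0, hyper.sigma0_sq, hyper.mu0
    kap = k0 + L
    nu = n0 + L
    sig = (n0 * s0 + b.ss_dev + L * k0 / kap * (m0 - b.mean) ** 2) / nu
    return (
        math.lgamma(nu / 2.0)
        - math.lgamma(n0 / 2.0)
        + 0.5 * (math.log(k0) - math.log(kap))
        + 0.5 * n0 * math.log(n0 * s0)
        - 0.5 * nu * math.log(nu * sig)
        - 0.5 * L * _LOG_PI
    )


def log_model(D: ConnectivityMatrix, z: Parcellation, hyper: Hyperparams) -> float:
    """Collapsed log likelihood of D under a parcellation: the sum of the
    block marginals over all parcel-pair blocks."""
    return sum(log_marginal_block(b, hyper) for b in block_stats(D, z).values())


def log_ddcrp_prior(links: LinkState, graph: SpatialGraph, hyper: Hyperparams) -> float:
    """Log probability of a link state under the dd-CRP prior.

    Each element independently links to itself with weight alpha or to any
    one neighbor with weight 1; links to non-neighbors have probability 0
    (returned as -inf rather than raised, since the sampler's support makes
    them unreachable).
    """
    c = links.links
    if len(c) != graph.n_elements:
        raise ValueError("link vector length does not match graph")
    idx = np.arange(graph.n_elements)
    nonself = idx[c != idx]
    for i in nonself:
        if not graph.are_neighbors(int(i), int(c[i])):
            return -math.inf
    n_self = int((c == idx).sum())
    log_z = float(np.log(hyper.alpha + graph.degrees).sum())
    if n_self > 0 and hyper.alpha == 0:
        return -math.inf
    log_w = n_self * math.log(hyper.alpha) if n_self > 0 else 0.0
    return log_w - log_z
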