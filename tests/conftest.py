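"""Shared fixtures and independent oracles for the test suite."""

import math

import numpy as np
import pytest

from ddparcel.core import ConnectivityMatrix, LinkState, SpatialGraph


@pytest.fixture
def path3():
    return SpatialGraph.from_edges(3, [(0, 1), (1, 2)])


@pytest.fixture
def path4():
    return SpatialGraph.from_edges(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def grid44():
    return SpatialGraph.grid(4, 4)


def quad_log_marginal(data, h):
    """Independent oracle for the block marginal likelihood: direct 2-D
    quadrature of Normal likelihood x Normal-Inverse-chi^2 prior density over
    (mean, variance)."""
    from scipy import integrate

    data = [float(x) for x in data]
    a = h.nu0 / 2.0
    scale = h.nu0 * h.sigma0_sq / 2.0
    log_norm_ig = a * math.log(scale) - math.lgamma(a)

    def integrand(A, s2):
        ll = -0.5 * len(data) * math.log(2 * math.pi * s2) - sum(
            (d - A) ** 2 for d in data
        ) / (2 * s2)
        lig = log_norm_ig - (a + 1) * math.log(s2) - scale / s2
        va = s2 / h.kappa0
        lpa = -0.5 * math.log(2 * math.pi * va) - (A - h.mu0) ** 2 / (2 * va)
        return math.exp(ll + lig + lpa)

    val, _ = integrate.dblquad(
        integrand, 1e-12, np.inf, -np.inf, np.inf, epsabs=1e-14, epsrel=1e-10
    )
    return math.log(val)


def enumerate_link_states(graph):
    """All link vectors valid under the dd-CRP support (self or neighbor)."""
    import itertools

    choices = [[i] + [int(v) for v in graph.neighbors[i]] for i in range(graph.n_elements)]
    for combo in itertools.product(*choices):
        yield LinkState(np.array(combo))


def random_valid_links(graph, rng):
    links = np.empty(graph.n_elements, dtype=np.int64)
    for i in range(graph.n_elements):
        cand = np.concatenate([[i], graph.neighbors[i]])
        links[i] = cand[int(rng.integers(len(cand)))]
    return LinkState(links)


def random_matrix(n, rng, symmetric=True):
    V = rng.normal(size=(n, n))
    if symmetric:
        V = (V + V.T) / 2.0
    np.fill_diagonal(V, 0.0)
    return ConnectivityMatrix(V, symmetric=symmetric, diagonal_defined=False)
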