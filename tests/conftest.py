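"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately share no code with the package: C_score is
recomputed as a double loop over all edges with cluster-membership tests,
and the AUC as the full pairwise positive-vs-negative comparison.
"""

import numpy as np
import pytest

from cluscore import BipartiteNetwork, T1_EDGES


@pytest.fixture
def t1():
    """Toy network: g1-d1, g1-d2, g2-d1, g2-d3, g3-d2."""
    return BipartiteNetwork.from_edges(T1_EDGES)


def oracle_c_score(network, gene, disease, exclude_direct_edge=False):
    """Brute force: double loop over all edges testing cluster membership."""
    d_cluster = set(network.gene_neighbors[gene])  # diseases adjacent to g
    g_cluster = set(network.disease_neighbors[disease])  # genes adjacent to d
    count = 0
    for g_prime, nbrs in network.gene_neighbors.items():
        for d_prime in nbrs:
            if g_prime in g_cluster and d_prime in d_cluster:
                if exclude_direct_edge and (g_prime, d_prime) == (gene, disease):
                    continue
                count += 1
    return count


def oracle_dg_score(network, gene, disease, exclude_direct_edge=False):
    c = oracle_c_score(network, gene, disease, exclude_direct_edge)
    return (1.0 / len(network.gene_neighbors[gene])
            + 1.0 / len(network.disease_neighbors[disease])) * c


def oracle_auc(pos, neg):
    """Mean over all (p, n) pairs of 1[p > n] + 0.5 * 1[p == n]."""
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_bipartite(rng, max_genes=12, max_diseases=12, p=None):
    """A random small bipartite network with at least one edge."""
    while True:
        n_g = rng.integers(2, max_genes + 1)
        n_d = rng.integers(2, max_diseases + 1)
        density = p if p is not None else rng.uniform(0.1, 0.6)
        adj = rng.random((n_g, n_d)) < density
        if adj.any():
            edges = [
                (f"g{i}", f"d{j}") for i, j in np.argwhere(adj)
            ]
            return BipartiteNetwork.from_edges(edges)
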