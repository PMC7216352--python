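"""Significance of clusters: similarity and C_score versus random clusters.

Two permutation-style analyses support the biological reading of gene and
disease clusters:

* within-cluster mean similarity of each real cluster versus size-matched
  random clusters drawn uniformly from the whole part, given an externally
  supplied similarity matrix;
* the C_score of each known edge versus the edge count between size-matched
  random gene and disease clusters.

Both report per-anchor empirical p-values with the add-one convention and a
pooled real-vs-random Mann-Whitney comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .network import BipartiteNetwork
from .scoring import c_score, disease_cluster, gene_cluster

logger = logging.getLogger(__name__)


class SimilarityMatrix:
    """Symmetric node-similarity table over one part of the network.

    Backed by a labelled square DataFrame with values in [0, 1]; symmetry is
    enforced within 1e-9 and diagonal entries are never consumed.
    """

    def __init__(self, frame: pd.DataFrame):
        if frame.shape[0] != frame.shape[1]:
            raise ValueError("similarity matrix must be square")
        if list(frame.index) != list(frame.columns):
            raise ValueError("row and column labels must match")
        values = frame.to_numpy(dtype=float)
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError("similarity matrix must be symmetric within 1e-9")
        off = values[~np.eye(len(values), dtype=bool)]
        if off.size and (off.min() < -1e-9 or off.max() > 1 + 1e-9):
            raise ValueError("similarity values must lie in [0, 1]")
        self.frame = frame
        self._index = {n: i for i, n in enumerate(frame.index)}
        self._values = values

    @classmethod
    def from_tsv(cls, path) -> "SimilarityMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t")

    @property
    def node_ids(self) -> list[str]:
        return list(self.frame.index)

    def __contains__(self, node: str) -> bool:
        return node in self._index

    def mean_pairwise(self, members) -> float:
        """Mean similarity over all unordered pairs of distinct members."""
        idx = []
        for m in members:
            if m not in self._index:
                raise KeyError(f"node {m!r} missing from similarity matrix")
            idx.append(self._index[m])
        if len(idx) < 2:
            raise ValueError("need at least 2 members for a pairwise mean")
        sub = self._values[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        return float(sub[iu].mean())


@dataclass
class ClusterSignificance:
    """One real cluster against its size-matched random clusters."""

    anchor: str
    cluster_size: int
    observed_mean_similarity: float
    random_mean_similarities: np.ndarray
    empirical_p: float


def cluster_mean_similarity(cluster, sim: SimilarityMatrix) -> float:
    """Average pairwise similarity within one cluster (size >= 2)."""
    return sim.mean_pairwise(sorted(cluster.members))


def cluster_similarity_significance(
    network: BipartiteNetwork,
    sim: SimilarityMatrix,
    part: str = "disease",
    n_random: int = 10_000,
    seed: int = 0,
):
    """Real-cluster similarity versus size-matched random clusters.

    For every anchor on the opposite part whose cluster has >= 2 members,
    draws ``n_random`` uniform same-size subsets of the whole ``part`` node
    set and compares mean within-cluster similarities.  Size-1 clusters are
    skipped (logged).  Returns the per-anchor results and a pooled summary
    with a one-sided Mann-Whitney p-value (real > random).
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    if part == "disease":
        anchors = sorted(network.gene_neighbors)
        pool = sorted(network.disease_neighbors)
        clusters = [disease_cluster(network, a) for a in anchors]
    elif part == "gene":
        anchors = sorted(network.disease_neighbors)
        pool = sorted(network.gene_neighbors)
        clusters = [gene_cluster(network, a) for a in anchors]
    else:
        raise ValueError(f"part must be 'gene' or 'disease', got {part!r}")

    rng = np.random.default_rng(seed)
    results: list[ClusterSignificance] = []
    skipped = 0
    for cluster in clusters:
        size = len(cluster)
        if size < 2:
            skipped += 1
            continue
        observed = cluster_mean_similarity(cluster, sim)
        random_means = np.empty(n_random)
        for r in range(n_random):
            members = rng.choice(pool, size=size, replace=False)
            random_means[r] = sim.mean_pairwise(members)
        p = (1 + int((random_means >= observed).sum())) / (1 + n_random)
        results.append(
            ClusterSignificance(
                anchor=cluster.anchor,
                cluster_size=size,
                observed_mean_similarity=observed,
                random_mean_similarities=random_means,
                empirical_p=p,
            )
        )
    if skipped:
        logger.info("skipped %d clusters of size < 2", skipped)
    if not results:
        raise ValueError("nothing to test: no cluster of size >= 2")

    real = np.array([r.observed_mean_similarity for r in results])
    random_pool = np.concatenate([r.random_mean_similarities for r in results])
    if np.ptp(np.concatenate([real, random_pool])) == 0:
        pooled_p = 1.0  # constant similarity: no signal by construction
    else:
        pooled_p = float(
            mannwhitneyu(real, random_pool, alternative="greater").pvalue
        )
    pooled = {
        "real_means": real,
        "random_means": random_pool,
        "mannwhitney_p": pooled_p,
    }
    return results, pooled


def known_edge_cscore_null(
    network: BipartiteNetwork,
    n_random: int = 1000,
    seed: int = 0,
    exclude_direct_edge: bool = False,
):
    """Observed C_score of each known edge versus random same-size clusters.

    For each edge (g, d): the observed statistic is C_score(g, d); each null
    draw replaces gCluster(d) by a uniform random gene set of the same size
    and dCluster(g) by a uniform random disease set of the same size, and
    counts the edges between the two random sets.  Returns a DataFrame with
    per-edge observed values, null means and empirical p-values, plus the
    pooled observed-vs-null Mann-Whitney comparison.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    genes = sorted(network.gene_neighbors)
    diseases = sorted(network.disease_neighbors)
    adj = network.adjacency().toarray().astype(bool)

    rows = []
    null_samples = []
    for g, d in network.edges():
        size_g = len(network.disease_neighbors[d])  # |gCluster(d)|
        size_d = len(network.gene_neighbors[g])  # |dCluster(g)|
        observed = c_score(network, g, d, exclude_direct_edge)
        nulls = np.empty(n_random)
        disease_idx = np.arange(len(diseases))
        for r in range(n_random):
            rand_g = rng.choice(len(genes), size=size_g, replace=False)
            rand_d = rng.choice(disease_idx, size=size_d, replace=False)
            nulls[r] = adj[np.ix_(rand_g, rand_d)].sum()
        rows.append(
            {
                "gene": g,
                "disease": d,
                "observed_c_score": observed,
                "null_mean": nulls.mean(),
                "empirical_p": (1 + int((nulls >= observed).sum())) / (1 + n_random),
            }
        )
        null_samples.append(nulls)

    frame = pd.DataFrame(rows)
    observed = frame["observed_c_score"].to_numpy(dtype=float)
    pooled_null = np.concatenate(null_samples)
    if np.ptp(np.concatenate([observed, pooled_null])) == 0:
        pooled_p = 1.0
    else:
        pooled_p = float(
            mannwhitneyu(observed, pooled_null, alternative="greater").pvalue
        )
    pooled = {
        "observed": observed,
        "null": pooled_null,
        "mannwhitney_p": pooled_p,
    }
    return frame, pooled
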