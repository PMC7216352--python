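"""Cluster association scores for gene-disease link prediction.

The method scores a candidate gene-disease pair (g, d) from the local
neighborhood structure of an association bipartite network:

* ``dCluster(g)`` — the diseases adjacent to gene g (its disease cluster);
* ``gCluster(d)`` — the genes adjacent to disease d (its gene cluster);
* ``C_score(g, d) = |L(dCluster(g), gCluster(d))|`` — the number of network
  edges running between the two clusters;
* ``DG_score(g, d) = (1/|N(g)| + 1/|N(d)|) * C_score(g, d)`` — the degree
  normalized association score, correcting the raw edge count's bias toward
  high-degree nodes.

In matrix form, with A the genes x diseases biadjacency matrix, the full
C_score table is ``A @ A.T @ A``; the per-pair implementation uses adjacency
set intersections.  Both routes are exposed and tested against each other.

The scikit-learn style entry point is :class:`ClusterAssociationScorer`:
``fit`` ingests the known association edges, ``predict`` returns DG_scores
for candidate pairs, and :meth:`ClusterAssociationScorer.rank_candidates`
produces the ranked prediction table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .network import BipartiteNetwork, NetworkError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Cluster:
    """The neighborhood of an anchor node on the opposite part."""

    anchor: str
    members: frozenset

    def __len__(self) -> int:
        return len(self.members)


def disease_cluster(network: BipartiteNetwork, gene: str) -> Cluster:
    """dCluster(g): the diseases associated with ``gene``."""
    if gene not in network.gene_neighbors:
        raise KeyError(f"gene {gene!r} not in network")
    return Cluster(anchor=gene, members=network.gene_neighbors[gene])


def gene_cluster(network: BipartiteNetwork, disease: str) -> Cluster:
    """gCluster(d): the genes associated with ``disease``."""
    if disease not in network.disease_neighbors:
        raise KeyError(f"disease {disease!r} not in network")
    return Cluster(anchor=disease, members=network.disease_neighbors[disease])


def c_score(
    network: BipartiteNetwork,
    gene: str,
    disease: str,
    exclude_direct_edge: bool = False,
) -> int:
    """Edges between gCluster(disease) and dCluster(gene).

    Computed lazily as ``sum over d' in N(gene) of |N(d') & N(disease)|``,
    i.e. O(deg(gene) * average degree) per pair.  When ``exclude_direct_edge``
    and (gene, disease) is itself a known edge, that edge (which always lies
    between the two clusters) is not counted.
    """
    d_members = network.gene_neighbors.get(gene)
    g_members = network.disease_neighbors.get(disease)
    if d_members is None:
        raise KeyError(f"gene {gene!r} not in network")
    if g_members is None:
        raise KeyError(f"disease {disease!r} not in network")
    total = sum(
        len(network.disease_neighbors[d_prime] & g_members) for d_prime in d_members
    )
    if exclude_direct_edge and network.has_edge(gene, disease):
        total -= 1
    return total


def dg_score(
    network: BipartiteNetwork,
    gene: str,
    disease: str,
    exclude_direct_edge: bool = False,
) -> float:
    """Degree-normalized association score for one pair."""
    c = c_score(network, gene, disease, exclude_direct_edge)
    deg_g = len(network.gene_neighbors[gene])
    deg_d = len(network.disease_neighbors[disease])
    return (1.0 / deg_g + 1.0 / deg_d) * c


# ---------------------------------------------------------------------------
# Candidate enumeration and ranked scoring


def _candidate_pairs(
    network: BipartiteNetwork,
    candidates,
    allow_known: bool = False,
) -> list[tuple[str, str]]:
    genes, diseases = network.node_index()
    if candidates in ("all", "all_non_edges"):
        pool = [(g, d) for g in genes for d in diseases]
    elif candidates in ("lncrna", "lncRNA_non_edges", "lncrna_non_edges"):
        lnc = sorted(network.lncrna_genes())
        pool = [(g, d) for g in lnc for d in diseases]
    else:
        pool = [(str(g), str(d)) for g, d in candidates]
        for g, d in pool:
            if g not in network.gene_neighbors:
                raise KeyError(f"gene {g!r} not in network")
            if d not in network.disease_neighbors:
                raise KeyError(f"disease {d!r} not in network")
        if not allow_known:
            known = [(g, d) for g, d in pool if network.has_edge(g, d)]
            if known:
                raise ValueError(
                    f"candidates contain known edges (use allow_known): {known[:5]}"
                )
        return pool
    return [(g, d) for g, d in pool if not network.has_edge(g, d)]


def _score_table(network: BipartiteNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Dense C and DG score tables for every gene x disease pair.

    C = A @ A.T @ A with A the biadjacency matrix; DG applies the degree
    weights row/column-wise.  Suitable up to a few million pairs.
    """
    A = network.adjacency()
    C = np.asarray((A @ (A.T @ A)).todense())
    deg_g = np.asarray(A.sum(axis=1)).ravel()
    deg_d = np.asarray(A.sum(axis=0)).ravel()
    weights = 1.0 / deg_g[:, None] + 1.0 / deg_d[None, :]
    return C, weights * C, np.asarray(A.todense())


def score_candidates(
    network: BipartiteNetwork,
    candidates="all_non_edges",
    exclude_direct_edge: bool = False,
    allow_known: bool = False,
) -> pd.DataFrame:
    """Score and rank candidate gene-disease pairs.

    Parameters
    ----------
    network
        The association bipartite network.
    candidates
        ``"all_non_edges"`` (every gene x disease non-edge), the
        lncRNA-restricted variant ``"lncrna_non_edges"``, or an explicit list
        of (gene, disease) pairs.  Explicit known edges are rejected unless
        ``allow_known`` is set (used by the known-edge validation analyses).
    exclude_direct_edge
        Do not count the (gene, disease) edge itself when the pair is a known
        edge.  Irrelevant for non-edge candidates.

    Returns
    -------
    DataFrame with columns gene, disease, gene_class, c_score, dg_score and
    a 1-based rank.  Ordering is dg_score descending with deterministic tie
    breaks (c_score descending, then gene id, then disease id).
    """
    pairs = _candidate_pairs(network, candidates, allow_known=allow_known)
    if not pairs:
        return pd.DataFrame(
            columns=["gene", "disease", "gene_class", "c_score", "dg_score", "rank"]
        )
    genes, diseases = network.node_index()
    gi = {g: i for i, g in enumerate(genes)}
    di = {d: j for j, d in enumerate(diseases)}
    C, DG, A = _score_table(network)
    rows_i = np.fromiter((gi[g] for g, _ in pairs), dtype=np.intp, count=len(pairs))
    cols_j = np.fromiter((di[d] for _, d in pairs), dtype=np.intp, count=len(pairs))
    c_vals = C[rows_i, cols_j]
    dg_vals = DG[rows_i, cols_j]
    if exclude_direct_edge:
        direct = A[rows_i, cols_j]
        c_vals = c_vals - direct
        deg_g = A.sum(axis=1)[rows_i]
        deg_d = A.sum(axis=0)[cols_j]
        dg_vals = (1.0 / deg_g + 1.0 / deg_d) * c_vals

    frame = pd.DataFrame(
        {
            "gene": [g for g, _ in pairs],
            "disease": [d for _, d in pairs],
            "gene_class": [
                network.gene_class.get(g, "unknown") for g, _ in pairs
            ],
            "c_score": c_vals.astype(np.int64),
            "dg_score": dg_vals,
        }
    )
    frame = frame.sort_values(
        by=["dg_score", "c_score", "gene", "disease"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    frame["rank"] = np.arange(1, len(frame) + 1)
    return frame


def top_fraction(scores: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """First ceil(fraction * n) entries of a ranked score table."""
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    cut = math.ceil(fraction * len(scores))
    logger.info("top fraction %.4g of %d pairs -> %d kept", fraction, len(scores), cut)
    return scores.iloc[:cut].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Estimator


class ClusterAssociationScorer(BaseEstimator):
    """Scikit-learn style scorer for gene-disease association prediction.

    The estimator is nonparametric: ``fit`` stores the association network
    built from the training edges, and ``predict`` evaluates the degree
    normalized cluster association score DG_score for query pairs.  Higher
    scores indicate stronger predicted association.

    Parameters
    ----------
    exclude_direct_edge : bool, default False
        When scoring a pair that is itself a known edge, do not count that
        edge among the cluster-to-cluster edges.  Candidate prediction only
        scores non-edges, so this matters only for known-edge analyses.

    Attributes
    ----------
    network_ : BipartiteNetwork
        The fitted association network.

    Examples
    --------
    >>> edges = [("g1", "d1"), ("g1", "d2"), ("g2", "d1"),
    ...          ("g2", "d3"), ("g3", "d2")]
    >>> scorer = ClusterAssociationScorer().fit(edges)
    >>> scorer.predict([("g3", "d1")])
    array([1.5])
    """

    def __init__(self, exclude_direct_edge: bool = False):
        self.exclude_direct_edge = exclude_direct_edge

    def fit(self, X, y=None) -> "ClusterAssociationScorer":
        """Ingest training associations.

        ``X`` may be a :class:`BipartiteNetwork`, a DataFrame with gene /
        disease (and optional gene_class) columns, or an iterable of
        (gene, disease) pairs.  ``y`` is ignored (present for API
        compatibility).
        """
        if isinstance(X, BipartiteNetwork):
            self.network_ = X
        elif isinstance(X, pd.DataFrame):
            classes = (
                dict(zip(X["gene"], X["gene_class"])) if "gene_class" in X else None
            )
            self.network_ = BipartiteNetwork.from_edges(
                list(zip(X["gene"], X["disease"])), classes
            )
        else:
            self.network_ = BipartiteNetwork.from_edges(list(X))
        return self

    def _check_fitted(self):
        if not hasattr(self, "network_"):
            raise NetworkError("scorer is not fitted; call fit(edges) first")

    def predict(self, X) -> np.ndarray:
        """DG_score for each (gene, disease) pair in ``X``."""
        self._check_fitted()
        return np.array(
            [
                dg_score(self.network_, g, d, self.exclude_direct_edge)
                for g, d in X
            ],
            dtype=float,
        )

    def c_scores(self, X) -> np.ndarray:
        """Raw C_score (cluster-to-cluster edge count) for each pair."""
        self._check_fitted()
        return np.array(
            [c_score(self.network_, g, d, self.exclude_direct_edge) for g, d in X],
            dtype=np.int64,
        )

    def rank_candidates(
        self, candidates="all_non_edges", allow_known: bool = False
    ) -> pd.DataFrame:
        """Ranked score table over a candidate set (see :func:`score_candidates`)."""
        self._check_fitted()
        return score_candidates(
            self.network_,
            candidates,
            exclude_direct_edge=self.exclude_direct_edge,
            allow_known=allow_known,
        )

    def predict_top(self, fraction: float = 0.01, candidates="all_non_edges") -> pd.DataFrame:
        """Top-fraction predictions (the method's headline output)."""
        return top_fraction(self.rank_candidates(candidates), fraction)
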