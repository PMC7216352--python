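"""Rank-based validation: LOOCV, k-fold cross-validation, ROC/AUC.

Each known test edge is removed from the network (one at a time in LOOCV,
fold by fold in k-fold CV), rescored on the reduced network, and ranked
against the candidate non-edge pairs (the negatives).  The AUC is the
tie-handled Mann-Whitney probability that a positive outranks a negative;
the ROC curve is obtained by sweeping the rank threshold over the pooled
score list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .network import BipartiteNetwork
from .scoring import _candidate_pairs, dg_score

logger = logging.getLogger(__name__)


@dataclass
class RankingEvaluation:
    """ROC points and AUC from a positives-vs-negatives ranking experiment."""

    positive_scores: np.ndarray
    negative_scores: np.ndarray
    roc_points: np.ndarray  # (n, 2) array of (FPR, TPR), (0,0) .. (1,1)
    auc: float
    fold_aucs: list[float] | None = None
    positives: list[tuple[str, str]] = field(default_factory=list)


def _mann_whitney_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """P(pos > neg) + 0.5 P(pos = neg) via midranks (exact with ties)."""
    pooled = np.concatenate([pos, neg])
    ranks = rankdata(pooled)
    r_pos = ranks[: len(pos)].sum()
    u = r_pos - len(pos) * (len(pos) + 1) / 2.0
    return u / (len(pos) * len(neg))


def roc_auc(positive_scores, negative_scores) -> RankingEvaluation:
    """ROC curve and Mann-Whitney AUC for two score lists.

    Ties between a positive and a negative contribute 0.5.  The trapezoidal
    area under the returned ROC points equals the AUC to within 1e-9.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("positive and negative score lists must be non-empty")
    labels = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    fpr, tpr, _ = roc_curve(labels, np.concatenate([pos, neg]), drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return RankingEvaluation(
        positive_scores=pos,
        negative_scores=neg,
        roc_points=points,
        auc=_mann_whitney_auc(pos, neg),
    )


def _as_edge_list(network: BipartiteNetwork, test_edges) -> list[tuple[str, str]]:
    if test_edges is None:
        return network.edges()
    edges = [(str(g), str(d)) for g, d in test_edges]
    for g, d in edges:
        if not network.has_edge(g, d):
            raise ValueError(f"test edge {(g, d)} is not in the network")
    if not edges:
        raise ValueError("empty test edge set")
    return edges


def _negative_scores(
    network: BipartiteNetwork, candidates, exclude_direct_edge: bool
) -> tuple[list[tuple[str, str]], np.ndarray]:
    pairs = _candidate_pairs(network, candidates)
    scores = np.array(
        [dg_score(network, g, d, exclude_direct_edge) for g, d in pairs]
    )
    return pairs, scores


def _score_removed_edge(
    network: BipartiteNetwork, gene: str, disease: str, exclude_direct_edge: bool
) -> float:
    """DG_score of (gene, disease) on the network with that edge deleted.

    Computed in place from adjacency sets (no network copy): the reduced
    clusters are N(gene) - {disease} and N(disease) - {gene}, and the reduced
    degrees drop by one.
    """
    d_members = network.gene_neighbors[gene] - {disease}
    g_members = network.disease_neighbors[disease] - {gene}
    if not d_members or not g_members:
        raise ValueError(
            f"removing edge {(gene, disease)} isolates an endpoint; "
            "degree-filter the network first"
        )
    # edges incident to gene or disease never lie between the reduced
    # clusters (gene/disease are excluded from them), so the full network's
    # neighbor sets can be used as-is
    c = sum(
        len(network.disease_neighbors[d_prime] & g_members) for d_prime in d_members
    )
    del exclude_direct_edge  # moot: the scored pair is no longer an edge
    return (1.0 / len(d_members) + 1.0 / len(g_members)) * c


def loocv(
    network: BipartiteNetwork,
    test_edges=None,
    candidates="all_non_edges",
    rescore_negatives_per_removal: bool = False,
    exclude_direct_edge: bool = False,
) -> RankingEvaluation:
    """Leave-one-out ranking validation over known edges.

    Each test edge is removed in turn and rescored on the reduced network.
    Negatives are the candidate non-edges of the full network, scored once by
    default; with ``rescore_negatives_per_removal`` they are recomputed on
    every reduced network and the AUC is the mean of the per-removal AUCs.

    The network should be degree-filtered first so that no removal isolates
    an endpoint (a violation raises).
    """
    edges = _as_edge_list(network, test_edges)

    pos_scores = np.empty(len(edges))
    if rescore_negatives_per_removal:
        per_removal_auc = []
        all_neg = []
        for i, (g, d) in enumerate(edges):
            reduced = network.remove_edges([(g, d)])
            if g not in reduced.gene_neighbors or d not in reduced.disease_neighbors:
                raise ValueError(
                    f"removing edge {(g, d)} isolates an endpoint; "
                    "degree-filter the network first"
                )
            pos_scores[i] = _score_removed_edge(network, g, d, exclude_direct_edge)
            _, neg = _negative_scores(reduced, candidates, exclude_direct_edge)
            per_removal_auc.append(
                _mann_whitney_auc(pos_scores[i : i + 1], neg)
            )
            all_neg.append(neg)
        neg_scores = np.concatenate(all_neg)
        ev = roc_auc(pos_scores, neg_scores)
        ev.auc = float(np.mean(per_removal_auc))
        ev.positives = edges
        return ev

    _, neg_scores = _negative_scores(network, candidates, exclude_direct_edge)
    for i, (g, d) in enumerate(edges):
        pos_scores[i] = _score_removed_edge(network, g, d, exclude_direct_edge)
    ev = roc_auc(pos_scores, neg_scores)
    ev.positives = edges
    return ev


def holdout_ranking(
    network: BipartiteNetwork,
    holdout_pairs,
    candidates="all_non_edges",
    exclude_direct_edge: bool = False,
) -> RankingEvaluation:
    """Rank withheld true pairs against the remaining candidate non-edges.

    The held-out pairs must be non-edges of ``network`` (e.g. the holdout
    list of the planted-block generator); they are scored as positives and
    every other candidate non-edge as a negative.
    """
    positives = [(str(g), str(d)) for g, d in holdout_pairs]
    if not positives:
        raise ValueError("empty holdout set")
    for g, d in positives:
        if network.has_edge(g, d):
            raise ValueError(f"holdout pair {(g, d)} is a known edge")
    pos_scores = np.array(
        [dg_score(network, g, d, exclude_direct_edge) for g, d in positives]
    )
    held = set(positives)
    pairs = [p for p in _candidate_pairs(network, candidates) if p not in held]
    neg_scores = np.array(
        [dg_score(network, g, d, exclude_direct_edge) for g, d in pairs]
    )
    ev = roc_auc(pos_scores, neg_scores)
    ev.positives = positives
    return ev


def kfold_cv(
    network: BipartiteNetwork,
    test_edges=None,
    k: int = 5,
    seed: int = 0,
    candidates="all_non_edges",
    exclude_direct_edge: bool = False,
) -> RankingEvaluation:
    """Seeded k-fold ranking validation.

    Test edges are shuffled with ``seed`` and split into k folds of sizes
    differing by at most one.  All edges of a fold are removed together and
    each is scored on the fold-reduced network; a positive whose endpoint is
    left with degree zero scores 0 (logged) rather than raising.  Positives
    are pooled across folds against negatives scored once on the full
    network; per-fold AUCs are also reported.
    """
    edges = _as_edge_list(network, test_edges)
    if k < 2 or k > len(edges):
        raise ValueError(f"k must be in [2, {len(edges)}], got {k}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(edges))
    folds = [sorted(order[i::k]) for i in range(k)]

    _, neg_scores = _negative_scores(network, candidates, exclude_direct_edge)

    pos_scores = np.empty(len(edges))
    fold_aucs = []
    n_zeroed = 0
    for fold in folds:
        fold_edges = [edges[i] for i in fold]
        reduced = network.remove_edges(fold_edges)
        fold_scores = []
        for i, (g, d) in zip(fold, fold_edges):
            if g in reduced.gene_neighbors and d in reduced.disease_neighbors:
                s = dg_score(reduced, g, d, exclude_direct_edge)
            else:
                s = 0.0
                n_zeroed += 1
            pos_scores[i] = s
            fold_scores.append(s)
        fold_aucs.append(_mann_whitney_auc(np.asarray(fold_scores), neg_scores))
    if n_zeroed:
        logger.info("%d positives had an isolated endpoint and scored 0", n_zeroed)

    ev = roc_auc(pos_scores, neg_scores)
    ev.fold_aucs = fold_aucs
    ev.positives = edges
    return ev
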