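"""Perturbation robustness: edge-deletion resampling and a rewired null model.

The protocol mirrors resampling-based signature screening: the top-fraction
predictions of the intact network form a fixed *verification set*; in each
repetition a fixed fraction of network edges is deleted uniformly at random,
predictions are recomputed on the remaining network, and each verification
pair is checked for membership in the new top-fraction list.  The per-pair
recovery counts over many repetitions measure the stability of the method.

A degree-preserving rewired network (double-edge swaps within the bipartite
structure) provides the structural null baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import BipartiteNetwork
from .scoring import score_candidates, top_fraction

logger = logging.getLogger(__name__)


@dataclass
class RobustnessReport:
    """Per-verification-edge recovery counts across deletion repetitions."""

    verification_edges: list[tuple[str, str]]
    deletion_fraction: float
    repetitions: int
    recovery_counts: np.ndarray

    @property
    def mean_accuracy(self) -> float:
        return float(self.recovery_counts.mean() / self.repetitions)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [g for g, _ in self.verification_edges],
                "disease": [d for _, d in self.verification_edges],
                "recovery_count": self.recovery_counts,
            }
        )


@dataclass
class RewiredNetwork:
    network: BipartiteNetwork
    swaps_performed: int
    seed: int


def build_verification_set(
    network: BipartiteNetwork, fraction: float, candidates="all_non_edges"
) -> list[tuple[str, str]]:
    """Top-fraction predicted pairs of the intact network."""
    top = top_fraction(score_candidates(network, candidates), fraction)
    return list(zip(top["gene"], top["disease"]))


def perturb_and_recover(
    network: BipartiteNetwork,
    verification: list[tuple[str, str]] | None = None,
    deletion_fraction: float = 0.2,
    repetitions: int = 1000,
    seed: int = 0,
    fraction: float = 0.01,
    candidates="all_non_edges",
) -> RobustnessReport:
    """Repeated random edge deletion with re-prediction and recovery counting.

    Per repetition, ``round(deletion_fraction * |L|)`` edges are deleted
    uniformly; the top-``fraction`` prediction list is recomputed over the
    non-edges of the remaining network; recovery_counts[i] is incremented for
    every verification pair present in that list.  Verification pairs whose
    endpoint becomes isolated (and is hence dropped from the remaining
    network) simply fail to be recovered in that repetition.

    ``seed`` spawns one independent substream per repetition, so results are
    reproducible and order-independent.
    """
    if not 0.0 < deletion_fraction < 1.0:
        raise ValueError(f"deletion_fraction must be in (0, 1), got {deletion_fraction}")
    if repetitions < 1:
        raise ValueError("repetitions must be >= 1")
    if verification is None:
        verification = build_verification_set(network, fraction, candidates)

    edges = network.edges()
    n_delete = round(deletion_fraction * len(edges))
    if n_delete >= len(edges):
        raise ValueError("deletion would remove every edge")

    streams = np.random.SeedSequence(seed).spawn(repetitions)
    counts = np.zeros(len(verification), dtype=np.int64)
    index = {pair: i for i, pair in enumerate(verification)}
    for stream in streams:
        rng = np.random.default_rng(stream)
        doomed = rng.choice(len(edges), size=n_delete, replace=False)
        remaining = network.remove_edges([edges[i] for i in doomed])
        top = top_fraction(score_candidates(remaining, candidates), fraction)
        for pair in zip(top["gene"], top["disease"]):
            i = index.get(pair)
            if i is not None:
                counts[i] += 1
    report = RobustnessReport(
        verification_edges=list(verification),
        deletion_fraction=deletion_fraction,
        repetitions=repetitions,
        recovery_counts=counts,
    )
    logger.info(
        "deletion %.0f%%: mean recovery accuracy %.3f over %d repetitions",
        100 * deletion_fraction,
        report.mean_accuracy,
        repetitions,
    )
    return report


def degree_preserving_rewire(
    network: BipartiteNetwork, seed: int = 0, swap_multiplier: float = 10.0
) -> RewiredNetwork:
    """Randomize edges by bipartite double-edge swaps, preserving all degrees.

    A swap replaces edges (g1, d1), (g2, d2) by (g1, d2), (g2, d1); it is
    rejected when it would duplicate an existing edge.  The target is
    ``swap_multiplier * |L|`` accepted swaps (a standard mixing heuristic);
    if the swap space is exhausted first (e.g. a complete bipartite graph has
    no legal swap) the partial result is returned with a warning.
    """
    if network.n_edges < 2:
        raise ValueError("need at least 2 edges to rewire")
    if swap_multiplier <= 0:
        raise ValueError("swap_multiplier must be positive")

    rng = np.random.default_rng(seed)
    edges = network.edges()
    edge_set = set(edges)
    target = max(1, int(round(swap_multiplier * len(edges))))
    max_attempts = 200 * target
    swaps = attempts = 0
    while swaps < target and attempts < max_attempts:
        attempts += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        g1, d1 = edges[i]
        g2, d2 = edges[j]
        if g1 == g2 or d1 == d2:
            continue
        if (g1, d2) in edge_set or (g2, d1) in edge_set:
            continue
        edge_set.difference_update([(g1, d1), (g2, d2)])
        edge_set.update([(g1, d2), (g2, d1)])
        edges[i] = (g1, d2)
        edges[j] = (g2, d1)
        swaps += 1
    if swaps < target:
        warnings.warn(
            f"rewiring stopped after {swaps} accepted swaps "
            f"({attempts} attempts); swap space may be exhausted",
            stacklevel=2,
        )
    if swaps == 0:
        return RewiredNetwork(network=network, swaps_performed=0, seed=seed)
    return RewiredNetwork(
        network=BipartiteNetwork.from_edges(edges, network.gene_class),
        swaps_performed=swaps,
        seed=seed,
    )
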