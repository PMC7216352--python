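"""Planted-block synthetic networks and similarity matrices.

The generator embodies the method's core assumption — genes (diseases)
sharing an association partner are more alike — as a bipartite planted
partition model: genes and diseases are split into aligned blocks, and a
gene-disease pair is an edge with probability ``p_in`` within a block and
``p_out`` across blocks.  A ``holdout_fraction`` of realized within-block
edges can be withheld as recoverable test positives.  Matching similarity
matrices assign ``within_block_similarity`` to same-block node pairs and
``between_block_similarity`` otherwise, plus truncated Gaussian noise.

All randomness is driven by the spec's single seed, so identical specs
produce identical fixtures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster_validation import SimilarityMatrix
from .network import BipartiteNetwork, NetworkError, write_edges


@dataclass(frozen=True)
class PlantedBlockSpec:
    """Parameters of the planted-block bipartite generator."""

    n_blocks: int = 4
    genes_per_block: int = 20
    diseases_per_block: int = 20
    p_in: float = 0.5
    p_out: float = 0.01
    holdout_fraction: float = 0.0
    seed: int = 0
    within_block_similarity: float = 0.8
    between_block_similarity: float = 0.1
    lncrna_fraction: float = 1.0
    activity_sd: float = 0.0

    def __post_init__(self):
        if self.n_blocks < 1 or self.genes_per_block < 1 or self.diseases_per_block < 1:
            raise ValueError("block counts and sizes must be >= 1")
        for name in ("p_in", "p_out", "within_block_similarity",
                     "between_block_similarity", "lncrna_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must be in [0, 1)")
        if self.activity_sd < 0:
            raise ValueError("activity_sd must be >= 0")

    @property
    def n_genes(self) -> int:
        return self.n_blocks * self.genes_per_block

    @property
    def n_diseases(self) -> int:
        return self.n_blocks * self.diseases_per_block


def _labels(spec: PlantedBlockSpec) -> tuple[list[str], list[str]]:
    genes = [f"g{i:03d}" for i in range(spec.n_genes)]
    diseases = [f"d{j:03d}" for j in range(spec.n_diseases)]
    return genes, diseases


def _block_of(spec: PlantedBlockSpec):
    gene_block = np.arange(spec.n_genes) // spec.genes_per_block
    disease_block = np.arange(spec.n_diseases) // spec.diseases_per_block
    return gene_block, disease_block


def generate_network(spec: PlantedBlockSpec):
    """Sample a planted-block network; returns (network, holdout edges).

    Holdout edges are drawn only from realized within-block edges (so they
    are recoverable in principle), removed from the returned network, and
    listed in deterministic order.  Holdout pairs whose endpoints vanish
    with the pruning of isolated nodes are dropped from the list.
    """
    rng = np.random.default_rng(spec.seed)
    genes, diseases = _labels(spec)
    gene_block, disease_block = _block_of(spec)
    same_block = gene_block[:, None] == disease_block[None, :]
    prob = np.where(same_block, spec.p_in, spec.p_out)
    if spec.activity_sd > 0:
        # per-node activity multipliers induce degree heterogeneity
        act_g = rng.lognormal(mean=0.0, sigma=spec.activity_sd, size=spec.n_genes)
        act_d = rng.lognormal(mean=0.0, sigma=spec.activity_sd, size=spec.n_diseases)
        prob = np.clip(prob * act_g[:, None] * act_d[None, :], 0.0, 1.0)
    adj = rng.random(prob.shape) < prob

    within = np.argwhere(adj & same_block)
    n_hold = int(round(spec.holdout_fraction * len(within)))
    holdout_idx = (
        within[rng.choice(len(within), size=n_hold, replace=False)]
        if n_hold
        else np.empty((0, 2), dtype=int)
    )
    adj[holdout_idx[:, 0], holdout_idx[:, 1]] = False

    edge_idx = np.argwhere(adj)
    if len(edge_idx) == 0:
        raise NetworkError(
            f"generated network is empty (p_in={spec.p_in}, p_out={spec.p_out}, "
            f"{spec.n_genes}x{spec.n_diseases} pairs)"
        )
    n_lnc = int(round(spec.lncrna_fraction * spec.n_genes))
    classes = {
        g: ("lncRNA" if i < n_lnc else "protein_coding")
        for i, g in enumerate(genes)
    }
    network = BipartiteNetwork.from_edges(
        [(genes[i], diseases[j]) for i, j in edge_idx], classes
    )
    holdout = sorted(
        (genes[i], diseases[j])
        for i, j in holdout_idx
        if genes[i] in network.gene_neighbors
        and diseases[j] in network.disease_neighbors
    )
    return network, holdout


def generate_similarity(
    spec: PlantedBlockSpec, part: str = "disease", noise_sd: float = 0.0
) -> SimilarityMatrix:
    """Block-structured similarity matrix for one part, with optional noise."""
    part_key = {"gene": 1, "disease": 2}.get(part)
    if part_key is None:
        raise ValueError(f"part must be 'gene' or 'disease', got {part!r}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, part_key]))
    if part == "gene":
        labels, _ = _labels(spec)
        block, _ = _block_of(spec)
    else:
        _, labels = _labels(spec)
        _, block = _block_of(spec)

    base = np.where(
        block[:, None] == block[None, :],
        spec.within_block_similarity,
        spec.between_block_similarity,
    ).astype(float)
    if noise_sd > 0:
        noise = rng.normal(0.0, noise_sd, size=base.shape)
        noise = np.triu(noise, k=1)
        base = base + noise + noise.T
    np.clip(base, 0.0, 1.0, out=base)
    np.fill_diagonal(base, 1.0)
    return SimilarityMatrix(pd.DataFrame(base, index=labels, columns=labels))


# toy network used throughout the documentation and tests
T1_EDGES = [("g1", "d1"), ("g1", "d2"), ("g2", "d1"), ("g2", "d3"), ("g3", "d2")]


def generate_fixture_suite(out_dir, seed: int = 0) -> dict:
    """Write a standard set of TSV fixtures and a JSON manifest.

    Produces the T1 toy network, a no-signal network (p_in = p_out), a
    strong-signal planted network with a 10% holdout, and gene/disease
    similarity matrices for the strong-signal spec.  The manifest records
    the generating parameters and summary statistics for each file.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "files": {}}

    t1 = BipartiteNetwork.from_edges(T1_EDGES)
    write_edges(t1, out / "t1.tsv")
    manifest["files"]["t1.tsv"] = {
        "n_genes": t1.n_genes, "n_diseases": t1.n_diseases, "n_edges": t1.n_edges
    }

    flat_spec = PlantedBlockSpec(
        n_blocks=4, genes_per_block=15, diseases_per_block=15,
        p_in=0.08, p_out=0.08, seed=seed,
    )
    flat, _ = generate_network(flat_spec)
    write_edges(flat, out / "no_signal.tsv")
    manifest["files"]["no_signal.tsv"] = {
        "spec": asdict(flat_spec), "n_genes": flat.n_genes,
        "n_diseases": flat.n_diseases, "n_edges": flat.n_edges,
    }

    strong_spec = PlantedBlockSpec(
        n_blocks=4, genes_per_block=20, diseases_per_block=20,
        p_in=0.5, p_out=0.01, holdout_fraction=0.1, seed=seed + 1,
    )
    strong, holdout = generate_network(strong_spec)
    write_edges(strong, out / "strong_signal.tsv")
    pd.DataFrame(holdout, columns=["gene", "disease"]).to_csv(
        out / "strong_signal_holdout.tsv", sep="\t", index=False
    )
    manifest["files"]["strong_signal.tsv"] = {
        "spec": asdict(strong_spec), "n_genes": strong.n_genes,
        "n_diseases": strong.n_diseases, "n_edges": strong.n_edges,
        "n_holdout": len(holdout),
    }

    for part in ("gene", "disease"):
        sim = generate_similarity(strong_spec, part=part, noise_sd=0.05)
        sim.to_tsv(out / f"{part}_similarity.tsv")
        manifest["files"][f"{part}_similarity.tsv"] = {
            "part": part, "n_nodes": len(sim.node_ids), "noise_sd": 0.05,
        }

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
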