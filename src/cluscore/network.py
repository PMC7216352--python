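"""Gene-disease bipartite association networks: reading, merging, filtering.

The central container is :class:`BipartiteNetwork`, an immutable bipartite
graph G(X, Y, L) whose two parts are genes (lncRNA and/or protein-coding)
and diseases, and whose edges are known associations.  Networks are built
from association records (typically a two- or three-column TSV edge list);
nodes exist only through edges, so every node has degree >= 1 by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

GENE_CLASSES = ("lncRNA", "protein_coding", "unknown")


class NetworkError(ValueError):
    """Invalid network construction or filtering outcome."""


class ParseError(ValueError):
    """Malformed association file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass(frozen=True)
class AssociationRecord:
    """One gene-disease association with optional provenance."""

    gene: str
    disease: str
    gene_class: str = "unknown"
    source: str = ""

    def __post_init__(self):
        if not self.gene or not self.disease:
            raise ValueError("gene and disease identifiers must be non-empty")
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")


@dataclass(frozen=True)
class BipartiteNetwork:
    """Immutable bipartite gene-disease association graph.

    Adjacency is stored as frozen neighbor sets on both parts.  Invariants
    enforced at construction: the two parts are disjoint, every edge endpoint
    is present, there are no duplicate edges, and every node has degree >= 1.
    """

    gene_neighbors: Mapping[str, frozenset]
    disease_neighbors: Mapping[str, frozenset]
    gene_class: Mapping[str, str] = field(default_factory=dict)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        gene_class: Mapping[str, str] | None = None,
    ) -> "BipartiteNetwork":
        """Build a network from (gene, disease) pairs, deduplicating edges."""
        gn: dict[str, set] = {}
        dn: dict[str, set] = {}
        for g, d in edges:
            g, d = str(g).strip(), str(d).strip()
            if not g or not d:
                raise NetworkError("empty identifier in edge list")
            gn.setdefault(g, set()).add(d)
            dn.setdefault(d, set()).add(g)
        if not gn:
            raise NetworkError("no associations: cannot build an empty network")
        overlap = sorted(set(gn) & set(dn))
        if overlap:
            raise NetworkError(
                "identifiers used as both gene and disease: " + ", ".join(overlap)
            )
        classes = {
            g: (gene_class or {}).get(g, "unknown") for g in gn
        }
        return cls(
            gene_neighbors={g: frozenset(v) for g, v in gn.items()},
            disease_neighbors={d: frozenset(v) for d, v in dn.items()},
            gene_class=classes,
        )

    @classmethod
    def from_records(cls, records: Sequence[AssociationRecord]) -> "BipartiteNetwork":
        if not records:
            raise NetworkError("no associations: record list is empty")
        classes: dict[str, str] = {}
        for r in records:
            # a concrete class wins over "unknown" when sources disagree
            if classes.get(r.gene, "unknown") == "unknown":
                classes[r.gene] = r.gene_class
        return cls.from_edges([(r.gene, r.disease) for r in records], classes)

    # -- basic queries -----------------------------------------------------

    @property
    def genes(self) -> frozenset:
        return frozenset(self.gene_neighbors)

    @property
    def diseases(self) -> frozenset:
        return frozenset(self.disease_neighbors)

    @property
    def n_genes(self) -> int:
        return len(self.gene_neighbors)

    @property
    def n_diseases(self) -> int:
        return len(self.disease_neighbors)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.gene_neighbors.values())

    def edges(self) -> list[tuple[str, str]]:
        """All (gene, disease) edges in deterministic sorted order."""
        return sorted(
            (g, d) for g, nbrs in self.gene_neighbors.items() for d in nbrs
        )

    def has_edge(self, gene: str, disease: str) -> bool:
        return disease in self.gene_neighbors.get(gene, frozenset())

    def degree(self, node: str) -> int:
        if node in self.gene_neighbors:
            return len(self.gene_neighbors[node])
        if node in self.disease_neighbors:
            return len(self.disease_neighbors[node])
        raise KeyError(f"node {node!r} not in network")

    def neighbors(self, node: str) -> frozenset:
        if node in self.gene_neighbors:
            return self.gene_neighbors[node]
        if node in self.disease_neighbors:
            return self.disease_neighbors[node]
        raise KeyError(f"node {node!r} not in network")

    def density(self) -> float:
        """Edge density |L| / (|X| * |Y|)."""
        return self.n_edges / (self.n_genes * self.n_diseases)

    def lncrna_genes(self) -> frozenset:
        return frozenset(
            g for g in self.gene_neighbors if self.gene_class.get(g) == "lncRNA"
        )

    # -- derived networks --------------------------------------------------

    def remove_edges(self, edges: Iterable[tuple[str, str]]) -> "BipartiteNetwork":
        """New network without the given edges; orphaned nodes are dropped."""
        drop = set(edges)
        kept = [
            (g, d)
            for g, nbrs in self.gene_neighbors.items()
            for d in nbrs
            if (g, d) not in drop
        ]
        if not kept:
            raise NetworkError("no associations: edge removal emptied the network")
        return BipartiteNetwork.from_edges(kept, self.gene_class)

    def transpose(self) -> "BipartiteNetwork":
        """Swap the two parts (genes become diseases and vice versa)."""
        return BipartiteNetwork(
            gene_neighbors=self.disease_neighbors,
            disease_neighbors=self.gene_neighbors,
            gene_class={},
        )

    # -- matrix / interop --------------------------------------------------

    def node_index(self) -> tuple[list[str], list[str]]:
        """Sorted gene and disease label lists used by :meth:`adjacency`."""
        return sorted(self.gene_neighbors), sorted(self.disease_neighbors)

    def adjacency(self) -> sp.csr_matrix:
        """Sparse genes x diseases biadjacency matrix (sorted label order)."""
        genes, diseases = self.node_index()
        gi = {g: i for i, g in enumerate(genes)}
        di = {d: j for j, d in enumerate(diseases)}
        rows, cols = [], []
        for g, nbrs in self.gene_neighbors.items():
            for d in nbrs:
                rows.append(gi[g])
                cols.append(di[d])
        data = np.ones(len(rows), dtype=np.float64)
        return sp.csr_matrix(
            (data, (rows, cols)), shape=(len(genes), len(diseases))
        )

    def to_networkx(self):
        """Export as a networkx.Graph with bipartite node attributes."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.gene_neighbors, bipartite="gene")
        g.add_nodes_from(self.disease_neighbors, bipartite="disease")
        g.add_edges_from(self.edges())
        return g


# ---------------------------------------------------------------------------
# File I/O


def _parse_descriptor(path) -> tuple[Path, str | None]:
    """Split 'book.xlsx::Sheet 1' descriptors into (path, sheet)."""
    if isinstance(path, (tuple, list)) and len(path) == 2:
        return Path(path[0]), path[1]
    text = str(path)
    if "::" in text:
        file_part, sheet = text.rsplit("::", 1)
        return Path(file_part), sheet
    return Path(text), None


def load_associations(path, format: str | None = None) -> list[AssociationRecord]:
    """Read gene-disease associations from a TSV edge list or an xlsx sheet.

    The TSV layout is ``gene<TAB>disease[<TAB>gene_class]`` with an optional
    header row.  ``path`` may be a plain path, a ``(file, sheet)`` tuple or a
    ``file.xlsx::sheet`` descriptor for spreadsheets.  Duplicate
    (gene, disease) rows are collapsed to the first occurrence; the number of
    collapsed duplicates is logged.
    """
    file_path, sheet = _parse_descriptor(path)
    if not file_path.exists():
        raise FileNotFoundError(f"association file not found: {file_path}")

    if format == "xlsx" or (format is None and file_path.suffix.lower() in (".xlsx", ".xls")):
        frame = pd.read_excel(file_path, sheet_name=sheet or 0, header=None, dtype=str)
        rows = [
            (i + 1, [c for c in row if isinstance(c, str) and c.strip()])
            for i, row in enumerate(frame.itertuples(index=False, name=None))
        ]
    else:
        with open(file_path, encoding="utf-8") as fh:
            rows = [
                (i, [c.strip() for c in line.rstrip("\n").split("\t") if c.strip()])
                for i, line in enumerate(fh, start=1)
                if line.strip()
            ]

    # drop a header row if present
    if rows and rows[0][1] and rows[0][1][0].lower() in ("gene", "lncrna", "gene_id"):
        rows = rows[1:]
    if not rows:
        raise ParseError("no associations in file")

    records: list[AssociationRecord] = []
    seen: set[tuple[str, str]] = set()
    duplicates = 0
    for line_no, cells in rows:
        if len(cells) < 2:
            raise ParseError(
                f"expected at least 2 columns, got {len(cells)}", line=line_no
            )
        gene, disease = cells[0], cells[1]
        gene_class = cells[2] if len(cells) > 2 else "unknown"
        if gene_class not in GENE_CLASSES:
            raise ParseError(f"unknown gene class {gene_class!r}", line=line_no)
        key = (gene, disease)
        if key in seen:
            duplicates += 1
            continue
        seen.add(key)
        records.append(
            AssociationRecord(gene, disease, gene_class, source=str(file_path))
        )
    if duplicates:
        logger.info("collapsed %d duplicate association rows", duplicates)
    return records


def build_network(records: Sequence[AssociationRecord]) -> BipartiteNetwork:
    """Construct the bipartite network from deduplicated association records."""
    return BipartiteNetwork.from_records(records)


def load_network(path) -> BipartiteNetwork:
    """Shortcut: ``build_network(load_associations(path))``."""
    return build_network(load_associations(path))


def write_edges(network: BipartiteNetwork, path) -> None:
    """Serialize the edge list as a three-column TSV (round-trip safe)."""
    frame = pd.DataFrame(network.edges(), columns=["gene", "disease"])
    frame["gene_class"] = [
        network.gene_class.get(g, "unknown") for g in frame["gene"]
    ]
    frame.to_csv(path, sep="\t", index=False)


def write_predictions(scores: pd.DataFrame, path) -> None:
    """Write ranked predictions as TSV.

    ``scores`` is the frame produced by :func:`cluscore.scoring.score_candidates`
    (columns gene, disease, gene_class, c_score, dg_score, rank, ranks 1-based
    strictly increasing).
    """
    cols = ["gene", "disease", "gene_class", "c_score", "dg_score", "rank"]
    frame = scores[cols] if len(scores) else pd.DataFrame(columns=cols)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Degree filtering


def remove_degree_one_nodes(
    network: BipartiteNetwork, mode: str = "single_pass"
) -> BipartiteNetwork:
    """Remove degree-1 nodes (and their incident edges) before LOOCV.

    ``single_pass`` removes exactly the nodes whose degree in the *input*
    network is 1; nodes orphaned by those removals are dropped too (a node
    cannot exist without edges).  ``iterative`` repeats the pass until no
    degree-1 node remains, so the result has minimum degree >= 2.
    """
    if mode not in ("single_pass", "iterative"):
        raise ValueError(f"unknown mode {mode!r}")

    current = network
    while True:
        low = {
            n
            for part in (current.gene_neighbors, current.disease_neighbors)
            for n, nbrs in part.items()
            if len(nbrs) == 1
        }
        if not low:
            return current
        kept = [
            (g, d)
            for g, nbrs in current.gene_neighbors.items()
            if g not in low
            for d in nbrs
            if d not in low
        ]
        if not kept:
            raise NetworkError("no evaluable edges: degree filtering emptied the network")
        current = BipartiteNetwork.from_edges(kept, network.gene_class)
        if mode == "single_pass":
            return current
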