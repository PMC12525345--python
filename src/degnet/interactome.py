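"""Build and filter the gene-level interaction network.

The raw input is a STRING-style edge list of protein pairs with an integer
confidence score in [0, 1000] (the "experimental" evidence channel). The
pipeline translates protein pairs to gene pairs, keeps only edges whose
confidence is strictly above ``score_min``, restricts the graph to genes
expressed in at least one dataset, and drops every connected component with
fewer than ``min_component_size`` nodes. The surviving graph is the universe
in which DEGs are projected, clustered and scored.

Edge confidences are kept as provenance on the edges, but the adjacency used
downstream is binary: an interaction either passed the confidence filter or
it did not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import (
    DegenerateNodeError,
    EmptyInputError,
    EmptyNetworkError,
    FormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

BIOTYPES = ("protein_coding", "lncRNA", "other_ncRNA", "pseudogene", "other")


@dataclass(frozen=True)
class GeneNode:
    """A gene vertex: stable identifier, display symbol and biotype."""

    gene_id: str
    symbol: str = ""
    biotype: str = "other"


@dataclass(frozen=True)
class EdgeRecord:
    """A scored, undirected gene-gene interaction."""

    gene_a: str
    gene_b: str
    score: int

    def __post_init__(self) -> None:
        if not 0 <= self.score <= 1000:
            raise ValidationError(f"edge score {self.score} outside [0, 1000]")


@dataclass
class NetworkConfig:
    """Thresholds of the network construction stage.

    score_min
        Strict lower bound on edge confidence (edges with score > score_min
        are kept). Default 150.
    min_component_size
        Connected components smaller than this are removed. Default 5.
    min_cluster_size
        Louvain communities smaller than this are dissolved into isolated
        DEGs. Default 3.
    adjacency_mode
        ``"symmetric"`` for D^(-1/2) A D^(-1/2) (default) or ``"random_walk"``
        for the row-stochastic D^(-1) A.
    """

    score_min: int = 150
    min_component_size: int = 5
    min_cluster_size: int = 3
    adjacency_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.score_min < 0:
            raise ValidationError("score_min must be >= 0")
        if self.min_component_size < 1 or self.min_cluster_size < 1:
            raise ValidationError("size thresholds must be positive")
        if self.adjacency_mode not in ("symmetric", "random_walk"):
            raise ValidationError(f"unknown adjacency_mode {self.adjacency_mode!r}")


class Interactome:
    """Simple undirected gene graph with a deterministic node ordering.

    Wraps a :class:`networkx.Graph`; node attributes hold ``symbol`` and
    ``biotype``, edge attribute ``score`` holds the retained (maximum)
    confidence. The node order used for all matrix views is lexicographic by
    gene id, so serialized matrices are reproducible.
    """

    def __init__(self, graph: nx.Graph):
        self.graph = graph

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[EdgeRecord],
        nodes: Mapping[str, GeneNode] | None = None,
    ) -> "Interactome":
        g = nx.Graph()
        for e in edges:
            if e.gene_a == e.gene_b:
                continue
            if g.has_edge(e.gene_a, e.gene_b):
                g[e.gene_a][e.gene_b]["score"] = max(g[e.gene_a][e.gene_b]["score"], e.score)
            else:
                g.add_edge(e.gene_a, e.gene_b, score=e.score)
        if nodes:
            for gid in g.nodes:
                meta = nodes.get(gid)
                if meta is not None:
                    g.nodes[gid]["symbol"] = meta.symbol
                    g.nodes[gid]["biotype"] = meta.biotype
        for gid, data in g.nodes(data=True):
            data.setdefault("symbol", gid)
            data.setdefault("biotype", "other")
        return cls(g)

    @property
    def node_order(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.graph

    def biotype(self, gene_id: str) -> str:
        return self.graph.nodes[gene_id].get("biotype", "other")

    def node_table(self) -> pd.DataFrame:
        comp_id = {}
        for i, comp in enumerate(
            sorted(nx.connected_components(self.graph), key=lambda c: (-len(c), min(c)))
        ):
            for g in comp:
                comp_id[g] = i
        rows = [
            {
                "gene_id": g,
                "symbol": self.graph.nodes[g].get("symbol", g),
                "biotype": self.graph.nodes[g].get("biotype", "other"),
                "degree": self.graph.degree[g],
                "component_id": comp_id.get(g, -1),
            }
            for g in self.node_order
        ]
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"gene_a": min(a, b), "gene_b": max(a, b), "score": d["score"]}
            for a, b, d in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows).sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def read_mapping(path) -> dict[str, list[GeneNode]]:
    """Read a protein->gene mapping TSV (protein_id, gene_id, symbol, biotype).

    A protein may map to several genes; every mapping is returned and the
    caller's deduplication (max score per gene pair) resolves the fan-out.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"protein_id", "gene_id"}
    if not required.issubset(df.columns):
        raise FormatError(f"mapping file missing columns {required - set(df.columns)}")
    mapping: dict[str, list[GeneNode]] = {}
    for row in df.itertuples(index=False):
        node = GeneNode(
            gene_id=row.gene_id,
            symbol=getattr(row, "symbol", row.gene_id) or row.gene_id,
            biotype=getattr(row, "biotype", "other") or "other",
        )
        mapping.setdefault(row.protein_id, []).append(node)
    return mapping


def load_edges(path, id_map: Mapping[str, Sequence[GeneNode]]) -> list[EdgeRecord]:
    """Read a STRING-style links file and translate proteins to genes.

    Protein pairs mapping to the same gene collapse to self-loops and are
    dropped; duplicate gene pairs keep the maximum score; proteins absent
    from ``id_map`` are dropped with a logged count.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype={"protein1": str, "protein2": str})
    if df.empty:
        raise EmptyInputError(f"edge file {path} has no rows")
    cols = list(df.columns)
    if "protein1" not in cols or "protein2" not in cols:
        raise FormatError(f"edge file needs protein1/protein2 columns, found {cols}")
    score_col = next((c for c in ("experimental", "combined_score", "score") if c in cols), None)
    if score_col is None:
        raise FormatError(f"edge file needs a score column, found {cols}")

    best: dict[tuple[str, str], int] = {}
    n_unmapped = 0
    for p1, p2, score in zip(df["protein1"], df["protein2"], df[score_col]):
        nodes_a = id_map.get(p1)
        nodes_b = id_map.get(p2)
        if not nodes_a or not nodes_b:
            n_unmapped += 1
            continue
        for na in nodes_a:
            for nb in nodes_b:
                if na.gene_id == nb.gene_id:
                    continue  # self-loop after gene collapse
                key = tuple(sorted((na.gene_id, nb.gene_id)))
                score = int(score)
                if best.get(key, -1) < score:
                    best[key] = score
    if n_unmapped:
        logger.info("load_edges: dropped %d rows with unmapped proteins", n_unmapped)
    return [EdgeRecord(a, b, s) for (a, b), s in sorted(best.items())]


def filter_confidence(edges: Iterable[EdgeRecord], score_min: int) -> list[EdgeRecord]:
    """Keep exactly the edges whose confidence is strictly above ``score_min``."""
    if score_min < 0:
        raise ValidationError("score_min must be >= 0")
    return [e for e in edges if e.score > score_min]


def restrict_to_expressed(net: Interactome, expressed: set[str]) -> Interactome:
    """Induce the subgraph on genes expressed in at least one dataset."""
    if not expressed:
        raise EmptyNetworkError("expressed gene set is empty")
    keep = set(net.graph.nodes) & set(expressed)
    if not keep:
        raise EmptyNetworkError("no network gene is in the expressed set")
    return Interactome(net.graph.subgraph(keep).copy())


def filter_components(net: Interactome, min_component_size: int) -> Interactome:
    """Remove every connected component with fewer than ``min_component_size`` nodes."""
    keep: set[str] = set()
    for comp in nx.connected_components(net.graph):
        if len(comp) >= min_component_size:
            keep.update(comp)
    removed = net.n_nodes - len(keep)
    if removed:
        logger.info("filter_components: removed %d nodes in small components", removed)
    return Interactome(net.graph.subgraph(keep).copy())


def normalized_adjacency(net: Interactome, mode: str = "symmetric") -> np.ndarray:
    """Degree-normalized binary adjacency over the lexicographic node order.

    ``symmetric`` returns D^(-1/2) A D^(-1/2); ``random_walk`` returns the
    row-stochastic D^(-1) A. Entries lie in [0, 1]; the symmetric form equals
    1/sqrt(d_i d_j) wherever an edge exists.
    """
    order = net.node_order
    if not order:
        raise EmptyNetworkError("cannot normalize an empty network")
    a = nx.to_numpy_array(net.graph, nodelist=order, weight=None)
    deg = a.sum(axis=1)
    zero = np.flatnonzero(deg == 0)
    if zero.size:
        raise DegenerateNodeError(f"zero-degree node(s): {[order[i] for i in zero[:5]]}")
    if mode == "symmetric":
        d_inv_sqrt = 1.0 / np.sqrt(deg)
        return a * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    if mode == "random_walk":
        return a / deg[:, None]
    raise ValidationError(f"unknown adjacency mode {mode!r}")


def build_network(
    edges: Sequence[EdgeRecord],
    cfg: NetworkConfig,
    expressed: set[str] | None = None,
    nodes: Mapping[str, GeneNode] | None = None,
) -> Interactome:
    """Run the fixed construction pipeline: confidence filter, expressed
    restriction (if an expressed universe is given), component filter."""
    kept = filter_confidence(edges, cfg.score_min)
    net = Interactome.from_edges(kept, nodes=nodes)
    if expressed is not None:
        net = restrict_to_expressed(net, expressed)
    return filter_components(net, cfg.min_component_size)
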