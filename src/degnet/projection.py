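"""Project DEGs onto the interactome and cluster them.

DEGs found in the filtered network are "mapped"; the remainder (uDEGs) are
triaged by biotype into coding, ncRNA, pseudogene and other. Mapped DEGs
induce a subgraph of the interactome, which is partitioned with the Louvain
modularity method; communities of at least ``min_cluster_size`` genes become
clusters, everything else is an "isolated DEG" ranked individually later.
The disease-causal gene is not injected into the induced subgraph - it
enters only through proximity scoring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
from networkx.algorithms.community import louvain_communities

from .deg_stats import DatasetConfig
from .interactome import Interactome, NetworkConfig

logger = logging.getLogger(__name__)

UDEG_CODING = "coding"
UDEG_NCRNA = "ncRNA"
UDEG_PSEUDO = "pseudogene"
UDEG_OTHER = "other"

_BIOTYPE_TO_CATEGORY = {
    "protein_coding": UDEG_CODING,
    "lncRNA": UDEG_NCRNA,
    "other_ncRNA": UDEG_NCRNA,
    "pseudogene": UDEG_PSEUDO,
}


@dataclass
class DegProjection:
    """Split of a dataset's DEGs into network-mapped genes and uDEGs."""

    mapped: set[str]
    udegs: dict[str, str]  # gene -> category

    def udeg_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in (UDEG_CODING, UDEG_NCRNA, UDEG_PSEUDO, UDEG_OTHER)}
        for cat in self.udegs.values():
            counts[cat] += 1
        return counts


@dataclass
class ClusterSet:
    """Louvain communities of mapped DEGs plus the isolated remainder.

    Cluster ids are stable integers assigned by decreasing size, ties broken
    by the lexicographically smallest member; gene lists are sorted.
    """

    clusters: dict[int, list[str]]
    isolated: list[str]
    dataset: DatasetConfig | None = None

    @property
    def mapped_genes(self) -> set[str]:
        out = set(self.isolated)
        for genes in self.clusters.values():
            out.update(genes)
        return out


def project_degs(
    net: Interactome,
    deg_genes: set[str],
    biotypes: dict[str, str] | None = None,
) -> DegProjection:
    """Split DEGs into mapped (present in the network) and categorized uDEGs."""
    biotypes = biotypes or {}
    mapped = {g for g in deg_genes if g in net}
    udegs = {
        g: _BIOTYPE_TO_CATEGORY.get(biotypes.get(g, "other"), UDEG_OTHER)
        for g in deg_genes - mapped
    }
    return DegProjection(mapped=mapped, udegs=udegs)


def _split_disconnected(graph: nx.Graph, community: set[str]) -> list[set[str]]:
    """Split a community into its connected parts within the induced graph."""
    sub = graph.subgraph(community)
    return [set(c) for c in nx.connected_components(sub)]


def cluster_degs(
    net: Interactome,
    projection: DegProjection,
    cfg: NetworkConfig,
    seed: int,
    dataset: DatasetConfig | None = None,
) -> ClusterSet:
    """Louvain-cluster the subgraph induced by mapped DEGs.

    Communities that come back disconnected within the induced subgraph are
    split into connected parts before the size filter. Mapped DEGs not in
    any community of size >= min_cluster_size become isolated DEGs.
    """
    mapped = sorted(projection.mapped)
    sub = net.graph.subgraph(mapped)
    if sub.number_of_edges() == 0:
        if mapped:
            logger.warning("cluster_degs: DEG-induced subgraph has no edges; all isolated")
        return ClusterSet(clusters={}, isolated=mapped, dataset=dataset)

    communities = louvain_communities(sub, resolution=1.0, seed=seed)
    parts: list[set[str]] = []
    for comm in communities:
        parts.extend(_split_disconnected(sub, set(comm)))

    keepers = [p for p in parts if len(p) >= cfg.min_cluster_size]
    keepers.sort(key=lambda p: (-len(p), min(p)))
    clusters = {i: sorted(p) for i, p in enumerate(keepers)}
    clustered = set().union(*keepers) if keepers else set()
    isolated = sorted(set(mapped) - clustered)
    return ClusterSet(clusters=clusters, isolated=isolated, dataset=dataset)
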