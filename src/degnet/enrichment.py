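"""Over-representation analysis and the cross-dataset enrichment network.

Each annotation term is tested against a query gene set with the upper-tail
hypergeometric test; p-values are Benjamini-Hochberg adjusted within each
query's term family. Significant terms across datasets are assembled into a
comparative network: terms are nodes (annotated with the datasets they are
significant in), an edge joins two terms sharing at least one DEG with the
shared-DEG count as weight, and whenever an ancestor and a descendant term
are both present only the descendant is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, ValidationError
from .projection import ClusterSet


@dataclass
class AnnotationCatalog:
    """Term -> gene sets plus parent -> child relations."""

    terms: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    hierarchy: set[tuple[str, str]] = field(default_factory=set)  # (parent, child)

    def __post_init__(self) -> None:
        dag = nx.DiGraph(list(self.hierarchy))
        if not nx.is_directed_acyclic_graph(dag):
            raise ValidationError("term hierarchy contains a cycle")

    @classmethod
    def from_gmt(cls, gmt_path, hierarchy_path=None) -> "AnnotationCatalog":
        terms: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        with open(gmt_path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    raise FormatError(f"GMT line has <3 fields: {line[:80]!r}")
                term_id, name, genes = parts[0], parts[1], [g for g in parts[2:] if g]
                if not genes:
                    continue
                terms[term_id] = set(genes)
                names[term_id] = name
        hierarchy: set[tuple[str, str]] = set()
        if hierarchy_path is not None:
            rel = pd.read_csv(hierarchy_path, sep="\t", dtype=str)
            if not {"parent_id", "child_id"}.issubset(rel.columns):
                raise FormatError("hierarchy file needs parent_id and child_id columns")
            hierarchy = set(zip(rel["parent_id"], rel["child_id"]))
        return cls(terms=terms, names=names, hierarchy=hierarchy)


def ora_test(query: set[str], term_genes: set[str], universe: set[str]) -> dict:
    """Upper-tail hypergeometric P(X >= k) for query/term overlap.

    Population N = universe, successes K = term genes in the universe,
    draws n = query size, overlap k.
    """
    if not universe:
        raise ValidationError("ORA universe is empty")
    query = set(query) & set(universe)
    term_in_universe = set(term_genes) & set(universe)
    n_pop, n_succ, n_draw = len(universe), len(term_in_universe), len(query)
    overlap = query & term_in_universe
    k = len(overlap)
    pvalue = float(hypergeom.sf(k - 1, n_pop, n_succ, n_draw)) if k > 0 else 1.0
    return {
        "k": k,
        "K": n_succ,
        "n": n_draw,
        "N": n_pop,
        "pvalue": min(pvalue, 1.0),
        "overlap_genes": sorted(overlap),
    }


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_query(
    query: set[str], catalog: AnnotationCatalog, universe: set[str]
) -> pd.DataFrame:
    """ORA over every catalog term with BH adjustment across the term family."""
    rows = []
    for term_id, genes in sorted(catalog.terms.items()):
        res = ora_test(query, genes, universe)
        res["term_id"] = term_id
        res["name"] = catalog.names.get(term_id, term_id)
        rows.append(res)
    df = pd.DataFrame(rows, columns=["term_id", "name", "k", "K", "n", "N", "pvalue", "overlap_genes"])
    df["padj"] = bh_adjust(df["pvalue"]) if len(df) else []
    return df.sort_values(["padj", "pvalue", "term_id"]).reset_index(drop=True)


def enrich_clusters(
    clusters: ClusterSet,
    catalog: AnnotationCatalog,
    universe: set[str],
    padj_threshold: float = 0.05,
) -> dict[int, pd.DataFrame]:
    """Per-cluster ORA; the ``significant`` column marks padj < threshold."""
    out = {}
    for cid, genes in clusters.clusters.items():
        df = enrich_query(set(genes), catalog, universe)
        df["significant"] = df["padj"] < padj_threshold
        out[cid] = df
    return out


def _prune_ancestors(term_ids: set[str], hierarchy: set[tuple[str, str]]) -> set[str]:
    """Drop any term that has a retained descendant (transitive closure)."""
    dag = nx.DiGraph([(p, c) for p, c in hierarchy])
    dag.add_nodes_from(term_ids)
    drop = set()
    for term in term_ids:
        if term not in dag:
            continue
        descendants = nx.descendants(dag, term)
        if descendants & term_ids:
            drop.add(term)
    return term_ids - drop


def comparative_network(
    per_dataset_results: dict[str, pd.DataFrame],
    hierarchy: set[tuple[str, str]],
    p_threshold: float = 0.05,
    p_column: str = "pvalue",
) -> nx.Graph:
    """Cross-dataset network of significant terms.

    ``per_dataset_results`` maps dataset name -> enrichment table with
    ``term_id``, a p column and ``overlap_genes``. Terms significant in at
    least one dataset become nodes (after ancestor pruning); two terms are
    joined when they share >= 1 DEG across the union of contributing
    datasets, weighted by the shared-DEG count.
    """
    term_datasets: dict[str, set[str]] = {}
    term_genes: dict[str, set[str]] = {}
    for ds, df in per_dataset_results.items():
        sig = df[df[p_column] < p_threshold]
        for row in sig.itertuples(index=False):
            term_datasets.setdefault(row.term_id, set()).add(ds)
            term_genes.setdefault(row.term_id, set()).update(row.overlap_genes)

    kept = _prune_ancestors(set(term_datasets), hierarchy)
    g = nx.Graph()
    for term in sorted(kept):
        g.add_node(term, datasets=sorted(term_datasets[term]))
    kept_sorted = sorted(kept)
    for i, ta in enumerate(kept_sorted):
        for tb in kept_sorted[i + 1 :]:
            shared = term_genes[ta] & term_genes[tb]
            if shared:
                g.add_edge(ta, tb, weight=len(shared), shared_genes=sorted(shared))
    return g
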