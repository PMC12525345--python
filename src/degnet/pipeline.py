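"""End-to-end orchestration: files in, run directory of reports out.

A run executes, per dataset: network construction -> expression filter and
DEG classification -> projection/Louvain clustering -> embedding-based
proximity scoring -> per-cluster ORA, then the cross-dataset comparative
enrichment network. Every source of randomness draws a per-stage seed
derived from the single global seed, and a JSON manifest records seeds,
config hash and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import deg_stats, enrichment, interactome, projection, proximity
from .deg_stats import DatasetConfig
from .errors import ValidationError
from .interactome import NetworkConfig
from .proximity import EmbeddingConfig

logger = logging.getLogger(__name__)


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed so one stage can be rerun in isolation."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for a full run."""

    edges: str
    mapping: str
    de_stats: str
    counts: str
    samples: str
    gmt: str
    hierarchy: str
    datasets: list[DatasetConfig]
    biotypes: str | None = None
    network: NetworkConfig = field(default_factory=NetworkConfig)
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    seed: int = 0
    epsilon: float = 1e-12
    probability_mode: str = "rank"
    cluster_padj_threshold: float = 0.05
    comparative_p_threshold: float = 0.05
    top_k_isolated: int = 10
    compute_umap: bool = False

    def validate(self) -> None:
        for attr in ("edges", "mapping", "de_stats", "counts", "samples", "gmt", "hierarchy"):
            path = getattr(self, attr)
            if path and not Path(path).exists():
                raise ValidationError(f"input file for {attr!r} not found: {path}")
        if not self.datasets:
            raise ValidationError("at least one dataset is required")
        names = [d.name for d in self.datasets]
        if len(set(names)) != len(names):
            raise ValidationError("dataset names must be unique")
        for d in self.datasets:
            if not d.causal_gene:
                raise ValidationError(f"dataset {d.name}: causal gene missing")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        datasets = [DatasetConfig(**d) for d in raw.pop("datasets")]
        network = NetworkConfig(**raw.pop("network", {}))
        embedding = EmbeddingConfig(**raw.pop("embedding", {}))
        return cls(datasets=datasets, network=network, embedding=embedding, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                **{k: v for k, v in asdict(self).items()},
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def bundle_config(
    bundle_dir,
    seed: int = 0,
    dataset_name: str = "synthetic",
    log2fc_cutoff: float = 0.6,
    min_libraries: int = 2,
    **overrides,
) -> PipelineConfig:
    """PipelineConfig pointed at a synthetic bundle directory.

    The causal gene is taken from the bundle's truth file.
    """
    bundle = Path(bundle_dir)
    truth = json.loads((bundle / "truth.json").read_text())
    ds = DatasetConfig(
        name=dataset_name,
        causal_gene=truth["causal_gene"],
        log2fc_cutoff=log2fc_cutoff,
        min_libraries=min_libraries,
    )
    return PipelineConfig(
        edges=str(bundle / "edges.tsv"),
        mapping=str(bundle / "mapping.tsv"),
        de_stats=str(bundle / "de_stats.tsv"),
        counts=str(bundle / "counts.tsv"),
        samples=str(bundle / "samples.tsv"),
        gmt=str(bundle / "annotations.gmt"),
        hierarchy=str(bundle / "hierarchy.tsv"),
        biotypes=str(bundle / "biotypes.tsv"),
        datasets=[ds],
        seed=seed,
        **overrides,
    )


#: stage names in execution order; each CLI subcommand runs the prefix up to
#: its own stage and writes the corresponding outputs.
STAGE_LEVELS = {"net": 1, "degs": 2, "project": 3, "score": 4, "enrich": 5, "all": 5}


def run_pipeline(cfg: PipelineConfig, outdir, upto: str = "all") -> Path:
    """Execute the stages up to ``upto`` and write reports into ``outdir``."""
    if upto not in STAGE_LEVELS:
        raise ValidationError(f"unknown stage {upto!r}")
    level = STAGE_LEVELS[upto]
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- expression universe (shared across datasets)
    counts = pd.read_csv(cfg.counts, sep="\t", index_col=0)
    sheet = pd.read_csv(cfg.samples, sep="\t")
    groups = pd.Series(sheet["group"].values, index=sheet["sample"])
    expressed_by_ds = {
        d.name: deg_stats.expression_filter(counts, groups, d) for d in cfg.datasets
    }
    expressed_union = set().union(*expressed_by_ds.values())

    # --- network construction
    id_map = interactome.read_mapping(cfg.mapping)
    gene_meta = {n.gene_id: n for nodes in id_map.values() for n in nodes}
    edges = interactome.load_edges(cfg.edges, id_map)
    net = interactome.build_network(
        edges, cfg.network, expressed=expressed_union, nodes=gene_meta
    )
    _write(net.node_table(), outdir / "network_nodes.tsv")
    _write(net.edge_table(), outdir / "network_edges.tsv")

    if level < 2:
        _write_manifest(cfg, net, outdir, None)
        return outdir

    # --- per-gene DE statistics
    stats_all = pd.read_csv(cfg.de_stats, sep="\t")
    biotypes: dict[str, str] = {g: n.biotype for g, n in gene_meta.items()}
    if cfg.biotypes:
        bt = pd.read_csv(cfg.biotypes, sep="\t")
        biotypes.update(dict(zip(bt["gene_id"], bt["biotype"])))

    order = net.node_order
    sim = link = None
    if level >= 4:
        # --- shared embedding of the filtered network
        adj = interactome.normalized_adjacency(net, mode=cfg.network.adjacency_mode)
        emb_cfg = EmbeddingConfig(
            **{**asdict(cfg.embedding), "seed": derive_seed(cfg.seed, "embed")}
        )
        emb = proximity.embed(adj, order, emb_cfg)
        sim = proximity.cosine_sim(emb)
        link = proximity.fit_link_model(sim, net, order, seed=derive_seed(cfg.seed, "link_model"))

    summaries = []
    table2_rows = []
    per_dataset_enrich: dict[str, pd.DataFrame] = {}
    catalog = enrichment.AnnotationCatalog.from_gmt(cfg.gmt, cfg.hierarchy)

    for ds in cfg.datasets:
        expressed = expressed_by_ds[ds.name]
        stats = stats_all[stats_all["gene_id"].isin(expressed)].copy()
        classified = deg_stats.classify_degs(stats, ds)
        _write(classified, outdir / f"deg_table_{ds.name}.tsv")
        summaries.append(
            deg_stats.dataset_summary(classified, expressed_genes=len(expressed), name=ds.name)
        )

        if level < 3:
            continue

        deg_genes = set(
            classified.loc[classified["status"] != deg_stats.STATUS_NS, "gene_id"]
        )
        proj = projection.project_degs(net, deg_genes, biotypes)
        cset = projection.cluster_degs(
            net, proj, cfg.network, seed=derive_seed(cfg.seed, f"louvain:{ds.name}"), dataset=ds
        )
        lfc = dict(zip(classified["gene_id"], classified["log2fc"]))
        status = dict(zip(classified["gene_id"], classified["status"]))
        member_rows = [
            {
                "dataset": ds.name,
                "cluster_id": cid,
                "gene_id": g,
                "log2fc": lfc.get(g),
                "status": status.get(g),
            }
            for cid, genes in cset.clusters.items()
            for g in genes
        ]
        _write(pd.DataFrame(member_rows, columns=["dataset", "cluster_id", "gene_id", "log2fc", "status"]),
               outdir / f"clusters_{ds.name}.tsv")
        _write(
            pd.DataFrame(
                [{"dataset": ds.name, "gene_id": g, "category": c} for g, c in sorted(proj.udegs.items())],
                columns=["dataset", "gene_id", "category"],
            ),
            outdir / f"udegs_{ds.name}.tsv",
        )
        cnt = proj.udeg_counts()
        table2_rows.append(
            {
                "dataset": ds.name,
                "mapped_degs": len(proj.mapped),
                "udegs": len(proj.udegs),
                "coding": cnt["coding"],
                "ncRNA": cnt["ncRNA"],
                "pseudogene": cnt["pseudogene"],
                "other": cnt["other"],
                "clusters": len(cset.clusters),
            }
        )

        if level < 4:
            continue

        # proximity scoring relative to this dataset's causal gene
        probs = proximity.association_prob(link, sim, order, ds.causal_gene)
        ranks = proximity.rank_normalize(probs)
        gene_rows = pd.DataFrame(
            {
                "gene_id": probs.index,
                "association_prob": probs.to_numpy(),
                "rank_score": ranks.to_numpy(),
            }
        )
        cluster_of = {g: cid for cid, genes in cset.clusters.items() for g in genes}
        gene_rows["is_DEG"] = gene_rows["gene_id"].isin(deg_genes)
        gene_rows["cluster_id"] = [
            str(cluster_of[g]) if g in cluster_of else ("isolated" if g in set(cset.isolated) else "")
            for g in gene_rows["gene_id"]
        ]
        _write(gene_rows, outdir / f"gene_proximity_{ds.name}.tsv")

        scores = proximity.score_clusters(
            cset,
            ranks,
            epsilon=cfg.epsilon,
            probability_mode=cfg.probability_mode,
            association_probs=probs,
        )
        _write(scores, outdir / f"cluster_scores_{ds.name}.tsv")
        _write(
            proximity.rank_isolated(cset.isolated, ranks, top_k=cfg.top_k_isolated),
            outdir / f"isolated_top_{ds.name}.tsv",
        )

        if cfg.compute_umap:
            coords = proximity.umap_coords(net, seed=derive_seed(cfg.seed, "umap"))
            coords["cluster_id"] = [str(cluster_of.get(g, "")) for g in coords["gene_id"]]
            coords["is_causal"] = coords["gene_id"] == ds.causal_gene
            _write(coords, outdir / f"umap_{ds.name}.tsv")

        if level < 5:
            continue

        # per-cluster ORA in the network-mapped expressed universe
        universe = expressed & set(order)
        enr = enrichment.enrich_clusters(
            cset, catalog, universe, padj_threshold=cfg.cluster_padj_threshold
        )
        for cid, df in enr.items():
            out = df.drop(columns=["overlap_genes"]).assign(
                overlap_genes=[",".join(g) for g in df["overlap_genes"]]
            )
            _write(out, outdir / f"enrichment_{ds.name}_cluster{cid}.tsv")

        # dataset-level enrichment of all DEGs, feeding the comparative network
        per_dataset_enrich[ds.name] = enrichment.enrich_query(
            deg_genes & set(order), catalog, universe
        )

    summary_df = deg_stats.cross_dataset_summary(summaries)
    _write(summary_df, outdir / "summary_table1.tsv")
    if table2_rows:
        _write(pd.DataFrame(table2_rows), outdir / "summary_table2.tsv")

    if level >= 5:
        comp = enrichment.comparative_network(
            per_dataset_enrich, catalog.hierarchy, p_threshold=cfg.comparative_p_threshold
        )
        _write(
            pd.DataFrame(
                [
                    {"term_id": t, "datasets": ",".join(d["datasets"])}
                    for t, d in sorted(comp.nodes(data=True))
                ],
                columns=["term_id", "datasets"],
            ),
            outdir / "comparative_nodes.tsv",
        )
        _write(
            pd.DataFrame(
                [
                    {"term_a": a, "term_b": b, "weight": d["weight"]}
                    for a, b, d in sorted(comp.edges(data=True))
                ],
                columns=["term_a", "term_b", "weight"],
            ),
            outdir / "comparative_edges.tsv",
        )

    _write_manifest(cfg, net, outdir, summary_df)
    return outdir


def _write_manifest(cfg: PipelineConfig, net, outdir: Path, summary_df) -> None:
    manifest = {
        "package": "degnet",
        "config_hash": cfg.config_hash(),
        "global_seed": cfg.seed,
        "stage_seeds": {
            s: derive_seed(cfg.seed, s)
            for s in ["embed", "link_model", "umap"]
            + [f"louvain:{d.name}" for d in cfg.datasets]
        },
        "network": {"nodes": net.n_nodes, "edges": net.n_edges},
    }
    if summary_df is not None:
        manifest["mean_expressed_genes"] = summary_df.attrs["mean_expressed_genes"]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
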