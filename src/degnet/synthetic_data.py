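"""Self-contained synthetic inputs with planted ground truth.

The generator emulates the statistical structure the analysis assumes: a
modular interactome (stochastic block model) containing a disease-causal
gene inside one community, DEG sets planted either in the causal community
("near") or in a distant community ("far"), extra DEGs absent from the
network (uDEGs) with assigned biotypes, negative-binomial count matrices
that exercise the CPM expression filter, and an annotation catalog whose
terms mirror the planted communities (plus decoy terms and parent terms for
the hierarchy-pruning rule).

Every output is a deterministic function of the seed, and the emitted files
use exactly the dialects the pipeline readers expect.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    Defaults: a 500-gene, 5-block modular network (within-block edge
    probability 0.2, between-block 0.01), 10 DEGs planted in the causal
    block and 10 in the most distant block, 10 uDEGs off-network, planted
    |log2FC| ~ N(2.0, 0.3), 3 vs 3 libraries with negative-binomial counts.
    """

    n_genes: int = 500
    n_blocks: int = 5
    p_in: float = 0.2
    p_out: float = 0.01
    causal_block: int = 0
    n_deg_near: int = 10
    n_deg_far: int = 10
    n_udeg: int = 10
    udeg_biotype_props: dict = field(
        default_factory=lambda: {"protein_coding": 0.3, "lncRNA": 0.5, "pseudogene": 0.2}
    )
    biotype_props: dict = field(
        default_factory=lambda: {"protein_coding": 0.8, "lncRNA": 0.15, "pseudogene": 0.05}
    )
    effect_mean: float = 2.0
    effect_sd: float = 0.3
    log2fc_cutoff: float = 0.6
    n_samples_per_group: int = 3
    nb_dispersion: float = 0.1
    n_silent: int = 20
    decoy_edge_fraction: float = 0.1
    n_decoy_terms: int = 10
    decoy_term_size: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.p_out < self.p_in <= 1:
            raise ValidationError("need 0 < p_out < p_in <= 1")
        if self.causal_block >= self.n_blocks:
            raise ValidationError("causal_block out of range")
        block = self.n_genes // self.n_blocks
        if self.n_deg_near >= block or self.n_deg_far > block:
            raise ValidationError("requested DEG counts exceed block size")


@dataclass
class TruthLabels:
    """Ground truth for recovery tests; consistent with the emitted files."""

    causal_gene: str
    block: dict[str, int]
    biotype: dict[str, str]
    near_genes: list[str]
    far_genes: list[str]
    udeg_genes: list[str]
    silent_genes: list[str]
    far_block: int

    @property
    def deg_genes(self) -> set[str]:
        return set(self.near_genes) | set(self.far_genes) | set(self.udeg_genes)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def _assign_biotypes(genes: list[str], props: dict, rng: np.random.Generator) -> dict[str, str]:
    kinds = sorted(props)
    p = np.array([props[k] for k in kinds], float)
    p = p / p.sum()
    draws = rng.choice(len(kinds), size=len(genes), p=p)
    return {g: kinds[d] for g, d in zip(genes, draws)}


def simulate_interactome(cfg: SimulationConfig):
    """Stochastic block model network with scored edges and a causal gene.

    Returns (edges DataFrame, mapping DataFrame, TruthLabels). Real edges
    get confidence scores uniform in [151, 1000]; a ``decoy_edge_fraction``
    of extra random pairs get scores in [1, 150] so the confidence filter
    has something to remove. Regenerates (with a warning) if the causal
    block's component would fall below five nodes.
    """
    rng = np.random.default_rng(cfg.seed)
    block_size = cfg.n_genes // cfg.n_blocks
    sizes = [block_size] * (cfg.n_blocks - 1) + [cfg.n_genes - block_size * (cfg.n_blocks - 1)]
    probs = np.full((cfg.n_blocks, cfg.n_blocks), cfg.p_out)
    np.fill_diagonal(probs, cfg.p_in)

    causal_idx = sum(sizes[: cfg.causal_block])
    for attempt in range(10):
        g = nx.stochastic_block_model(sizes, probs.tolist(), seed=int(rng.integers(2**31)))
        comp = next(c for c in nx.connected_components(g) if causal_idx in c)
        if len(comp) >= 5:
            break
        logger.warning("simulate_interactome: causal block under-connected, regenerating")
    genes = [_gene_id(i) for i in range(cfg.n_genes)]
    block_of = {}
    start = 0
    for b, size in enumerate(sizes):
        for i in range(start, start + size):
            block_of[genes[i]] = b
        start += size

    edges = []
    for u, v in sorted(g.edges()):
        edges.append((f"P{u:04d}", f"P{v:04d}", int(rng.integers(151, 1001))))
    n_decoy = int(round(cfg.decoy_edge_fraction * len(edges)))
    existing = {tuple(sorted(e)) for e in g.edges()}
    added = 0
    while added < n_decoy:
        u, v = rng.integers(0, cfg.n_genes, size=2)
        if u == v or tuple(sorted((int(u), int(v)))) in existing:
            continue
        existing.add(tuple(sorted((int(u), int(v)))))
        edges.append((f"P{min(u, v):04d}", f"P{max(u, v):04d}", int(rng.integers(1, 151))))
        added += 1
    edge_df = pd.DataFrame(edges, columns=["protein1", "protein2", "experimental"])

    biotype = _assign_biotypes(genes, cfg.biotype_props, rng)
    causal_gene = genes[sum(sizes[: cfg.causal_block])]
    biotype[causal_gene] = "protein_coding"
    mapping_df = pd.DataFrame(
        {
            "protein_id": [f"P{i:04d}" for i in range(cfg.n_genes)],
            "gene_id": genes,
            "symbol": [f"SYM{i:04d}" for i in range(cfg.n_genes)],
            "biotype": [biotype[g] for g in genes],
        }
    )

    # far block: maximal block index distinct from the causal one
    far_block = max(b for b in range(cfg.n_blocks) if b != cfg.causal_block)
    labels = TruthLabels(
        causal_gene=causal_gene,
        block=block_of,
        biotype=biotype,
        near_genes=[],
        far_genes=[],
        udeg_genes=[],
        silent_genes=[],
        far_block=far_block,
    )
    return edge_df, mapping_df, labels


def simulate_degs(cfg: SimulationConfig, labels: TruthLabels):
    """Plant near/far DEGs and off-network uDEGs; emit a DE stats table.

    Planted DEGs get |log2FC| ~ N(effect_mean, effect_sd) with random sign
    and padj ~ U(0, 0.01); background genes get log2FC ~ N(0, 0.2) and
    padj ~ U(0.2, 1), so classification at the configured cutoff recovers
    exactly the planted set. Returns (stats DataFrame, biotype DataFrame);
    fills the near/far/udeg fields of ``labels`` in place.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    genes = sorted(labels.block)
    causal_pool = [
        g for g in genes if labels.block[g] == cfg.causal_block and g != labels.causal_gene
    ]
    far_pool = [g for g in genes if labels.block[g] == labels.far_block]
    if cfg.n_deg_near > len(causal_pool) or cfg.n_deg_far > len(far_pool):
        raise ValidationError("requested DEG counts exceed block size")
    near = sorted(str(g) for g in rng.choice(causal_pool, size=cfg.n_deg_near, replace=False))
    far = sorted(str(g) for g in rng.choice(far_pool, size=cfg.n_deg_far, replace=False))
    udeg = [f"U{i:04d}" for i in range(cfg.n_udeg)]
    udeg_biotype = _assign_biotypes(udeg, cfg.udeg_biotype_props, rng)

    rows = []
    planted = set(near) | set(far) | set(udeg)
    for g in genes + udeg:
        if g in planted:
            mag = abs(rng.normal(cfg.effect_mean, cfg.effect_sd))
            mag = max(mag, cfg.log2fc_cutoff + 0.1)  # construction margin
            lfc = mag * (1 if rng.random() < 0.5 else -1)
            padj = rng.uniform(0, 0.01)
        else:
            lfc = rng.normal(0, 0.2)
            padj = rng.uniform(0.2, 1.0)
        rows.append({"gene_id": g, "log2fc": lfc, "pvalue": padj / 2, "padj": padj})
    stats = pd.DataFrame(rows)

    labels.near_genes = list(near)
    labels.far_genes = list(far)
    labels.udeg_genes = udeg
    labels.biotype.update(udeg_biotype)
    biotype_df = pd.DataFrame(
        {"gene_id": genes + udeg, "biotype": [labels.biotype[g] for g in genes + udeg]}
    )
    return stats, biotype_df


def simulate_counts(cfg: SimulationConfig, labels: TruthLabels, stats: pd.DataFrame):
    """Negative-binomial counts with group means shifted by planted 2^log2FC.

    Adds ``n_silent`` near-zero genes to exercise the expression filter.
    Returns (counts DataFrame genes x samples, sample sheet DataFrame).
    """
    rng = np.random.default_rng(cfg.seed + 2)
    lfc = dict(zip(stats["gene_id"], stats["log2fc"]))
    genes = list(stats["gene_id"])
    silent = [f"S{i:04d}" for i in range(cfg.n_silent)]
    labels.silent_genes = silent

    base = rng.lognormal(mean=np.log(100), sigma=0.6, size=len(genes))
    all_genes = genes + silent
    mu_ctrl = np.concatenate([base, np.full(len(silent), 0.05)])
    mu_treat = np.concatenate(
        [base * np.power(2.0, [lfc[g] for g in genes]), np.full(len(silent), 0.05)]
    )

    def nb(mu: np.ndarray, size: int) -> np.ndarray:
        n = 1.0 / cfg.nb_dispersion
        p = n / (n + mu)
        return rng.negative_binomial(n, p[:, None], size=(len(mu), size))

    ctrl = nb(mu_ctrl, cfg.n_samples_per_group)
    treat = nb(mu_treat, cfg.n_samples_per_group)
    samples = [f"ctrl_{i}" for i in range(cfg.n_samples_per_group)] + [
        f"treat_{i}" for i in range(cfg.n_samples_per_group)
    ]
    counts = pd.DataFrame(np.hstack([ctrl, treat]), index=all_genes, columns=samples)
    counts.index.name = "gene_id"
    sheet = pd.DataFrame(
        {"sample": samples, "group": ["ctrl"] * cfg.n_samples_per_group + ["treat"] * cfg.n_samples_per_group}
    )
    return counts, sheet


def simulate_annotations(cfg: SimulationConfig, labels: TruthLabels):
    """Block terms, pairwise parent terms and random decoy terms.

    Returns (gmt rows as list of (term_id, name, genes), hierarchy
    DataFrame of parent_id/child_id pairs).
    """
    rng = np.random.default_rng(cfg.seed + 3)
    genes = sorted(labels.block)
    by_block: dict[int, list[str]] = {}
    for g in genes:
        by_block.setdefault(labels.block[g], []).append(g)

    gmt: list[tuple[str, str, list[str]]] = []
    hierarchy = []
    for b in sorted(by_block):
        gmt.append((f"T:block{b}", f"block {b} module", sorted(by_block[b])))
    for a in sorted(by_block):
        for b in sorted(by_block):
            if a < b:
                pid = f"T:pair{a}_{b}"
                gmt.append((pid, f"blocks {a}+{b} parent", sorted(by_block[a] + by_block[b])))
                hierarchy.append({"parent_id": pid, "child_id": f"T:block{a}"})
                hierarchy.append({"parent_id": pid, "child_id": f"T:block{b}"})
    for d in range(cfg.n_decoy_terms):
        members = sorted(rng.choice(genes, size=min(cfg.decoy_term_size, len(genes)), replace=False))
        gmt.append((f"T:decoy{d}", f"decoy term {d}", members))
    return gmt, pd.DataFrame(hierarchy)


def write_gmt(gmt: list[tuple[str, str, list[str]]], path) -> None:
    with open(path, "w") as fh:
        for term_id, name, genes in gmt:
            fh.write("\t".join([term_id, name] + list(genes)) + "\n")


def generate_bundle(cfg: SimulationConfig, outdir) -> TruthLabels:
    """Simulate everything and write the file bundle the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edge_df, mapping_df, labels = simulate_interactome(cfg)
    stats, biotype_df = simulate_degs(cfg, labels)
    counts, sheet = simulate_counts(cfg, labels, stats)
    gmt, hierarchy = simulate_annotations(cfg, labels)

    edge_df.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    mapping_df.to_csv(outdir / "mapping.tsv", sep="\t", index=False)
    stats.to_csv(outdir / "de_stats.tsv", sep="\t", index=False)
    biotype_df.to_csv(outdir / "biotypes.tsv", sep="\t", index=False)
    counts.to_csv(outdir / "counts.tsv", sep="\t")
    sheet.to_csv(outdir / "samples.tsv", sep="\t", index=False)
    write_gmt(gmt, outdir / "annotations.gmt")
    hierarchy.to_csv(outdir / "hierarchy.tsv", sep="\t", index=False)
    (outdir / "truth.json").write_text(labels.to_json())
    return labels
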