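"""Expression filtering, DEG classification and dataset summaries.

Differential-expression model fitting is consumed, not performed: the input
is a per-gene statistics table (log2 fold change, p, adjusted p) as produced
by a DESeq2-style analysis. This module applies the expression-level filter
(counts per million in a minimum number of libraries per group), labels each
gene as over-expressed / down-regulated / not significant by a per-dataset
log2FC cutoff plus an adjusted-p threshold, and computes the dataset-level
summary arithmetic (DEG counts, percent down-regulated, mean expressed genes
across datasets).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateNodeError, FormatError, ValidationError


@dataclass
class DatasetConfig:
    """Per-dataset analysis parameters.

    log2fc_cutoff is the minimum |log2FC| for a gene to count as a DEG;
    min_libraries (MLS) is the floor on the number of libraries per group in
    which a gene must exceed cpm_threshold CPM to count as expressed. For
    groups larger than three libraries the requirement scales to two-thirds
    of the group (see :func:`expression_filter`).
    """

    name: str
    causal_gene: str
    log2fc_cutoff: float
    min_libraries: int = 2
    cpm_threshold: float = 2.0
    padj_threshold: float = 0.05
    proportional_group_size: int = 3  # groups larger than this use the 2/3 rule

    def __post_init__(self) -> None:
        if self.log2fc_cutoff < 0:
            raise ValidationError("log2fc_cutoff must be >= 0")
        if self.min_libraries < 1:
            raise ValidationError("min_libraries must be >= 1")
        if not 0 < self.padj_threshold <= 1:
            raise ValidationError("padj_threshold must be in (0, 1]")


@dataclass
class DatasetSummary:
    """Counts mirroring one row of the expressed/DEG summary table."""

    name: str
    expressed_genes: int
    degs: int
    over: int
    down: int

    @property
    def pct_down(self) -> float:
        """Percent of DEGs that are down-regulated, one decimal, half-up."""
        if self.degs == 0:
            return 0.0
        frac = 100.0 * self.down / self.degs
        return math.floor(frac * 10 + 0.5) / 10


STATUS_OVER = "over"
STATUS_DOWN = "down"
STATUS_NS = "not_significant"


def cpm_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million: entry(g, s) = counts(g, s) * 1e6 / column total."""
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise DegenerateNodeError(f"samples with zero total counts: {list(zero.index)[:5]}")
    return counts * 1e6 / totals


def required_libraries(group_size: int, cfg: DatasetConfig) -> int:
    """Libraries per group a gene must be expressed in to pass the filter.

    Small groups (size <= proportional_group_size, default 3) use the flat
    MLS floor; larger groups require at least two-thirds of the group,
    never less than MLS.
    """
    if group_size <= cfg.proportional_group_size:
        return cfg.min_libraries
    return max(cfg.min_libraries, math.ceil(2 * group_size / 3))


def expression_filter(
    counts: pd.DataFrame, groups: pd.Series, cfg: DatasetConfig
) -> set[str]:
    """Genes reaching cpm_threshold CPM in enough libraries of *each* group.

    ``groups`` maps sample -> {"ctrl", "treat"}. Returns the expressed-gene
    universe for the dataset.
    """
    groups = groups.reindex(counts.columns)
    if groups.isna().any():
        raise FormatError("every count column needs a group label")
    cpm = cpm_transform(counts)
    keep = pd.Series(True, index=counts.index)
    for label, cols in groups.groupby(groups).groups.items():
        need = required_libraries(len(cols), cfg)
        n_ok = (cpm[list(cols)] >= cfg.cpm_threshold).sum(axis=1)
        keep &= n_ok >= need
    return set(counts.index[keep])


def classify_degs(stats: pd.DataFrame, cfg: DatasetConfig) -> pd.DataFrame:
    """Label each gene over / down / not_significant.

    ``stats`` needs columns gene_id, log2fc, pvalue, padj (DESeq2 column
    aliases log2FoldChange are accepted). A gene is a DEG when
    |log2fc| >= cutoff and padj < padj_threshold.
    """
    stats = stats.rename(
        columns={"log2FoldChange": "log2fc", "gene": "gene_id", "log2FC": "log2fc"}
    ).copy()
    required = {"gene_id", "log2fc", "padj"}
    if not required.issubset(stats.columns):
        raise FormatError(f"stats table missing columns {required - set(stats.columns)}")
    lfc = stats["log2fc"].to_numpy(float)
    padj = stats["padj"].to_numpy(float)
    sig = np.nan_to_num(padj, nan=1.0) < cfg.padj_threshold
    status = np.where(
        sig & (lfc >= cfg.log2fc_cutoff),
        STATUS_OVER,
        np.where(sig & (lfc <= -cfg.log2fc_cutoff), STATUS_DOWN, STATUS_NS),
    )
    stats["status"] = status
    return stats


def dataset_summary(records: pd.DataFrame, expressed_genes: int, name: str = "") -> DatasetSummary:
    """Summarize a classified DEG table into one table row."""
    over = int((records["status"] == STATUS_OVER).sum())
    down = int((records["status"] == STATUS_DOWN).sum())
    return DatasetSummary(
        name=name, expressed_genes=expressed_genes, degs=over + down, over=over, down=down
    )


def summary_from_counts(name: str, expressed: int, over: int, down: int) -> DatasetSummary:
    """Build a summary row directly from printed counts."""
    return DatasetSummary(name=name, expressed_genes=expressed, degs=over + down, over=over, down=down)


def cross_dataset_summary(summaries: list[DatasetSummary]) -> pd.DataFrame:
    """Per-dataset rows plus the mean expressed-gene count (one decimal)."""
    if not summaries:
        raise ValidationError("need at least one dataset summary")
    rows = [
        {
            "dataset": s.name,
            "expressed_genes": s.expressed_genes,
            "degs": s.degs,
            "over": s.over,
            "down": s.down,
            "pct_down": s.pct_down,
        }
        for s in summaries
    ]
    df = pd.DataFrame(rows)
    df.attrs["mean_expressed_genes"] = round(
        float(np.mean([s.expressed_genes for s in summaries])), 1
    )
    return df
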