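"""Embedding-based proximity of DEG clusters to the disease-causal gene.

The network is embedded with node2vec-style random walks over the
degree-normalized adjacency matrix: ``num_walks`` walks of ``walk_length``
steps start at every node, transition probabilities proportional to the
normalized-adjacency entries (with the usual return/in-out biases p and q;
p = q = 1 reduces to first-order walks). Windowed word-context co-occurrence
counts from the walk corpus are factorized through their positive pointwise
mutual information (PPMI) matrix by truncated SVD - the closed-form
equivalent of skip-gram training on the same corpus - yielding one vector
per gene. This makes the embedding deterministic given the walk seed.

Cosine similarities between vectors are calibrated into link probabilities
by a logistic regression trained to separate network edges from sampled
non-edges. Each gene's probability of association with the causal gene is
rank-normalized over all network genes; cluster scores combine the member
genes' upper-tail rank p-values with Fisher's method, so a cluster whose
members all sit next to the causal gene scores near 1 and a random cluster
scores near uniform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import chi2, rankdata
from sklearn.linear_model import LogisticRegression

from .errors import DegenerateNodeError, ValidationError
from .interactome import Interactome
from .projection import ClusterSet

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingConfig:
    """node2vec walk and factorization parameters.

    The defaults are the scoring parameter set; :meth:`for_visualization`
    returns the lighter/denser set used for the 2-D UMAP view.
    """

    dimensions: int = 128
    walk_length: int = 100
    num_walks: int = 10
    p: float = 1.0
    q: float = 1.0
    window: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.dimensions, self.walk_length, self.num_walks, self.window) < 1:
            raise ValidationError("embedding parameters must be positive")
        if self.p <= 0 or self.q <= 0:
            raise ValidationError("p and q must be positive")

    @classmethod
    def for_visualization(cls, seed: int = 0) -> "EmbeddingConfig":
        return cls(dimensions=64, walk_length=30, num_walks=200, p=1.0, q=1.0, window=10, seed=seed)


@dataclass
class Embedding:
    node_order: list[str]
    vectors: np.ndarray  # n x dimensions

    def __post_init__(self) -> None:
        if len(self.node_order) != self.vectors.shape[0]:
            raise ValidationError("one vector per node required")


@dataclass
class LinkModel:
    """Logistic calibration of cosine similarity into edge probability."""

    intercept: float
    slope: float
    n_positive: int
    n_negative: int
    seed: int

    def predict(self, similarity: np.ndarray) -> np.ndarray:
        z = self.intercept + self.slope * np.asarray(similarity, float)
        return 1.0 / (1.0 + np.exp(-z))


def _first_order_walks(
    weights: sp.csr_matrix, walk_length: int, num_walks: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorized weighted first-order walks; one row per walk."""
    n = weights.shape[0]
    indptr, indices, data = weights.indptr, weights.indices, weights.data
    gcs = np.cumsum(data)
    base = np.concatenate(([0.0], gcs))[indptr[:-1]]
    totals = np.add.reduceat(data, indptr[:-1]) if len(data) else np.zeros(n)

    cur = np.repeat(np.arange(n, dtype=np.int64), num_walks)
    walks = np.empty((cur.size, walk_length), dtype=np.int32)
    walks[:, 0] = cur
    for step in range(1, walk_length):
        r = rng.random(cur.size) * totals[cur]
        pos = np.searchsorted(gcs, base[cur] + r, side="left")
        pos = np.clip(pos, indptr[cur], indptr[cur + 1] - 1)
        cur = indices[pos].astype(np.int64)
        walks[:, step] = cur
    return walks


def _second_order_walks(
    weights: sp.csr_matrix, cfg: EmbeddingConfig, rng: np.random.Generator
) -> np.ndarray:
    """Biased (p, q) walks; per-walker loop, used only when p or q != 1."""
    n = weights.shape[0]
    w = weights.toarray()
    adj = w > 0
    walks = np.empty((n * cfg.num_walks, cfg.walk_length), dtype=np.int32)
    k = 0
    for start in range(n):
        for _ in range(cfg.num_walks):
            walk = [start]
            prev = -1
            for _ in range(cfg.walk_length - 1):
                cur = walk[-1]
                wt = w[cur].copy()
                if prev >= 0:
                    bias = np.where(adj[prev], 1.0, 1.0 / cfg.q)
                    bias[prev] = 1.0 / cfg.p
                    wt *= bias
                total = wt.sum()
                nxt = int(np.searchsorted(np.cumsum(wt), rng.random() * total))
                prev = cur
                walk.append(min(nxt, n - 1))
            walks[k] = walk
            k += 1
    return walks


def _cooccurrence(walks: np.ndarray, n: int, window: int) -> np.ndarray:
    """Symmetric word-context counts within the skip-gram window."""
    counts = np.zeros(n * n, dtype=np.float64)
    for d in range(1, window + 1):
        if walks.shape[1] <= d:
            break
        left = walks[:, :-d].ravel().astype(np.int64)
        right = walks[:, d:].ravel().astype(np.int64)
        counts += np.bincount(left * n + right, minlength=n * n)
    c = counts.reshape(n, n)
    return c + c.T


def _ppmi(counts: np.ndarray) -> np.ndarray:
    total = counts.sum()
    marg = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        pmi = np.log(counts * total / np.outer(marg, marg))
    pmi[~np.isfinite(pmi)] = 0.0
    return np.maximum(pmi, 0.0)


def embed(norm_adj: np.ndarray, node_order: list[str], cfg: EmbeddingConfig) -> Embedding:
    """Walk the normalized adjacency and factorize the walk co-occurrences.

    Returns one ``dimensions``-vector per node (rank is capped at n). The
    result is a deterministic function of the matrix and the seed.
    """
    a = np.asarray(norm_adj, float)
    n = a.shape[0]
    if n == 0:
        raise ValidationError("cannot embed an empty network")
    if np.any(a.sum(axis=1) == 0):
        bad = [node_order[i] for i in np.flatnonzero(a.sum(axis=1) == 0)[:5]]
        raise DegenerateNodeError(f"isolated node(s) cannot be embedded: {bad}")
    rng = np.random.default_rng(cfg.seed)
    weights = sp.csr_matrix(a)
    if cfg.p == 1.0 and cfg.q == 1.0:
        walks = _first_order_walks(weights, cfg.walk_length, cfg.num_walks, rng)
    else:
        walks = _second_order_walks(weights, cfg, rng)
    counts = _cooccurrence(walks, n, cfg.window)
    ppmi = _ppmi(counts)
    u, s, _ = np.linalg.svd(ppmi, full_matrices=False)
    d = min(cfg.dimensions, n)
    u, s = u[:, :d], s[:d]
    # fix SVD sign ambiguity so identical inputs give identical vectors
    signs = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(d)])
    signs[signs == 0] = 1.0
    vectors = u * signs * np.sqrt(s)
    if vectors.shape[1] < cfg.dimensions:
        pad = np.zeros((n, cfg.dimensions - vectors.shape[1]))
        vectors = np.hstack([vectors, pad])
    return Embedding(node_order=list(node_order), vectors=vectors)


def cosine_sim(emb: Embedding) -> np.ndarray:
    """Pairwise cosine similarity; symmetric with unit diagonal."""
    norms = np.linalg.norm(emb.vectors, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise DegenerateNodeError(
            f"zero-norm embedding vector(s): {[emb.node_order[i] for i in zero[:5]]}"
        )
    unit = emb.vectors / norms[:, None]
    s = unit @ unit.T
    np.clip(s, -1.0, 1.0, out=s)
    np.fill_diagonal(s, 1.0)
    return s


def fit_link_model(
    sim: np.ndarray,
    net: Interactome,
    node_order: list[str],
    seed: int,
    max_positives: int = 20000,
    negative_ratio: float = 1.0,
) -> LinkModel:
    """Train edge-vs-non-edge logistic regression on similarity values.

    Positives are the network edges (uniformly subsampled above
    ``max_positives``); negatives are an equal-size (times
    ``negative_ratio``) uniform sample of non-adjacent pairs.
    """
    idx = {g: i for i, g in enumerate(node_order)}
    n = len(node_order)
    edges = [(idx[a], idx[b]) for a, b in net.graph.edges if a in idx and b in idx]
    if not edges:
        raise ValidationError("link model needs at least one edge")
    rng = np.random.default_rng(seed)
    if len(edges) > max_positives:
        chosen = rng.choice(len(edges), size=max_positives, replace=False)
        edges = [edges[i] for i in chosen]
    pos = np.array(edges)

    adj = {tuple(sorted(e)) for e in edges} | {
        tuple(sorted((idx[a], idx[b]))) for a, b in net.graph.edges if a in idx and b in idx
    }
    n_neg = int(round(len(pos) * negative_ratio))
    neg: list[tuple[int, int]] = []
    attempts = 0
    while len(neg) < n_neg and attempts < 50 * n_neg:
        i, j = rng.integers(0, n, size=2)
        attempts += 1
        if i == j:
            continue
        key = (min(i, j), max(i, j))
        if key in adj:
            continue
        neg.append((i, j))
    if not neg:
        raise ValidationError("link model needs at least one non-edge")
    neg_arr = np.array(neg)

    x = np.concatenate([sim[pos[:, 0], pos[:, 1]], sim[neg_arr[:, 0], neg_arr[:, 1]]])
    y = np.concatenate([np.ones(len(pos)), np.zeros(len(neg_arr))])
    lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
    lr.fit(x[:, None], y)
    return LinkModel(
        intercept=float(lr.intercept_[0]),
        slope=float(lr.coef_[0, 0]),
        n_positive=len(pos),
        n_negative=len(neg_arr),
        seed=seed,
    )


def association_prob(
    model: LinkModel, sim: np.ndarray, node_order: list[str], causal: str
) -> pd.Series:
    """Per-gene probability of a link with the causal gene (causal excluded)."""
    if causal not in node_order:
        raise ValidationError(f"causal gene {causal!r} is not in the network")
    ci = node_order.index(causal)
    probs = model.predict(sim[:, ci])
    out = pd.Series(probs, index=node_order)
    return out.drop(causal)


def rank_normalize(probs: pd.Series) -> pd.Series:
    """Empirical upper-tail rank in (0, 1]; ties get the mean rank."""
    if len(probs) < 2:
        raise ValidationError("rank normalization needs at least two genes")
    ranks = rankdata(probs.to_numpy(), method="average")
    return pd.Series(ranks / len(probs), index=probs.index)


def fisher_combine(pvals, epsilon: float = 1e-12) -> float:
    """Fisher's combined probability: X = -2 sum(ln p) ~ chi2(2k)."""
    p = np.asarray(list(pvals), float)
    if p.size == 0:
        raise ValidationError("fisher_combine needs at least one p-value")
    if np.any(p > 1) or np.any(p < 0):
        raise ValidationError("p-values must lie in [0, 1]")
    p = np.maximum(p, epsilon)
    x = -2.0 * np.sum(np.log(p))
    return float(chi2.sf(x, df=2 * p.size))


def score_clusters(
    clusters: ClusterSet,
    rank_scores: pd.Series,
    epsilon: float = 1e-12,
    probability_mode: str = "rank",
    association_probs: pd.Series | None = None,
) -> pd.DataFrame:
    """Fisher-combined proximity score per cluster, sorted best-first.

    In ``rank`` mode (default) each member gene contributes
    p_i = 1 - rank_score(gene); in ``direct`` mode p_i = 1 - association
    probability. score = 1 - combined_p, reported to two decimals in the
    ``score`` column (exact value kept in ``score_exact``).
    """
    if probability_mode not in ("rank", "direct"):
        raise ValidationError(f"unknown probability_mode {probability_mode!r}")
    if probability_mode == "direct" and association_probs is None:
        raise ValidationError("direct mode needs association_probs")
    rows = []
    for cid, genes in clusters.clusters.items():
        missing = [g for g in genes if g not in rank_scores.index]
        if missing:
            raise ValidationError(f"cluster {cid} members missing rank scores: {missing[:5]}")
        if probability_mode == "rank":
            p = 1.0 - rank_scores[genes].to_numpy()
        else:
            p = 1.0 - association_probs[genes].to_numpy()
        combined = fisher_combine(np.maximum(p, epsilon), epsilon=epsilon)
        rows.append(
            {
                "cluster_id": cid,
                "size": len(genes),
                "combined_p": combined,
                "score_exact": 1.0 - combined,
                "score": round(1.0 - combined, 2),
                "members": ",".join(genes),
            }
        )
    df = pd.DataFrame(
        rows, columns=["cluster_id", "size", "combined_p", "score_exact", "score", "members"]
    )
    if len(df):
        df = df.sort_values(
            ["score_exact", "cluster_id"], ascending=[False, True]
        ).reset_index(drop=True)
    return df


def rank_isolated(isolated: list[str], rank_scores: pd.Series, top_k: int = 10) -> pd.DataFrame:
    """Isolated DEGs sorted by rank score, best first; top-k returned."""
    present = [g for g in isolated if g in rank_scores.index]
    df = pd.DataFrame({"gene_id": present, "rank_score": rank_scores[present].to_numpy()})
    df = df.sort_values(["rank_score", "gene_id"], ascending=[False, True]).reset_index(drop=True)
    return df.head(top_k)


def umap_coords(net: Interactome, seed: int, cfg: EmbeddingConfig | None = None) -> pd.DataFrame:
    """2-D UMAP of the visualization embedding (n_neighbors=15, min_dist=0.1)."""
    import umap  # deferred: numba compilation is slow to import

    from .interactome import normalized_adjacency

    cfg = cfg or EmbeddingConfig.for_visualization(seed=seed)
    order = net.node_order
    emb = embed(normalized_adjacency(net), order, cfg)
    n_neighbors = 15
    if len(order) <= n_neighbors:
        n_neighbors = max(2, len(order) - 1)
        logger.warning("umap_coords: shrinking n_neighbors to %d for %d nodes", n_neighbors, len(order))
    reducer = umap.UMAP(
        n_neighbors=n_neighbors,
        min_dist=0.1,
        n_components=2,
        metric="euclidean",
        random_state=seed,
    )
    xy = reducer.fit_transform(emb.vectors)
    return pd.DataFrame({"gene_id": order, "x": xy[:, 0], "y": xy[:, 1]})
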