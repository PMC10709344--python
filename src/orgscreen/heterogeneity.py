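"""Single-organoid heterogeneity mapping.

Organoid-timepoint observations are described by six image-derived
features — area, invasive area, fraction affected, invasive fraction,
brightness and texture — centered and scaled to unit variance. Informative
principal components are selected by a permutation scheme (parallel
analysis): each permutation shuffles every column independently, the
observed explained-variance share of each PC is compared to its permuted
distribution, and Holm-adjusted permutation p-values below alpha retain a
leading contiguous block of PCs. Retained PCs feed a t-SNE embedding with
the perplexity set to floor(sqrt(n)); a k-nearest-neighbor graph over the
embedding (k capped at n−1) with edge weights set to the complement of the
Euclidean distance (1 − d/d_max over realized edges) is partitioned with
the Louvain community-detection algorithm. Cluster profiles report mean
rank-normalized features and metadata enrichment; the cluster most
enriched for baseline (t₀) observations anchors the downstream trajectory
root.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = [
    "FEATURES",
    "FeatureMatrix",
    "EmbeddingModel",
    "build_feature_matrix",
    "select_informative_pcs",
    "embed_tsne",
    "cluster_embedding",
    "rank_normalize",
    "cluster_profiles",
    "map_heterogeneity",
]

#: the six phenotype features used for embedding
FEATURES = ["bf_area", "inv_area", "fa", "inv_fraction", "brightness", "texture"]

_META_COLUMNS = ["plate_id", "well", "organoid_id", "time_h", "regimen", "role"]


@dataclass
class FeatureMatrix:
    """Standardized observation × feature matrix with aligned metadata."""

    X: np.ndarray  # standardized, rows = organoid-timepoints
    features: list[str]
    meta: pd.DataFrame
    center: np.ndarray
    scale: np.ndarray
    n_dropped_missing: int = 0
    dropped_constant: list[str] = field(default_factory=list)


def build_feature_matrix(states: pd.DataFrame) -> FeatureMatrix:
    """Assemble and standardize the feature matrix from an organoid-state table.

    Rows with any missing feature are dropped (counted); zero-variance
    columns are excluded with a warning.
    """
    missing_cols = [f for f in FEATURES if f not in states.columns]
    if missing_cols:
        raise DataError(f"states table missing feature column(s): {missing_cols}")
    df = states[[c for c in _META_COLUMNS if c in states.columns] + FEATURES].copy()
    complete = df[FEATURES].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("dropping %d rows with missing feature values", n_dropped)
    df = df[complete].reset_index(drop=True)
    if df.empty:
        raise DataError("no complete observations for the feature matrix")

    raw = df[FEATURES].to_numpy(dtype=float)
    center = raw.mean(axis=0)
    scale = raw.std(axis=0, ddof=1)
    keep = scale > 0
    dropped_constant = [f for f, k in zip(FEATURES, keep) if not k]
    if dropped_constant:
        logger.warning("excluding constant feature column(s): %s", dropped_constant)
    X = (raw[:, keep] - center[keep]) / scale[keep]
    return FeatureMatrix(
        X=X,
        features=[f for f, k in zip(FEATURES, keep) if k],
        meta=df.drop(columns=FEATURES),
        center=center[keep],
        scale=scale[keep],
        n_dropped_missing=n_dropped,
        dropped_constant=dropped_constant,
    )


def select_informative_pcs(
    X: np.ndarray, n_perm: int = 1000, alpha: float = 0.05, seed: int = 0
) -> tuple[np.ndarray, pd.DataFrame]:
    """Permutation (parallel-analysis) selection of informative PCs.

    For each PC, the permutation p-value is
    ``(1 + #{permuted variance share >= observed}) / (1 + n_perm)`` where
    every permutation shuffles each column independently. P-values are
    Holm-adjusted in eigenvalue order and retention stops at the first
    non-significant PC, keeping a leading contiguous block.

    Returns ``(scores_of_retained_pcs, table)`` where the table has one row
    per PC (variance share, p, p_holm, retained). Zero PCs retained yields
    an empty score matrix with 0 columns.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2 or n < 10:
        raise DataError(f"PC selection needs >= 2 features and >= 10 rows (got {X.shape})")
    if n_perm < 100:
        logger.warning("n_perm = %d gives coarse permutation p-values", n_perm)
    rng = np.random.default_rng(seed)
    pca = PCA(n_components=p)
    scores = pca.fit_transform(X)
    observed = pca.explained_variance_ratio_

    exceed = np.zeros(p, dtype=int)
    perm_pca = PCA(n_components=p)
    Xp = X.copy()
    for _ in range(n_perm):
        for j in range(p):
            rng.shuffle(Xp[:, j])
        perm_pca.fit(Xp)
        exceed += perm_pca.explained_variance_ratio_ >= observed
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    _, p_holm, _, _ = multipletests(pvals, alpha=alpha, method="holm")

    retained = np.zeros(p, dtype=bool)
    for i in range(p):
        if p_holm[i] < alpha:
            retained[i] = True
        else:
            break
    table = pd.DataFrame({
        "pc": np.arange(1, p + 1),
        "variance_ratio": observed,
        "p_perm": pvals,
        "p_holm": p_holm,
        "retained": retained,
    })
    return scores[:, retained], table


def tsne_perplexity(n: int) -> tuple[float, bool]:
    """Perplexity = floor(sqrt(n)), lowered to floor((n−1)/3) for small n.

    Returns (perplexity, lowered_flag).
    """
    perp = float(int(np.sqrt(n)))
    if n < 3 * perp:
        lowered = float(int((n - 1) / 3))
        logger.warning("n = %d too small for perplexity %g; lowering to %g", n, perp, lowered)
        return lowered, True
    return perp, False


def embed_tsne(X: np.ndarray, seed: int = 0, perplexity: float | None = None) -> np.ndarray:
    """Deterministic 2-D t-SNE of the retained-PC scores."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    if perplexity is None:
        perplexity, _ = tsne_perplexity(n)
    if perplexity < 1:
        raise DataError(f"too few observations for t-SNE (n = {n})")
    init = "pca" if X.shape[1] >= 2 else "random"  # PCA init needs >= 2 input dims
    tsne = TSNE(
        n_components=2, perplexity=perplexity, random_state=seed, init=init,
        max_iter=500,
    )
    return tsne.fit_transform(X)


def knn_graph(
    coords: np.ndarray, k: int = 1000, weight_scheme: str = "relative"
) -> nx.Graph:
    """Undirected kNN graph with complement-of-distance edge weights.

    ``k`` is capped at n−1. Weights: "relative" gives ``1 − d/d_max`` over
    the realized edge set (bounded in [0, 1]); "absolute" gives
    ``d_max − d``. Duplicate points (d = 0 everywhere) get weight 1.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n < 2:
        raise DataError("need >= 2 observations to build a graph")
    k_eff = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(coords)
    dist, idx = nn.kneighbors(coords)
    d_max = dist.max()
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for i in range(n):
        for d, j in zip(dist[i], idx[i]):
            if j == i:  # with duplicate points "self" need not be column 0
                continue
            if weight_scheme == "relative":
                w = 1.0 - d / d_max if d_max > 0 else 1.0
            elif weight_scheme == "absolute":
                w = d_max - d
            else:
                raise DataError(f"unknown weight scheme {weight_scheme!r}")
            graph.add_edge(i, int(j), weight=float(w))
    return graph


def cluster_embedding(
    coords: np.ndarray, k: int = 1000, seed: int = 0, resolution: float = 1.0,
    weight_scheme: str = "relative",
) -> np.ndarray:
    """Louvain community labels (1..C) of the kNN graph over the embedding."""
    graph = knn_graph(coords, k=k, weight_scheme=weight_scheme)
    communities = nx.community.louvain_communities(
        graph, weight="weight", resolution=resolution, seed=seed
    )
    communities = sorted(communities, key=min)  # stable label order
    labels = np.empty(len(coords), dtype=int)
    for c, members in enumerate(communities, start=1):
        labels[list(members)] = c
    return labels


def rank_normalize(values) -> np.ndarray:
    """Average ranks scaled to (0, 1]; ties share their mean rank."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DataError("rank_normalize needs >= 1 value")
    return rankdata(values, method="average") / len(values)


def cluster_profiles(
    labels: np.ndarray, fm: FeatureMatrix, enrich_on: tuple[str, ...] = ("time_h", "regimen")
) -> tuple[pd.DataFrame, pd.DataFrame, int]:
    """Characterize clusters by mean rank-normalized features and enrichment.

    Enrichment of a metadata level within a cluster is the within-cluster
    fraction divided by the overall fraction (1 = no enrichment). Returns
    ``(profiles, enrichment, baseline_cluster)`` where the baseline cluster
    maximizes enrichment of the earliest timepoint.
    """
    labels = np.asarray(labels)
    if len(labels) != len(fm.meta):
        raise DataError("labels and feature matrix are not aligned")
    ranked = np.column_stack([rank_normalize(fm.X[:, j]) for j in range(fm.X.shape[1])])
    prof = pd.DataFrame(ranked, columns=fm.features).assign(cluster=labels)
    profiles = prof.groupby("cluster").mean()
    profiles["n"] = pd.Series(labels).value_counts().sort_index()

    records = []
    for col in enrich_on:
        if col not in fm.meta.columns:
            continue
        overall = fm.meta[col].value_counts(normalize=True)
        for cluster in np.unique(labels):
            within = fm.meta.loc[labels == cluster, col].value_counts(normalize=True)
            for level, frac_overall in overall.items():
                records.append({
                    "cluster": int(cluster), "variable": col, "level": level,
                    "enrichment": within.get(level, 0.0) / frac_overall,
                })
    enrichment = pd.DataFrame(records)

    t0 = fm.meta["time_h"].min()
    base = enrichment[
        (enrichment["variable"] == "time_h") & (enrichment["level"] == t0)
    ].set_index("cluster")["enrichment"]
    baseline_cluster = int(base.idxmax())
    return profiles.reset_index(), enrichment, baseline_cluster


@dataclass
class EmbeddingModel:
    """End-to-end heterogeneity map of one organoid population."""

    feature_matrix: FeatureMatrix
    pc_table: pd.DataFrame
    pc_scores: np.ndarray
    perplexity: float
    coords: np.ndarray
    knn_k: int
    labels: np.ndarray
    profiles: pd.DataFrame
    enrichment: pd.DataFrame
    baseline_cluster: int
    seed: int


def map_heterogeneity(
    states: pd.DataFrame, seed: int = 0, n_perm: int = 1000, alpha: float = 0.05,
    knn_k: int = 1000, resolution: float = 1.0,
) -> EmbeddingModel:
    """Full map: features → informative PCs → t-SNE → Louvain → profiles.

    If the permutation test retains no PC (pure-noise data), all
    standardized features are embedded instead so the pipeline stays total.
    """
    fm = build_feature_matrix(states)
    pc_scores, pc_table = select_informative_pcs(fm.X, n_perm=n_perm, alpha=alpha, seed=seed)
    if pc_scores.shape[1] == 0:
        logger.warning("no informative PCs; embedding all standardized features")
        pc_scores = fm.X
    perplexity, _ = tsne_perplexity(len(pc_scores))
    coords = embed_tsne(pc_scores, seed=seed, perplexity=perplexity)
    labels = cluster_embedding(coords, k=knn_k, seed=seed, resolution=resolution)
    profiles, enrichment, baseline_cluster = cluster_profiles(labels, fm)
    return EmbeddingModel(
        feature_matrix=fm, pc_table=pc_table, pc_scores=pc_scores,
        perplexity=perplexity, coords=coords, knn_k=min(knn_k, len(coords) - 1),
        labels=labels, profiles=profiles, enrichment=enrichment,
        baseline_cluster=baseline_cluster, seed=seed,
    )
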