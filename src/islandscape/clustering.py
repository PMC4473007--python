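"""k-means clustering of promoter enrichment patterns.

Rows are per-million-scaled promoter profiles (no per-row standardization:
the absolute enrichment magnitude is the signal that separates silent genes
from marked ones).  Lloyd iterations with Euclidean distance and k-means++
seeding, best of ``n_restarts`` by inertia; deterministic for a fixed seed.
Cluster labels are relabelled 1..k by decreasing centroid mean signal, so the
flat/low-signal cluster is always the highest-numbered label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterResult:
    k: int
    assignments: pd.Series  # gene_id -> label in 1..k
    centroids: pd.DataFrame  # index 1..k, columns = matrix bins
    inertia: float
    expression_summary: pd.DataFrame | None = None


def cluster_promoters(
    matrix: ProfileMatrix, k: int, seed: int = 0, n_restarts: int = 10
) -> ClusterResult:
    """Cluster the promoter matrix into k enrichment-pattern classes."""
    X = matrix.scaled()
    if X.empty:
        raise ValueError("promoter matrix is empty")
    if k < 2:
        raise ValueError("k must be at least 2")
    if k > len(X):
        raise ValueError(f"k = {k} exceeds the number of genes ({len(X)})")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    raw_labels = km.fit_predict(X.to_numpy())
    # stable relabelling: 1..k by decreasing centroid mean signal
    order = np.argsort(-km.cluster_centers_.mean(axis=1), kind="stable")
    relabel = {int(old): new + 1 for new, old in enumerate(order)}
    labels = pd.Series(
        [relabel[int(l)] for l in raw_labels], index=X.index, name="cluster"
    )
    centroids = pd.DataFrame(
        km.cluster_centers_[order], index=range(1, k + 1), columns=X.columns
    )
    centroids.index.name = "cluster"
    return ClusterResult(
        k=k, assignments=labels, centroids=centroids, inertia=float(km.inertia_)
    )


def expression_by_cluster(result: ClusterResult, expression: pd.Series) -> pd.DataFrame:
    """Five-number expression summary per cluster (log2 units)."""
    expr = expression.reindex(result.assignments.index)
    df = pd.DataFrame({"cluster": result.assignments, "value": expr}).dropna()
    out = (
        df.groupby("cluster")["value"]
        .agg(
            n="count",
            min="min",
            q1=lambda v: v.quantile(0.25),
            median="median",
            q3=lambda v: v.quantile(0.75),
            max="max",
        )
        .reset_index()
    )
    return out


def sort_and_render(
    matrix: ProfileMatrix, result: ClusterResult, expression: pd.Series
) -> tuple[pd.DataFrame, list[int], pd.DataFrame]:
    """Heatmap-ready sorted matrix plus per-cluster expression summaries.

    Rows are grouped by cluster (1..k) and, within each cluster, sorted by
    descending expression.  Genes lacking an expression value are dropped
    with a warning.  Returns (sorted per-million matrix, cluster boundary row
    offsets, expression summary table).
    """
    expr = expression.reindex(result.assignments.index)
    missing = expr.isna()
    if missing.any():
        logger.warning(
            "%d genes lack expression values and are dropped from rendering",
            int(missing.sum()),
        )
    keep = expr.index[~missing]
    order_df = pd.DataFrame(
        {"cluster": result.assignments.loc[keep], "expr": expr.loc[keep]}
    )
    order_df = order_df.sort_values(
        ["cluster", "expr"], ascending=[True, False], kind="mergesort"
    )
    sorted_matrix = matrix.scaled().loc[order_df.index]
    boundaries = np.cumsum(order_df["cluster"].value_counts().sort_index().to_numpy())[:-1]
    summary = expression_by_cluster(result, expression)
    return sorted_matrix, [int(b) for b in boundaries], summary


def plot_heatmap(
    sorted_matrix: pd.DataFrame, boundaries: list[int], path: str, vmax_quantile: float = 0.98
) -> None:
    """Write a PNG heatmap of the sorted promoter matrix with cluster separators."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = sorted_matrix.to_numpy()
    vmax = np.quantile(data, vmax_quantile) if data.size else 1.0
    fig, ax = plt.subplots(figsize=(5, 8))
    ax.imshow(data, aspect="auto", cmap="Reds", vmin=0, vmax=max(vmax, 1e-9),
              interpolation="nearest")
    for b in boundaries:
        ax.axhline(b - 0.5, color="black", lw=0.8)
    ax.set_xlabel("position bin (5' -> 3')")
    ax.set_ylabel("genes (clustered, expression-sorted)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
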