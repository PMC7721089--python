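"""Cluster-number selection and k-means subtype assignment.

The number of modification patterns is chosen by a majority vote of
four internal validity indices evaluated over a range of k (default
2..15, mirroring the published consensus-over-indices approach):
silhouette, Calinski-Harabasz and the gap statistic vote for their
maximizing k, Davies-Bouldin for its minimizing k; ties go to the
smaller k. K-means itself is Lloyd's algorithm with ``nstart`` random
restarts (default 25, keeping the published setting), and the returned
labels are renumbered so that cluster 1 has the lowest mean feature
value and cluster k the highest — giving the C1 = low-regulator,
C3 = high-regulator semantics used throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_score,
)

from .io import ExpressionMatrix
from .panel import RegulatorPanel, clustering_panel, restrict_to_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "ClusteringConfig",
    "ClusterAssignment",
    "select_k",
    "kmeans_cluster",
    "m6a_clusters",
    "pca_view",
]

DEFAULT_INDICES = ("silhouette", "calinski_harabasz", "davies_bouldin", "gap")


@dataclass(frozen=True)
class ClusteringConfig:
    k_min: int = 2
    k_max: int = 15
    nstart: int = 25
    indices: tuple[str, ...] = DEFAULT_INDICES
    gap_b: int = 10
    seed: int = 0
    k: int | None = None  # force a cluster count, skipping selection

    def __post_init__(self) -> None:
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.nstart < 1:
            raise ValueError("nstart must be >= 1")
        unknown = set(self.indices) - set(DEFAULT_INDICES)
        if unknown:
            raise ValueError(f"unknown selection indices: {sorted(unknown)}")


@dataclass
class ClusterAssignment:
    """Per-sample cluster labels (1..k, ordered low to high mean)."""

    sample_ids: list[str]
    labels: np.ndarray
    k: int
    centers: np.ndarray
    seed: int
    selection_report: pd.DataFrame | None = None
    inertia: float = float("nan")

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("labels and sample_ids differ in length")
        present = set(np.unique(self.labels))
        if not present <= set(range(1, self.k + 1)):
            raise ValueError("labels must lie in 1..k")

    def as_series(self, name: str = "cluster") -> pd.Series:
        return pd.Series(
            self.labels, index=pd.Index(self.sample_ids, name="sample_id"),
            name=name,
        )

    def to_tsv(self, path) -> None:
        self.as_series("m6Acluster").to_frame().to_csv(path, sep="\t")


def _wcss(data: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = data[labels == lab]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return float(total)


def _gap_statistic(
    data: np.ndarray, k: int, nstart: int, b: int, rng: np.random.Generator
) -> float:
    """Tibshirani gap: E*[log W_ref] - log W_data, uniform-box reference."""
    km = KMeans(n_clusters=k, n_init=nstart,
                random_state=int(rng.integers(2**31 - 1)))
    labels = km.fit_predict(data)
    log_w = np.log(max(_wcss(data, labels), np.finfo(float).tiny))
    lo, hi = data.min(axis=0), data.max(axis=0)
    ref_log_w = []
    for _ in range(b):
        ref = rng.uniform(lo, hi, size=data.shape)
        ref_labels = KMeans(
            n_clusters=k, n_init=1, random_state=int(rng.integers(2**31 - 1))
        ).fit_predict(ref)
        ref_log_w.append(np.log(max(_wcss(ref, ref_labels), np.finfo(float).tiny)))
    return float(np.mean(ref_log_w) - log_w)


def select_k(
    data: np.ndarray | pd.DataFrame,
    k_min: int = 2,
    k_max: int = 15,
    indices: tuple[str, ...] = DEFAULT_INDICES,
    nstart: int = 25,
    gap_b: int = 10,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Choose the cluster count by majority vote over validity indices.

    ``data`` is samples x features. Each index votes for its optimal k
    over ``[k_min, k_max]`` (capped at n_samples - 1); the majority
    wins, ties broken toward the smaller k. Returns ``(k_best,
    report)`` where the report holds every index value at every k plus
    the per-index votes.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] < 1:
        raise ValueError("data must be a 2-D samples x features array")
    if np.allclose(data, data[0]):
        raise ValueError("degenerate data: all samples identical")
    n = data.shape[0]
    k_max = min(k_max, n - 1)
    if n < k_max + 1:
        raise ValueError("need at least k_max + 1 samples")
    rng = np.random.default_rng(seed)
    ks = list(range(k_min, k_max + 1))
    table = {name: [] for name in indices}
    for k in ks:
        km = KMeans(n_clusters=k, n_init=nstart,
                    random_state=int(rng.integers(2**31 - 1)))
        labels = km.fit_predict(data)
        if len(np.unique(labels)) < 2:
            for name in indices:
                table[name].append(np.nan)
            continue
        for name in indices:
            if name == "silhouette":
                table[name].append(silhouette_score(data, labels))
            elif name == "calinski_harabasz":
                table[name].append(calinski_harabasz_score(data, labels))
            elif name == "davies_bouldin":
                table[name].append(davies_bouldin_score(data, labels))
            elif name == "gap":
                table[name].append(_gap_statistic(data, k, nstart, gap_b, rng))
    report = pd.DataFrame(table, index=pd.Index(ks, name="k"))
    votes = {}
    for name in indices:
        col = report[name]
        if name == "davies_bouldin":
            votes[name] = int(col.idxmin())
        else:
            votes[name] = int(col.idxmax())
    counts = pd.Series(votes).value_counts()
    best = counts[counts == counts.max()].index.min()  # tie -> smaller k
    report.attrs["votes"] = votes
    report.attrs["k_best"] = int(best)
    return int(best), report


def kmeans_cluster(
    data: np.ndarray | pd.DataFrame,
    k: int,
    nstart: int = 25,
    seed: int = 0,
) -> ClusterAssignment:
    """Best-of-``nstart`` Lloyd k-means with mean-ordered labels.

    Labels are renumbered so cluster 1 has the lowest mean feature
    value (averaged over the cluster center) and cluster k the
    highest; negating the features therefore reverses the label order.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if isinstance(data, pd.DataFrame):
        sample_ids = list(data.index.astype(str))
        values = data.to_numpy(dtype=float)
    else:
        values = np.asarray(data, dtype=float)
        sample_ids = [f"sample_{i}" for i in range(values.shape[0])]
    if values.shape[0] <= k:
        raise ValueError("need more samples than clusters")
    km = KMeans(n_clusters=k, n_init=nstart, random_state=seed,
                algorithm="lloyd", tol=1e-6, max_iter=300)
    raw = km.fit_predict(values)
    centers = km.cluster_centers_
    order = np.argsort(centers.mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw]
    return ClusterAssignment(
        sample_ids=sample_ids,
        labels=labels,
        k=k,
        centers=centers[order],
        seed=seed,
        inertia=float(km.inertia_),
    )


def m6a_clusters(
    expr: ExpressionMatrix,
    panel: RegulatorPanel | None = None,
    config: ClusteringConfig | None = None,
) -> tuple[ClusterAssignment, pd.DataFrame]:
    """Assign m6A modification-pattern clusters from regulator expression.

    Restricts the matrix to the 20-gene clustering panel (IGF2BPs
    removed), standardizes each gene to mean 0 / SD 1 (dropping
    zero-variance genes with a warning), selects k by the index vote
    and runs k-means. Returns the assignment and the per-cluster mean
    expression table of the panel genes (on the original scale).
    """
    if config is None:
        config = ClusteringConfig()
    cpanel = clustering_panel(panel) if panel is not None else clustering_panel()
    sub_panel, _missing = restrict_to_matrix(cpanel, expr)
    if len(sub_panel) < 5:
        raise ValueError(
            f"only {len(sub_panel)} panel genes measured; need at least 5"
        )
    block = expr.data.loc[sub_panel.genes]
    sds = block.std(axis=1, ddof=0)
    constant = sds[sds == 0.0].index.tolist()
    if constant:
        warnings.warn(
            f"dropping constant-expression panel genes: {constant}",
            UserWarning, stacklevel=2,
        )
        block = block.drop(index=constant)
        sds = sds.drop(index=constant)
    standardized = block.sub(block.mean(axis=1), axis=0).div(sds, axis=0)
    samples_by_genes = standardized.T
    if config.k is not None:
        k_best, report = config.k, None
    else:
        k_best, report = select_k(
            samples_by_genes, config.k_min, config.k_max,
            indices=config.indices, nstart=config.nstart,
            gap_b=config.gap_b, seed=config.seed,
        )
    assignment = kmeans_cluster(
        samples_by_genes, k_best, nstart=config.nstart, seed=config.seed
    )
    assignment.selection_report = report
    cluster_means = block.T.groupby(assignment.as_series()).mean().T
    cluster_means.columns = [f"C{c}" for c in cluster_means.columns]
    return assignment, cluster_means


def pca_view(
    data: np.ndarray | pd.DataFrame, labels: np.ndarray
) -> tuple[pd.DataFrame, float]:
    """Two-component PCA coordinates and cluster separation ratio.

    The ratio is between-cluster variance over total variance in the
    2-D projection (0 for identical points, approaching 1 for fully
    separated clusters).
    """
    if isinstance(data, pd.DataFrame):
        index = data.index
        values = data.to_numpy(dtype=float)
    else:
        values = np.asarray(data, dtype=float)
        index = pd.RangeIndex(values.shape[0])
    if values.shape[1] < 2:
        raise ValueError("pca_view needs at least 2 features")
    labels = np.asarray(labels)
    centered = values - values.mean(axis=0)
    if np.allclose(centered, 0.0):
        coords = np.zeros((values.shape[0], 2))
    else:
        coords = PCA(n_components=2, random_state=0).fit_transform(values)
    total = ((coords - coords.mean(axis=0)) ** 2).sum()
    if total == 0.0:
        ratio = 0.0
    else:
        between = 0.0
        grand = coords.mean(axis=0)
        for lab in np.unique(labels):
            pts = coords[labels == lab]
            between += len(pts) * ((pts.mean(axis=0) - grand) ** 2).sum()
        ratio = float(between / total)
    frame = pd.DataFrame(coords, index=index, columns=["PC1", "PC2"])
    frame["cluster"] = labels
    return frame, ratio
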