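"""Metabolic subtyping from pathway enrichment scores.

Samples are clustered on their enrichment scores for the metabolic
pathway panel (same k selection and k-means procedure as the
modification-pattern clustering). The most altered metabolic category
is found by comparing cluster centroids: for each category the mean
pairwise Euclidean distance between cluster centroids, restricted to
that category's pathways and normalized by the square root of the
pathway count, makes categories of different sizes comparable.

With three clusters the groups are named by their mean lipid-pathway
enrichment: LML (lipid metabolism low), LMI (intermediate), LMH
(high). In the HCC setting the LML group is the one with the highest
m6A regulator expression and the poorest survival.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .clustering import ClusterAssignment, ClusteringConfig, kmeans_cluster, select_k
from .gsva import EnrichmentScores

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolicSubtypes",
    "metabolic_clusters",
    "category_distance",
    "lipid_labels",
]

LIPID_CATEGORY = "lipid"


@dataclass
class MetabolicSubtypes:
    labels: pd.Series  # sample_id -> LML/LMI/LMH (or L1..Lk fallback)
    assignment: ClusterAssignment
    category_distances: pd.DataFrame | None
    category_map: dict[str, str]
    cluster_lipid_means: pd.Series | None = None

    def to_tsv(self, path) -> None:
        self.labels.rename("metabolic_subgroup").to_frame().to_csv(path, sep="\t")


def metabolic_clusters(
    scores: EnrichmentScores, config: ClusteringConfig | None = None
) -> ClusterAssignment:
    """Cluster samples on the pathway-score matrix (samples x sets)."""
    if config is None:
        config = ClusteringConfig()
    if len(scores.set_names) < 2:
        raise ValueError("need at least 2 gene sets to cluster on")
    data = scores.values.T  # samples x sets
    if config.k is not None:
        k_best, report = config.k, None
    else:
        k_best, report = select_k(
            data, config.k_min, config.k_max, indices=config.indices,
            nstart=config.nstart, gap_b=config.gap_b, seed=config.seed,
        )
    assignment = kmeans_cluster(data, k_best, nstart=config.nstart,
                                seed=config.seed)
    assignment.selection_report = report
    return assignment


def category_distance(
    scores: EnrichmentScores,
    assignment: ClusterAssignment,
    category_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Between-cluster centroid separation per metabolic category.

    For category c: mean Euclidean distance between cluster centroids
    over c's pathways, divided by sqrt(#pathways in c) so that adding
    redundant pathways leaves the measure unchanged. Sorted descending
    (the top row is the most altered category). Empty categories are
    skipped with a warning.
    """
    if category_map is None:
        category_map = {}
    labels = assignment.as_series()
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    values = scores.values.loc[:, labels.index]
    categories = sorted({category_map.get(n) for n in scores.set_names
                         if category_map.get(n) is not None})
    rows = []
    for cat in categories:
        members = [n for n in scores.set_names if category_map.get(n) == cat]
        if not members:
            warnings.warn(f"category {cat!r} has no scored set; skipped",
                          UserWarning, stacklevel=2)
            continue
        block = values.loc[members]
        centroids = block.T.groupby(labels).mean()  # clusters x sets
        dists = [
            float(np.linalg.norm(centroids.loc[a] - centroids.loc[b]))
            for a, b in combinations(clusters, 2)
        ]
        rows.append((cat, np.mean(dists) / np.sqrt(len(members)), len(members)))
    out = pd.DataFrame(rows, columns=["category", "distance", "n_sets"])
    return out.sort_values("distance", ascending=False).reset_index(drop=True)


def lipid_labels(
    scores: EnrichmentScores,
    assignment: ClusterAssignment,
    category_map: dict[str, str],
) -> MetabolicSubtypes:
    """Name the clusters by their mean lipid-pathway enrichment.

    Lowest mean lipid score -> LML, middle -> LMI, highest -> LMH.
    Requires exactly 3 clusters; otherwise generic L1..Lk labels are
    returned with a warning. Ties in the lipid mean are broken by
    cluster size (larger cluster gets the lower label), logged.
    """
    labels = assignment.as_series()
    clusters = sorted(labels.unique())
    lipid_sets = [n for n in scores.set_names
                  if category_map.get(n) == LIPID_CATEGORY]
    if not lipid_sets:
        raise ValueError("no lipid-category set among the scored sets")
    lipid_block = scores.values.loc[lipid_sets, labels.index]
    cluster_means = lipid_block.mean(axis=0).groupby(labels).mean()
    distances = category_distance(scores, assignment, category_map)
    if len(clusters) != 3:
        warnings.warn(
            f"{len(clusters)} clusters: using generic L1..Lk labels instead "
            "of LML/LMI/LMH", UserWarning, stacklevel=2,
        )
        name_of = {c: f"L{c}" for c in clusters}
    else:
        sizes = labels.value_counts()
        if cluster_means.duplicated().any():
            logger.info("tied lipid means; breaking ties by cluster size")
        order = sorted(
            clusters, key=lambda c: (cluster_means.loc[c], sizes.loc[c])
        )
        name_of = dict(zip(order, ("LML", "LMI", "LMH")))
    named = labels.map(name_of).rename("metabolic_subgroup")
    return MetabolicSubtypes(
        labels=named,
        assignment=assignment,
        category_distances=distances,
        category_map=dict(category_map),
        cluster_lipid_means=cluster_means,
    )
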