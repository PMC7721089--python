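"""Single-sample gene-set enrichment scoring (GSVA-style).

The statistic follows the gene set variation analysis recipe: each
gene's expression is first replaced by an estimate of its cumulative
density across samples (Gaussian-kernel CDF with bandwidth sd/4, or the
empirical CDF), genes are then ranked within each sample, and a random
walk over the ranked gene list accumulates weighted increments for
in-set genes against constant decrements for out-of-set genes. The
default score is the signed sum of the maximum positive and minimum
negative walk deviations, which is bounded in [-1, 1]; a "max
deviation" mode returning the single largest-magnitude deviation is
also available.

Ties in the per-sample ranking are broken by gene-symbol lexicographic
order so that scores are bit-reproducible across platforms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .io import ExpressionMatrix, GeneSetCollection

__all__ = [
    "GsvaParams",
    "EnrichmentScores",
    "density_transform",
    "sample_ranks",
    "rank_statistic",
    "walk_statistic",
    "gsva_scores",
]


@dataclass(frozen=True)
class GsvaParams:
    kernel: str = "gaussian"  # or "ecdf"
    tau: float = 1.0
    mode: str = "diff_of_maxima"  # or "max_deviation"
    min_set_size: int = 5
    max_set_size: int = 500

    def __post_init__(self) -> None:
        if self.kernel not in ("gaussian", "ecdf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.mode not in ("diff_of_maxima", "max_deviation"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 < self.min_set_size <= self.max_set_size:
            raise ValueError("need 0 < min_set_size <= max_set_size")


@dataclass
class EnrichmentScores:
    """Gene sets x samples score matrix plus the parameters that made it."""

    values: pd.DataFrame
    params: GsvaParams
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def set_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def skipped_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"set_name": list(self.skipped), "reason": list(self.skipped.values())}
        )


def density_transform(expr: ExpressionMatrix, kernel: str = "gaussian") -> pd.DataFrame:
    """Replace each value by its estimated cumulative density across samples.

    Gaussian kernel: ``t_ij = mean_l Phi((x_ij - x_il) / h_i)`` with
    per-gene bandwidth ``h_i = sd_i / 4`` (floored at machine epsilon,
    so constant genes map to 0.5 everywhere). ECDF: fraction of samples
    with value <= x_ij. Both are strictly monotone within a gene, so
    sample ordering is preserved.
    """
    x = expr.data.to_numpy(dtype=float)
    n_genes, n_samples = x.shape
    if n_samples < 3:
        raise ValueError("density_transform needs at least 3 samples")
    if kernel == "ecdf":
        out = (x[:, :, None] >= x[:, None, :]).mean(axis=2)
    elif kernel == "gaussian":
        sd = x.std(axis=1, ddof=1)
        h = np.maximum(sd / 4.0, np.finfo(float).eps)
        out = np.empty_like(x)
        chunk = max(1, int(2e7 // (n_samples * n_samples)))
        for start in range(0, n_genes, chunk):
            stop = min(start + chunk, n_genes)
            diffs = (x[start:stop, :, None] - x[start:stop, None, :]) / h[
                start:stop, None, None
            ]
            out[start:stop] = ndtr(diffs).mean(axis=2)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return pd.DataFrame(out, index=expr.data.index, columns=expr.data.columns)


def sample_ranks(transformed: pd.DataFrame) -> pd.DataFrame:
    """Rank genes within each sample, descending by transformed value.

    Rank 1 is the highest value; ties go to the lexicographically
    smaller gene symbol. Returns an integer matrix of the same shape.
    """
    values = transformed.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("sample_ranks requires finite values")
    genes = np.asarray(transformed.index.astype(str))
    lex = np.argsort(genes, kind="stable")  # secondary key
    n_genes = len(genes)
    ranks = np.empty_like(values, dtype=np.int64)
    for j in range(values.shape[1]):
        col = values[lex, j]
        order = lex[np.argsort(-col, kind="stable")]
        ranks[order, j] = np.arange(1, n_genes + 1)
    return pd.DataFrame(
        ranks, index=transformed.index, columns=transformed.columns
    )


def rank_statistic(ranks: pd.DataFrame | pd.Series) -> pd.DataFrame | pd.Series:
    """Symmetric rank statistic ``r = |G|/2 - rank + 1/2``.

    Sums to zero over all genes; the top-ranked gene gets the largest
    positive value and the bottom-ranked the most negative.
    """
    n_genes = ranks.shape[0]
    return n_genes / 2.0 - ranks + 0.5


def walk_statistic(
    sample_rank_vector: pd.Series,
    gene_set,
    tau: float = 1.0,
    mode: str = "diff_of_maxima",
) -> float:
    """Random-walk enrichment score of one gene set in one sample.

    Walk the genes in rank order; an in-set gene adds its ``|r|^tau``
    weight (normalized by the in-set total), an out-of-set gene
    subtracts ``1 / (|G| - |set|)``. ``diff_of_maxima`` returns the
    signed sum of the maximum positive and minimum negative deviation;
    ``max_deviation`` the single deviation of largest magnitude.
    """
    genes = sample_rank_vector.index
    in_set = genes.isin(set(gene_set))
    m = int(in_set.sum())
    if m == 0:
        raise ValueError("gene set has no member among the ranked genes")
    n_genes = len(genes)
    if m == n_genes:
        raise ValueError("gene set covers every gene; walk undefined")
    ranks = sample_rank_vector.to_numpy(dtype=float)
    order = np.argsort(ranks, kind="stable")  # rank 1 first
    in_ordered = in_set[order]
    r = np.abs(n_genes / 2.0 - ranks[order] + 0.5) ** tau
    total_w = r[in_ordered].sum()
    if total_w == 0.0:  # set carries only zero-weight (mid-rank) genes
        weights = in_ordered / m
    else:
        weights = np.where(in_ordered, r / total_w, 0.0)
    step = np.where(in_ordered, weights, -1.0 / (n_genes - m))
    dev = np.cumsum(step)
    pos = max(dev.max(), 0.0)
    neg = min(dev.min(), 0.0)
    if mode == "diff_of_maxima":
        return float(pos + neg)
    if mode == "max_deviation":
        return float(pos if pos >= -neg else neg)  # magnitude tie -> positive
    raise ValueError(f"unknown mode {mode!r}")


def _score_set_vectorized(
    order_idx: np.ndarray,
    absr_ordered: np.ndarray,
    member_mask: np.ndarray,
    mode: str,
) -> np.ndarray:
    """Walk scores for one set across all samples at once."""
    n_genes, n_samples = order_idx.shape
    in_ordered = member_mask[order_idx]  # genes x samples, walk order
    m = int(member_mask.sum())
    pos_w = absr_ordered * in_ordered
    pos_tot = pos_w.sum(axis=0)
    degenerate = pos_tot == 0.0  # set carries only zero-weight genes
    if degenerate.any():
        pos_w[:, degenerate] = in_ordered[:, degenerate] / m
        pos_tot = pos_w.sum(axis=0)
    step = pos_w / pos_tot - (~in_ordered) / (n_genes - m)
    dev = np.cumsum(step, axis=0)
    pos = np.maximum(dev.max(axis=0), 0.0)
    neg = np.minimum(dev.min(axis=0), 0.0)
    if mode == "diff_of_maxima":
        return pos + neg
    return np.where(pos >= -neg, pos, neg)  # magnitude tie -> positive


def gsva_scores(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    params: GsvaParams | None = None,
) -> EnrichmentScores:
    """Full enrichment pipeline: density transform, ranking, walks.

    Sets whose intersection with the measured genes falls outside
    ``[min_set_size, max_set_size]`` are skipped with a warning and
    listed in the result's skipped-set report. Raises if every set is
    skipped.
    """
    if params is None:
        params = GsvaParams()
    transformed = density_transform(expr, kernel=params.kernel)
    ranks = sample_ranks(transformed)
    rank_values = ranks.to_numpy(dtype=np.int64)
    n_genes, n_samples = rank_values.shape
    order_idx = np.argsort(rank_values, axis=0, kind="stable")
    absr = np.abs(n_genes / 2.0 - rank_values + 0.5) ** params.tau
    absr_ordered = np.take_along_axis(absr, order_idx, axis=0)
    gene_index = {g: i for i, g in enumerate(expr.genes)}

    rows = {}
    skipped: dict[str, str] = {}
    for name, members in sets.sets.items():
        idx = [gene_index[g] for g in members if g in gene_index]
        if len(idx) < params.min_set_size or len(idx) > params.max_set_size:
            reason = (
                f"{len(idx)} measured members outside "
                f"[{params.min_set_size}, {params.max_set_size}]"
            )
            warnings.warn(f"skipping set {name!r}: {reason}", UserWarning,
                          stacklevel=2)
            skipped[name] = reason
            continue
        mask = np.zeros(n_genes, dtype=bool)
        mask[idx] = True
        rows[name] = _score_set_vectorized(
            order_idx, absr_ordered, mask, params.mode
        )
    if not rows:
        raise ValueError("all gene sets were skipped; no scores computed")
    values = pd.DataFrame.from_dict(rows, orient="index", columns=expr.samples)
    values.index.name = "set_name"
    return EnrichmentScores(values=values, params=params, skipped=skipped)
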