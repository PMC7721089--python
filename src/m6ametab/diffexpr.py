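"""Moderated differential expression between modification patterns.

Implements the empirical-Bayes moderated t-test for log-scale
expression: per-gene pooled variances are shrunk toward a prior
variance whose scale ``s0^2`` and degrees of freedom ``d0`` are
estimated from the marginal distribution of the observed variances by
moment matching on ``log s_g^2`` (mean via the digamma function,
spread via the trigamma function). The moderated statistic

    t_g = log2FC_g / (s~_g * sqrt(1/nA + 1/nB)),
    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

is referred to a t distribution with ``d0 + d_g`` degrees of freedom.
As ``d0 -> 0`` this reduces to the ordinary two-sample t-test; as
``d0 -> inf`` all genes share one variance.

DEGs between k > 2 patterns default to the union of all pairwise
contrasts, each BH-adjusted separately; a one-vs-rest mode is also
provided. The published filter is adjusted p < 0.05 with
|log2 fold change| strictly greater than 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

from .clustering import ClusterAssignment
from .io import ExpressionMatrix

__all__ = ["DEGTable", "moderated_test", "bh_adjust", "cluster_degs"]


@dataclass
class DEGTable:
    """Per-gene, per-contrast moderated-test results with pass flags."""

    table: pd.DataFrame  # columns: gene, contrast, log2_fc, t_mod, p, p_adj, passes
    alpha: float
    fc_min: float

    def passing_genes(self) -> list[str]:
        hits = self.table.loc[self.table["passes"], "gene"]
        return sorted(set(hits))


def _fit_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from observed gene variances.

    Under the hierarchical model, e_g = log s_g^2 has
    E[e] = log s0^2 + digamma(d_g/2) - log(d_g/2)
           - (digamma(d0/2) - log(d0/2))
    Var[e] = trigamma(d_g/2) + trigamma(d0/2).
    Solve the variance equation for d0 by inverting the trigamma
    function, then back out s0^2 from the mean.
    """
    s2 = np.maximum(s2, np.finfo(float).tiny)
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 1e-10:
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(e)))
        return d0, s0_sq

    def objective(log_half_d0: float) -> float:
        return float(special.polygamma(1, np.exp(log_half_d0)) - e_var)

    sol = optimize.brentq(objective, -20.0, 20.0)
    half_d0 = float(np.exp(sol))
    d0 = 2.0 * half_d0
    s0_sq = float(np.exp(np.mean(e) + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def moderated_test(
    expr_a: pd.DataFrame | np.ndarray,
    expr_b: pd.DataFrame | np.ndarray,
    d0_override: float | None = None,
) -> pd.DataFrame:
    """Empirical-Bayes moderated two-group test on log2 expression.

    ``expr_a`` and ``expr_b`` are genes x samples blocks with aligned
    gene rows. Returns a frame with ``log2_fc`` (mean A - mean B),
    ``t_mod``, ``p``, the shrunk standard deviation and the prior
    parameters in ``attrs``. ``d0_override`` fixes the prior degrees
    of freedom (0 recovers the ordinary t-test).
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("gene rows of the two groups are not aligned")
    n_a, n_b = a.shape[1], b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 samples")
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2_fc = mean_a - mean_b
    df_resid = n_a + n_b - 2
    ss = ((a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    if d0_override is None:
        d0, s0_sq = _fit_prior(s2, df_resid)
    else:
        d0 = float(d0_override)
        s0_sq = float(np.exp(np.mean(np.log(np.maximum(s2, 1e-300))))) if d0 > 0 else 0.0
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_tilde * (1.0 / n_a + 1.0 / n_b))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(se > 0, log2_fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    index = (
        expr_a.index
        if isinstance(expr_a, pd.DataFrame)
        else pd.RangeIndex(a.shape[0])
    )
    out = pd.DataFrame(
        {"log2_fc": log2_fc, "t_mod": t_mod, "p": p, "s_tilde": np.sqrt(s2_tilde)},
        index=index,
    )
    out.attrs["d0"] = d0
    out.attrs["s0_sq"] = s0_sq
    out.attrs["df_resid"] = df_resid
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cluster_degs(
    expr: ExpressionMatrix,
    assignment: ClusterAssignment,
    alpha: float = 0.05,
    fc_min: float = 1.0,
    mode: str = "pairwise",
) -> tuple[DEGTable, list[str]]:
    """DEGs between modification-pattern clusters.

    ``mode="pairwise"`` tests every unordered cluster pair,
    ``mode="one_vs_rest"`` each cluster against all others; BH is
    applied within each contrast. The union gene list collects genes
    passing (adjusted p < alpha and |log2FC| > fc_min) in at least one
    contrast, deduplicated and sorted.
    """
    if mode not in ("pairwise", "one_vs_rest"):
        raise ValueError(f"unknown mode {mode!r}")
    labels = assignment.as_series()
    data = expr.data.loc[:, labels.index]
    clusters = sorted(labels.unique())
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters for differential expression")
    if mode == "pairwise":
        contrasts = [
            (f"C{a}_vs_C{b}", labels == a, labels == b)
            for i, a in enumerate(clusters)
            for b in clusters[i + 1:]
        ]
    else:
        contrasts = [
            (f"C{c}_vs_rest", labels == c, labels != c) for c in clusters
        ]
    frames = []
    for name, mask_a, mask_b in contrasts:
        if mask_a.sum() < 2 or mask_b.sum() < 2:
            warnings.warn(
                f"contrast {name}: a group has < 2 samples; skipped",
                UserWarning, stacklevel=2,
            )
            continue
        res = moderated_test(data.loc[:, mask_a.values], data.loc[:, mask_b.values])
        res = res.copy()
        res["p_adj"] = bh_adjust(res["p"].to_numpy())
        res["passes"] = (res["p_adj"] < alpha) & (res["log2_fc"].abs() > fc_min)
        res["contrast"] = name
        res["gene"] = res.index
        frames.append(res.reset_index(drop=True))
    if not frames:
        raise ValueError("no testable contrast (all clusters too small)")
    table = pd.concat(frames, ignore_index=True)[
        ["gene", "contrast", "log2_fc", "t_mod", "p", "p_adj", "passes"]
    ]
    deg_table = DEGTable(table=table, alpha=alpha, fc_min=fc_min)
    return deg_table, deg_table.passing_genes()
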