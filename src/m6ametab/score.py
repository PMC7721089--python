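"""The m6A gene signature and per-sample m6Ascore.

Candidate genes (typically the DEGs between modification-pattern
clusters) are screened one at a time with a univariate Cox
proportional-hazards model on overall survival. Genes with Wald
p < alpha form the signature and are split at hazard ratio 1: HR > 1
genes are *risk* genes, HR < 1 genes *protective*. Each signature
gene's expression is min-max scaled to [-1, 1] across the cohort and
the per-sample score is

    m6Ascore = sum_i X_i - sum_j Y_j

with X over scaled risk genes and Y over scaled protective genes, so
high scores mark samples expressing the hazardous part of the
signature. Cohorts are split at the median score into high and low
groups (median ties go to "low" for determinism).

The scaling bounds computed on the discovery cohort are frozen inside
the signature so that new cohorts can be scored against the same
reference frame.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .io import ClinicalTable, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CoxScreenTable",
    "SignaturePartition",
    "ScoreTable",
    "cox_screen",
    "signature_partition",
    "minmax_scale",
    "compute_m6ascore",
    "score_groups",
]


@dataclass
class CoxScreenTable:
    """Per-gene univariate Cox results: HR, SE, Wald p."""

    table: pd.DataFrame  # index gene; columns hr, log_hr, se, p, n_used
    excluded: dict[str, str] = field(default_factory=dict)


@dataclass
class SignaturePartition:
    """Signature genes split at HR = 1, with frozen scaling bounds."""

    risk_genes: list[str]
    protective_genes: list[str]
    alpha: float
    screen: CoxScreenTable | None = None
    scale_bounds: pd.DataFrame | None = None  # index gene; columns min, max

    def __post_init__(self) -> None:
        overlap = set(self.risk_genes) & set(self.protective_genes)
        if overlap:
            raise ValueError(f"genes in both partitions: {sorted(overlap)}")

    @property
    def genes(self) -> list[str]:
        return list(self.risk_genes) + list(self.protective_genes)

    def to_tsv(self, path) -> None:
        """Signature file fully determining the scoring of new cohorts."""
        rows = []
        screen = self.screen.table if self.screen is not None else None
        for side, genes in (("risk", self.risk_genes),
                            ("protective", self.protective_genes)):
            for g in genes:
                hr = p = np.nan
                if screen is not None and g in screen.index:
                    hr, p = screen.loc[g, "hr"], screen.loc[g, "p"]
                lo = hi = np.nan
                if self.scale_bounds is not None and g in self.scale_bounds.index:
                    lo = self.scale_bounds.loc[g, "min"]
                    hi = self.scale_bounds.loc[g, "max"]
                rows.append((g, side, hr, p, lo, hi))
        pd.DataFrame(
            rows, columns=["gene", "side", "hr", "p", "scale_min", "scale_max"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, alpha: float = 0.05) -> "SignaturePartition":
        df = pd.read_csv(path, sep="\t")
        bounds = df.set_index("gene")[["scale_min", "scale_max"]]
        bounds.columns = ["min", "max"]
        return cls(
            risk_genes=df.loc[df["side"] == "risk", "gene"].tolist(),
            protective_genes=df.loc[df["side"] == "protective", "gene"].tolist(),
            alpha=alpha,
            scale_bounds=bounds if bounds.notna().all().all() else None,
        )


@dataclass
class ScoreTable:
    """Per-sample m6Ascore, optional group labels and the scaled parts."""

    scores: pd.Series  # index sample_id
    groups: pd.Series | None = None  # "low"/"high"
    cutoff: float | None = None
    scaled_risk: pd.DataFrame | None = None
    scaled_protective: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.scores.rename("m6ascore").to_frame()
        if self.groups is not None:
            out["score_group"] = self.groups
        return out


def cox_screen(
    expr_subset: ExpressionMatrix,
    clinical: ClinicalTable,
    min_events: int = 10,
) -> CoxScreenTable:
    """Univariate Cox screen of each gene against overall survival.

    Each gene's unscaled log2 expression enters a proportional-hazards
    model as the sole covariate (Breslow tie handling). Zero-variance
    and non-converging genes are flagged and excluded.
    """
    shared = [s for s in expr_subset.samples if s in set(clinical.samples)]
    if not shared:
        raise ValueError("no shared samples between expression and clinical")
    surv = clinical.data.loc[shared, ["os_time", "os_event"]]
    n_events = int(surv["os_event"].sum())
    if n_events < min_events:
        raise ValueError(
            f"only {n_events} events; need >= {min_events} for the Cox screen"
        )
    data = expr_subset.data.loc[:, shared]
    rows = {}
    excluded: dict[str, str] = {}
    for gene in data.index:
        x = data.loc[gene]
        if float(x.std(ddof=0)) == 0.0:
            excluded[gene] = "zero variance"
            logger.warning("cox_screen: gene %s has zero variance; excluded", gene)
            continue
        frame = pd.DataFrame(
            {"os_time": surv["os_time"], "os_event": surv["os_event"], "x": x}
        )
        fitter = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter.fit(frame, duration_col="os_time", event_col="os_event")
        except Exception as exc:  # non-convergence, singular information
            excluded[gene] = f"fit failed: {exc}"
            logger.warning("cox_screen: gene %s excluded (%s)", gene, exc)
            continue
        summary = fitter.summary.loc["x"]
        rows[gene] = {
            "hr": float(np.exp(summary["coef"])),
            "log_hr": float(summary["coef"]),
            "se": float(summary["se(coef)"]),
            "p": float(summary["p"]),
            "n_used": len(frame),
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    return CoxScreenTable(table=table, excluded=excluded)


def signature_partition(
    screen: CoxScreenTable, alpha: float = 0.05
) -> SignaturePartition:
    """Keep genes with Wald p < alpha and split them at HR = 1."""
    table = screen.table
    if table.empty:
        raise ValueError("empty Cox screen table")
    significant = table[table["p"] < alpha]
    neutral = significant[significant["log_hr"].abs() < 1e-12].index.tolist()
    if neutral:
        warnings.warn(
            f"genes with HR exactly 1 excluded from the signature: {neutral}",
            UserWarning, stacklevel=2,
        )
        significant = significant.drop(index=neutral)
    risk = significant[significant["log_hr"] > 0].index.tolist()
    protective = significant[significant["log_hr"] < 0].index.tolist()
    if not risk and not protective:
        raise ValueError(
            "no gene passed the Cox screen; consider a larger cohort or a "
            "looser alpha"
        )
    return SignaturePartition(
        risk_genes=risk, protective_genes=protective, alpha=alpha, screen=screen
    )


def minmax_scale(
    expr_subset: pd.DataFrame, bounds: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene affine map onto [-1, 1]: x' = 2 (x - min)/(max - min) - 1.

    ``bounds`` (columns ``min``/``max``) lets new samples be scaled
    against a frozen signature; by default the bounds are taken from
    the data and returned alongside. Constant genes map to 0 with a
    warning. Values outside the frozen bounds are clipped to [-1, 1].
    """
    if bounds is None:
        bounds = pd.DataFrame(
            {"min": expr_subset.min(axis=1), "max": expr_subset.max(axis=1)}
        )
    lo = bounds.loc[expr_subset.index, "min"]
    hi = bounds.loc[expr_subset.index, "max"]
    span = hi - lo
    constant = span[span == 0.0].index.tolist()
    if constant:
        warnings.warn(
            f"constant genes scaled to 0: {constant[:5]}"
            + ("..." if len(constant) > 5 else ""),
            UserWarning, stacklevel=2,
        )
    safe_span = span.replace(0.0, 1.0)
    scaled = (expr_subset.sub(lo, axis=0).div(safe_span, axis=0) * 2.0) - 1.0
    scaled.loc[constant] = 0.0
    return scaled.clip(-1.0, 1.0), bounds


def compute_m6ascore(
    expr: ExpressionMatrix,
    partition: SignaturePartition,
    freeze_bounds: bool = True,
) -> ScoreTable:
    """Per-sample m6Ascore: sum of scaled risk minus scaled protective genes.

    Signature genes absent from the matrix are dropped with a logged
    count. If the partition carries frozen scaling bounds they are
    used; otherwise bounds are computed from this cohort (and stored on
    the partition when ``freeze_bounds``).
    """
    present_risk = [g for g in partition.risk_genes if g in expr.data.index]
    present_prot = [g for g in partition.protective_genes if g in expr.data.index]
    n_missing = len(partition.genes) - len(present_risk) - len(present_prot)
    if n_missing:
        logger.info("compute_m6ascore: %d signature genes not measured", n_missing)
    if not present_risk and not present_prot:
        raise ValueError("no signature gene present in the expression matrix")
    sub = expr.data.loc[present_risk + present_prot]
    known = partition.scale_bounds
    known = known.loc[known.index.intersection(sub.index)] if known is not None else None
    if known is not None and len(known) == len(sub):
        scaled, bounds = minmax_scale(sub, bounds=known)
    else:
        scaled, bounds = minmax_scale(sub)
        if freeze_bounds:
            partition.scale_bounds = bounds
    scaled_risk = scaled.loc[present_risk]
    scaled_prot = scaled.loc[present_prot]
    scores = scaled_risk.sum(axis=0) - scaled_prot.sum(axis=0)
    scores.name = "m6ascore"
    scores.index.name = "sample_id"
    return ScoreTable(
        scores=scores,
        scaled_risk=scaled_risk,
        scaled_protective=scaled_prot,
    )


def score_groups(
    scores: ScoreTable, cutoff: float | str = "median"
) -> ScoreTable:
    """Split samples into high (score > cutoff) and low groups.

    The default cutoff is the cohort median; scores exactly at the
    cutoff go to "low" so the split is deterministic.
    """
    s = scores.scores
    if len(s) < 2:
        raise ValueError("need at least 2 samples to form score groups")
    cut = float(s.median()) if cutoff == "median" else float(cutoff)
    groups = pd.Series(
        np.where(s > cut, "high", "low"), index=s.index, name="score_group"
    )
    if (groups == "low").all():
        warnings.warn(
            "all samples fall in the low score group (tied scores?)",
            UserWarning, stacklevel=2,
        )
    scores.groups = groups
    scores.cutoff = cut
    return scores
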