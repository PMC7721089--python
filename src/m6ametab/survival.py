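"""Survival analytics: Kaplan-Meier, log-rank, Cox, nomogram, AUC(t).

Kaplan-Meier estimation, the unweighted log-rank test and
proportional-hazards fits (Breslow tie handling) are delegated to
``lifelines``; the time-dependent cumulative-case / dynamic-control
AUC with inverse-probability-of-censoring weights comes from
``scikit-survival``. The nomogram point system is built here: each
multivariate Cox factor is mapped to points proportional to its
coefficient-times-value range, the widest factor spanning exactly
0-100, and the total-points scale is mapped to predicted survival at
the requested horizons through the model's baseline survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sksurv.metrics import cumulative_dynamic_auc
from sksurv.util import Surv

from .io import ClinicalTable

__all__ = [
    "KMCurve",
    "CoxModel",
    "NomogramModel",
    "km_estimate",
    "logrank_test",
    "cox_multivariate",
    "build_nomogram",
    "time_dependent_auc",
]


@dataclass
class KMCurve:
    """Product-limit estimate for one group, with Greenwood variance."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_var: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "greenwood_var": self.greenwood_var,
                "group": self.group,
            }
        )


def km_estimate(times, events, groups=None) -> list[KMCurve]:
    """Kaplan-Meier curves per group (right censoring handled).

    Empty groups are skipped with a warning. With ``groups=None`` a
    single pooled curve labelled ``"all"`` is returned.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("negative survival times")
    if groups is None:
        groups = np.full(len(times), "all")
    if isinstance(groups, pd.Series):
        groups = groups.to_numpy() if not isinstance(
            groups.dtype, pd.CategoricalDtype) else groups.array
    if isinstance(groups, pd.Categorical):
        levels = list(groups.categories)
        groups = np.asarray(groups)
    else:
        groups = np.asarray(groups)
        levels = list(pd.unique(groups))
    curves = []
    for g in levels:
        mask = groups == g
        if mask.sum() == 0:
            warnings.warn(f"empty group {g!r} skipped", UserWarning, stacklevel=2)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask], label=str(g))
        table = kmf.event_table
        t = table.index.to_numpy(dtype=float)
        n = table["at_risk"].to_numpy(dtype=float)
        d = table["observed"].to_numpy(dtype=float)
        surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            increments = np.where(n * (n - d) > 0, d / (n * (n - d)), 0.0)
        greenwood = surv**2 * np.cumsum(increments)
        curves.append(
            KMCurve(
                group=str(g), times=t, survival=surv,
                at_risk=n, greenwood_var=greenwood,
            )
        )
    return curves


def logrank_test(times, events, groups) -> tuple[float, int, float]:
    """Unweighted k-group log-rank test: (chi2, df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("log-rank test needs at least 2 groups")
    res = multivariate_logrank_test(times, groups, events)
    df = len(levels) - 1
    return float(res.test_statistic), df, float(res.p_value)


@dataclass
class CoxModel:
    """A fitted multivariate proportional-hazards model.

    ``design`` is the numeric design matrix actually fitted (categorical
    factors expanded against their stated reference level); ``summary``
    carries HR, 95% CI and Wald p per design column.
    """

    fitter: CoxPHFitter
    design: pd.DataFrame
    durations: pd.Series
    events: pd.Series
    summary: pd.DataFrame
    references: dict[str, object] = field(default_factory=dict)

    def linear_predictor(self, design: pd.DataFrame | None = None) -> pd.Series:
        design = self.design if design is None else design
        beta = self.fitter.params_
        return design[beta.index] @ beta

    def predict_survival(self, design: pd.DataFrame, times) -> pd.DataFrame:
        """S(t | x) rows=times, cols=samples."""
        frame = design.copy()
        return self.fitter.predict_survival_function(frame, times=np.asarray(times))


def _expand_design(
    covariates: pd.DataFrame, references: dict[str, object] | None
) -> tuple[pd.DataFrame, dict[str, object]]:
    references = dict(references or {})
    pieces = []
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            pieces.append(s.astype(float))
        else:
            levels = sorted(s.dropna().unique(), key=str)
            ref = references.get(col, levels[0])
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {col!r}")
            references[col] = ref
            for lev in levels:
                if lev == ref:
                    continue
                pieces.append((s == lev).astype(float).rename(f"{col}[{lev}]"))
    design = pd.concat(pieces, axis=1)
    return design, references


def cox_multivariate(
    covariates: pd.DataFrame,
    clinical: ClinicalTable | pd.DataFrame,
    references: dict[str, object] | None = None,
) -> CoxModel:
    """Joint proportional-hazards fit with Breslow tie handling.

    Categorical columns are expanded to indicator columns against a
    reference level (the lexicographically first level unless stated
    in ``references``). Constant or duplicated design columns raise.
    Fewer than 10 events per covariate triggers a warning.
    """
    clin = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    shared = covariates.index.intersection(clin.index)
    if shared.empty:
        raise ValueError("no shared samples between covariates and clinical")
    covariates = covariates.loc[shared]
    clin = clin.loc[shared]
    design, references = _expand_design(covariates, references)
    for col in design.columns:
        if design[col].std(ddof=0) == 0.0:
            raise ValueError(f"constant design column {col!r}")
    if design.shape[1] > 1:
        corr = np.atleast_2d(np.corrcoef(design.to_numpy(), rowvar=False))
        dup = np.argwhere(np.triu(np.isclose(np.abs(corr), 1.0), k=1))
        if dup.size:
            i, j = dup[0]
            raise ValueError(
                f"collinear design columns {design.columns[i]!r} and "
                f"{design.columns[j]!r}"
            )
    n_events = int(clin["os_event"].sum())
    if n_events < 10 * design.shape[1]:
        warnings.warn(
            f"{n_events} events for {design.shape[1]} covariates "
            "(< 10 per covariate); estimates may be unstable",
            UserWarning, stacklevel=2,
        )
    frame = design.copy()
    frame["os_time"] = clin["os_time"].astype(float)
    frame["os_event"] = clin["os_event"].astype(int)
    fitter = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fitter.fit(frame, duration_col="os_time", event_col="os_event")
    except Exception as exc:
        raise RuntimeError(
            f"multivariate Cox fit failed ({exc}); check covariate scaling "
            "and event counts"
        ) from exc
    summ = fitter.summary
    summary = pd.DataFrame(
        {
            "hr": np.exp(summ["coef"]),
            "ci_lower": np.exp(summ["coef lower 95%"]),
            "ci_upper": np.exp(summ["coef upper 95%"]),
            "p": summ["p"],
        }
    )
    return CoxModel(
        fitter=fitter,
        design=design,
        durations=frame["os_time"],
        events=frame["os_event"],
        summary=summary,
        references=references,
    )


@dataclass
class NomogramModel:
    """Additive point system over the fitted Cox factors.

    Per-factor points are ``100 * beta_f (x - x_ref) / max_range``
    where ``x_ref`` is the observed value minimizing ``beta_f x`` and
    ``max_range`` the widest observed ``beta_f x`` span, so the widest
    factor runs exactly 0..100. The total-points axis maps to predicted
    survival at each horizon through the model's baseline survival.
    """

    model: CoxModel
    horizons: tuple[float, ...]
    factor_refs: pd.Series  # per design column, value at 0 points
    factor_ranges: pd.Series  # per design column, beta*x span
    max_range: float
    reference_survival: pd.Series  # S(t) at the all-reference profile
    point_table: pd.DataFrame  # index total points; one column per horizon

    def points(self, design: pd.DataFrame) -> pd.DataFrame:
        beta = self.model.fitter.params_
        contrib = design[beta.index].mul(beta, axis=1)
        ref_contrib = self.factor_refs * beta
        pts = (contrib - ref_contrib) * (100.0 / self.max_range)
        pts["total"] = pts.sum(axis=1)
        return pts

    def predict_survival_from_points(
        self, total_points, horizon: float
    ) -> np.ndarray:
        """Interpolate the point table at the given horizon."""
        col = self.point_table[horizon]
        return np.interp(
            np.asarray(total_points, dtype=float),
            self.point_table.index.to_numpy(),
            col.to_numpy(),
        )


def build_nomogram(
    model: CoxModel, horizons: tuple[float, ...] = (1.0, 3.0, 5.0)
) -> NomogramModel:
    """Derive the nomogram point system from a fitted Cox model.

    Horizons beyond the observed follow-up are refused with a warning
    (no extrapolation). The point table tabulates predicted survival on
    a 0..max-total grid of 201 points per kept horizon.
    """
    max_follow = float(model.durations.max())
    kept = tuple(h for h in horizons if h <= max_follow)
    dropped = tuple(h for h in horizons if h > max_follow)
    if dropped:
        warnings.warn(
            f"horizons beyond observed follow-up refused: {dropped}",
            UserWarning, stacklevel=2,
        )
    if not kept:
        raise ValueError("no horizon within the observed follow-up")
    beta = model.fitter.params_
    design = model.design[beta.index]
    contrib = design.mul(beta, axis=1)
    refs = pd.Series(
        {c: design[c][contrib[c].idxmin()] for c in design.columns}
    )
    ranges = contrib.max() - contrib.min()
    max_range = float(ranges.max())
    if max_range <= 0:
        raise ValueError("all factors have zero coefficient range")
    ref_row = refs.to_frame().T
    ref_surv = model.predict_survival(ref_row, kept).iloc[:, 0]
    ref_surv.index = list(kept)
    max_total = float(ranges.sum() * 100.0 / max_range)
    grid = np.linspace(0.0, max_total, 201)
    lp_ref = float((refs * beta).sum())
    lp_grid = lp_ref + grid * max_range / 100.0
    # S(t|x) = S0(t)^exp(lp); recover S0 from the reference profile
    table = {}
    for h in kept:
        s_ref = float(ref_surv.loc[h])
        log_s0 = np.log(max(s_ref, 1e-300)) / np.exp(lp_ref)
        table[h] = np.exp(log_s0 * np.exp(lp_grid))
    point_table = pd.DataFrame(table, index=pd.Index(grid, name="total_points"))
    return NomogramModel(
        model=model,
        horizons=kept,
        factor_refs=refs,
        factor_ranges=ranges,
        max_range=max_range,
        reference_survival=ref_surv,
        point_table=point_table,
    )


def time_dependent_auc(
    scores: pd.Series,
    clinical: ClinicalTable | pd.DataFrame,
    horizons=(1.0, 3.0, 5.0),
) -> pd.Series:
    """Cumulative/dynamic AUC at each horizon with IPCW weighting.

    Cases are events by the horizon, controls samples still at risk;
    censoring is reweighted by the Kaplan-Meier estimate of the
    censoring distribution. Horizons with no cases or no controls (or
    outside follow-up) are skipped with a warning.
    """
    clin = clinical.data if isinstance(clinical, ClinicalTable) else clinical
    shared = scores.index.intersection(clin.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 aligned samples")
    s = scores.loc[shared].to_numpy(dtype=float)
    t = clin.loc[shared, "os_time"].to_numpy(dtype=float)
    e = clin.loc[shared, "os_event"].to_numpy(dtype=int).astype(bool)
    y = Surv.from_arrays(event=e, time=t)
    out = {}
    for h in horizons:
        n_cases = int(((t <= h) & e).sum())
        n_controls = int((t > h).sum())
        if n_cases == 0 or n_controls == 0:
            warnings.warn(
                f"horizon {h}: {n_cases} cases / {n_controls} controls; skipped",
                UserWarning, stacklevel=2,
            )
            continue
        try:
            auc, _mean = cumulative_dynamic_auc(y, y, s, [h])
        except ValueError as exc:
            warnings.warn(f"horizon {h} skipped: {exc}", UserWarning, stacklevel=2)
            continue
        out[h] = float(auc[0])
    return pd.Series(out, name="auc")
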