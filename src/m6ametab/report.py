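"""Cross-tabulations and association summaries tying the strata together.

Chi-square tests of independence between stratifications (Pearson,
continuity correction off by default), Pearson correlations between
the m6Ascore and pathway enrichment scores, treatment-response
contrasts between score groups, and the long-format flow table behind
an alluvial diagram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gsva import EnrichmentScores
from .score import ScoreTable

__all__ = [
    "ContingencyResult",
    "crosstab",
    "score_pathway_correlation",
    "response_contrast",
    "alluvial_table",
]


@dataclass
class ContingencyResult:
    observed: pd.DataFrame
    expected: pd.DataFrame
    chi2: float
    df: int
    p: float
    low_expected: bool  # any expected cell < 5


def crosstab(
    labels_a: pd.Series, labels_b: pd.Series, correction: bool = False
) -> ContingencyResult:
    """Pearson chi-square test of independence between two label columns.

    Continuity (Yates) correction is off by default and only applies to
    2x2 tables. A zero row or column margin raises.
    """
    frame = pd.concat(
        [labels_a.rename("a"), labels_b.rename("b")], axis=1, join="inner"
    ).dropna()
    if frame["a"].nunique() < 2 or frame["b"].nunique() < 2:
        raise ValueError("each label column needs at least 2 levels")
    observed = pd.crosstab(frame["a"], frame["b"])
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise ValueError("zero margin in the contingency table")
    chi2, p, df, expected = stats.chi2_contingency(
        observed.to_numpy(), correction=correction
    )
    expected = pd.DataFrame(expected, index=observed.index,
                            columns=observed.columns)
    low = bool((expected.to_numpy() < 5).any())
    if low:
        warnings.warn(
            "expected cell count below 5; chi-square approximation is weak",
            UserWarning, stacklevel=2,
        )
    return ContingencyResult(
        observed=observed, expected=expected,
        chi2=float(chi2), df=int(df), p=float(p), low_expected=low,
    )


def score_pathway_correlation(
    scores: ScoreTable | pd.Series, enrichment: EnrichmentScores
) -> pd.DataFrame:
    """Pearson r (and two-sided p) of the m6Ascore against each set.

    Zero-variance sets are skipped with a warning. Output sorted by r
    ascending, so the most negatively correlated pathways come first.
    """
    s = scores.scores if isinstance(scores, ScoreTable) else scores
    shared = s.index.intersection(enrichment.values.columns)
    if len(shared) < 3:
        raise ValueError("need at least 3 aligned samples")
    x = s.loc[shared].to_numpy(dtype=float)
    rows = []
    for name in enrichment.set_names:
        y = enrichment.values.loc[name, shared].to_numpy(dtype=float)
        if np.std(y) == 0.0 or np.std(x) == 0.0:
            warnings.warn(f"set {name!r} skipped: zero variance",
                          UserWarning, stacklevel=2)
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((name, float(r), float(p)))
    out = pd.DataFrame(rows, columns=["set_name", "pearson_r", "p"])
    return out.sort_values("pearson_r").reset_index(drop=True)


def response_contrast(
    score_group: pd.Series, response: pd.Series
) -> tuple[pd.DataFrame, ContingencyResult | None]:
    """PR/SD rate per score group plus the 2x2 chi-square test.

    Samples without response data are excluded (count logged via
    warning when nonzero). If every observed response is identical the
    rates are still reported but the test is skipped with a warning.
    """
    frame = pd.concat(
        [score_group.rename("group"), response.rename("response")],
        axis=1, join="inner",
    )
    n_missing = int(frame["response"].isna().sum())
    frame = frame.dropna()
    if n_missing:
        warnings.warn(
            f"{n_missing} samples without response data excluded",
            UserWarning, stacklevel=2,
        )
    if frame.empty or frame["group"].nunique() < 1:
        raise ValueError("no sample with both score group and response")
    rates = (
        frame.assign(responded=frame["response"] == "PR/SD")
        .groupby("group")["responded"]
        .agg(n="size", pr_sd_rate="mean")
        .reset_index()
    )
    result = None
    if frame["response"].nunique() < 2 or frame["group"].nunique() < 2:
        warnings.warn(
            "degenerate response table; chi-square test skipped",
            UserWarning, stacklevel=2,
        )
    else:
        result = crosstab(frame["group"], frame["response"])
    return rates, result


def alluvial_table(assignments: list[pd.Series]) -> pd.DataFrame:
    """Counts for every path across >= 2 aligned stratifications.

    Returns a long-format table with one column per stratification and
    an ``n`` column; the counts sum to the number of shared samples.
    """
    if len(assignments) < 2:
        raise ValueError("need at least 2 label columns")
    names = []
    for i, s in enumerate(assignments):
        names.append(s.name if s.name else f"labels_{i}")
    frame = pd.concat(
        [s.rename(n) for s, n in zip(assignments, names)], axis=1, join="inner"
    ).dropna()
    flows = frame.groupby(names, observed=True).size().rename("n").reset_index()
    return flows.sort_values("n", ascending=False).reset_index(drop=True)
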