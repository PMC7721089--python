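"""Readers, writers and containers for the formats the pipeline touches.

Expression matrices are genes x samples tables of log2-scale values
(log2 FPKM for RNA-seq cohorts). Clinical tables carry overall-survival
time/event plus optional age, TNM stage, T stage, treatment response and
arbitrary extra label columns. Gene sets use the standard GMT format
with an optional two-column category table for metabolic pathways.

Readers validate rather than coerce: duplicated sample IDs, non-numeric
cells and malformed GMT lines are errors, not warnings. Samples missing
survival time or event status are dropped (with a logged count), which
is the usual exclusion rule for survival cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "GeneSetCollection",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_categories",
    "write_categories",
    "align",
    "concat_cohorts",
]

_STAGES = ("i", "ii", "iii", "iv")
_RESPONSES = ("PD", "PR/SD")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression values."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups[:5]}")
        if df.columns.duplicated().any():
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        if any(not str(g).strip() for g in df.index):
            raise ValueError("missing/empty gene symbol in expression matrix")
        self.data = df.astype(float)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)
        self.data.index.name = "gene"

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        present = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[present].copy())

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(samples)].copy())

    def drop_incomplete_genes(self) -> "ExpressionMatrix":
        """Drop genes with any missing value (count logged)."""
        mask = self.data.notna().all(axis=1)
        n_dropped = int((~mask).sum())
        if n_dropped:
            logger.info("dropped %d genes with missing values", n_dropped)
        return ExpressionMatrix(self.data.loc[mask].copy())


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations indexed by sample ID.

    Required columns: ``os_time`` (>= 0) and ``os_event`` (0/1).
    Optional: ``age``, ``stage_tnm`` (i..iv), ``stage_t`` (ordinal),
    ``response`` (PD or PR/SD) and any extra label columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in ("os_time", "os_event"):
            if col not in df.columns:
                raise ValueError(f"clinical table missing required column {col!r}")
        if df.index.duplicated().any():
            raise ValueError("duplicate sample IDs in clinical table")
        df = df.copy()
        df.index = df.index.astype(str)
        df.index.name = "sample_id"
        n_before = len(df)
        df = df.dropna(subset=["os_time", "os_event"])
        if len(df) < n_before:
            logger.info(
                "excluded %d samples without survival information",
                n_before - len(df),
            )
        df["os_time"] = df["os_time"].astype(float)
        if (df["os_time"] < 0).any():
            raise ValueError("negative os_time")
        events = df["os_event"].astype(float)
        if not np.isin(events, (0.0, 1.0)).all():
            bad = sorted(set(events) - {0.0, 1.0})
            raise ValueError(f"os_event must be 0/1, found {bad}")
        df["os_event"] = events.astype(int)
        if "stage_tnm" in df.columns:
            df["stage_tnm"] = _normalize_stage(df["stage_tnm"])
        if "response" in df.columns:
            df["response"] = _normalize_response(df["response"])
        self.data = df

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional per-set category annotations."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise ValueError(f"gene set {name!r} has duplicate members")

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def sets_in_category(self, category: str) -> list[str]:
        return [n for n in self.sets if self.categories.get(n) == category]

    def __len__(self) -> int:
        return len(self.sets)


def _normalize_stage(series: pd.Series) -> pd.Series:
    def norm(v):
        if pd.isna(v):
            return np.nan
        s = str(v).strip().lower()
        if s in _STAGES:
            return s
        # accept arabic numerals
        arabic = {"1": "i", "2": "ii", "3": "iii", "4": "iv"}
        if s in arabic:
            return arabic[s]
        raise ValueError(f"unrecognized TNM stage {v!r}")

    return series.map(norm)


def _normalize_response(series: pd.Series) -> pd.Series:
    def norm(v):
        if pd.isna(v):
            return np.nan
        s = str(v).strip().upper().replace(" ", "")
        if s == "PD":
            return "PD"
        if s in ("PR/SD", "PRSD", "PR", "SD"):
            return "PR/SD"
        raise ValueError(f"unrecognized treatment response {v!r}")

    return series.map(norm)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path: str | Path, duplicate_policy: str = "max-mean"
) -> ExpressionMatrix:
    """Read a genes x samples TSV/CSV (first column = gene symbols).

    Duplicate gene rows are collapsed according to ``duplicate_policy``:
    ``"max-mean"`` keeps the row with the highest mean expression (the
    common convention), ``"error"`` raises.
    """
    path = Path(path)
    sep = _sep_for(path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dups = pd.Index(header)[pd.Index(header).duplicated()].unique().tolist()
    if dups:
        raise ValueError(f"{path}: duplicated sample IDs in header: {dups[:5]}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    # locate non-numeric cells precisely before failing
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        rows, cols = np.nonzero(bad.to_numpy())
        g, s = df.index[rows[0]], df.columns[cols[0]]
        raise ValueError(
            f"{path}: non-numeric value {df.loc[g, s]!r} at gene {g!r}, sample {s!r}"
        )
    df = numeric
    if df.index.duplicated().any():
        if duplicate_policy == "error":
            raise ValueError(f"{path}: duplicate gene symbols")
        if duplicate_policy != "max-mean":
            raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
        n_before = len(df)
        means = df.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        df = df.iloc[order]
        df = df[~df.index.duplicated(keep="first")]
        logger.info(
            "collapsed %d duplicate gene rows (kept highest mean)",
            n_before - len(df),
        )
    return ExpressionMatrix(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    matrix.data.to_csv(path, sep=_sep_for(path))


def read_clinical(path: str | Path) -> ClinicalTable:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'sample_id'")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id values")
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def write_clinical(table: ClinicalTable, path: str | Path) -> None:
    path = Path(path)
    table.data.to_csv(path, sep=_sep_for(path))


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name, description, members...)."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) != len(members):
                warnings.warn(
                    f"{path}:{lineno}: set {name!r} had duplicate members "
                    "(deduplicated)",
                    UserWarning,
                    stacklevel=2,
                )
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = deduped
            descriptions[name] = desc
    if not sets:
        warnings.warn(f"{path}: empty GMT file", UserWarning, stacklevel=2)
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_categories(path: str | Path) -> dict[str, str]:
    """Read a two-column (set_name, category) TSV."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    if list(df.columns[:2]) != ["set_name", "category"]:
        raise ValueError(
            f"{path}: expected columns 'set_name', 'category', got {list(df.columns)}"
        )
    return dict(zip(df["set_name"].astype(str), df["category"].astype(str)))


def write_categories(categories: dict[str, str], path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame(
        {"set_name": list(categories), "category": list(categories.values())}
    ).to_csv(path, sep=_sep_for(path), index=False)


def align(
    expr: ExpressionMatrix, clinical: ClinicalTable
) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both inputs to the shared samples, in matching order."""
    shared = [s for s in expr.samples if s in set(clinical.samples)]
    if not shared:
        raise ValueError("expression and clinical tables share no sample IDs")
    n_expr_dropped = len(expr.samples) - len(shared)
    n_clin_dropped = len(clinical.samples) - len(shared)
    if n_expr_dropped:
        logger.info("align: dropped %d expression-only samples", n_expr_dropped)
    if n_clin_dropped:
        logger.info("align: dropped %d clinical-only samples", n_clin_dropped)
    return (
        expr.subset_samples(shared),
        ClinicalTable(clinical.data.loc[shared].copy()),
    )


def concat_cohorts(matrices: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate cohorts on their shared genes.

    No batch correction is applied; merging cohorts from different
    platforms without it will confound downstream clustering.
    """
    warnings.warn(
        "concat_cohorts performs no batch correction; merged cohorts from "
        "different platforms may carry batch structure",
        UserWarning,
        stacklevel=2,
    )
    shared = set(matrices[0].genes)
    for m in matrices[1:]:
        shared &= set(m.genes)
    if not shared:
        raise ValueError("cohorts share no genes")
    genes = [g for g in matrices[0].genes if g in shared]
    merged = pd.concat([m.data.loc[genes] for m in matrices], axis=1)
    return ExpressionMatrix(merged)
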