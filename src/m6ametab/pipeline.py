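"""End-to-end pipeline: from expression + clinical + gene sets to reports.

Stage order: IO/alignment -> modification-pattern clustering on the
regulator panel -> single-sample enrichment (methylation + metabolic
sets) -> differential expression between patterns -> univariate Cox
screen -> signature partition -> m6Ascore + median split -> metabolic
subtyping -> survival analyses (KM/log-rank, multivariate Cox,
nomogram, time-dependent AUC) -> association reports. Every
intermediate artifact is written to the run directory as TSV/JSON
together with a machine-readable manifest; identical configs reproduce
identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import ClusteringConfig, m6a_clusters, pca_view
from .diffexpr import cluster_degs
from .gsva import GsvaParams, gsva_scores
from .io import (
    ExpressionMatrix,
    align,
    read_categories,
    read_clinical,
    read_expression,
    read_gmt,
)
from .metabolic import lipid_labels, metabolic_clusters
from .panel import default_panel
from .report import (
    alluvial_table,
    crosstab,
    response_contrast,
    score_pathway_correlation,
)
from .score import (
    compute_m6ascore,
    cox_screen,
    score_groups,
    signature_partition,
)
from .survival import (
    build_nomogram,
    cox_multivariate,
    km_estimate,
    logrank_test,
    time_dependent_auc,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and parameters of a full run; unknown keys are rejected.

    Defaults keep the published settings where they are stated: k range
    2..15, nstart 25, DEG filter adjusted p < 0.05 with |log2FC| > 1,
    Cox screen alpha 0.05, median score split, horizons 1/3/5 years.
    """

    expression: str | None = None
    clinical: str | None = None
    gene_sets: str | None = None
    categories: str | None = None
    output_dir: str = "m6ametab_run"
    k_min: int = 2
    k_max: int = 15
    nstart: int = 25
    indices: tuple[str, ...] = (
        "silhouette", "calinski_harabasz", "davies_bouldin", "gap",
    )
    gap_b: int = 10
    k: int | None = None
    alpha: float = 0.05
    fc_min: float = 1.0
    deg_mode: str = "pairwise"
    kernel: str = "gaussian"
    tau: float = 1.0
    mode: str = "diff_of_maxima"
    min_set_size: int = 5
    max_set_size: int = 500
    horizons: tuple[float, ...] = (1.0, 3.0, 5.0)
    cutoff: str | float = "median"
    methylation_set: str = "mRNA_methylation"
    seed: int = 0

    def __post_init__(self) -> None:
        self.indices = tuple(self.indices)
        self.horizons = tuple(float(h) for h in self.horizons)

    @classmethod
    def from_dict(cls, mapping: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def clustering(self) -> ClusteringConfig:
        return ClusteringConfig(
            k_min=self.k_min, k_max=self.k_max, nstart=self.nstart,
            indices=self.indices, gap_b=self.gap_b, seed=self.seed, k=self.k,
        )

    def gsva(self) -> GsvaParams:
        return GsvaParams(
            kernel=self.kernel, tau=self.tau, mode=self.mode,
            min_set_size=self.min_set_size, max_set_size=self.max_set_size,
        )


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(name, exc) from exc
        return wrapped
    return decorator


def run_pipeline(
    config: PipelineConfig,
    *,
    expression: ExpressionMatrix | None = None,
    clinical=None,
    gene_sets=None,
    categories: dict[str, str] | None = None,
) -> Path:
    """Execute the full analysis; returns the run directory.

    Inputs may be passed in memory (as produced by the synthetic
    cohort generator) or read from the paths in the config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO)

    # ---- inputs ---------------------------------------------------------
    try:
        if expression is None:
            if config.expression is None:
                raise ValueError("no expression matrix provided")
            expression = read_expression(config.expression)
        if clinical is None:
            if config.clinical is None:
                raise ValueError("no clinical table provided")
            clinical = read_clinical(config.clinical)
        if gene_sets is None:
            if config.gene_sets is None:
                raise ValueError("no gene-set collection provided")
            gene_sets = read_gmt(config.gene_sets)
        if categories is None and config.categories is not None:
            categories = read_categories(config.categories)
        if categories is None:
            categories = dict(gene_sets.categories)
        expression = expression.drop_incomplete_genes()
        expression, clinical = align(expression, clinical)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("io", exc) from exc

    # ---- m6A pattern clustering ----------------------------------------
    @_stage("m6a_clusters")
    def stage_clusters():
        assignment, cluster_means = m6a_clusters(
            expression, default_panel(), config.clustering()
        )
        assignment.to_tsv(out / "m6a_clusters.tsv")
        cluster_means.to_csv(out / "regulator_cluster_means.tsv", sep="\t")
        if assignment.selection_report is not None:
            assignment.selection_report.to_csv(
                out / "cluster_selection_report.tsv", sep="\t"
            )
        return assignment

    assignment = stage_clusters()

    @_stage("gsva")
    def stage_gsva():
        scores = gsva_scores(expression, gene_sets, config.gsva())
        scores.values.to_csv(out / "gsva_scores.tsv", sep="\t")
        scores.skipped_report().to_csv(
            out / "gsva_skipped_sets.tsv", sep="\t", index=False
        )
        return scores

    enrichment = stage_gsva()

    @_stage("differential_expression")
    def stage_degs():
        table, union = cluster_degs(
            expression, assignment, alpha=config.alpha,
            fc_min=config.fc_min, mode=config.deg_mode,
        )
        table.table.to_csv(out / "degs.tsv", sep="\t", index=False)
        (out / "deg_union.txt").write_text("\n".join(union) + "\n")
        return table, union

    _deg_table, deg_union = stage_degs()

    @_stage("cox_screen")
    def stage_screen():
        screen = cox_screen(expression.subset_genes(deg_union), clinical)
        screen.table.to_csv(out / "cox_screen.tsv", sep="\t")
        return screen

    screen = stage_screen()

    @_stage("signature")
    def stage_signature():
        partition = signature_partition(screen, alpha=config.alpha)
        return partition

    partition = stage_signature()

    @_stage("m6ascore")
    def stage_score():
        table = compute_m6ascore(expression, partition)
        table = score_groups(table, cutoff=config.cutoff)
        table.to_frame().to_csv(out / "m6ascore.tsv", sep="\t")
        partition.to_tsv(out / "signature.tsv")
        return table

    score_table = stage_score()

    @_stage("metabolic_subtypes")
    def stage_metabolic():
        metabolic_names = [n for n in enrichment.set_names if n in categories]
        met_scores = dataclasses.replace(
            enrichment, values=enrichment.values.loc[metabolic_names]
        )
        met_assignment = metabolic_clusters(met_scores, config.clustering())
        subtypes = lipid_labels(met_scores, met_assignment, categories)
        subtypes.to_tsv(out / "metabolic_subgroups.tsv")
        if subtypes.category_distances is not None:
            subtypes.category_distances.to_csv(
                out / "category_distance.tsv", sep="\t", index=False
            )
        return subtypes

    subtypes = stage_metabolic()

    @_stage("survival")
    def stage_survival():
        clin = clinical.data
        groups = score_table.groups.loc[clin.index]
        curves = km_estimate(clin["os_time"], clin["os_event"], groups)
        pd.concat([c.to_frame() for c in curves]).to_csv(
            out / "km_curves.tsv", sep="\t", index=False
        )
        chi2, df, p = logrank_test(clin["os_time"], clin["os_event"], groups)
        results = {"logrank": {"chi2": chi2, "df": df, "p": p}}

        covariates = pd.DataFrame({"score_high": (groups == "high").astype(float)})
        references = {}
        if "stage_tnm" in clin.columns and clin["stage_tnm"].notna().any():
            covariates["stage_tnm"] = clin["stage_tnm"]
            references["stage_tnm"] = "i"
        if "age" in clin.columns and clin["age"].notna().any():
            covariates["age"] = clin["age"].astype(float)
        model = cox_multivariate(covariates, clinical, references=references)
        model.summary.to_csv(out / "cox_multivariate.tsv", sep="\t")
        nomogram = build_nomogram(model, horizons=config.horizons)
        nomogram.point_table.to_csv(out / "nomogram_point_table.tsv", sep="\t")
        total_points = nomogram.points(model.design)["total"]
        auc = time_dependent_auc(total_points, clinical, config.horizons)
        auc.rename_axis("horizon").to_frame().to_csv(out / "auc.tsv", sep="\t")
        results["auc"] = {str(h): float(a) for h, a in auc.items()}
        (out / "survival_tests.json").write_text(json.dumps(results, indent=2))
        return results, nomogram

    survival_results, _nomogram = stage_survival()

    @_stage("report")
    def stage_report():
        clin = clinical.data
        corr = score_pathway_correlation(score_table, enrichment)
        corr.to_csv(out / "score_pathway_correlation.tsv", sep="\t", index=False)
        labels = {
            "m6Acluster": assignment.as_series("m6Acluster").astype(str),
            "metabolic_subgroup": subtypes.labels,
            "score_group": score_table.groups,
        }
        if "stage_tnm" in clin.columns:
            labels["stage_tnm"] = clin["stage_tnm"]
        flows = alluvial_table(list(labels.values()))
        flows.to_csv(out / "alluvial_flows.tsv", sep="\t", index=False)
        tests = {}
        for name, series in labels.items():
            if name == "score_group":
                continue
            try:
                res = crosstab(score_table.groups, series)
                tests[f"score_group_vs_{name}"] = {
                    "chi2": res.chi2, "df": res.df, "p": res.p,
                    "low_expected": res.low_expected,
                }
            except ValueError as exc:
                tests[f"score_group_vs_{name}"] = {"error": str(exc)}
        if "response" in clin.columns and clin["response"].notna().any():
            rates, res = response_contrast(score_table.groups, clin["response"])
            rates.to_csv(out / "response_rates.tsv", sep="\t", index=False)
            if res is not None:
                tests["score_group_vs_response"] = {
                    "chi2": res.chi2, "df": res.df, "p": res.p,
                }
        (out / "association_tests.json").write_text(json.dumps(tests, indent=2))

    stage_report()

    manifest = {
        "package": "m6ametab",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_samples": len(expression.samples),
        "n_genes": len(expression.genes),
        "n_signature_genes": len(partition.genes),
        "k_selected": assignment.k,
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
    logger.info("pipeline complete: %s", out)
    return out
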