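"""Synthetic HCC-like cohort generator.

Emulates the statistical structure the downstream analysis assumes:
three latent m6A modification patterns with graded regulator expression,
pattern-coupled prognostic (risk / protective) genes, a metabolic gene
block whose pathway activity is negatively correlated with the pattern
index, pattern-linked survival hazard, stage and binary treatment
response — plus a matching gene-set collection (one mRNA-methylation
set and 50 category-annotated metabolic sets).

Expression is generated directly on the log2 scale (no count layer),
matching the log2-FPKM inputs the pipeline expects. Survival is
exponential with uniform censoring so that Cox parameter recovery has a
closed-form ground truth.

Structure of the regulator block (pattern index z in {0, 1, 2} for the
default three patterns): each role follows a per-pattern mean profile
in units of ``regulator_shift`` — readers (0, 1, 0.35): highest in the
intermediate pattern, so patterns 1 and 2 differ mostly in readers;
writers (0, 0.1, 1): stepping up in the top pattern, so patterns 1/2
vs 3 differ mostly in writers; erasers (0, 0.5, 1): graded. Pattern 1
has the lowest and pattern 3 the highest overall regulator expression,
and the three pattern centroids sit near-equidistant in regulator
space, i.e. the patterns are genuinely trimodal rather than a single
gradient.

The metabolic block is organised into four categories, each with its
own per-pattern activity profile: lipid activity collapses in the top
(high-methylation) pattern, carbohydrate declines gradually, and
amino-acid and "other" metabolism dip in the intermediate pattern with
partial recovery under the proliferative top pattern. All profiles
start highest in pattern 1, so mean metabolic expression is negatively
correlated with the pattern index. |metabolic_coupling| sets how
tightly a category's realized activity tracks its pattern-determined
profile; a quarter of the activity noise is shared by all pathways of
a category, the rest is pathway-specific. The lipid category has the
largest expression loading, making it the most altered category.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    write_categories,
    write_clinical,
    write_expression,
    write_gmt,
)
from .panel import ERASERS, READERS, WRITERS, default_panel

__all__ = ["SimulationConfig", "SyntheticCohort", "simulate_cohort",
           "simulate_gene_sets", "write_fixture", "read_fixture"]

CATEGORIES = ("carbohydrate", "lipid", "amino_acid", "other")

# category loadings on expression: lipid most altered between patterns,
# carbohydrate low, "other" lowest (ordering used by the category-
# distance analysis downstream)
_CATEGORY_AMPLITUDE = {
    "carbohydrate": 1.0,
    "lipid": 1.5,
    "amino_acid": 1.2,
    "other": 1.0,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions.

    ``regulator_shift`` is the log2-scale mean offset between adjacent
    patterns; ``cluster_log_hazard`` the per-pattern log hazard
    multipliers; ``metabolic_coupling`` the (negative) correlation
    between the latent pattern index and metabolic pathway activity.
    Age and TNM stage carry their own log-hazard terms
    (``age_log_hazard`` per year around the cohort mean,
    ``stage_log_hazard`` per stage level) so that the nomogram factors
    are genuinely prognostic, as in real HCC cohorts.
    """

    n_samples: int = 300
    n_genes: int = 2000
    n_clusters: int = 3
    cluster_props: tuple[float, ...] | None = None
    regulator_shift: float = 1.5
    n_signature_risk: int = 40
    n_signature_protective: int = 40
    noise_sd: float = 1.0
    baseline_hazard: float = 0.15
    cluster_log_hazard: tuple[float, ...] = (0.0, 0.3, 0.8)
    age_log_hazard: float = 0.05
    stage_log_hazard: float = 0.3
    censor_time_max: float = 10.0
    metabolic_coupling: float = -0.8
    response_probs: tuple[float, ...] = (0.2, 0.35, 0.6)
    n_metabolic_sets: int = 50
    set_size_range: tuple[int, int] = (10, 30)
    set_overlap: float = 0.2
    category_pool_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cluster_props is None:
            self.cluster_props = tuple([1.0 / self.n_clusters] * self.n_clusters)
        self.cluster_props = tuple(float(p) for p in self.cluster_props)
        self.cluster_log_hazard = tuple(float(h) for h in self.cluster_log_hazard)
        self.response_probs = tuple(float(p) for p in self.response_probs)
        self.validate()

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ValueError("n_samples must be positive")
        if self.n_genes < 200:
            raise ValueError("n_genes must be >= 200")
        if self.n_clusters <= 0:
            raise ValueError("n_clusters must be positive")
        if len(self.cluster_props) != self.n_clusters:
            raise ValueError("cluster_props length must equal n_clusters")
        if abs(sum(self.cluster_props) - 1.0) > 1e-8 or min(self.cluster_props) < 0:
            raise ValueError("cluster_props must be a probability vector summing to 1")
        if self.regulator_shift < 0:
            raise ValueError("regulator_shift must be non-negative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if len(self.cluster_log_hazard) != self.n_clusters:
            raise ValueError("cluster_log_hazard length must equal n_clusters")
        if self.censor_time_max <= 0:
            raise ValueError("censor_time_max must be positive")
        if self.metabolic_coupling > 0:
            raise ValueError("metabolic_coupling must be <= 0")
        if not -1.0 <= self.metabolic_coupling <= 0.0:
            raise ValueError("metabolic_coupling must lie in [-1, 0]")
        if len(self.response_probs) != self.n_clusters:
            raise ValueError("response_probs length must equal n_clusters")
        if not all(0.0 <= p <= 1.0 for p in self.response_probs):
            raise ValueError("response_probs must lie in [0, 1]")
        if self.n_signature_risk < 0 or self.n_signature_protective < 0:
            raise ValueError("signature gene counts must be non-negative")
        lo, hi = self.set_size_range
        if not (0 < lo <= hi):
            raise ValueError("set_size_range must satisfy 0 < min <= max")
        if not 0.0 <= self.set_overlap <= 0.5:
            raise ValueError("set_overlap must lie in [0, 0.5]")


@dataclass
class SyntheticCohort:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth_samples: pd.DataFrame  # sample_id -> latent cluster (1-based)
    truth_genes: pd.DataFrame  # gene -> role tag (+ category)
    gene_sets: GeneSetCollection
    config: SimulationConfig


def _gene_layout(config: SimulationConfig, rng: np.random.Generator):
    """Deterministic gene naming, set membership and category map."""
    panel = default_panel()
    regulators = panel.genes
    risk = [f"RISKSIG{i:04d}" for i in range(1, config.n_signature_risk + 1)]
    prot = [f"PROTSIG{i:04d}" for i in range(1, config.n_signature_protective + 1)]

    lo, hi = config.set_size_range
    sizes = rng.integers(lo, hi + 1, size=config.n_metabolic_sets)
    set_category = [
        CATEGORIES[i % len(CATEGORIES)] for i in range(config.n_metabolic_sets)
    ]

    met_genes: list[str] = []
    met_gene_category: dict[str, str] = {}
    met_gene_group: dict[str, str] = {}  # shared-factor group: set name or pool
    sets: dict[str, list[str]] = {}
    categories: dict[str, str] = {}
    pools: dict[str, list[str]] = {}
    counter = 0

    def new_gene(cat: str, group: str) -> str:
        nonlocal counter
        counter += 1
        name = f"MET{counter:05d}"
        met_genes.append(name)
        met_gene_category[name] = cat
        met_gene_group[name] = group
        return name

    for cat in CATEGORIES:
        pools[cat] = [
            new_gene(cat, f"pool_{cat}") for _ in range(config.category_pool_size)
        ]
    for i, (size, cat) in enumerate(zip(sizes, set_category)):
        name = f"{cat.upper()}_PATHWAY_{i + 1:02d}"
        n_shared = min(int(round(config.set_overlap * size)),
                       config.category_pool_size)
        n_core = int(size) - n_shared
        core = [new_gene(cat, name) for _ in range(n_core)]
        shared = (
            list(rng.choice(pools[cat], size=n_shared, replace=False))
            if n_shared
            else []
        )
        sets[name] = core + shared
        categories[name] = cat

    n_used = len(regulators) + len(risk) + len(prot) + len(met_genes)
    n_noise = config.n_genes - n_used
    if n_noise < 10:
        raise ValueError(
            f"n_genes={config.n_genes} too small to host the regulator, "
            f"signature and metabolic blocks ({n_used} genes needed)"
        )
    noise = [f"NOISE{i:05d}" for i in range(1, n_noise + 1)]

    # mRNA methylation set: the regulators plus decoy genes
    n_decoys = min(10, n_noise)
    methylation_set = regulators + noise[:n_decoys]
    sets_all = {"mRNA_methylation": methylation_set, **sets}

    genes = regulators + risk + prot + met_genes + noise
    roles = (
        ["regulator"] * len(regulators)
        + ["risk_signature"] * len(risk)
        + ["protective_signature"] * len(prot)
        + ["metabolic"] * len(met_genes)
        + ["noise"] * len(noise)
    )
    truth_genes = pd.DataFrame({"gene": genes, "role": roles}).set_index("gene")
    truth_genes["category"] = pd.Series(met_gene_category)
    collection = GeneSetCollection(
        sets=sets_all,
        categories=categories,
        descriptions={n: "synthetic" for n in sets_all},
    )
    return panel, risk, prot, met_genes, met_gene_category, met_gene_group, \
        noise, truth_genes, collection


def simulate_gene_sets(config: SimulationConfig) -> GeneSetCollection:
    """The gene-set collection of the synthetic cohort.

    One ``mRNA_methylation`` set (regulators plus decoys) and
    ``n_metabolic_sets`` metabolic pathways cycled over the four
    categories. Identical to ``simulate_cohort(config).gene_sets``.
    """
    rng = np.random.default_rng(config.seed)
    return _gene_layout(config, rng)[-1]


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort; same seed, same bits."""
    if config is None:
        config = SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    (panel, risk, prot, met_genes, met_cat, met_group, noise_genes,
     truth_genes, gene_sets) = _gene_layout(config, rng)

    n = config.n_samples
    k = config.n_clusters
    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    z = rng.choice(k, size=n, p=config.cluster_props)

    genes = list(truth_genes.index)
    baseline = rng.uniform(3.0, 9.0, size=len(genes))
    expr = np.empty((len(genes), n))
    gene_pos = {g: i for i, g in enumerate(genes)}
    s = config.regulator_shift
    zf = z.astype(float)
    top = k - 1

    # regulators: role-specific pattern profiles (per-cluster mean offsets
    # in units of regulator_shift). Readers peak in pattern 2 and stay
    # partially elevated in pattern 3 (patterns 1 vs 2 differ mostly in
    # readers); writers step up in the top pattern (patterns 1/2 vs 3
    # differ mostly in writers); erasers are graded. The profiles place
    # the three pattern centroids near-equidistant in regulator space
    # while keeping overall regulator expression lowest in pattern 1 and
    # highest in pattern 3.
    role_profile = {
        "reader": np.array([0.0, 1.0, 0.35]),
        "writer": np.array([0.0, 0.1, 1.0]),
        "eraser": np.array([0.0, 0.5, 1.0]),
    }
    roles = panel.roles
    # profiles are defined over 3 patterns; other k interpolate the path
    pos = 2.0 * zf / (k - 1) if k > 1 else np.zeros(n)
    for g in panel.genes:
        profile = role_profile[roles[g].value]
        expr[gene_pos[g]] = s * np.interp(pos, [0.0, 1.0, 2.0], profile)

    # prognostic signature genes: monotone in the pattern index
    for g in risk:
        expr[gene_pos[g]] = s * zf
    for g in prot:
        expr[gene_pos[g]] = s * (top - zf)

    # metabolic block: per-category activity profiles over the patterns,
    # globally decreasing with the pattern index (the methylation-
    # metabolism anti-coupling). Lipid activity collapses only in the
    # top pattern (so the top pattern is the lipid-low group and lipid
    # is the most altered category); carbohydrate and "other" decline
    # gradually; amino-acid activity drops in the intermediate pattern
    # and partially recovers, which keeps the three pattern centroids
    # from being collinear in pathway space. |metabolic_coupling| is
    # the correlation between a category's pattern-determined activity
    # and its realized latent activity; the per-category noise SD is
    # derived from it. Sets add a small shared jitter on top, genes
    # their own noise.
    rho = abs(config.metabolic_coupling)
    pos_met = 2.0 * zf / (k - 1) if k > 1 else np.zeros(n)
    profile_grid = [0.0, 1.0, 2.0]
    cat_profile = {
        "lipid": np.array([1.0, 0.45, 0.0]),
        "carbohydrate": np.array([1.0, 0.4, 0.0]),
        "amino_acid": np.array([1.0, 0.0, 0.75]),
        "other": np.array([1.0, 0.1, 0.6]),
    }
    # one quarter of a category's activity noise is shared by all its
    # pathways (a common physiological state), the rest is pathway-
    # specific; only the shared part survives averaging over pathways
    shared_frac = 0.25
    cat_shared: dict[str, np.ndarray] = {}
    cat_sigma: dict[str, float] = {}
    cat_det: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        det = np.interp(pos_met, profile_grid, cat_profile[cat])
        det_sd = float(np.interp(np.arange(k) * (2.0 / max(k - 1, 1)),
                                 profile_grid, cat_profile[cat]).std())
        if rho == 0.0:  # uncoupled: activity is pure noise
            det = np.zeros(n)
            sigma = max(det_sd, 0.3)
        elif rho >= 1.0:
            sigma = 0.0
        else:
            sigma = det_sd * math.sqrt(1.0 / rho**2 - 1.0)
        cat_det[cat] = det
        cat_sigma[cat] = sigma
        cat_shared[cat] = rng.standard_normal(n)
    group_eps: dict[str, np.ndarray] = {}
    for g in met_genes:
        grp = met_group[g]
        if grp not in group_eps:
            group_eps[grp] = rng.standard_normal(n)
        cat = met_cat[g]
        sigma = cat_sigma[cat]
        latent = cat_det[cat] + sigma * (
            math.sqrt(shared_frac) * cat_shared[cat]
            + math.sqrt(1.0 - shared_frac) * group_eps[grp]
        )
        expr[gene_pos[g]] = _CATEGORY_AMPLITUDE[cat] * latent

    for g in noise_genes:
        expr[gene_pos[g]] = 0.0

    expr += baseline[:, None]
    expr += rng.normal(0.0, config.noise_sd, size=expr.shape)

    expression = ExpressionMatrix(
        pd.DataFrame(expr, index=genes, columns=sample_ids)
    )

    # ---- clinical layer -------------------------------------------------
    age = np.clip(np.round(rng.normal(62.0 - 2.0 * zf, 10.0)), 18, 90)
    stage_probs = _stage_probabilities(k)
    stage_idx = np.array(
        [rng.choice(4, p=stage_probs[zi]) for zi in z]
    )
    stage_tnm = np.array(["i", "ii", "iii", "iv"])[stage_idx]
    stage_t = np.minimum(
        4, np.maximum(1, stage_idx + 1 + rng.integers(-1, 2, size=n))
    )

    cluster_lh = np.asarray(config.cluster_log_hazard)[z]
    log_h = (
        math.log(config.baseline_hazard)
        + cluster_lh
        + config.age_log_hazard * (age - age.mean())
        + config.stage_log_hazard * stage_idx
    )
    event_time = rng.exponential(1.0 / np.exp(log_h))
    censor_time = rng.uniform(0.0, config.censor_time_max, size=n)
    os_time = np.minimum(event_time, censor_time)
    os_event = (event_time <= censor_time).astype(int)

    response_p = np.asarray(config.response_probs)[z]
    responded = rng.uniform(size=n) < response_p
    response = np.where(responded, "PR/SD", "PD")

    clinical = ClinicalTable(
        pd.DataFrame(
            {
                "os_time": os_time,
                "os_event": os_event,
                "age": age,
                "stage_tnm": stage_tnm,
                "stage_t": stage_t,
                "response": response,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    truth_samples = pd.DataFrame(
        {"cluster": z + 1}, index=pd.Index(sample_ids, name="sample_id")
    )
    return SyntheticCohort(
        expression=expression,
        clinical=clinical,
        truth_samples=truth_samples,
        truth_genes=truth_genes,
        gene_sets=gene_sets,
        config=config,
    )


def _stage_probabilities(k: int) -> np.ndarray:
    """TNM stage distributions shifted toward higher stages for higher z."""
    base = np.array([0.45, 0.30, 0.18, 0.07])
    advanced = np.array([0.15, 0.25, 0.38, 0.22])
    if k == 1:
        return base[None, :]
    w = np.linspace(0.0, 1.0, k)[:, None]
    probs = (1 - w) * base + w * advanced
    return probs / probs.sum(axis=1, keepdims=True)


def write_fixture(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write the cohort as plain-text files; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_expression(cohort.expression, directory / "expression.tsv")
    write_clinical(cohort.clinical, directory / "clinical.tsv")
    write_gmt(cohort.gene_sets, directory / "gene_sets.gmt")
    write_categories(cohort.gene_sets.categories, directory / "categories.tsv")
    cohort.truth_samples.to_csv(directory / "truth_samples.tsv", sep="\t")
    cohort.truth_genes.to_csv(directory / "truth_genes.tsv", sep="\t")
    manifest = {
        "config": asdict(cohort.config),
        "seed": cohort.config.seed,
        "n_samples": cohort.config.n_samples,
        "n_genes": cohort.config.n_genes,
        "files": [
            "expression.tsv",
            "clinical.tsv",
            "gene_sets.gmt",
            "categories.tsv",
            "truth_samples.tsv",
            "truth_genes.tsv",
        ],
    }
    with (directory / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_fixture(directory: str | Path) -> SyntheticCohort:
    """Round-trip a fixture written by :func:`write_fixture`."""
    from .io import read_categories, read_clinical, read_expression, read_gmt

    directory = Path(directory)
    with (directory / "manifest.json").open() as fh:
        manifest = json.load(fh)
    cfg_dict = dict(manifest["config"])
    for key in ("cluster_props", "cluster_log_hazard", "response_probs"):
        if cfg_dict.get(key) is not None:
            cfg_dict[key] = tuple(cfg_dict[key])
    cfg_dict["set_size_range"] = tuple(cfg_dict["set_size_range"])
    config = SimulationConfig(**cfg_dict)
    gene_sets = read_gmt(directory / "gene_sets.gmt")
    gene_sets.categories = read_categories(directory / "categories.tsv")
    return SyntheticCohort(
        expression=read_expression(directory / "expression.tsv"),
        clinical=read_clinical(directory / "clinical.tsv"),
        truth_samples=pd.read_csv(
            directory / "truth_samples.tsv", sep="\t", index_col=0
        ),
        truth_genes=pd.read_csv(
            directory / "truth_genes.tsv", sep="\t", index_col=0
        ),
        gene_sets=gene_sets,
        config=config,
    )
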