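"""Prognostic evaluation: KM split, multivariate Cox, nomogram, AUC(t).

Splits the cohort at the median m6Ascore, tests the survival
difference, fits a multivariate Cox model (score group + TNM stage +
age), builds the nomogram point system and reports 1/3/5-year
time-dependent AUC of the total points.
"""

import pandas as pd

from m6ametab import (
    ClusteringConfig,
    SimulationConfig,
    build_nomogram,
    cluster_degs,
    compute_m6ascore,
    cox_multivariate,
    cox_screen,
    default_panel,
    logrank_test,
    m6a_clusters,
    score_groups,
    signature_partition,
    simulate_cohort,
    time_dependent_auc,
)

cohort = simulate_cohort(SimulationConfig(seed=1))
assignment, _ = m6a_clusters(
    cohort.expression, default_panel(), ClusteringConfig(seed=1, k=3)
)
_, degs = cluster_degs(cohort.expression, assignment)
partition = signature_partition(
    cox_screen(cohort.expression.subset_genes(degs), cohort.clinical)
)
table = score_groups(compute_m6ascore(cohort.expression, partition))

clin = cohort.clinical.data
chi2, df, p = logrank_test(clin["os_time"], clin["os_event"], table.groups)
print(f"log-rank, score-high vs score-low: chi2 = {chi2:.1f}, p = {p:.2e}")

covariates = pd.DataFrame({
    "score_high": (table.groups == "high").astype(float),
    "stage_tnm": clin["stage_tnm"],
    "age": clin["age"].astype(float),
})
model = cox_multivariate(covariates, cohort.clinical,
                         references={"stage_tnm": "i"})
print("\nmultivariate Cox (HR with 95% CI):")
print(model.summary.round(3).to_string())

nomogram = build_nomogram(model, horizons=(1.0, 3.0, 5.0))
points = nomogram.points(model.design)["total"]
auc = time_dependent_auc(points, cohort.clinical, horizons=(1.0, 3.0, 5.0))
print("\ntime-dependent AUC of nomogram total points:")
print(auc.round(3).to_string())
# A score-high HR near 2 independent of stage and age, with AUC above
# 0.65 at every horizon, mirrors the prognostic value the score is
# designed to capture.
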