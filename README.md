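# m6ametab

Expression-based subtyping of hepatocellular carcinoma (HCC) by its
N6-methyladenosine (m6A) regulator landscape, with a prognostic
m6Ascore and metabolic subgrouping.

m6A is the most abundant internal mRNA modification; it is deposited
by *writer* proteins, removed by *erasers* and recognised by
*readers*. Tumors differ in how strongly this machinery is expressed,
and in HCC the resulting modification patterns track metabolic state,
stage, survival and treatment response. This package implements the
full analysis pipeline as a tested Python library for bioinformaticians
working with bulk expression cohorts (log2 FPKM matrices plus clinical
tables):

1. **Modification-pattern clustering** — k-means on a curated 23-gene
   regulator panel (20 genes after removing the IGF2BP readers), with
   the cluster count chosen by a majority vote of four validity
   indices (silhouette, Calinski–Harabasz, Davies–Bouldin, gap
   statistic) over k = 2..15, k-means restarted 25 times.
2. **Single-sample enrichment (GSVA-style)** — per gene, a
   Gaussian-kernel CDF transform (bandwidth sd/4); per sample, a
   rank-based random walk over each gene set with the symmetric rank
   statistic r = |G|/2 − rank + ½; the score is the signed sum of the
   maximum positive and minimum negative walk deviations, bounded in
   [−1, 1].
3. **m6A gene signature and m6Ascore** — empirical-Bayes moderated
   t-tests between patterns (adjusted p < 0.05, |log2FC| > 1), a
   univariate Cox screen of the DEGs, a split at hazard ratio 1 into
   risk genes C_i and protective genes C_j, per-gene min–max scaling
   to [−1, 1], and

   m6Ascore = Σ_i X_i − Σ_j Y_j,   X ∈ C_i, Y ∈ C_j,

   with cohorts divided at the median score into high/low groups.
4. **Metabolic subtyping** — the same clustering procedure on
   enrichment scores of 50 metabolism-associated pathways; groups are
   named LML/LMI/LMH by their mean lipid-pathway enrichment, and the
   most altered category is found from normalized between-cluster
   centroid distances.
5. **Prognostic evaluation** — Kaplan–Meier curves and log-rank tests,
   multivariate Cox models (score group, TNM stage, age), a nomogram
   point system, IPCW cumulative/dynamic AUC at 1/3/5 years, and
   chi-square association reports (stage, subgroup, sorafenib
   response).

A first-class synthetic-cohort generator (`m6ametab.simulate`)
emulates the statistical structure the analysis assumes — three latent
modification patterns, an anti-correlated metabolic axis,
pattern-linked hazard, stage and response — so the entire pipeline is
testable without external downloads.

## Worked example

```python
from m6ametab import (SimulationConfig, simulate_cohort, default_panel,
                      m6a_clusters, ClusteringConfig)

cohort = simulate_cohort(SimulationConfig(seed=1))
assignment, means = m6a_clusters(cohort.expression, default_panel(),
                                 ClusteringConfig(seed=1))
print(assignment.k)                      # 3
print(assignment.selection_report.attrs["votes"])
# {'silhouette': 3, 'calinski_harabasz': 3, 'davies_bouldin': 3, 'gap': 3}
```

All four indices vote for three clusters, and the assignment recovers
the generator's latent patterns with adjusted Rand index 0.94.
Continuing through the signature (`examples/04_signature_and_score.py`)
prints

```
signature: 32 risk (HR>1), 103 protective (HR<1) genes
mean m6Ascore by latent pattern:
1   -32.7
2     6.1
3    30.6
```

— the m6Ascore rises monotonically across the patterns, so the median
split separates low- from high-methylation tumors. The survival stage
(`examples/06_survival_and_nomogram.py`) prints a score-high hazard
ratio of 2.03 (95% CI 1.51–2.74) independent of stage and age, and
1/3/5-year AUCs of 0.73/0.78/0.79 for the nomogram total points.

The `examples/` directory contains one short narrative script per
capability (simulation, clustering, enrichment, scoring, metabolic
subtyping, survival). A thin CLI covers fixture generation and full
runs:

```bash
m6ametab simulate --out fixture/ --seed 1
m6ametab run --expression fixture/expression.tsv \
             --clinical fixture/clinical.tsv \
             --gene-sets fixture/gene_sets.gmt \
             --categories fixture/categories.tsv --out run/ --seed 1
```

## Layout

```
src/m6ametab/
  panel.py        curated m6A regulator panel (roles, clustering subset)
  io.py           expression/clinical/GMT readers and validators
  simulate.py     synthetic cohort + gene-set generator
  gsva.py         single-sample enrichment statistic
  clustering.py   cluster-number vote, k-means, PCA view
  diffexpr.py     moderated t-test, BH adjustment, DEG calling
  score.py        Cox screen, signature partition, m6Ascore
  metabolic.py    metabolic subtyping, category distances, LML/LMI/LMH
  survival.py     KM, log-rank, multivariate Cox, nomogram, AUC(t)
  report.py       chi-square cross-tabs, correlations, alluvial table
  pipeline.py     end-to-end orchestration with run manifests
  cli.py          `m6ametab simulate` / `m6ametab run`
```

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
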