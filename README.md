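# qsp — disease-state drug repurposing for fatty liver disease

`qsp` implements a quantitative systems pharmacology (QSP) pipeline for
non-alcoholic fatty liver disease (NAFLD): starting from a patient-by-gene
expression matrix it derives per-patient pathway-enrichment profiles,
clusters patients into molecular disease states, builds category-stratified
disease gene signatures, screens those signatures against a perturbation
database by connectivity mapping to find signature-reverting compounds, and
complements that ranking with the network proximity of each drug's targets
to a disease subnetwork. A bootstrap evaluation harness for a penalized
multinomial classifier ties model-system samples back to patient disease
classes. Every input can be generated synthetically, with ground-truth
labels, so the whole pipeline is testable without any external download.

It is written for computational biologists and systems pharmacologists who
want the individual statistical components (single-sample enrichment,
moderated-t differential analysis, KS connectivity scores, permutation
calibration, degree-matched proximity nulls) as a tested library, with a
thin `qsp` command-line interface over them.

## The statistics at the core

**Single-sample pathway enrichment.** For gene *i* and sample *j* the
expression value is converted to a cross-sample cumulative density
ẑᵢⱼ (Gaussian or Poisson kernel, or a plain ECDF). Within each sample
genes are ranked by ẑ and a weighted Kolmogorov–Smirnov random walk over
the ranked list is computed per gene set; the enrichment score is the sum
of the largest positive and largest negative walk deviations, in [−1, 1].
Patients are clustered on standardized enrichment profiles with Ward
linkage on 1 − Pearson distances and the dendrogram cut to three clusters;
cluster robustness is measured by bootstrap Jaccard coefficients.

**Moderated t.** Per-feature pooled variances s²_g are shrunk toward a
prior s₀² with prior degrees of freedom d₀ estimated by moment matching of
the log-variance distribution: s̃²_g = (d₀s₀² + d_g s²_g)/(d₀ + d_g), and
t̃_g = Δ̄_g / (s̃_g √(1/n_A + 1/n_B)) with d₀ + d_g degrees of freedom.
With d₀ = 0 this is exactly the pooled two-sample t.

**Connectivity score.** A disease signature is a pair of disjoint up/down
gene sets. Against a perturbation instance's gene ranking, two KS
enrichment statistics ES_up and ES_down are computed
(a = maxⱼ(j/t − V(j)/n), b = maxⱼ(V(j)/n − (j−1)/t); ES = a if a > b else
−b). If ES_up and ES_down share a sign, CS = 0; otherwise
CS = (ES_up − ES_down)/2. CS near −1 marks a predicted signature
reverter. Significance comes from a permutation null of random
(instance, gene-set) pairs; compounds are summarized per query by their
most negative CS or by the max-quantile statistic (33rd/67th percentile of
cell-type-normalized CS, larger magnitude wins) and prioritized by
frequency of appearance across the twelve signature queries.

**Network proximity.** For drug targets T and disease module S in a
protein-interaction network, d(S,T) = (1/|T|) Σ_t min_s sp(s,t); z =
(d − µ)/δ against 1000 draws of degree-matched random node sets
(logarithmic degree bins). Negative z: targets are closer to the disease
module than degree-matched chance.

## Worked example

```python
from qsp.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    out_dir="scratch/demo", seed=1,
    cohort=dict(
        n_genes=600, n_pathways=48, genes_per_pathway=10,
        n_samples_per_class={"normal": 8, "steatosis": 8, "lobular": 8, "fibrosis": 8},
    ),
    perturb=dict(n_compounds=10, n_instances_per_compound=2, n_reverters=2),
    network=dict(n_nodes=150, n_drugs=6, n_disease_nodes=15),
    cmap_n_perm=500, proximity_n_rand=50, stability_boot=5,
)
out = run_pipeline(cfg)

import json, pandas as pd
print(json.load(open(out / "cluster_summary.json")))
print(pd.read_csv(out / "priority.tsv", sep="\t").head(2))
print(pd.read_csv(out / "proximity.tsv", sep="\t").head(2))
```

prints (seed 1):

```
{'n_clusters': 3, 'jaccard': {'1': 0.89, '2': 0.78, '3': 0.74}, 'chi2': 64.0, 'chi2_p': 6.9e-12}
  compound_id  frequency  best_rank  queries_hit
0      cpd000          2          1   s1:1;s9:10
1      cpd001          2          1  s2:1;s10:10
      drug    d     mu  delta      z  n_targets_used
0  drug000  0.5  1.505  0.341 -2.948               4
1  drug001  0.5  1.530  0.359 -2.867               4
```

Three enrichment clusters, all bootstrap-stable (Jaccard ≥ 0.74) and
significantly associated with the planted diagnosis labels (χ² = 64,
p = 6.9 × 10⁻¹²); the two planted reverter compounds (`cpd000`, `cpd001`)
lead the cross-query frequency prioritization; and the planted proximal
drugs get the most negative network-proximity z-scores. The same stages
are exposed on the command line
(`qsp simulate|enrich|cluster|de|signatures|cmap|proximity|evaluate|run`).

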