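# Methods

This note records the models and procedures implemented in `qsp`, the
assumptions behind them, the parameter choices that matter, and the limits
of what the synthetic-data tests can show.

## Pipeline overview

The pipeline operates on a genes × samples expression matrix for a cohort
spanning four liver disease classes (normal, steatosis, lobular
inflammation, fibrosis) and runs in three conceptual units:

1. **Disease states.** Per-sample pathway enrichment profiles are
   computed, standardized, and clustered; pairwise cluster comparisons are
   analyzed for differential genes and differentially enriched pathways;
   the differential genes lying on enriched pathways annotated with one of
   four disease-process categories (C1 insulin resistance/oxidative
   stress, C2 cell stress/apoptosis/lipotoxicity, C3 inflammation, C4
   fibrosis) form twelve up/down gene signatures (3 comparisons × 4
   categories, indexed s1–s12 row-major).
2. **Connectivity mapping.** Each signature is scored against every
   instance of a perturbation database (compound × cell type × time ×
   dose, each carrying a full signed gene profile); compounds are
   summarized per query and prioritized by frequency of appearance across
   the query top lists.
3. **Network proximity.** Drugs are independently ranked by the
   standardized distance of their protein targets to a disease subnetwork
   within a background interactome.

A fourth, optional unit evaluates a penalized multinomial classifier of
disease class by stratified bootstrap.

## Single-sample enrichment

For gene *i*, sample *j*, the expression statistic is a cross-sample
kernel CDF estimate: Gaussian kernel with per-gene bandwidth s<sub>i</sub>/4
(the conventional choice for log-scale data), a Poisson kernel for raw
counts, or the plain ECDF. Genes are ranked per sample by this statistic,
the symmetric rank statistic |p/2 − r<sub>ij</sub>| weights a KS random
walk over the ranked list, and the enrichment score is the sum of the
largest positive and the largest negative walk deviation (the
"difference of extreme deviations" variant, chosen because it responds to
bidirectional shifts within a set; the single max-deviation variant is
available via `mx_diff=False`). Scores live in [−1, 1]. At least two
samples are required (the CDF is estimated across samples); constant gene
rows are excluded with a warning; a set with no gene in the universe
scores as missing.

Note the cross-sample semantics: a gene's contribution reflects its
standing *across samples*, not its within-sample magnitude, so enrichment
values are relative to the cohort analyzed.

## Clustering and stability

Sample profiles are standardized per pathway row (mean 0, sample SD 1;
constant rows become zeros with a warning rather than being dropped, so
matrix shape is stable). Pairwise distance is 1 − Pearson correlation;
linkage is Ward applied directly to that distance matrix (the
Ward.D-on-distances convention — documented, since applying Ward to
non-Euclidean distances is a convention, not a theorem), and the tree is
cut to exactly `cut_level` clusters (default 3). Standardizing before a
correlation distance is harmless: correlation is affine-invariant per row,
so the result is insensitive to the order of those two steps.

Stability: each bootstrap resamples samples with replacement, re-clusters
the unique drawn samples, and matches each original cluster to its
maximum-Jaccard counterpart (ties broken by counterpart size, then label
order); the per-cluster mean over bootstraps is reported, with 0.6 the
conventional dissolution threshold. Cluster–covariate association uses
Pearson's chi-squared without continuity correction.

## Differential analysis

Counts are transformed to log2-CPM with a 0.5 pseudocount; this replaces
full precision-weighted linear modeling, a deliberate simplification —
the package does not model the mean–variance trend of counts, which is
acceptable for the moderate-depth synthetic data it is validated on and
should be revisited for shallow real libraries. Quantile normalization
(columns forced onto the mean order-statistic vector, ties averaged) is
available for matrices with distributional batch artifacts.

The moderated t shrinks per-feature pooled variances toward a prior:
s̃² = (d₀s₀² + d·s²)/(d₀ + d), with (d₀, s₀²) estimated by matching the
mean and variance of log s² to their theoretical values under a
scaled-inverse-chi-squared model (digamma/trigamma moments; the trigamma
inverse is solved by Newton iteration). p-values use d₀ + d degrees of
freedom. Degenerate regimes: d₀ = 0 reduces to the ordinary pooled t;
d₀ → ∞ pools every feature to s₀² and uses the normal reference; if the
observed spread of log s² is no larger than its sampling spread, complete
shrinkage (d₀ = ∞) is reported. Multiple testing uses Benjamini–Hochberg
throughout (delegated to statsmodels).

Preranked gene-set analysis ranks features by a score (typically the
moderated t), runs the weighted running sum with weight |score|¹, and
calibrates by gene-label permutation (equivalently random same-size sets)
with the add-one estimator, sign-stratified; nulls are cached per set
size. Gene-permutation rather than sample-permutation nulls are used
because the input is a precomputed ranking. Concordance between two
result tables is assessed on sets significant in both (q < α): same
direction = concordant, opposite = discordant; sets significant in only
one table are excluded from both percentages.

## Signatures

For each comparison and category: pathways with q < α (default 0.001)
carrying the category are selected, their member genes pooled, the pool
intersected with the comparison's differential genes at q < α, and the
result split by the *gene-level* direction into up/down sets. Empty
signatures are emitted rather than dropped so the s1–s12 indexing is
stable; downstream queries skip them with a logged warning. The
s-index ↔ (comparison, category) mapping is this package's documented
convention (comparisons in their canonical order × C1..C4, row-major).

## Connectivity mapping

`ks_enrichment` implements the classic unweighted two-sided KS statistic
on hit positions (a = maxⱼ(j/t − V(j)/n), b = maxⱼ(V(j)/n − (j−1)/t);
ES = a if a > b else −b); a weighted (exponent-1) variant is available.
The combine rule is exact: sign-agreeing ES pairs give CS = 0, an ES of
exactly 0 is treated as agreeing with anything (conservative), otherwise
CS = (ES_up − ES_down)/2. A one-sided signature (one empty side) is
scored by its single statistic, CS = ES_up or −ES_down, so negative CS
always means reversal. Note the discrete-statistic bound: a perfect
reverter attains ES_up = −1 exactly but ES_down = 1 − t/n, so CS reaches
−1 only as the universe grows.

Permutation p-values draw `n_perm` (default 50,000) random
(instance, gene-set) pairs matched to the query's up/down sizes; p is
two-sided on |CS| with the add-one estimator and BH-adjusted per query.
Because the null CS has an atom at 0 (sign-agreeing pairs, roughly half
the draws), this deterministic p-value is necessarily non-uniform: it is
exactly uniform below the nonzero-CS mass and conservative above it
(P(p ≤ α) ≤ α at every α). For calibration studies the randomized
p-value for discrete statistics (`smooth=True`;
p = (#{>} + U·(1 + #{=}))/(n_perm + 1), U ~ U(0,1)) is provided, which is
exactly uniform under the null. The pipeline default stays deterministic
and conservative.

Compound summaries: `most_negative` takes the minimum CS over a
compound's instances (even when positive — the ranking is by score order,
not sign). `max_quantile` first normalizes CS within cell type by
dividing each score by the mean |CS| of same-signed scores in that cell
type (an identity-normalization option exists; the transform is recorded
in output metadata), then takes Q_lo = 33rd and Q_hi = 67th
linear-interpolation percentiles and reports whichever is larger in
magnitude, ties going to Q_lo (reverter-favoring). Prioritization keeps,
per query, the `top_n` (default 20) compounds by ascending summary that
pass q < 0.05 on the compound's best instance (the instance-vs-summary
level of this filter is ambiguous in general; the best-instance rule is
logged), then orders compounds by frequency of appearance across queries,
best within-query rank, and compound id.

## Network proximity

d(S,T) is the average over targets of the unweighted hop distance to the
nearest module node, computed by multi-source BFS. Targets absent from
the network or unreachable from the module are excluded from the average
and counted (a diameter+1 penalty mode exists behind a flag; the average
is simply undefined for infinite distances, so exclusion is the default).
The null redraws degree-matched stand-ins for both S and T per iteration
(a targets-only mode is available — which group the reference
randomization varies is a genuine modeling choice, so both ship);
degree matching uses logarithmic (doubling) degree bins with per-bin
counts preserved exactly in every draw. z = (d − µ)/δ over `n_rand`
(default 1000) draws; a degenerate null (δ = 0) reports z as missing with
a warning. Note that z is centered at zero for null targets only
*marginally* over networks: conditional on one fixed network and disease
set, the set's idiosyncrasy biases z, so self-consistency checks average
across independently generated networks.

## Classifier evaluation

Feature preparation: variance-filter each matrix to its top `top_n`
genes independently (filter-then-intersect), intersect, and standardize
each matrix gene-wise on its own samples (reusing training moments for
the new data is a documented alternative; the independent standardization
matches the procedure evaluated here). Evaluation: `n_sets` (default
100) stratified splits with per-class training size round-half-up of
0.7·n; the classifier — a pluggable contract satisfied by default by a
saga-solver multinomial elastic-net logistic regression (mixing parameter
α = 0.95, strength chosen by internal cross-validation, 5 folds by
default) — is fitted per split and scored one-vs-rest
(sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)) per class, with
mean and SD over splits. The evaluation protocol, not the optimizer, is
the point; any solver exposing `fit`/`predict`/`predict_proba`/`coef_`
can be plugged in. The final model is fitted on all labeled samples,
reports its nonzero-coefficient genes, and classifies new samples with
probabilities summing to one.

## Synthetic data

The generators produce inputs with the statistical structure the analysis
assumes, plus ground truth:

* **Cohort** — negative-binomial counts (gamma-Poisson; variance
  m + φm²), gene baseline means log-normal (median 100, log-SD 1),
  library sizes log-normal with CV ≈ 0.2, default class sizes 36/46/50/50
  (the study cohort's composition), default dispersion 0.1 and shift
  2 log2 units. Half the pathways (disjoint gene blocks) are unshifted;
  the rest are planted in up/down pairs per (disease class, category)
  so every downstream signature carries genes on both sides; pairs cycle
  classes and categories with coprime periods, covering all 12
  combinations when ≥ 24 pathways are shifted (hence the default of 48
  pathways). An optional batch artifact multiplies a random sample subset
  by gene-wise log-normal factors.
* **Perturbation database** — per-instance standard-normal gene scores;
  each reverter compound is assigned a signature (cycling through the
  non-empty ones) and its instances subtract/add `reversal_strength`
  (default 6, i.e. several noise SDs) on the signature's up/down genes.
  The exchangeable-noise model is a stand-in: real perturbation profiles
  have correlated, heavy-tailed noise that is not characterized here.
* **Network** — preferential-attachment graph (heavy-tailed degrees, so
  the degree-matched null is non-trivial; m(n−m) edges), a uniformly
  drawn disease node set, proximal drugs targeting the disease set and
  its first neighbors, distal drugs targeting uniformly outside that halo.

What passing tests on these data do **not** show: recovery on real
cohorts (no confounding beyond the optional batch factor, no
gene–gene correlation, no library-composition effects), realistic liver
biology, dose–response structure within compounds, or identifier
harmonization between expression, perturbation and network namespaces
(a single shared namespace is assumed).

## Problem sizes and numerical choices

Default test and acceptance runs use desk-scale inputs chosen as the
smallest sizes at which every planted effect is comfortably resolvable:
cohorts of ~40–180 samples over 600–2000 genes and 24–48 pathways,
perturbation databases of 150–200 instances with 2000-draw permutation
nulls, and 300-node networks with 150–200-draw proximity nulls.
Quantiles use linear interpolation between order statistics (alternatives
differ at small n). All randomness flows from a single top-level seed
through `numpy.random.SeedSequence` substreams, one per pipeline stage,
so stages are independently rerunnable; set iterations feeding any RNG
are sorted first, so runs are reproducible across processes. Ties are
broken deterministically everywhere (documented per operation).

## Known limitations

* No precision weighting or mean–variance trend modeling for counts.
* Surrogate-variable-style latent confounder correction is out of scope;
  only the explicit batch factor in the generator poses that problem.
* The cell-type normalization inside the max-quantile summary and the
  S/T randomization scope of the proximity null are conventions chosen
  from reasonable alternatives; both are configurable and recorded in
  outputs.
* GSVA-style scores depend on cohort composition; adding samples changes
  all scores.
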