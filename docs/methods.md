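# Methods

This note records the models behind each stage, the defaults and why they
were chosen, what the synthetic generators do and do not emulate, and the
numerical conventions a user relying on exact reproducibility should know.

## Cell QC and normalization

Cells pass QC iff UMI total > `min_umi` (default 2000, strict), detected
genes in [`min_genes`, `max_genes`] (500–7000, inclusive at both ends),
mitochondrial percentage < `max_pct_mito` (10%, strict), and predicted
singlet. The mixed strict/inclusive boundary semantics are deliberate and
covered by boundary tests; `filter_cells` logs per-criterion removal counts
(criteria counted independently). Normalization is total-count scaling to
`target_sum` = 10,000 per cell followed by log1p — the common convention for
UMI data; the raw counts layer is never modified, so filtering and
normalization are idempotent.

## Gap-score markers

Specificity is measured after max-normalizing the per-cluster means of a
gene, as 1 minus the second-highest normalized mean. This is scale-free:
multiplying the whole log-normalized layer by a positive constant leaves
every gap unchanged (property-tested). Conventions:

* Ties for the top cluster break toward the higher expressing fraction,
  then the lexicographically smaller cluster name — determinism over
  arbitrariness.
* Genes with all-zero cluster means are dropped, not errors.
* Candidate thresholds (top mean > 0.4, expressing fraction > 10%) are
  strict inequalities.
* The confirmatory test is a two-sided Wilcoxon rank-sum of the top cluster
  against **all** other cells (one-vs-rest, the standard marker contrast),
  with Benjamini–Hochberg correction across the candidate list.

Refinement targets use on bulk tissue: a marker is kept only if its mean
expression in every *other* major cell type stays strictly below
`leakage_ratio` (default 0.5) times its top-cluster mean. This replaces a
manual curation step with an explicit, parameterized rule; with a very
large `leakage_ratio` every marker survives.

## Signature scores

A gene-set score is the arithmetic mean of the observation's expression over
the set genes present in the matrix (absent genes dropped with a warning,
entirely absent sets are errors). On bulk cohorts the same operation runs on
per-gene z-scored expression ("subcluster score"), so scores are
cohort-relative by construction.

## Survival cut-off scanning

Cohort expression is standardized per gene within each cohort (sample sd,
ddof = 1; constant genes dropped). Q1/Q3 use linear-interpolation quantiles
(the convention is parameter-free in numpy and exposed nowhere else; other
conventions move candidates by at most one grid cell). The candidate grid is
anchored at Q1 and advances in steps of 0.04 without exceeding Q3 — a step
rule, not an endpoint rule, so Q3 itself appears only if it lies exactly on
the grid. Score-high means strictly greater than the cut-off. A `min_group`
= 5 guard skips candidates that would leave a near-empty group, because the
log-rank statistic degenerates there; skipped candidates are recorded. Ties
in the minimum p break toward the candidate nearest the score median.

No multiplicity correction is applied across the grid — the scan
deliberately reproduces the minimum-p procedure, and the suite documents the
resulting optimism (under a null cohort the optimal p is stochastically
smaller than uniform). The honest check of a scanned cut-off is
`cross_validate_cutoff`: the cut-off trained on one cohort is applied
unchanged to an independent cohort and judged by that cohort's log-rank p.

The log-rank test and Kaplan–Meier estimator delegate to lifelines; the test
suite verifies them against an independent life-table implementation, a
hand-tabulated four-observation example, and a 10,000-shuffle permutation
oracle. For the permutation comparison at n = 20 the tolerance is 0.03
absolute: Monte-Carlo error alone is ~0.005, but the chi-square reference
distribution is itself an approximation at that sample size.

## Cycling deconvolution

The classifier is a multinomial logistic regression with L2 penalty, C = 1,
trained on non-cycling cells with the cell-cycle genes removed from the
feature space (otherwise the shared cycling program dominates and the
problem becomes unlearnable by construction). Hyperparameters are fixed —
no search — because determinism matters more here than squeezing accuracy;
a stratified 20% holdout of the reference reports accuracy before refitting
on the full reference. The enrichment z-test is the pooled two-proportion
test, two-sided, uncorrected by default (a `correction` option applies any
statsmodels multiple-testing method). Each cluster is tested one-vs-rest
against the pooled remainder; a cluster absent from the non-cycling
compartment yields infinite enrichment and an `undefined` flag.

## Composition and diversity

Proportions are computed within compartments so cancer-cell and CAF
compositions remain separately interpretable; concatenated with equal
weight for clustering (an interpretation choice — no reweighting by
compartment size). Clustering is agglomerative with Ward linkage on
Euclidean distance, cut at k = 3 by default; rows are sorted by patient id
before linkage and groups relabelled by first appearance, making the labels
invariant to input row order. Shannon diversity uses the natural log
(`base` exposed); zero proportions contribute nothing.

## Spatial neighborhood enrichment

"Up to the third most proximal spots" is read as three *distance shells* —
the three smallest distinct realized center-to-center distances from the
focal spot — rather than three nearest individual spots, which is
tie-degenerate on a lattice. Shells are computed per focal spot, so boundary
spots get their own (smaller) neighborhoods. An interior spot of a square
lattice has 12 neighbors in three shells (4 at d=1, 4 at d=√2, 4 at d=2);
an interior hex spot has 6 in the first shell. Distances are rounded to
1e-6 lattice units before grouping, absorbing floating-point noise in hex
geometry.

The focal spot is excluded from its own neighborhood (otherwise the focal
type's own high value trivially inflates its self-enrichment); the expected
profile uses the mean abundance over **all** spots, high spots included.
Per-focal-type aggregation is the mean of per-spot observed/expected ratios
(`aggregate="ratio_of_sums"` is selectable). Across samples, directional
scores are unweighted means over the samples in which the focal type has
high spots. An edge requires both directional scores strictly above 1;
types that are never focal keep their node, flagged, with no edges.

## Synthetic generators

`simulate_cells` draws gamma-Poisson (negative-binomial) counts with
variance μ + αμ² (dispersion α = 0.3), per-gene baseline means log-normal
(σ = 0.5) around `nb_mean` = 2 for realism. Marker genes of cluster k have
mean multiplied by `marker_fold_change` (default 8) inside k only; marker
sets are disjoint by construction. The cycling population is drawn from
randomly chosen parent clusters with a dedicated 30-gene cycle program at
8-fold superposed on the parent profile — mimicking how proliferation
transcriptionally converges otherwise distinct cells. Ten low-expressed
mitochondrial genes provide the mito percentage. When `qc_fail_fraction` >
0 the generator first deterministically nudges every cell to pass the
default QC thresholds, then modifies the selected cells to violate exactly
one criterion each (thinned counts for low UMI, count concentration for low
gene complexity, inflated mitochondrial counts, or a doublet flag), so the
filter's retained set is exactly the complement of the planted failures;
this mode needs ≥ 1000 genes so passing cells clear the detected-gene
floor. With `qc_fail_fraction` = 0 counts are pure NB draws.

`simulate_cohort` mixes the true cluster mean profiles with Dirichlet(1)
weights per sample and adds heteroscedastic Gaussian noise with sd equal to
50% of each gene's mean profile level (a typical inter-tumor coefficient of
variation; a floor keeps silent genes from being constant). After per-gene
standardization the planted signature genes correlate at roughly r ≈ 0.5 —
strongly co-regulated but not duplicated. Survival is a two-group
exponential proportional-hazards model: baseline median OS 24 months,
hazard multiplied by `hazard_ratio` for samples whose signature score
exceeds the `true_cutoff_quantile` quantile. The two-group (rather than
continuous-score) hazard makes the planted cut-off a well-defined recovery
target. Censoring is an independent exponential whose rate gives the
baseline group a censoring probability of `censor_rate`; `censor_rate` = 0
yields fully observed cohorts.

`simulate_spatial` lays spots on a square or hex lattice (offset rows at
√3/2 row spacing, matching Visium geometry) and plants: one exactly
constant type above the high-spot threshold (its enrichment ratio is 1.0
*exactly*, a sharp oracle), a co-localized pair sharing one circular
domain, a segregated pair in two domains separated by far more than three
shells, and two sub-threshold background types. Domain abundances sit at
5–6 against a < 0.5 background, so high-spot calls equal domain membership
exactly.

### What the generators do not emulate

Ambient RNA, doublet expression profiles (doublets exist only as a QC
flag), batch effects, patient-level compositional structure in the cell
simulator, gene-gene correlation beyond cluster membership, non-proportional
hazards, and spatial abundance gradients or partial-volume mixtures at
domain edges. Passing recovery tests therefore demonstrates correctness of
the *procedures* under their stated models, not robustness to every
real-data pathology.

## Problem sizes and observed behavior

The suite runs the stages at deliberately compact sizes: cell tables of
400–5000 cells × 300–2000 genes, cohorts of 200 samples, 50 scan
replicates, 200 null replicates, 16×16 spot grids × 20 seeds. At these
sizes marker recovery at fold 8 is essentially complete (and at chance for
fold 1), cycling parent recovery is ~100%, cross-cohort cut-off transfer is
significant in ~100% of replicates with null cohorts at the nominal 5%,
composition archetypes are recovered at adjusted Rand ≈ 0.96, and planted
co-localized/segregated pairs produce/withhold mutual edges in 20/20 grids.

One caveat is measured and worth stating: recovering the planted survival
cut-off to within a single 0.04 grid step succeeds in only ~65–72% of
replicates under these conditions. The scan localizes the threshold to
within a few *samples* (median error 1–2 of 200), but near the score median
one 0.04 step spans only ~4 samples, and the minimum-p criterion
occasionally jumps several steps — the same optimism the null-scan property
documents. Tightening one-grid-step recovery further would require either
larger cohorts or a signature whose score distribution is wider relative to
the fixed step; cross-cohort transfer, the scientifically meaningful
validation, is unaffected.
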