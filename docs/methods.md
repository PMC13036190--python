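# Methods

## The classification model

The package treats "detected as a DEG" as a per-contrast Bernoulli event
determined by two thresholds: |log2FC| ≥ `lfc_min` (closed bound, default
0.5) and FDR-adjusted p < `fdr_max` (open bound, default 0.05). The
closed/open convention follows the usual reading of "the log2FC = 0.5
threshold" (a gene sitting exactly on the line is beyond it) and
"p < 0.05". Classification over the three contrasts (L, S, LS vs a
common wild-type control) is a pure set rule on the detection triple:

| detected in L | detected in S | detected in LS | class  |
|---|---|---|---|
| yes | no  | yes | L_DEG  |
| no  | yes | yes | S_DEG  |
| yes | yes | yes | LS_DEG |
| any other pattern | | | OTHER |

The classification universe is the intersection of the gene sets of the
three tables; genes absent from any table are excluded with a logged
count, since a detection triple is undefined for them.

Co-regulation of the shared program is summarized by the Pearson
correlation of (log2FC in L, log2FC in S) over all LS-DEGs, plus a
three-way concordance label per gene: *inverse* when the two fold changes
have opposite signs and **both** magnitudes are ≥ `lfc_min` (a gene with
one sub-threshold effect is evidence of nothing and is labeled
*sub-threshold*, not inverse); *concordant* otherwise. The inverse
fraction uses all LS-DEGs as denominator.

## The synthetic-data generator

`simulate_contrasts` emulates the data-generating picture the analysis
assumes: a gene universe partitioned into L-specific, S-specific, shared
(LS) and null classes, allocated **exactly** by largest-remainder
rounding of the configured proportions (defaults 911/814/5528/3749 of
11002, the reference study's dataset composition). Effect magnitudes are
truncated normals bounded below by `effect_floor` (default 0.5, the
fold-change threshold), so every planted effect is detectable by
construction; signs are up/down with equal probability.

Shared-class effect pairs are coupled through a Gaussian copula. The
copula correlation is **calibrated** — via the Hermite-polynomial
expansion of the magnitude transform and a scalar root-find — so that the
*population Pearson correlation of the full LS scatter*, including the
planted inverse-regulated fraction f, equals `rho_LS`. With magnitude
mean m, variance v and copula-induced magnitude covariance c(ρ_g), the
scatter correlation is (1 − 2f)(m² + c(ρ_g))/(m² + v); the generator
solves this for ρ_g and raises with the feasible `rho_LS` interval when
the target is unreachable (e.g. tight magnitude spread caps how far below
1 − 2f the correlation can fall). We calibrate the *overall* scatter
rather than the concordant subset because the quantity the analysis
reports — and the quantity printed for the real dataset — is the
correlation of the full LS scatter with inverse genes included.

Inverse genes are Bernoulli(f) draws among LS genes, sign-flipped in the
S contrast, with both magnitudes above the floor by construction. The
double-mutant (LS-table) effect of a shared gene is the mean of its two
single-mutant effects plus Normal(0, `effect_magnitude_sd`/2) noise; for
inverse genes the raw mean of two opposite-sign effects would typically
sit below the detection floor and make the gene unclassifiable, so the LS
effect is instead the mean *magnitude* carrying the sign of the dominant
effect. Consequences of the LS-table noise: with the default
`effect_magnitude_sd` = 0.8, a few percent of planted LS genes fall below
the fold-change floor in the LS contrast and classify as OTHER; setting
`effect_magnitude_sd = 0` gives the noise-free regime in which planted
labels are recovered exactly.

Significance is generated directly on both scales: raw p ~ U(0, α/10)
for true effects and U(0, 1) for nulls; adjusted p is drawn below α for
true effects and above α for nulls (α = 0.05), with configurable
false-negative/false-positive rates injecting threshold misses. Adjusted
values are *not* re-derived by BH from the raw p — applying BH to the
mixed uniforms would let the smallest null order statistics cross the
threshold and break the exact separability that the noise-free tests
rely on; the loaders accept adjusted p that is not a monotone function of
raw p for exactly this reason.

`simulate_cohort` emulates the TPM cohort: per-gene log2-normal baseline
(mean 3, sd 2 in log2 TPM units), additive planted log2 shifts for
selected (genotype, stage) groups, Gaussian dispersion (default sd 0.5,
log2 units) per sample, then renormalization of every sample to 10⁶
(TPM convention). Default group sizes follow the reference cohort's
genotype × stage composition (237/7/3/51 early, 61/2/2/18 late). Note the
renormalization slightly attenuates planted fold changes when the shifted
genes carry a non-trivial share of the library (≈ 0.1 log2 units for 50
of 2000 genes shifted by +2); recovery tests use tolerances that absorb
this. What the generator does **not** model: UMI-level counts, cell-level
heterogeneity, batch effects, gene–gene correlation beyond the planted
structure, or realistic mRNA length effects — so passing recovery tests
demonstrate correctness of the analysis logic under the assumed model,
not robustness to real single-cell artifacts.

## Enrichment workflow

The over-representation test is the one-sided hypergeometric upper tail
of the observed overlap between a query list and each gene set restricted
to the universe, with BH adjustment across the terms of each run. The
default universe is the classification universe intersected with the
genes annotated in at least one set (standard ORA practice). Terms with
zero hits keep p = 1 and fall to the filter. The per-class queries are
split by fold-change sign in the class's defining contrast, tested as
up/down/complete runs, and merged term-wise keeping the largest
intersection (ties: smaller adjusted p, then complete > up > down).
The retention filter is hits > 3 and FDR < 0.05; `gene_ratio` is
hits / full term size.

"Hierarchical k-means with silhouette selection" is implemented as both
halves of that hybrid phrase: k-means over the rows of the term-term
Jaccard matrix (50 restarts, fixed seed) for each candidate k, selection
by maximum mean silhouette on distance = 1 − similarity, plus an
average-linkage leaf ordering of the same distance for display. An
all-equal similarity matrix degenerates to a single cluster with a
warning. Per-cluster unique gene sets are the union of the cluster's
intersections minus genes appearing in any other cluster.

## Cohort comparison

Correlation and the stage-stratified DEA operate on log2(TPM + 1).
Subgroups are defined by three-valued mutation-flag requirements
(required true / required false / don't-care) with an optional stage
filter; the shipped `exclusive_genotype_subgroups` mirrors the
cell-line-matched split (exactly one of LKB1/SMARCA4/TP53 mutated, or
none for WT). Cross-dataset correlation compares log2FC-vs-WT profiles —
subgroup means minus the WT subgroup mean on the cohort side, contrast
log2FC on the cell-line side — over the shared gene index (≥ 30 genes),
which makes bulk-cohort and contrast data commensurable without assuming
a common absolute scale. The stage-stratified DEA uses the same
`Thresholds` object as the contrast classifier (one object enforces the
"identical parameters" contract), a two-sided Wilcoxon-Mann-Whitney test
per gene, and BH within each (genotype, stage) stratum; groups below
`min_group_size` (default 2) are skipped with a warning. PCA reduction
retains the smallest component count reaching 80% explained variance,
capped at 10 (both configurable; the cap matters for isotropic inputs
where the variance curve is flat). Heatmap scaling offers row min–max
(to [0, 1]) and row z-scores; constant rows map to 0 by convention in
both modes.

## Numerical and design choices

- Gene identifiers are case-sensitive opaque strings; no symbol mapping.
- DE-table readers accept TSV/CSV with remappable column names; a missing
  adjusted-p column is BH-derived from raw p and flagged in provenance.
- MatrixMarket cohort input uses 1-based indices, genes × samples on
  disk, with `.rows`/`.cols` sidecar name files.
- All stochastic components consume a `numpy.random.default_rng` seeded
  from explicit config fields; pipeline outputs are byte-stable because
  TSVs are written with a fixed float format and sorted indices, and the
  manifest contains no timestamps.
- Edge lists are undirected: pairs are canonicalized lexicographically,
  duplicates keep the maximum score, self-loops are dropped on load.
- The silhouette selection breaks exact ties toward the smaller k.
- Test problem sizes (e.g. 5,000-gene scatters over 20 seeds, 2,000-gene
  cohorts at n = 30/group, 100 clustering replicates) were chosen as the
  smallest scales at which the targeted effects are comfortably
  identifiable; they run in seconds.

## Known limitations

- The p-value generator is calibrated, not mechanistic: it does not model
  a test statistic, so power curves against effect size are flat by
  design.
- The classifier inherits any upstream miscalibration of adjusted
  p-values; it applies thresholds, it does not re-test.
- ORA treats gene sets as flat; no ontology-DAG-aware semantic similarity
  or redundancy reduction beyond the intersection-size merge.
- The cohort DEA assumes exchangeable samples within groups (no purity,
  batch or covariate adjustment) and a common dispersion across genes.
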