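# Methods

This note documents the models, defaults and numerical choices behind
`crcmicro`, and what the synthetic-cohort tests do and do not establish
about real data.

## Preprocessing

The pipeline starts from a denoised ASV count table. Filters run in a fixed
order: lineage exclusion and the prevalence filter first, then rarefaction,
then relative-abundance conversion or rank collapsing. Lineage exclusion is
a case-insensitive substring match of the excluded tokens (Mitochondria,
Chloroplast, Archaea, Eukaryota) against every rank field, which is robust
to SILVA prefix dialects. The prevalence rule keeps a taxon detected in at
least `min_samples = 3` samples (inclusive). Rarefaction is a single
multivariate-hypergeometric draw per sample (without replacement) to
`depth = 14,221` reads; samples below depth are dropped, not resampled.
Collapsing sums counts over the lineage prefix up to the requested rank;
taxa unassigned at that rank pool into one explicit `unassigned@rank` bin so
per-sample totals are conserved exactly.

## Community statistics

* **Shannon diversity** uses the natural log on per-sample relative
  abundances.
* **perMANOVA** partitions the Gower-centred inner-product matrix of
  squared Bray–Curtis distances. Terms are tested marginally by default
  (each term after all others, adonis2's `by="margin"` semantics);
  a sequential mode (`by="terms"`) gives additive sums of squares. Marginal
  sums of squares are not additive when terms are correlated, so the
  "R² sums to one" identity is guaranteed only for single-term or
  sequential partitions. Significance comes from free permutation of sample
  labels, `p = (1 + #{F* ≥ F}) / (1 + n_perm)` with 999 permutations by
  default; for n ≤ 9 an exact mode enumerates all n! orderings.
  Numeric metadata columns are treated as centred covariates, everything
  else as dummy-coded factors; singleton factor levels are rejected.
* **CAP** performs PCoA (axes with non-positive eigenvalues dropped),
  optionally residualizes the coordinates on a conditioning design, then
  runs linear discriminant analysis on the leading m axes, with m chosen by
  leave-one-out classification success (ties favor fewer axes, search
  capped at 20). Axis signs are canonicalized against the id-sorted sample
  order so scores do not depend on input order.
* **AVD** standardizes each taxon within its group (sample sd, ddof 1) and
  averages |z| per sample over taxa with positive variance; a group whose
  taxa are all constant reports 0 with a `no_variation` flag. Group
  contrasts use one-way ANOVA with Tukey-HSD compact letters at α = 0.05.
  For large Gaussian panels the per-sample AVD approaches E|Z| = √(2/π) ≈
  0.7979, which the tests verify to 0.01.
* **SPEC-OCCU** defines specificity as the group-normalized mean relative
  abundance (so a taxon's specificities sum to 1 across groups — the
  un-normalized verbal definition cannot live on a [0,1] biplot axis) and
  occupancy as within-group prevalence; specialists satisfy the 0.5/0.5
  rule among each group's 500 most abundant taxa.
* **Differential abundance** is Kruskal–Wallis per taxon with BH
  correction; constant taxa get p = 1 and a flag.

## Co-occurrence networks and drivers

Per-group networks use Spearman correlation on relative abundances
(monotone-transform robust), a prevalence floor of 0.3, and an edge rule of
|ρ| ≥ 0.6 with BH-adjusted t-approximation p ≤ 0.05. Networks need at
least five samples per group; association estimates at the study's T1 size
(n = 9) cannot clear BH-adjusted significance at ρ = 0.6 across thousands
of pairs, so driver analyses are meaningful only for groups of a few dozen
samples — the packaged network-study condition uses 40 per compared group.

Driver scoring follows the neighbor-shift idea: with A and B a node's
neighbor sets in the control and case networks, the score
`(1 − |A∩B|/|A∪B|) + |B∖A|/|A∪B|` lies in [0,2], is zero for unchanged or
empty neighborhoods, and weights case-gained neighbors. The scoring
function is deliberately pluggable; the fixed contract is the bounds,
zero-on-identity, and the driver conjunction: a driver must score at or
above the 0.90 quantile of common-sub-network scores **and** increase in
normalized betweenness (computed on the unweighted thresholded graphs —
thresholding already encodes strength) from control to case. Greedy
modularity communities on the case network are attached for reporting only.

## Staging model

Features are relative abundances at the chosen rank. Random forests use
500 trees (the classical randomForest defaults: √p features per split for
classification, p/3 for regression); screening importance is the impurity
decrease, which is orders of magnitude cheaper than out-of-bag permutation
at thousands of features and ranks planted effects equally well, while a
permutation "mean decrease accuracy" helper is provided for the final
(small) feature set. The age screen fits a regression of host age over
control samples and traces 10-fold CV RMSE over nested top-feature subsets
whose sizes halve from p down to 1; the selected set is the size at the CV
minimum. (A one-standard-error option exists, but with several equally
informative, mutually redundant planted taxa it collapses to two or three
features — prediction saturates — while the screen's purpose is to catch
*all* age-discriminatory taxa.) The stage screen classifies BP/T1–T4 on
the remaining features and keeps the top 15; folds shrink with a warning
when the smallest class (T4, n = 6) is below 10.

Diagnosis assigns the class holding ≥ 50% of tree votes, else the
plurality class with a low-confidence flag; ties break by the fixed order
(T1, T2, T3, T4, BP). Published-style whole-cohort reports score training
samples by out-of-bag votes and held-out samples by ordinary votes, so the
confusion matrix sums to the cohort size; a pure test-set report is also
emitted. The rank sweep repeats screen → fit → diagnose at phylum, class,
order, family, genus and ASV ranks and picks the best overall accuracy,
ties toward the finer rank. The bias audit runs a Mann–Whitney test of age
and Fisher's exact test of gender against diagnostic correctness, BH
adjusted.

The train/test split is group-stratified with largest-remainder rounding;
at the default fraction (67/95) it reproduces a 67/28 split with 32/13 BP.

## Synthetic cohorts

The generator emulates the study design: group sizes 45/9/13/22/6, ages
21–89 with a mild stage gradient (default +4 years of mean age per
successive group, creating the age–stage confound the model must remove),
70/95 male fraction, library sizes from a truncated normal (81,710 ±
47,466, floored at twice the rarefaction depth) and a rarefaction depth of
14,221.

Composition: baseline abundances are log-normal (σ = 1.5) with phylum mass
rescaled so Firmicutes, Bacteroidota and Proteobacteria hold ~75% in
expectation. Per-sample log abundances add (i) background co-occurrence
*modules* — eight latent factors, each shared by a block of taxa at
correlation-scale loading 0.9, which give the thresholded group networks
non-trivial topology (a factor-free community yields edgeless networks and
degenerate betweenness); (ii) idiosyncratic log-normal noise (sd 0.8, a
realistic within-taxon spread for amplicon data); and the planted effects:

* **Age taxa** (9): log abundance shifts linearly at 0.06 per year of
  centred age. This slope is calibrated so a forest on the planted taxa
  reproduces the high diagnosed-vs-chronological age consistency
  (r ≈ 0.9) the motivating study reports; at half this slope the planted
  taxa are statistically inseparable from the noise floor at n = 45.
* **Stage taxa** (15): half with monotone log2 fold-changes growing to
  ±2.0 at T4, half with a single-stage ±2.0 spike, signs random.
* **Driver taxa** (13): in the case group (T1) only, each taxon's
  standardized deviation is blended (loading √0.8) with a latent Gaussian
  field over the taxa arranged on a ring, correlation decaying as
  exp(−(d/0.75k)²) with ring distance d. Pairwise case-group correlation
  is therefore ≈ 0.8 between ring neighbors, fading with distance;
  marginal means and variances are preserved exactly. The decay is what
  makes rewiring *detectable*: a single common factor produces a complete
  clique whose internal betweenness is identically zero, defeating the
  driver definition, whereas the ring thresholds into an incomplete
  lattice in which every rewired taxon gains intermediation. All planted taxa are
  drawn from the top abundance quartile, mirroring the observation that
  the discriminatory and network-shift taxa are among the abundant
  members; planting in the rare tail buries the planted signal under
  count noise.

Counts are Dirichlet-multinomial around the per-sample composition with
per-taxon concentration `overdispersion × n_taxa × pᵢ` (default scale 100,
i.e. technical CV ≈ 0.1 at mean abundance), so technical noise does not
depend on the number of simulated taxa. All randomness flows from one seed
through spawned generators; outputs record the config hash.

### What the tests show — problem sizes

Tests and the acceptance script run scaled-down cohorts chosen as the
smallest sizes at which each effect is statistically identifiable: 95
samples × 300 taxa at depth 8,000 for the age/stage screens and the
deconfounding contrast; 40 BP + 40 T1 × 250 taxa at depth 10,000 for
network drivers; 25 samples × 40 taxa for null calibration (200
replicates). Passing parameter-recovery tests establishes that the
inference machinery finds effects of the planted kind and size under
Dirichlet-multinomial noise; they do not establish performance on real
tumor microbiomes, whose effect sizes, correlation structure and
zero-inflation can differ. The generator also does not emulate read-level
error, chimeras, or phylogenetic structure (tree-based metrics are out of
scope).

## Known limitations

* Marginal perMANOVA R² values are reported as computed; with correlated
  designs they need not sum to one with the residual.
* The betweenness-increase requirement makes driver recall sensitive to
  network density at the edge threshold; in very dense case networks
  genuine rewiring can hide inside near-cliques.
* The genus-level block of the published staging table is internally
  inconsistent (its entries imply 63.2%, not the printed 70.6%); the
  verification helper flags rather than repairs it.
* CAP axis selection maximizes leave-one-out success, which is optimistic
  as an absolute accuracy estimate; it is used only to pick the dimension.
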