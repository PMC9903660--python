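# Methods

This note documents the models, parameter choices and numerical decisions
behind `clonetrace`, and what the synthetic experiments do and do not show
about real data.

## Neutral-drift model

Cells divide independently each hour with probability *rr*; after 168 h,
*bns* cells are drawn uniformly without replacement (multinomial
with-replacement sampling is available as an option) and restart the week.
Division is applied clone-wise with binomial draws, which is exactly
equivalent in distribution to per-cell Bernoulli trials but runs in
O(#clones); the test suite cross-checks this against an independent
cell-wise implementation.

Defaults are `rr = 0.03`, `sp = 1000`, `bns = 1000`.  At 168 h per week,
`rr = 0.03` corresponds to roughly a 140-fold weekly expansion before the
bottleneck — a strongly proliferating culture in which the bottleneck,
not growth stochasticity, dominates drift.  All three parameters are
plain configuration; nothing in the package depends on these particular
values.

Entropy-based neutrality checks use lower-tail empirical p-values with
the +1/(n+1) finite-sample correction, which guarantees validity (the
p-value stochastically dominates uniform under the null).

## Selective generator

The ground-truthed generator runs the same weekly growth/bottleneck cycle
over a clone genealogy.  Copy numbers are tracked per segment per allele
(diploid root: one A and one B copy everywhere).  Events are either
planted — at a given week, on a named clone, on a named founder's
lineage, or on the largest unmutated ("pristine") clone, converting
`n_cells` cells — or stochastic at configurable per-cell rates.  Each
event multiplies the clone's hourly division probability by its fitness
factor (clamped at 1).

Observations per sampled cell:

* **Counts** — negative binomial per bin with mean proportional to
  (copy number / 2) × library size × a smooth multiplicative GC curve;
  dispersion and GC amplitude are configurable.  A direct Gaussian
  profile-noise mode (`profile_noise_sd`) supports experiments that start
  downstream of normalization.
* **Barcodes** — one library barcode per founder, assigned at week 0
  (an error is raised if the library is smaller than the founder count,
  unless collisions are explicitly enabled); per-cell detection is
  Bernoulli with a configurable rate, with undetected barcodes recorded
  as missing.
* **sSNVs** — ternary observations per (cell, variant): carried variants
  are seen as ALT with probability (1 − fn), non-carriers produce false
  ALT at rate fp, and loci escape coverage with probability
  (1 − coverage).

What this emulates: clonal expansion under selection, barcode dropout,
count overdispersion and GC bias, and allele dropout in mutation
detection.  What it does not: doublets, replication-timing and
breakage-fusion artifacts, chromothripsis, subclonal copy-number mosaics
within one cell, index hopping, or spatially structured growth.  Passing
recovery tests on these simulations therefore demonstrates correctness of
the inference chain under its stated model, not robustness to every
artifact of real libraries.

## Count processing

* Bin filter: bins with fewer than 3000 unique restriction cut sites are
  removed (inclusive boundary: exactly 3000 is kept).
* Normalization: per-cell division by the median bin count, times 2, so
  every cell's median copy number is exactly 2.  Normalization is
  scale-invariant per cell.
* GC correction: per-cell LOESS (tricube-weighted local linear
  regression, `statsmodels` lowess) of copy number on GC fraction,
  window span 0.3 by default (no span is canonical; 0.3 balances bias
  and variance at ~100–6000 bins).  The correction is additive and
  mean-preserving: `corrected = raw − fit(GC) + mean(fit)`.  Clipping to
  [0, 4] is applied after GC correction; the cap mitigates inflated
  noise at high copy numbers at the cost of censoring amplifications
  above 4.
* Cell QC: cells are embedded in 2-D by PCA (deterministic; only cluster
  separation matters here — a UMAP embedding can be plugged in),
  k-means clustered with k = 12, and clusters are auto-labeled noisy
  when their median profile spikiness (median |lag-1 bin difference|)
  exceeds 2× the overall median — replacing the manual cluster
  identification of interactive workflows.  A 300-tree class-balanced
  random forest trained on the bin values plus two per-cell dispersion
  summaries assigns noisy-class posteriors; cells above 0.99 are
  discarded.  The dispersion features let the forest overrule occasional
  cluster-label errors; posteriors are taken from the fitted forest on
  the full matrix.

## Segmentation and states

Cells are Ward-clustered on Euclidean distance over raw bins; the cluster
count maximizes the mean silhouette (computed on raw bins).  The
`forced_splits` parameter re-cuts a named cluster one linkage level
deeper, reproducing the "conservative overclustering" hook of interactive
analyses.

Circular binary segmentation per chromosome: the maximal two-sample
t statistic over all circular arcs is compared against a permutation null
(bin order shuffled within the chromosome).  The global variance factor
of the t statistic is permutation-invariant and omitted.  The permutation
driver stops early once the exceedance count guarantees p > α — the
split decision is unchanged; the reported p is then based on the shuffles
actually run, +1-corrected.  Splits recurse while p ≤ 0.05 (10,000
shuffles by default); a final merge pass removes breakpoints whose
adjacent segment means differ by less than 0.6 (smallest step first),
equivalent to rejecting the split during recursion.  Constant segments
(range < 1e-12) are never split.  Note the permutation test has no power
on very short profiles: with 6 bins the best split of a two-level profile
is reproduced by ~20–30% of shuffles, so only longer runs can reach
p ≤ 0.05.

Integer calls are rounded (half-to-even, documented tie rule) per-cell
segment medians.  The 0.025 variance filter acts on the rounding
residuals (median − nearest integer) across cells: segments whose
medians sit between integers in many cells ("hard to resolve") are
rejected, while genuinely polymorphic segments — cells cleanly at 1.0
vs 2.0 — pass.  Raw-median variance would reject every informative CNV
segment, which cannot be the intent of the filter.

Allele-specific calls multiply the total integer copy number by the
A-allele frequency from diplotype-oriented gSNV counts
(`A = round(total × freq_A)`, `B = total − A`); cells without informative
gSNV molecules in a segment get missing calls and are excluded from
state grouping (wildcard matching would merge states through
missingness).

CNV states are exact-vector groups (hamming distance 0), ranked by
descending size; singleton vectors are discarded and reported.

## Tree inference

Edit distance between state vectors is the L1 sum of per-segment copy
differences — "amount of edits" read as single-copy steps; a
changed-segment count metric is available (`--edit-metric`).  Gains and
losses are weighted equally; no asymmetry is defined.

The state-time graph has one node per (state, timepoint) with abundance
linearly interpolated between observations (zero outside the observed
range).  Cross-state edges run from every timepoint of the parent to the
first timepoint of the child at or after it ("first-appearance" mode;
all-pairs mode available) — keeping each tree edge interpretable as "the
child was founded from the parent".  Pruning removes backward-in-time
edges and edges that would raise a segment from zero copies.  The
artificial all-diploid root connects to each state's first appearance
only.  The minimum spanning arborescence is extracted with Edmonds'
algorithm (networkx); tie-breaking is made deterministic by perturbing
weights below the integer resolution, preferring parents with larger
abundance and then lower state id.  Tests verify optimality against
exhaustive enumeration on all graphs up to 7 nodes.

The stream-plot layout assigns each state a band of width equal to its
abundance, nests children inside the parent's span from the branch time
on, smooths band edges with cubic splines through the per-timepoint
anchors, and splits bands into stacked sub-lanes by barcode or sSNV
composition.

## Barcodes

Merging: sequences are processed in ascending (count, quality) order;
each is absorbed into its highest-ranked neighbor within hamming
distance 2, chains are resolved transitively, and counts are summed into
the surviving representative.  The procedure is idempotent,
count-conserving, and leaves canonical barcodes mutually more than 2
apart; it is oracle-checked against an independent all-pairs
implementation.

Origin classification accepts shared-barcode evidence transitively
through ancestors (a barcode present in a state and its grandparent but
missed in the parent is attributed to sampling).  "Pre-existing" requires
at least two distinct barcodes none of which is shared with the ancestry.
The minimum number of cells to call a barcode "present" in a state is 1
(configurable).  The parallel bound counts distinct barcodes present on
both sides of a tree edge — a lower bound, never an estimate, of
independent occurrences.  Weekly bulk barcode tables are consumed as
plain count fractions.

## sSNVs

Phasing links each candidate to the heterozygous gSNV with the most
informative cells (cells with any molecule spanning both loci); the phase
is the modal gSNV allele on alt-carrying molecules, and concordance is
the fraction of alt-informative cells agreeing with it (≥ 0.95 retained).
In the ternary matrix, ALT takes precedence over REF within a cell
(within-cell mixtures are out of model); REF requires a molecule carrying
both the phased gSNV allele and the reference base; variants need ALT in
≥ 2 cells and cells need ≥ 4 non-missing calls.  A manual exclusion list
can remove individually rejected variants.

The artifact filter is a 100-tree class-balanced random forest over
caller annotations, alt-read count and quality, gSNV overlap means, and
sequence-complexity features (unique 5-mer and 7-mer counts in centered
75/150/300/500/1000-bp windows), scored by leave-one-out (≤ 500
candidates) or stratified 10-fold cross-validation.

Imputation is an iterative maximum-likelihood clone model: cells are
assigned to clones under a per-entry error model with fixed false
negative rate 0.001 and false positive rate 0.0001; clone genotypes and
assignments alternate (hard EM, monotone log-likelihood) from a k-means
initialization; the clone count is chosen by BIC over a configurable
range.  Missing entries take the assigned clone's genotype.  Accuracy is
estimated by 10-fold cross-validation masking 10% of observed entries.
At zero error rates an impossible observation has likelihood zero; such
cells are flagged (internally, log 0 is replaced by −10⁹ to keep the
arithmetic NaN-free).

Branch classes are operationalized with explicit support counts
(`min_support`, default 1; 2 recommended and used in the robustness
experiments): class 1 needs ALT on both sides and zero REF in the child;
class 2 needs ALT absent from the parent with REF support there; class 3
needs ALT and REF support on both sides.  The hypergeometric
co-occurrence tail is computed in log space (logsumexp over log-pmfs),
stable to populations of 1e5, and checked against exact rational
arithmetic.

## Cohort analyses

The synthetic cohort draws per-contig log copy ratios from a
Gaussian-copula mixture (loss component N(−0.6, 0.1), neutral component
N(0, 0.1)), with contig correlations via the copula; survival is
exponential with per-sample hazard multiplied by configured effects for
named event combinations, censored administratively at 120 months.

Losses are log ratio < −0.4, strictly.  The ordering test permutes the
chromosome-4 ratios across samples; the statistic is the fraction of
samples with the chromosome-18 ratio strictly below chromosome 4, the
tail is enrichment (≥ observed), and the p-value carries the +1
correction.  Both directional fractions are always reported.  The
conditional scan filters contigs by mean |log ratio| among aberrant
samples (> 0.4; an all-samples variant is a config switch), derives each
contig's direction from the sign of its mean aberrant ratio, and for
each ordered pair with ≥ 30 doubly-aberrant samples fits a Cox model on
the priming-event carriers with a single both-events indicator;
Benjamini-Hochberg correction runs across all retained pairs.

## Problem sizes in the recovery experiments

The canned study conditions were chosen once for desk-scale runs:
genealogy recovery uses 30 founders, a 1000-cell bottleneck, five planted
single-copy losses (fitness 1.15, chains of depth 2) and 200 sampled
cells at weeks 3/5/7 over 120 bins on three chromosomes; planted clones
start from 40–60 converted cells so that every intermediate state is
reliably sampled (single-cell plantings are dominated by branching-
process noise).  The parallel-evolution design splits the population with
one sSNV (taking over the largest founder lineage) and plants the same
loss once or twice at week 4; barcode detection is 0.5 per cell.  The
conditional-hazard design uses loss prevalence 0.35 for the two focal
contigs and 0.02 elsewhere at n = 2000, giving ~245 doubly-aberrant
samples (log-HR standard error ≈ 0.085) — real-cohort prevalences near
0.14 would leave the doubly-aberrant group too small for a stable fit at
this cohort size.  Reconstruction inside these experiments runs CBS with
1000–2000 shuffles; the stand-alone segmentation benchmark uses the full
10,000.

## Known limitations

* CBS recursion tests arcs against a global-variance t statistic; very
  heteroscedastic profiles may over-split (the variance filter downstream
  removes most such segments).
* The imputer is a point-estimate (hard-EM) stand-in for posterior
  sampling: it reports no uncertainty over clone assignments and can hit
  local optima for overlapping clones; BIC can under-select clones when
  discriminating variants are few.
* The tree model assumes states are founded once per edge; the barcode
  and class-3 detectors exist precisely because this assumption fails
  under parallel evolution, but the tree itself still shows one edge.
* Layout nesting assumes child abundances fit within the parent span at
  the branch time; widths are not rescaled to enforce this.
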