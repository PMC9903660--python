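# clonetrace

Reconstruction of parallel tumor evolution from three simultaneous
single-cell lineage measurements: copy-number (CNV) states, somatic SNVs
(sSNVs), and viral lineage barcodes.

## The problem

Barcoded cancer-organoid evolution experiments follow a founder population
through months of weekly passaging while sampling single cells for
whole-genome sequencing.  Three independent lineage markers are read from
the same cells: the genome-wide copy-number profile, phased somatic point
mutations, and a lentiviral barcode introduced once at the start of the
culture.  `clonetrace` implements the full desk-scale analysis chain for
such experiments, aimed at researchers studying clonal dynamics and the
order and recurrence of chromosomal aberrations:

* **Neutral-drift null** — a stochastic simulator of hourly cell division
  (rate *rr*), starting population *sp* and weekly bottleneck *bns*;
  Shannon entropy `H = −Σ pᵢ log₂ pᵢ` of clone sizes summarises diversity,
  and observed entropy series are tested against the null with empirical
  lower-tail p-values.
* **CNV calling** — per-cell molecule counts in 500-kb bins are filtered
  (≥ 3000 unique cut sites per bin), median-normalized to a baseline of 2,
  LOESS GC-corrected, clipped at copy number 4, and QC-filtered with a
  cluster-trained random forest (noisy-class posterior > 0.99 discarded).
* **Segmentation and CNV states** — Ward clustering (silhouette-selected
  k), circular binary segmentation per cluster (p = 0.05, 10,000 shuffles;
  steps < 0.6 rejected), per-cell integer calls by rounded segment medians
  (unresolvable segments with residual variance > 0.025 rejected),
  allele-specific copy numbers from diplotyped B-allele frequencies, and
  exact (hamming-0) grouping of cells into CNV states (≥ 2 cells).
* **Clonal tree** — a time-layered directed graph over (state, timepoint)
  nodes with L1 edit-distance weights, zero-weight temporal chains, a
  diploid root and biological pruning (no backward edges, no regrowth from
  zero copies); the minimum spanning arborescence (Edmonds' algorithm) is
  the clonal evolution tree, with a stream-plot layout.
* **Parallel-evolution detectors** — (i) k distinct lineage barcodes
  shared across a tree edge bound the edge's CNV change to ≥ k independent
  occurrences; (ii) sSNVs at branch points fall in three classes, where
  class 3 (mutant and wild-type backgrounds on *both* sides of a branch)
  proves the copy-number change happened at least twice.
* **Cohort statistics** — loss calls at log copy ratio < −0.4, a
  permutation test for ordered chromosome-18-before-chromosome-4 loss, a
  hypergeometric co-occurrence test, log-rank survival comparisons and a
  systematic priming/conditional Cox proportional-hazards scan with
  Benjamini-Hochberg correction.

A first-class synthetic-data module (`evolution_sim`, plus a cohort
generator in `cohort`) produces fully ground-truthed experiments — clone
genealogies with planted CNV/sSNV events, barcode dropout, negative-
binomial counts with GC bias, and survival cohorts — so every stage is
verifiable without any sequencing data.

## Worked example

Simulate a neutral culture (200 founders, division probability 0.03 per
hour, weekly bottleneck of 200 cells) and test an observed entropy series
against that null:

```python
from clonetrace.evolution_sim import (DriftParams, simulate_neutral_drift,
                                      entropy_neutrality_check)

params = DriftParams(rr=0.03, sp=200, bns=200, weeks=6, seed=11)
series = simulate_neutral_drift(params)
print(series.entropy_series().round(3))
```

```
0    7.644
1    6.367
2    5.799
3    5.323
4    5.075
5    4.640
6    4.376
```

Week 0 is `log₂(200) = 7.644` bits (every founder a unique clone); drift
erodes ~0.5–1 bit per passage.  An experiment whose diversity collapses
faster than this is under selection:

```python
obs = [7.644, 6.5, 5.2, 4.0, 2.9, 1.8, 0.9]
print(entropy_neutrality_check(obs, params, n_sims=500, seed=0))
```

```
 week  observed_entropy  p_value
    0             7.644   1.0000
    1             6.500   0.8982
    2             5.200   0.0020
    3             4.000   0.0020
    4             2.900   0.0020
    5             1.800   0.0020
    6             0.900   0.0020
```

From week 2 on, the observed entropy is lower than in every one of the 500
neutral simulations (p = 1/501): the collapse is incompatible with drift.

The same style applies to the genomic statistics.  Out of 1,641 cells,
944 carried the chromosome-18 loss and all 449 chromosome-4 losses
occurred inside that set; the chance probability is

```python
from clonetrace.ssnv import cooccurrence_log10
cooccurrence_log10(1641, 944, 449, 449)   # -> -134.46, i.e. p ≈ 3e-135
```

— far below 1e-100, so the Δ18→Δ4 ordering is not coincidental.

A command-line interface mirrors the library:
`clonetrace simulate-drift`, `simulate-experiment`, `normalize`, `qc`,
`segment`, `states`, `cooccurrence`, and `clonetrace cohort
simulate|losses|ordering-test|conditional-scan|logrank`.

## Layout

```
src/clonetrace/
  evolution_sim.py    # drift null + ground-truthed selective generator
  cnv_pipeline.py     # bin filter, normalization, GC fit, cell QC
  segmentation.py     # Ward clustering, CBS, integer & allele calls, states
  tree_inference.py   # state-time graph, Edmonds arborescence, layout
  lineage_barcodes.py # barcode merging, origin calls, parallel bounds
  ssnv.py             # phasing, ternary genotypes, imputation, classes 1-3
  cohort.py           # cohort generator, ordering test, Cox scan, log-rank
  workflow.py         # end-to-end reconstruction + recovery scoring
  io.py, cli.py
docs/methods.md       # model assumptions, parameters, numerical choices
```
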