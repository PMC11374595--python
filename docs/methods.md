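# Methods

This note documents the statistical procedures implemented in
`mirsource`, the design decisions behind them, the synthetic-data
generator used to validate them, and known limitations.

## Literature catalog

The unit of evidence is a *mention record* (document id, normalized gene
symbol, species, disease query label) as exported by a
literature-annotation service. The pipeline does no named-entity
recognition itself.

* **Human filtering** is exact equality of the species column with the
  human taxon label (default "Homo sapiens").
* **Frequency** of a (gene, disease) pair is the number of *distinct
  documents* mentioning it. Counting documents rather than raw mentions
  is robust to a gene being named several times in one abstract; the
  choice is encapsulated in `build_catalog` and would be a one-line
  change.
* **Symbol case**: symbols are upper-cased before joining to the biotype
  map, except miRNA-convention symbols (`hsa-…`), which are
  case-sensitive by community convention.
* **Biotypes**: unknown symbols map to `other` instead of being dropped,
  so biotype summaries always sum to the distinct-gene count.
* **Ranking ties** are broken lexicographically so top-k lists are
  stable and reproducible.

## Target consensus

Predicted miRNA→mRNA pairs from five prediction databases are combined
by *distinct-source counting*: a pair is kept iff at least
`min_sources = 2` databases report it. Scores are carried through (mean
of per-source descending ranks) for ordering but never for filtering —
the retention rule is purely the source count.

Experimentally validated pairs are treated with **union semantics**:
pairs in the validated table but absent from the consensus set are added
with `n_sources = 0`, and a pair that is both predicted and validated is
typed *validated* for reporting. Rationale: predicted and validated
edges are bookkept as separate edge classes in the network, which
implies validated evidence stands on its own; the alternative
(validated-only pairs excluded) is recoverable by dropping
`n_sources == 0` rows.

Finally the interaction set is intersected with the text-mined gene
lists, restoring the constraint that every retained edge connects a
mined miRNA to a mined mRNA, so the downstream network has no orphan
evidence.

## Regulatory network

The network is a strictly bipartite undirected graph (miRNA side, mRNA
side) with edges typed `predicted`/`validated`. Violations of
bipartiteness in the input are hard errors, not warnings, because a
symbol appearing on both sides almost always indicates an annotation
bug.

* **Frequency–degree correlation** is Spearman's rho over miRNAs present
  in both the catalog and the network. Because rho is rank-based, the
  log10(x+1) transform used for plotting does not affect it. The p-value
  uses the large-sample t approximation; an exact permutation p-value by
  full enumeration is available for n ≤ 8 (8! = 40,320 permutations —
  beyond that enumeration cost grows factorially and the t approximation
  is already accurate).
* **miRNA prioritization** averages the *ranks* of frequency and degree
  (mid-ranks for ties), which is invariant under monotone transforms of
  either variable; averaging the raw values is available behind the
  `raw_average` flag but mixes incommensurable scales. Final ties are
  broken by higher frequency, then symbol.

## Over-representation analysis

For a query of n genes against a set of K genes inside a universe of N,
the p-value is the hypergeometric upper tail P(X ≥ k). The universe is
an explicit parameter; the default when enriching miRNA target sets is
the mRNA side of the interaction set under study. Adjustment is
Benjamini–Hochberg across the sets of one collection. There is no
minimum-overlap filter by default (`min_overlap = 1`).

## Single-cell core

The dataset container is an `AnnData` with raw counts, cell metadata
(cell type, subtype, disease state: Heal / NonI / Infl) and derived QC
covariates.

* **QC**: a cell is kept iff it has ≥ 250 detected genes, ≥ 100 total
  counts and ≤ 25% mitochondrial reads. Boundary cells (exactly at a
  threshold) are kept — the removal rule is "fewer than" / "more than",
  not "at most". The filter is idempotent. Mitochondrial genes are
  identified by the `MT-` symbol prefix (configurable regex).
* **Normalization** is library-size CP10K followed by natural log1p:
  `ln(1 + c·10⁴ / total)`. The scale factor 10⁴ is the community default
  and is configurable. Zeros are preserved exactly, so detection
  (value > 0) is identical on raw and normalized data. Z-scoring is
  deliberately *not* applied before the DOR or DEG statistics, which
  operate on normalized or binarized values; clustering and embedding
  are out of scope — cell labels are inputs.

## Diagnostic odds ratio (cellular sourcing)

Expression of a feature is binarized (detected ⇔ value > 0). For each
candidate group (one-vs-rest at the chosen label level, default merged
cell subtypes):

    TP = in-group detected      FP = out-group detected
    FN = in-group undetected    TN = out-group undetected

    DOR = ((TP + 0.5) / (FP + 0.5)) / ((FN + 0.5) / (TN + 0.5))

The 0.5 pseudocount in all four cells keeps the DOR finite and strictly
positive for any table; the trade-off is that a feature detected
*nowhere* still gets a DOR > 1 in small groups, which is exactly why the
**minimum-detection filter** exists: features detected in < 5% of a
group's cells are non-significant there. The filter applies to the
in-group fraction only and is enforced at reporting, so all computed
DORs remain inspectable. The cellular source of a miRNA is the group
with the largest DOR among those passing the filter.

Disease-state comparisons within the source group use pairwise
two-sided Wilcoxon rank-sum tests with BH adjustment (the test is a
package choice; states with < 3 cells are summarized but not tested).

## Subcluster analysis

Source-group cells are partitioned by detection of the miRNA. A
degenerate partition (all positive or all negative) is an error.

* **Differential expression**: per-gene two-sided Wilcoxon rank-sum on
  normalized values (the default test of the standard single-cell
  marker-finding function), with
  `log2FC = log2((mean_pos + 1)/(mean_neg + 1))` computed on de-logged
  CP10K means. A gene is a DEG iff raw p < 0.05 and |log2FC| > 1; the
  BH-adjusted p is always reported alongside the raw p used by the
  threshold. Genes constant across both subclusters get p = 1. log2FC is
  exactly antisymmetric under label swap by construction.
* **Target overlap** compares genes *downregulated in the
  miRNA-positive subcluster* (the expected footprint of miRNA
  repression) with the miRNA's predicted target set; the opposite
  directionality is one parameter away.
* **Module scores**: genes are placed into 24 equal-frequency bins by
  mean normalized expression; each set gene contributes 100 control
  draws from its bin (with replacement when the bin is small); the score
  of a cell is mean(set) − mean(control draws). Defaults (24 bins, 100
  controls) follow the published algorithm's defaults. Scores are
  deterministic under a fixed seed. A set scored against its own control
  pool is zero in expectation, up to control-sampling noise. The binned
  matching presumes the set genes do not dominate their expression bins;
  for gene sets comparable in size to a bin the control pool degenerates
  and the score shrinks toward zero.
* **Score comparisons** between subclusters use Wilcoxon rank-sum with
  BH across sets and conventional star coding (p < 0.05/0.01/0.001/1e-4).

## Synthetic-data generator

The generator emulates the statistical structure of every pipeline
input; all parameters live in `SimulationConfig` and all randomness
flows from one seed through independent named streams (fixed seed ⇒
bit-identical outputs).

* **Mentions**: per-(gene, disease) frequencies are zipf(a = 2) draws
  (discrete power law, support ≥ 1), reflecting the heavy-tailed
  attention literature pays to genes. Records are emitted with distinct
  document ids so distinct-document counting reproduces the planted
  frequencies exactly.
* **Predictions**: each miRNA receives a target set; every true edge is
  covered by each source independently with probability
  `per_source_coverage` (default 0.6), forced to ≥ 2 sources so true
  edges survive the consensus rule; decoy edges (default 100) get
  exactly one source. A `validated_fraction` (default 0.2) of true edges
  forms the validated table.
* **Frequency–degree coupling**: per-miRNA (frequency, degree) pairs are
  drawn from a Gaussian copula with Pearson r = 2·sin(π·ρ/6), the value
  whose bivariate-normal Spearman correlation is ρ (default 0.6), then
  mapped through the zipf quantile and a uniform degree range (2–30).
  Ties in the discrete zipf margin attenuate the realized correlation,
  so the ground truth records the *population* Spearman of the realized
  margins (estimated once by a 200k-draw Monte Carlo), which is what the
  sampled correlation converges to.
* **Counts**: negative binomial with global dispersion (0.5) and
  per-gene log-normal mean scaling around `nb_mean = 0.3` — the standard
  overdispersed model for UMI counts. Default geometry: three cell types
  × 250 cells, two subtypes each, disease states assigned uniformly.
  miRNA features are simulated as ordinary rows of the matrix (the
  source technology quantifies miRNA loci like any feature); no
  small-RNA chemistry is modeled.
* **Planted cellular specificity**: a planted (miRNA, cell type) pair is
  detected with probability 0.6 inside the type and 0.02 outside
  (positive counts are 1 + Poisson). Non-planted miRNAs get a uniform 1%
  background detection, below the 5% reporting filter everywhere.
* **Planted DE**: planted genes (default 20, 4-fold down) are shifted
  multiplicatively between miRNA-positive and miRNA-negative cells of
  the first planted pair's type. Planted DE genes sit at the configured
  baseline mean rather than at a random log-normal draw: the fold
  change, not the baseline lottery, is the planted experimental
  variable — a 4-fold effect on a gene expressed at ~0 counts is not a
  recoverable DE gene and would measure the baseline draw, not the
  method.
* **Not emulated**: doublets, ambient RNA, batch effects, realistic
  literature text. Passing tests therefore demonstrate correctness of
  the statistics and recovery under idealized noise, not robustness to
  those artifacts.

## Problem sizes used in validation

The test suite and the acceptance script run the generator at desk
scale, chosen so each statistical claim has adequate power: 200–250
cells per type (binomial tolerance ±0.07 on detection fractions), 200
miRNAs for correlation recovery (sampling SD of rho ≈ 0.07), 1,000 null
genes with 200 vs 200 cells for DE calibration, 500 cells and 2,000
genes for module-score calibration, and exhaustive enumeration wherever
it is exact (contingency tables with group sizes ≤ 50, gene-set
universes ≤ 25, permutations at n ≤ 8).

## Known limitations

* Alias/synonym resolution of gene symbols is an input concern; matching
  is exact after case normalization.
* The DOR has no confidence interval here (standard log-OR intervals
  could be added).
* The exact Spearman permutation p is limited to n ≤ 8; beyond that only
  the t approximation is offered.
* The enrichment module implements over-representation only, not
  running-sum (GSEA-style) statistics or ontology-topology-aware tests.
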