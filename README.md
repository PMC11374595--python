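# mirsource

**Literature-mined miRNA–mRNA consensus networks and single-cell,
DOR-based cellular sourcing of miRNAs.**

miRNAs act as post-transcriptional repressors and are heavily studied in
inflammatory bowel disease (IBD) and its subtypes (Crohn's disease,
ulcerative colitis), but individual reports disagree about which miRNAs
matter and which cells produce them. `mirsource` implements, as a
reusable and tested pipeline, an integrative inference chain for this
problem:

1. **Literature catalog** — ingest gene-mention tables exported from a
   literature-annotation service, keep human genes, annotate biotypes
   (protein-coding / miRNA / lncRNA / other), and rank genes by
   per-disease mention frequency *f* (distinct documents).
2. **Target consensus** — combine miRNA→mRNA predictions from five
   databases; keep a pair only when ≥ 2 independent sources predict it;
   flag pairs present in an experimentally validated interaction table
   (union semantics); intersect with the text-mined gene lists.
3. **Regulatory network** — build the bipartite miRNA–mRNA graph, tally
   nodes/edges by type, test the Spearman correlation between mention
   frequency *f* and network degree *d*, and prioritize miRNAs by the
   average of their frequency and degree ranks.
4. **Enrichment** — generic over-representation analysis of target or DEG
   lists against GMT gene-set collections:
   *p* = P(X ≥ k), X ~ Hypergeom(N, K, n), with Benjamini–Hochberg
   adjustment.
5. **Single-cell core** — sparse cell × gene counts (AnnData), QC (keep
   cells with ≥ 250 genes, ≥ 100 counts, ≤ 25% mitochondrial reads),
   CP10K + log1p normalization.
6. **Cellular source** — binarize expression (detected ⇔ normalized
   value > 0) and compute, per cell group, the pseudocounted diagnostic
   odds ratio

   ```
   DOR = ((TP + 0.5) / (FP + 0.5)) / ((FN + 0.5) / (TN + 0.5))
   ```

   one-vs-rest, filtering out features detected in < 5% of a group's
   cells. The cellular source of a miRNA is the group with the top DOR.
7. **Subcluster** — split the source cells into miRNA-positive /
   miRNA-negative subclusters, compute Wilcoxon rank-sum DEGs
   (DEG ⇔ p < 0.05 and |log2FC| > 1, log2FC on de-logged CP10K means
   with +1 pseudocount), overlap downregulated genes with predicted
   targets, and score hallmark-style gene sets per cell against
   expression-matched binned controls.

A first-class **synthetic-data module** generates every pipeline input
with planted, recoverable structure (power-law mention frequencies,
multi-source predictions with decoys, negative-binomial counts with
planted cell-type-specific miRNA detection and planted DE genes), so
each stage can be checked against a known ground truth.

## Worked example

```python
from mirsource import *
from mirsource.literature_catalog import mined_sets
from mirsource.synthetic_data import SimulationConfig, simulate_all
import mirsource.sc_core as sc

study = simulate_all(SimulationConfig(seed=1))

mrnas, mirnas = mined_sets(study.catalog, "IBD")
inter = build_interactions(study.predictions, study.validated, mrnas, mirnas)
net = build_network(inter)
stats = network_stats(net)
print(f"network: {stats.n_mirna} miRNAs, {stats.n_mrna} mRNAs, "
      f"{stats.n_edges} edges ({100*stats.fraction_validated:.1f}% validated)")

rho, p, n = frequency_degree_correlation(net, study.catalog, "IBD")
print(f"frequency-degree Spearman rho = {rho:.2f} (p = {p:.2g}, n = {n})")

adata = sc.annotate_cells(study.dataset)
adata, report = qc_filter(adata, min_genes=10, min_counts=10, max_mito=1.0)
normalize(adata)
top = rank_sources(dor_table(adata, ["hsa-miR-145"], "cell_type"), k=1)
r = top.iloc[0]
print(f"hsa-miR-145 source: {r['group']} "
      f"(DOR = {r['dor']:.1f}, detected in {100*r['detection_in']:.0f}% of cells)")

split = split_by_positivity(adata, "hsa-miR-145", "myofibroblast", level="cell_type")
degs = differential_expression(adata, split)
ov = target_overlap(degs, inter, "hsa-miR-145")
print(f"subclusters: {split.n_positive}+ / {split.n_negative}-; "
      f"{int(degs['is_deg'].sum())} DEGs, "
      f"{len(ov.overlap)} downregulated DEGs among predicted targets")
```

prints

```
network: 40 miRNAs, 433 mRNAs, 603 edges (20.1% validated)
frequency-degree Spearman rho = 0.69 (p = 1.1e-06, n = 40)
hsa-miR-145 source: myofibroblast (DOR = 57.8, detected in 58% of cells)
subclusters: 144+ / 106-; 31 DEGs, 1 downregulated DEGs among predicted targets
```

The simulated miRNA–mRNA network recovers exactly the planted consensus
edges with the configured validated share; the planted coupling between
how often a miRNA is mentioned and how many targets it has shows up as a
positive rank correlation; the planted hsa-miR-145/myofibroblast pair is
sourced correctly with a large odds ratio; and the positive/negative
split finds the planted downregulated genes.

The same stages are available as a command-line chain:

```sh
mirsource simulate --outdir sim --seed 1
mirsource catalog  --mentions sim/mentions.tsv --biotypes sim/biotypes.tsv \
                   --diseases IBD,CD,UC --out cat
mirsource targets  --predictions sim/predictions --validated sim/validated.tsv \
                   --catalog cat/catalog.tsv --disease IBD --out interactions.tsv
mirsource network  --interactions interactions.tsv --catalog cat/catalog.tsv \
                   --disease IBD --out net
mirsource sc-qc    --dataset sim/matrix --out qc
mirsource dor      --dataset qc --level cell_type --out dor
mirsource subcluster --dataset qc --feature hsa-miR-145 \
                   --group myofibroblast --level cell_type \
                   --interactions interactions.tsv --out sub
```

## Documentation

`docs/methods.md` describes the statistical model of each stage, the
synthetic-data generator and its planted structure, parameter defaults,
numerical conventions and known limitations.
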