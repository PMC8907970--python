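# laminar

Cross-dataset analysis of gene expression across the layers of the human
neocortex.

Layer-resolved expression data comes in incompatible shapes: bulk RNA-seq of
transverse slices that each straddle several layers, spatial transcriptomics
aggregated to layer-level replicate samples, and single-nucleus RNA-seq with
per-nucleus layer and cell-type labels. `laminar` harmonizes all three into
gene × layer matrices of log2 counts-per-million (layers L1…L6, WM) and
answers two questions on top of them:

- **Single gene** — what is this gene's laminar profile in each dataset, and
  how well do datasets agree? Agreement is the Pearson correlation *r* of
  the layer profiles, with a two-sided p from the t transform
  *t = r√(n−2)/√(1−r²)* and a genome-wide percentile of *r* within the
  distribution of all same-gene cross-dataset correlations.
- **Gene set** — is the set enriched or depleted in each layer? Per
  (dataset, layer), genes are ranked by their per-gene z-scored expression
  and the set's ROC AUC is computed: AUC = U/(n₁n₂) with the Mann–Whitney U
  statistic, AUC > 0.5 enrichment, < 0.5 depletion, p-values exact for small
  tie-free problems and tie-corrected normal otherwise, Bonferroni-adjusted
  over the whole query (every dataset × layer cell). A cross-dataset mean
  AUC per layer summarizes the heatmap.

A synthetic-data module generates all three dataset shapes with
negative-binomial counts and planted layer markers, so the entire pipeline
is testable end to end without any external data.

## Worked example

```
laminar simulate  --out study/raw --seed 7 --n-genes 300
laminar harmonize --config study/raw/config.yaml --out study/harm
laminar query gene G001       --matrices study/harm --out study/gene
laminar query set study/raw/markers.txt --matrices study/harm --out study/set
```

`simulate` writes a three-dataset study (bulk slices + slice→layer map,
spatial layer replicates, annotated nuclei) with 25 genes planted at 8-fold
elevation in L3, plus a ready-to-run config. `harmonize` produces five
matrices (bulk, spatial, and one per nucleus cell type). The queries print:

```
Gene G001 assayed in 5/5 datasets: bulk_sim, snrna_sim_GABAergic,
snrna_sim_glutamatergic, snrna_sim_non-neuronal, spatial_sim.
Agreement (bulk_sim vs spatial_sim): r = 0.880 (p = 0.0089, n = 7 layers),
92th percentile genome-wide.
```

G001 is one of the planted markers: its profiles in the two tissue-level
datasets correlate strongly (r = 0.88), and that correlation sits in the
92nd percentile of all same-gene cross-dataset correlations.

```
Queried 25 genes.
  bulk_sim: 25/25 genes assayed.
  ...
Mean agreement (bulk_sim vs spatial_sim): r = 0.860 (p = 0.013, n = 7 layers),
90th percentile genome-wide.
Highest cross-dataset mean AUC: L3 (1.000).
```

The planted marker set is recovered: the cross-dataset mean AUC peaks at L3,
the layer the markers were planted in. Each query also writes a JSON/TSV
report and figures (enrichment heatmap with significance asterisks at
adjusted p < 0.05; per-dataset expression heatmap for ≤ 30 genes, dot plot
with per-layer medians otherwise; single-gene bar plot of CPM on a log
scale).

Everything is also available as a library:

```python
import laminar as lm

cfg = lm.SimConfig(n_genes=2000, layers=("L1","L2","L3","L4","L5","L6"))
markers = lm.MarkerSpec.uniform(cfg.gene_ids()[:25], "L3", 8.0)
ds = lm.simulate_dataset(cfg, markers)
m = lm.harmonize_spatial_layers(ds.table, meta={"name": "sim"})
result = lm.enrichment_table([m], list(markers.genes))
print(result.mean_auc.idxmax())   # -> "L3"
```

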