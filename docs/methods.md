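# Methods

`laminar` harmonizes cortical expression datasets of three very different
shapes into a common gene-by-layer representation and runs two statistical
analyses on it. This note records the models, the numerical conventions, and
the design choices that were genuinely open.

## Harmonization model

Every dataset ends up as a genes × layers matrix of log2 counts-per-million,
with layers ordered anatomically L1 → L6 → WM (white matter). The routes
differ by input shape:

**Bulk transverse slices.** Slices are cut parallel to the pial surface, so
each slice overlaps one or more layers. Replicate sample columns are first
summed per slice; slices are then combined into layer columns by a weighted
average,

    value(g, ℓ) = Σ_s w(s, ℓ) · count(g, s) / Σ_s w(s, ℓ),

where `w(s, ℓ)` is the fractional membership of slice `s` in layer `ℓ`
(rows of the slice→layer map sum to 1). This makes every layer column a
convex combination of slice columns: if a layer's weight comes from a single
slice, the layer column equals that slice exactly, and values always stay
within the min/max of the contributing slices.

**Spatial layer replicates.** Spot-level data arrives already aggregated to
one column per (layer, replicate); replicate columns are summed per layer.

**Single nuclei.** Nuclei flagged as outliers in the metadata are dropped,
the requested region is selected (exact string match), and nucleus counts
within each major cell type (GABAergic, glutamatergic, non-neuronal) are
equalized per layer by sampling without replacement down to the minimum
per-layer count for that cell type. Equalization keeps the sparsity of lowly
expressed genes comparable across the layer columns that are then formed by
summing. One matrix is produced per cell type. Layers with no nuclei for a
cell type are simply absent rather than forcing the minimum to zero.

**Normalization.** All routes finish with `log2((c + 1) / Σ(c + 1) × 1e6)`:
the pseudocount of 1 is added to the raw counts *before* the library size is
computed, so the linear-scale CPM of every layer column sums to exactly 1e6
(the acceptance script verifies this to relative 1e−9; in practice it holds
to machine epsilon). Note that log2-CPM values can be negative whenever the
offset library size exceeds 1e6 — a zero count then maps to CPM 1e6/libsize
< 1 — so no lower bound is imposed on stored values.

**Gene identity.** Cross-dataset joins are by gene symbol, exact and
case-sensitive. When several source identifiers (e.g. Ensembl ids) map to
one symbol, their count rows are replaced by the per-sample arithmetic mean.
Identifiers with no mapping are retained verbatim and logged; dropping them
would be destructive and nothing downstream requires removal.

## Agreement statistics

For a single gene, agreement between two datasets is the Pearson correlation
of its layer profiles over the shared layers (WM is dropped automatically
when one side lacks it); at least 3 shared layers are required, and constant
profiles are flagged as not computable. The two-sided p-value uses the exact
t transform `t = r√(n−2)/√(1−r²)` with `df = n − 2` layers.

To give the correlation a genome-wide calibration, the same-gene correlation
is computed for *every* shared gene (the "null" distribution; genes constant
in either dataset are excluded and counted), and the query's percentile in
that distribution is reported using the midrank convention
`100 · (#below + ½·#ties) / N`, so a value equal to the entire null sits at
the 50th percentile. An alternative reading of the genome-wide reference —
all cross-gene pairs rather than all same-gene correlations — would scale
quadratically in gene count and answers a different question ("is this
correlation high for *any* pair?" rather than "is this gene's cross-dataset
consistency high among genes?"); the same-gene null is the default and only
implementation.

For a gene set, the reported statistic is the arithmetic mean of the
per-gene correlations over the genes present in both datasets (missing genes
are listed, not fatal), ranked against the same single-gene null. The
t-transform p of a *mean* correlation is only descriptive — the mean of
correlated r's has no exact small-sample null of this form — which is also
why externally reported (mean r, p) pairs need not match the single-gene
transform; the percentile carries the calibrated comparison.

## Layer enrichment

Enrichment of a query set in a layer is the ROC AUC of set membership
against the layer's normalized expression ranking:

1. Genes with linear CPM < 0.1 in **every** layer are removed (a gene above
   threshold in any one layer survives).
2. Each gene's layer profile is z-scored (sample sd, n−1). Genes constant
   across layers get z = 0, are flagged, and stay in the background. The
   z-scoring is per gene across layers — the question is where each gene
   peaks, not which genes dominate a layer.
3. Per layer, genes are ranked by z with midranks for ties;
   `U = Σ_set rank − n_set(n_set+1)/2` counts the (set, background) pairs
   where the set gene ranks higher (ties ½), and `AUC = U/(n_set·n_bg)`.
   AUC > 0.5 is enrichment, < 0.5 depletion; reversing the ranking maps
   AUC to 1 − AUC.

Significance is Mann–Whitney, computed from (U, n_set, n_bg, tie structure):
when `n_set·n_bg ≤ 400` and the ranking is tie-free, the exact two-sided p
from full enumeration of the null U distribution (a dynamic program over
rank placements); otherwise a normal approximation with tie-corrected
variance `n₁n₂/12 · ((n+1) − Σ(t³−t)/(n(n−1)))` and a 0.5 continuity
correction. The exact branch is validated against brute-force enumeration
of all rank placements, the approximate branch against scipy's asymptotic
test on raw data.

One query's Bonferroni family is **all** computed (dataset × layer) cells —
e.g. 2·7 + 3·6 = 32 cells for two 7-layer and three 6-layer datasets — since
the whole heatmap is inspected at once. Datasets where the query cannot be
evaluated contribute flagged cells and shrink the family rather than
aborting the query. A cross-dataset per-layer mean AUC is also reported,
averaging only over the datasets that contain that layer.

Agreement statistics are restricted to the bulk-role vs spatial-role pair of
matrices; single-nucleus matrices are excluded from correlation (but not
from enrichment) because nuclear transcriptomes correlate much more weakly
with tissue-level profiles, which would make the percentile calibration
misleading.

## Synthetic data

The generator exists to give the pipeline inputs with known truth, not to
imitate laminar biology. Counts are negative binomial with mean
`μ(g, unit) = baseline · fold(g, layer(unit)) · libfactor(unit)` and
variance `μ + φμ²`:

| parameter | default | meaning |
|---|---|---|
| n_genes | 1000 | independent genes |
| baseline_mean | 100 | NB mean per gene per unit (counts) |
| dispersion φ | 0.2 | NB overdispersion, typical bulk RNA-seq scale |
| libsize_sigma | 0.2 | sd of log-normal library-size factors (makes CPM non-trivial) |
| n_slices × n_donors | 18 × 4 | bulk shape: slice columns per donor |
| n_replicates | 4 | spatial shape: replicate samples per layer |
| nuclei_per_group | 40 (drawn in [n, 2n)) | nuclei per (layer, cell type); varied so downsampling is non-trivial |
| outlier_fraction | 0.05 | Bernoulli outlier flags on nuclei |
| noise_sd | 0.3 | per-dataset log2 noise in paired generation |
| shared_profile_sd | 0.25 | sd of the shared log2 laminar profile in paired generation |

Markers are planted by an 8-fold (log2 = 3) elevation by default, large
against the ~0.25–0.3 log2 background variation, so recovery is expected but
not trivial given NB sampling noise at 7 layer points. The bulk slice→layer
map is deterministic: 18 equal-width slices intersected with 7 equal-width
layer bands, overlaps normalized per slice. All randomness flows from a
single integer seed (`numpy.random.default_rng` / `SeedSequence`), and a
fixed seed reproduces every table byte for byte.

What the generator does **not** emulate: per-gene baseline variation,
gene–gene correlation, cell-type-specific expression programs, spot
geometry, donor batch effects, or realistic layer-width profiles. Passing
tests therefore demonstrate the correctness of the aggregation and the rank
statistics under a known model, not performance on real tissue.

## Numerical choices and degenerate inputs

- Percentile and AUC tie handling are both midrank-based, making reversals
  and symmetric inputs exact (AUC complements sum to 1; a query equal to the
  whole null is the 50th percentile).
- |r| = 1 reports the smallest positive double as p, flagged, rather than 0.
- Empty gene lists warn and return empty; an all-outlier nucleus table or an
  absent region yields an empty table with a warning; an empty gene set at
  normalization is an error (a library size of 0 genes is meaningless).
- The expression-view branch is exact at the boundary: ≤ 30 genes renders a
  heatmap, 31 a dot plot with the set's per-layer median.
- Problem sizes in the test-suite simulations (2,000 genes × 6 layers × 20
  seeds for marker recovery; 1,000 genes for paired correlation) are the
  package's desk-scale defaults: large enough for stable rank statistics,
  small enough to iterate on.

## Known limitations

- The weighted-average slice aggregation assumes slice→layer weights are
  fractional memberships summing to 1 per slice; maps from other conventions
  must be normalized first.
- Bonferroni is the only multiplicity correction offered, by design.
- The percentile calibration inherits whatever genes survive in both
  datasets; heavy filtering on one side changes the null.
- Reports serialize figures as views of the JSON values; figures are
  deterministic in content, but SVG/PNG byte streams are not guaranteed
  stable across library versions.
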