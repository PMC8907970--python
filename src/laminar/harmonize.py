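"""Harmonize raw dataset shapes into normalized gene-by-layer matrices.

Three input shapes occur in laminar transcriptomics and each needs its own
route to a gene × layer matrix:

* **bulk slices** — transverse cortical slices cut parallel to the pia; each
  slice overlaps one or more layers, so slice columns are combined into layer
  columns by a weighted average using a slice→layer membership map.
* **spatial layer replicates** — spot-level data already aggregated to one
  column per (layer, replicate sample); replicates are summed per layer.
* **nuclei** — single-nucleus counts with per-nucleus layer / cell-type /
  region / outlier annotations; nuclei are filtered, optionally equalized in
  number per layer within each cell type, and summed into layer columns per
  cell type.

All routes finish with the same normalization: add 1 to every count, convert
to counts-per-million against the offset library size, and log2-transform.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_matrix import LAYER_ORDER, CountTable, LayerMatrix, ParseError

logger = logging.getLogger(__name__)

CELL_TYPES: tuple[str, ...] = ("GABAergic", "glutamatergic", "non-neuronal")


@dataclass
class SliceLayerMap:
    """Fractional membership of each transverse slice in the cortical layers.

    ``weights`` is a slices × layers DataFrame; every row sums to 1 (within
    1e-9) and columns are drawn from the canonical layer set.
    """

    weights: pd.DataFrame

    def __post_init__(self) -> None:
        unknown = [l for l in self.weights.columns if l not in LAYER_ORDER]
        if unknown:
            raise ParseError(f"slice map has unknown layer label(s): {unknown}")
        w = self.weights.to_numpy()
        if (w < 0).any():
            raise ParseError("slice map has negative weights")
        sums = w.sum(axis=1)
        bad = np.abs(sums - 1.0) > 1e-9
        if bad.any():
            slices = list(self.weights.index[bad])
            raise ParseError(f"slice weights do not sum to 1 for: {slices[:5]}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SliceLayerMap":
        """Read a long-format TSV with columns slice_label, layer_label, weight."""
        df = pd.read_csv(path, sep="\t")
        needed = {"slice_label", "layer_label", "weight"}
        if not needed.issubset(df.columns):
            raise ParseError(f"slice map {path} lacks columns {sorted(needed)}")
        wide = (
            df.pivot_table(index="slice_label", columns="layer_label",
                           values="weight", aggfunc="sum", fill_value=0.0)
            .astype(float)
        )
        wide = wide[[l for l in LAYER_ORDER if l in wide.columns]]
        wide.index = wide.index.astype(str)
        wide.index.name = None
        wide.columns.name = None
        return cls(wide)

    def to_tsv(self, path: str | Path) -> None:
        long = self.weights.stack().rename("weight").reset_index()
        long.columns = ["slice_label", "layer_label", "weight"]
        long = long[long["weight"] > 0]
        long.to_csv(path, sep="\t", index=False, float_format="%.17g")


def sum_replicates(table: CountTable, group_key: str) -> CountTable:
    """Sum sample columns sharing a metadata value; group values become sample ids."""
    if group_key not in table.sample_meta.columns:
        raise ValueError(f"metadata field {group_key!r} not present")
    groups = table.sample_meta[group_key]
    missing = list(groups.index[groups.isna()])
    if missing:
        raise ValueError(f"samples lacking {group_key!r}: {missing[:5]}")
    order = list(dict.fromkeys(groups))
    summed = table.counts.T.groupby(groups, sort=False).sum().T[order]
    meta = pd.DataFrame(index=pd.Index(order, name="sample_id"))
    meta[group_key] = order
    return CountTable(summed, meta)


def pseudobulk_slices(table: CountTable, slice_map: SliceLayerMap) -> CountTable:
    """Aggregate slice columns into layer columns by weighted average.

    ``value(g, layer) = Σ_s w(s, layer)·count(g, s) / Σ_s w(s, layer)``, a
    convex combination of the contributing slices' counts. Layers with zero
    total weight are dropped with a warning.
    """
    absent = [s for s in table.sample_ids if s not in slice_map.weights.index]
    if absent:
        raise ValueError(f"slice(s) absent from slice map: {absent[:5]}")
    w = slice_map.weights.loc[table.sample_ids]
    cols = {}
    for layer in [l for l in LAYER_ORDER if l in w.columns]:
        total = w[layer].sum()
        if total <= 0:
            warnings.warn(f"layer {layer} has zero total weight; dropped", stacklevel=2)
            continue
        cols[layer] = table.counts.to_numpy() @ (w[layer].to_numpy() / total)
    out = pd.DataFrame(cols, index=table.counts.index)
    meta = pd.DataFrame(index=pd.Index(out.columns, name="sample_id"))
    meta["layer_label"] = list(out.columns)
    return CountTable(out, meta)


def filter_outliers(table: CountTable) -> CountTable:
    """Drop samples flagged ``outlier_call``; order of the rest preserved."""
    if "outlier_call" not in table.sample_meta.columns:
        return table
    flags = table.sample_meta["outlier_call"].astype(bool)
    keep = [s for s, f in zip(table.sample_ids, flags) if not f]
    if not keep:
        warnings.warn("all samples flagged as outliers; table is empty", stacklevel=2)
    return table.subset_samples(keep)


def select_region(table: CountTable, region: str) -> CountTable:
    """Retain samples whose ``region`` annotation equals ``region`` exactly."""
    if "region" not in table.sample_meta.columns:
        raise ValueError("metadata lacks a region column")
    keep = [s for s, r in zip(table.sample_ids, table.sample_meta["region"])
            if r == region]
    if not keep:
        warnings.warn(f"no samples from region {region!r}", stacklevel=2)
    return table.subset_samples(keep)


def downsample_equal(table: CountTable, seed: int) -> CountTable:
    """Equalize nucleus counts per layer within each major cell type.

    Within each cell type, every represented layer keeps exactly n* nuclei,
    where n* is the minimum nucleus count over that cell type's layers;
    sampling is without replacement and reproducible for a fixed seed.
    Equalizing per layer keeps the sparsity of lowly expressed genes
    comparable across the layer columns built later.
    """
    meta = table.sample_meta
    for col in ("layer_label", "cell_type"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks {col!r}")
    rng = np.random.default_rng(seed)
    keep: set[str] = set()
    for cell_type in sorted(meta["cell_type"].unique()):
        sub = meta[meta["cell_type"] == cell_type]
        per_layer = sub.groupby("layer_label", sort=True).size()
        n_star = int(per_layer.min())
        for layer in per_layer.index:
            ids = list(sub.index[sub["layer_label"] == layer])
            chosen = rng.choice(len(ids), size=n_star, replace=False)
            keep.update(ids[i] for i in sorted(chosen))
    return table.subset_samples([s for s in table.sample_ids if s in keep])


def pseudobulk_nuclei(table: CountTable) -> dict[str, CountTable]:
    """Sum nucleus counts into layer columns, one output table per cell type."""
    meta = table.sample_meta
    for col in ("layer_label", "cell_type"):
        if col not in meta.columns:
            raise ValueError(f"metadata lacks {col!r}")
    out: dict[str, CountTable] = {}
    for cell_type in sorted(meta["cell_type"].unique()):
        samples = [s for s, c in zip(table.sample_ids, meta["cell_type"])
                   if c == cell_type]
        sub = table.subset_samples(samples)
        layers = sub.sample_meta["layer_label"]
        order = [l for l in LAYER_ORDER if l in set(layers)]
        summed = sub.counts.T.groupby(layers, sort=False).sum().T[order]
        m = pd.DataFrame(index=pd.Index(order, name="sample_id"))
        m["layer_label"] = order
        m["cell_type"] = cell_type
        out[cell_type] = CountTable(summed, m)
    return out


def cpm_log2(table: CountTable, meta: dict | None = None) -> LayerMatrix:
    """Normalize layer-column counts to log2 counts-per-million.

    A pseudocount of 1 is added to every count *before* the library size is
    computed, so ``v(g, l) = log2((c+1) / Σ_g'(c'+1) × 1e6)`` and the
    linear-scale CPM of each layer column sums to exactly 1e6.
    """
    if table.n_genes == 0:
        raise ValueError("cannot CPM-normalize an empty gene set")
    layers = list(table.counts.columns)
    unknown = [l for l in layers if l not in LAYER_ORDER]
    if unknown:
        raise ParseError(f"cpm_log2 expects layer columns; got {unknown}")
    offset = table.counts.to_numpy() + 1.0
    cpm = offset / offset.sum(axis=0, keepdims=True) * 1e6
    values = pd.DataFrame(np.log2(cpm), index=table.counts.index, columns=layers)
    ordered = [l for l in LAYER_ORDER if l in layers]
    return LayerMatrix(values[ordered], dict(meta or {}))


def harmonize_bulk_slices(
    table: CountTable,
    slice_map: SliceLayerMap,
    *,
    slice_key: str = "slice_label",
    meta: dict | None = None,
) -> LayerMatrix:
    """Bulk route: sum replicate columns per slice, weight-average slices
    into layers, CPM-normalize."""
    slices = sum_replicates(table, slice_key)
    layered = pseudobulk_slices(slices, slice_map)
    return cpm_log2(layered, meta)


def harmonize_spatial_layers(
    table: CountTable, *, meta: dict | None = None
) -> LayerMatrix:
    """Spatial route: sum replicate samples per layer, CPM-normalize."""
    layered = sum_replicates(table, "layer_label")
    ordered = [l for l in LAYER_ORDER if l in layered.counts.columns]
    layered = CountTable(layered.counts[ordered], layered.sample_meta.loc[ordered])
    return cpm_log2(layered, meta)


def harmonize_nuclei(
    table: CountTable,
    *,
    region: str | None = None,
    seed: int = 0,
    downsample: bool = True,
    meta: dict | None = None,
) -> dict[str, LayerMatrix]:
    """Single-nucleus route, one matrix per major cell type.

    Outlier-flagged nuclei are removed, the requested region selected, nucleus
    counts equalized per layer within each cell type, then summed into layer
    columns and CPM-normalized.
    """
    table = filter_outliers(table)
    if region is not None:
        table = select_region(table, region)
    if downsample:
        table = downsample_equal(table, seed=seed)
    bulked = pseudobulk_nuclei(table)
    out: dict[str, LayerMatrix] = {}
    for cell_type, sub in bulked.items():
        m = dict(meta or {})
        m["cell_type"] = cell_type
        if m.get("name"):
            m["name"] = f"{m['name']}_{cell_type}"
        out[cell_type] = cpm_log2(sub, m)
    return out
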