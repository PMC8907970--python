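"""Readers, writers, and containers for count tables and layer matrices.

Two on-disk count formats are supported: a dense TSV (header row of sample
ids, first column of gene ids) and a sparse Matrix Market coordinate file
with companion one-label-per-line row (gene) and column (sample) files.
Harmonized gene-by-layer matrices are stored as TSV with the layer header in
anatomical order (L1..L6, then WM) and dataset metadata embedded as leading
``#meta key=value`` comment lines, so a single file round-trips losslessly.

All cross-dataset joins in this package are by gene symbol, exact and
case-sensitive; :func:`collapse_gene_ids` maps source identifiers (e.g.
Ensembl ids) onto symbols by averaging the counts of identifiers that share
a symbol.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

#: Anatomical layer order: pia to white matter.
LAYER_ORDER: tuple[str, ...] = ("L1", "L2", "L3", "L4", "L5", "L6", "WM")

#: Per-sample annotation columns recognised in metadata tables.
META_COLUMNS: tuple[str, ...] = (
    "slice_label",
    "layer_label",
    "cell_type",
    "region",
    "outlier_call",
)


class ParseError(ValueError):
    """Raised when an on-disk table violates its format contract."""


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ParseError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


@dataclass
class CountTable:
    """Gene-by-sample matrix of non-negative counts with sample annotations.

    ``counts`` is a genes × samples :class:`pandas.DataFrame` (float);
    ``sample_meta`` is indexed by sample id and carries any of the
    :data:`META_COLUMNS`. Counts may be fractional: collapsing duplicate
    gene identifiers averages member rows.
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        _check_unique(list(self.counts.index), "gene id")
        _check_unique(list(self.counts.columns), "sample id")
        vals = self.counts.to_numpy()
        if vals.size and not np.all(np.isfinite(vals)):
            raise ParseError("counts contain non-finite values")
        if vals.size and (vals < 0).any():
            g, s = np.argwhere(vals < 0)[0]
            raise ParseError(
                f"negative count at gene {self.counts.index[g]!r}, "
                f"sample {self.counts.columns[s]!r}"
            )
        if self.sample_meta.empty:
            self.sample_meta = pd.DataFrame(index=self.counts.columns)
        else:
            missing = self.counts.columns.difference(self.sample_meta.index)
            if len(missing):
                raise ParseError(f"samples missing from metadata: {list(missing)[:5]}")
            self.sample_meta = self.sample_meta.loc[self.counts.columns]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        """Return a new table restricted to ``sample_ids``, order preserved."""
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return CountTable(
            counts=self.counts[keep].copy(),
            sample_meta=self.sample_meta.loc[keep].copy(),
        )


@dataclass
class LayerMatrix:
    """Gene-by-layer matrix of log2-CPM values with dataset metadata.

    ``values`` is genes × layers; columns are an ordered subset of
    :data:`LAYER_ORDER`. ``meta`` records dataset name, region, technique
    and (for single-nucleus data) cell type.
    """

    values: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        layers = list(self.values.columns)
        unknown = [l for l in layers if l not in LAYER_ORDER]
        if unknown:
            raise ParseError(f"unknown layer label(s): {unknown}")
        _check_unique(layers, "layer label")
        order = [l for l in LAYER_ORDER if l in layers]
        if layers != order:
            raise ParseError(f"layer labels out of order: {layers} (expected {order})")
        _check_unique(list(self.values.index), "gene id")
        vals = self.values.to_numpy()
        if vals.size and not np.all(np.isfinite(vals)):
            raise ParseError("layer matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def layer_labels(self) -> list[str]:
        return list(self.values.columns)

    @property
    def name(self) -> str:
        return str(self.meta.get("name", "unnamed"))


# ---------------------------------------------------------------------------
# count tables


def read_count_table(
    path: str | Path,
    fmt: str = "dense_tsv",
    *,
    genes_path: str | Path | None = None,
    samples_path: str | Path | None = None,
    meta_path: str | Path | None = None,
) -> CountTable:
    """Read a count table from disk.

    Parameters
    ----------
    path
        Dense TSV file (``fmt="dense_tsv"``) or Matrix Market coordinate
        file (``fmt="triplet"``).
    genes_path, samples_path
        Companion label files for the triplet format, one label per line
        (rows = genes, columns = samples). Required for ``triplet``.
    meta_path
        Optional CSV/TSV sample-metadata table with a ``sample_id`` column.
    """
    path = Path(path)
    if fmt == "dense_tsv":
        table = _read_dense_tsv(path)
    elif fmt == "triplet":
        if genes_path is None or samples_path is None:
            raise ValueError("triplet format requires genes_path and samples_path")
        table = _read_triplet(path, Path(genes_path), Path(samples_path))
    else:
        raise ValueError(f"unknown count-table format: {fmt!r}")
    if meta_path is not None:
        meta = read_sample_meta(meta_path)
        missing = table.counts.columns.difference(meta.index)
        if len(missing):
            raise ParseError(f"metadata missing sample(s): {list(missing)[:5]}")
        table = CountTable(table.counts, meta.loc[table.counts.columns])
    return table


def _read_dense_tsv(path: Path) -> CountTable:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    # pandas silently mangles duplicate header cells, so check the raw line
    _check_unique(header[1:], f"sample id in {path.name} header")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas message varies
        raise ParseError(f"{path}: could not parse dense TSV: {exc}") from exc
    df.index.name = None
    df.columns.name = None
    _check_unique(list(df.index), f"gene id in {path.name}")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            gene = df.index[np.argmax(bad.to_numpy())]
            raise ParseError(
                f"{path.name}: non-numeric count at gene {gene!r}, sample {col!r}"
            )
        df[col] = coerced
    if df.isna().to_numpy().any():
        raise ParseError(f"{path.name}: missing count cell")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return CountTable(df.astype(float))


def _read_labels(path: Path) -> list[str]:
    labels = [ln.strip() for ln in path.read_text().splitlines()]
    return [l for l in labels if l]


def _read_triplet(path: Path, genes_path: Path, samples_path: Path) -> CountTable:
    genes = _read_labels(genes_path)
    samples = _read_labels(samples_path)
    try:
        mat = spio.mmread(path)
    except Exception as exc:
        raise ParseError(f"{path}: could not parse Matrix Market file: {exc}") from exc
    mat = sparse.coo_matrix(mat)
    if mat.shape != (len(genes), len(samples)):
        raise ParseError(
            f"{path.name}: matrix is {mat.shape[0]} rows x {mat.shape[1]} cols but "
            f"label files list {len(genes)} genes x {len(samples)} samples"
        )
    dense = np.asarray(mat.todense(), dtype=float)
    df = pd.DataFrame(dense, index=genes, columns=samples)
    return CountTable(df)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a count table as dense TSV (gene ids in column 1)."""
    table.counts.to_csv(path, sep="\t", index_label="gene_id", float_format="%.17g")


def write_count_table_triplet(
    table: CountTable,
    mtx_path: str | Path,
    genes_path: str | Path,
    samples_path: str | Path,
) -> None:
    """Write counts as Matrix Market coordinate + row/column label files."""
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(table.counts.to_numpy()))
    Path(genes_path).write_text("\n".join(table.gene_ids) + "\n")
    Path(samples_path).write_text("\n".join(table.sample_ids) + "\n")


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata table (CSV or TSV) indexed by ``sample_id``."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path.name}: metadata lacks a sample_id column")
    _check_unique(list(df["sample_id"]), f"sample_id in {path.name}")
    df = df.set_index("sample_id")
    if "outlier_call" in df.columns:
        df["outlier_call"] = df["outlier_call"].str.upper().isin(("TRUE", "T", "1"))
    return df


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    meta.to_csv(path, sep=sep, index_label="sample_id")


# ---------------------------------------------------------------------------
# gene id collapsing


@dataclass
class GeneIdMap:
    """Many-to-one mapping from source identifiers to gene symbols."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        self.mapping = dict(self.mapping)

    @classmethod
    def from_table(cls, path: str | Path) -> "GeneIdMap":
        """Read a two-column (source_id, symbol) TSV, header optional."""
        df = pd.read_csv(path, sep="\t", dtype=str, header=None)
        if list(df.iloc[0]) == ["source_id", "symbol"]:
            df = df.iloc[1:]
        ids = list(df.iloc[:, 0])
        _check_unique(ids, "source_id in gene id map")
        return cls(dict(zip(ids, df.iloc[:, 1])))


def collapse_gene_ids(table: CountTable, id_map: GeneIdMap) -> CountTable:
    """Collapse rows whose source ids map to the same symbol by averaging.

    Rows sharing a symbol are replaced by one row per symbol whose counts are
    the per-sample arithmetic mean of the member rows. Source ids absent from
    the map pass through unchanged (and are logged); output gene ids are
    unique symbols in first-occurrence order.
    """
    mapping = id_map.mapping
    unmapped = [g for g in table.gene_ids if g not in mapping]
    if unmapped:
        logger.info(
            "collapse_gene_ids: %d identifier(s) not in map, retained verbatim "
            "(first few: %s)", len(unmapped), unmapped[:5],
        )
    symbols = [mapping.get(g, g) for g in table.gene_ids]
    grouped = table.counts.groupby(pd.Index(symbols, name="symbol"), sort=False).mean()
    return CountTable(grouped, table.sample_meta.copy())


# ---------------------------------------------------------------------------
# layer matrices


def write_layer_matrix(matrix: LayerMatrix, path: str | Path) -> None:
    """Write a layer matrix as TSV with ``#meta`` header comment lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for key in sorted(matrix.meta):
            fh.write(f"#meta {key}={matrix.meta[key]}\n")
        matrix.values.to_csv(fh, sep="\t", index_label="gene_id", float_format="%.17g")


def read_layer_matrix(path: str | Path) -> LayerMatrix:
    """Read a layer matrix written by :func:`write_layer_matrix`."""
    path = Path(path)
    meta: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#meta "):
            key, _, val = line[len("#meta "):].rstrip("\n").partition("=")
            meta[key] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0)
    df.index.name = None
    df.columns.name = None
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return LayerMatrix(df.astype(float), meta)


def read_gene_list(path: str | Path) -> list[str]:
    """Read a newline-delimited gene list: trimmed, de-duplicated, case kept."""
    raw = Path(path).read_text().splitlines()
    out: list[str] = []
    seen: set[str] = set()
    for line in raw:
        sym = line.strip()
        if sym and sym not in seen:
            seen.add(sym)
            out.append(sym)
    if not out:
        warnings.warn(f"gene list {path} is empty", stacklevel=2)
    return out
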