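"""Cross-dataset laminar correlation and layer-specific AUC enrichment.

Two statistical engines operate on harmonized gene-by-layer matrices:

* **Agreement** — Pearson correlation between a gene's layer profiles in two
  datasets, with a two-sided p-value from the t transform and a genome-wide
  percentile placing that correlation within the null distribution of all
  same-gene cross-dataset correlations. For a gene set, the arithmetic mean
  of the per-gene correlations is ranked against the same null.

* **Enrichment** — for each (dataset, layer), the probability that a random
  query-set gene out-ranks a random background gene in that layer's
  z-scored expression (the ROC AUC; 0.5 = no enrichment, >0.5 enrichment,
  <0.5 depletion), with Mann–Whitney U significance and Bonferroni
  correction over the whole query family, plus a cross-dataset per-layer
  mean AUC.

The Mann–Whitney p-value is computed from (U, n_set, n_bg, tie structure)
directly: exact enumeration of the null U distribution when the problem is
small and tie-free, otherwise a normal approximation with tie-corrected
variance and continuity correction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_matrix import LAYER_ORDER, LayerMatrix

logger = logging.getLogger(__name__)

#: Smallest problem size n_set*n_bg handled by exact Mann–Whitney enumeration.
EXACT_MAX_PRODUCT = 400

#: Minimum CPM a gene must reach in at least one layer to enter enrichment.
LOW_EXPRESSION_CPM = 0.1


@dataclass
class CorrelationResult:
    """Agreement between two datasets' layer profiles for a gene or set."""

    query: str
    r: float
    n_layers: int
    p: float
    percentile: float
    flags: list[str] = field(default_factory=list)
    per_gene_r: dict[str, float] = field(default_factory=dict)
    missing: dict[str, list[str]] = field(default_factory=dict)

    @property
    def computable(self) -> bool:
        return math.isfinite(self.r)


# ---------------------------------------------------------------------------
# correlation


def profile_correlation(x: pd.Series, y: pd.Series) -> tuple[float, int, list[str]]:
    """Pearson r between two layer profiles over their shared layers.

    Returns ``(r, n_shared_layers, flags)``; r is NaN (with a flag) when
    fewer than 3 layers are shared or either profile is constant.
    """
    shared = [l for l in LAYER_ORDER if l in x.index and l in y.index]
    n = len(shared)
    if n < 3:
        return float("nan"), n, ["fewer than 3 shared layers"]
    xv = x[shared].to_numpy(dtype=float)
    yv = y[shared].to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return float("nan"), n, ["constant profile"]
    r = float(sps.pearsonr(xv, yv).statistic)
    return r, n, []


def correlation_pvalue(r: float, n_layers: int) -> tuple[float, list[str]]:
    """Two-sided p for Pearson r via t = r·sqrt(n−2)/sqrt(1−r²), df = n−2."""
    if n_layers < 3:
        raise ValueError("p-value requires at least 3 layers")
    if not math.isfinite(r) or abs(r) > 1:
        raise ValueError(f"invalid correlation {r}")
    if abs(r) == 1.0:
        return float(np.nextafter(0.0, 1.0)), ["|r| = 1: p at floating-point floor"]
    df = n_layers - 2
    t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), df)), []


def correlation_null(a: LayerMatrix, b: LayerMatrix) -> pd.Series:
    """Same-gene cross-dataset correlations for every shared gene.

    The genome-wide null: for each gene present in both matrices, the Pearson
    correlation between its two layer profiles over the shared layers. Genes
    constant in either dataset are excluded (and counted in the log).
    """
    shared_layers = [l for l in LAYER_ORDER
                     if l in a.layer_labels and l in b.layer_labels]
    if len(shared_layers) < 3:
        raise ValueError(f"only {len(shared_layers)} shared layers; need >= 3")
    genes = a.values.index.intersection(b.values.index)
    if len(genes) == 0:
        raise ValueError("no shared genes between matrices")
    av = a.values.loc[genes, shared_layers].to_numpy(dtype=float)
    bv = b.values.loc[genes, shared_layers].to_numpy(dtype=float)
    ac = av - av.mean(axis=1, keepdims=True)
    bc = bv - bv.mean(axis=1, keepdims=True)
    denom = np.sqrt((ac * ac).sum(axis=1) * (bc * bc).sum(axis=1))
    ok = denom > 0
    n_const = int((~ok).sum())
    if n_const:
        logger.info("correlation_null: %d constant-profile gene(s) excluded", n_const)
    r = (ac * bc).sum(axis=1)[ok] / denom[ok]
    return pd.Series(np.clip(r, -1.0, 1.0), index=genes[ok], name="r")


def correlation_percentile(r: float, null: pd.Series | np.ndarray) -> float:
    """Midrank percentile of r in the null: strictly-below plus half of ties."""
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    below = float((null < r).sum())
    ties = float((null == r).sum())
    return 100.0 * (below + 0.5 * ties) / null.size


def gene_correlation(
    gene: str, a: LayerMatrix, b: LayerMatrix, null: pd.Series | None = None
) -> CorrelationResult:
    """Single-gene agreement: r, t-transform p, genome-wide percentile."""
    missing = {m.name: [gene] for m in (a, b) if gene not in m.values.index}
    if missing:
        raise KeyError(f"gene {gene!r} absent from: {sorted(missing)}")
    r, n, flags = profile_correlation(a.values.loc[gene], b.values.loc[gene])
    if not math.isfinite(r):
        return CorrelationResult(gene, r, n, float("nan"), float("nan"), flags)
    p, pflags = correlation_pvalue(r, n)
    if null is None:
        null = correlation_null(a, b)
    pct = correlation_percentile(r, null)
    return CorrelationResult(gene, r, n, p, pct, flags + pflags,
                             per_gene_r={gene: r})


def set_correlation(
    genes: list[str], a: LayerMatrix, b: LayerMatrix,
    null: pd.Series | None = None,
) -> CorrelationResult:
    """Gene-set agreement: mean per-gene r, ranked against the single-gene null.

    The reported p is the t-transform p of the mean correlation at the shared
    layer count — a descriptive pairing, since the mean of correlated r's has
    no exact small-sample null; the genome-wide percentile carries the
    calibrated comparison.
    """
    missing = {
        m.name: [g for g in genes if g not in m.values.index] for m in (a, b)
    }
    usable = [g for g in genes
              if g in a.values.index and g in b.values.index]
    if not usable:
        raise KeyError(
            f"no queried gene present in both datasets; missing: {missing}")
    per_gene: dict[str, float] = {}
    flags: list[str] = []
    n_layers = 0
    for g in usable:
        r, n, gflags = profile_correlation(a.values.loc[g], b.values.loc[g])
        n_layers = max(n_layers, n)
        if math.isfinite(r):
            per_gene[g] = r
        else:
            flags.append(f"{g}: {'; '.join(gflags)}")
    if not per_gene:
        return CorrelationResult(
            "+".join(genes), float("nan"), n_layers, float("nan"), float("nan"),
            flags, missing=missing)
    mean_r = float(np.mean(list(per_gene.values())))
    p, pflags = correlation_pvalue(mean_r, n_layers)
    if null is None:
        null = correlation_null(a, b)
    pct = correlation_percentile(mean_r, null)
    return CorrelationResult("+".join(genes), mean_r, n_layers, p, pct,
                             flags + pflags, per_gene, missing)


# ---------------------------------------------------------------------------
# enrichment


def filter_low_expression(
    m: LayerMatrix, threshold_cpm: float = LOW_EXPRESSION_CPM
) -> LayerMatrix:
    """Drop genes whose linear CPM is below threshold in every layer."""
    cpm = np.exp2(m.values.to_numpy())
    keep = (cpm >= threshold_cpm).any(axis=1)
    if not keep.any():
        raise ValueError(f"all genes below {threshold_cpm} CPM in every layer")
    return LayerMatrix(m.values.loc[keep].copy(), dict(m.meta))


def zscore_by_gene(m: LayerMatrix) -> tuple[LayerMatrix, list[str]]:
    """Standardize each gene's layer profile to mean 0, sd 1 (sample sd).

    Constant genes get z = 0 in every layer and are returned in the flag
    list; they stay in the background for enrichment.
    """
    if len(m.layer_labels) < 2:
        raise ValueError("z-scoring requires at least 2 layers")
    v = m.values.to_numpy(dtype=float)
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0)
    sd[constant] = 1.0
    z = (v - mean) / sd
    z[constant] = 0.0
    flagged = list(m.values.index[constant])
    if flagged:
        logger.info("zscore_by_gene: %d constant gene(s) set to z=0", len(flagged))
    zm = LayerMatrix(pd.DataFrame(z, index=m.values.index, columns=m.values.columns),
                     dict(m.meta))
    return zm, flagged


def layer_auc(
    z: LayerMatrix, gene_set: list[str], layer: str
) -> tuple[float, float, int, int]:
    """ROC AUC of a gene set in one layer's z-scored expression ranking.

    Genes are ranked by z descending with midranks for ties; U counts, over
    all (set, background) pairs, how often the set gene ranks above the
    background gene (ties count 0.5), and ``auc = U / (n_set · n_bg)``.

    Returns ``(auc, U, n_set, n_bg)``.
    """
    if layer not in z.layer_labels:
        raise KeyError(f"layer {layer!r} not in matrix {z.name}")
    in_set = z.values.index.isin(set(gene_set))
    n_set = int(in_set.sum())
    n_bg = int(len(z.values.index) - n_set)
    if n_set == 0:
        raise ValueError("no query gene present after filtering")
    if n_bg == 0:
        raise ValueError("no background genes: query set covers the matrix")
    col = z.values[layer].to_numpy(dtype=float)
    # ascending midranks; rank-sum of the set minus its minimum possible
    # rank-sum gives the number of (set > background) pairs with ties at 0.5
    ranks = sps.rankdata(col, method="average")
    u = float(ranks[in_set].sum() - n_set * (n_set + 1) / 2.0)
    return u / (n_set * n_bg), u, n_set, n_bg


def tie_structure(values: np.ndarray | pd.Series) -> np.ndarray:
    """Sizes of tie groups (>1) in a ranking column."""
    _, counts = np.unique(np.asarray(values, dtype=float), return_counts=True)
    return counts[counts > 1]


def mannwhitney_u_distribution(n1: int, n2: int) -> np.ndarray:
    """Exact null distribution of the Mann–Whitney U statistic.

    ``out[u]`` is the number of ways to interleave n1 set and n2 background
    ranks (no ties) so that exactly u of the n1·n2 ordered (set, background)
    pairs have the set member ranked higher; ``out.sum() == C(n1+n2, n1)``.
    """
    max_u = n1 * n2
    # walk the ranks from smallest to largest; a set element placed after b
    # background elements beats exactly those b, adding b to U
    dp = np.zeros((n1 + 1, max_u + 1), dtype=float)
    dp[0, 0] = 1.0
    for i in range(n1 + n2):
        nxt = np.zeros_like(dp)
        for k in range(min(i, n1) + 1):
            row = dp[k]
            if not row.any():
                continue
            b = i - k  # background elements already placed
            if b < n2:
                nxt[k] += row
            if k < n1:
                if b:
                    nxt[k + 1, b:] += row[:max_u + 1 - b]
                else:
                    nxt[k + 1] += row
        dp = nxt
    return dp[n1]


def mannwhitney_p(
    u: float,
    n_set: int,
    n_bg: int,
    ties: np.ndarray | None = None,
) -> tuple[float, str]:
    """Two-sided Mann–Whitney p from the statistic and group sizes.

    Exact enumeration of the null U distribution when ``n_set·n_bg <= 400``
    and the ranking is tie-free; otherwise a normal approximation with
    tie-corrected variance and a 0.5 continuity correction.

    Returns ``(p, method)`` with method in {"exact", "normal"}.
    """
    if n_set < 1 or n_bg < 1:
        raise ValueError("both group sizes must be >= 1")
    has_ties = ties is not None and len(np.atleast_1d(ties)) > 0
    mu = n_set * n_bg / 2.0
    if n_set * n_bg <= EXACT_MAX_PRODUCT and not has_ties:
        counts = mannwhitney_u_distribution(n_set, n_bg)
        dev = abs(u - mu)
        support = np.arange(counts.size, dtype=float)
        p = counts[np.abs(support - mu) >= dev - 1e-12].sum() / counts.sum()
        return float(min(1.0, p)), "exact"
    n = n_set + n_bg
    tie_term = 0.0
    if has_ties:
        t = np.asarray(ties, dtype=float)
        tie_term = float((t**3 - t).sum()) / (n * (n - 1))
    sigma2 = n_set * n_bg / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return 1.0, "normal"
    dev = abs(u - mu)
    z = max(0.0, dev - 0.5) / math.sqrt(sigma2)
    return float(min(1.0, 2.0 * sps.norm.sf(z))), "normal"


def bonferroni(p_values: np.ndarray | list[float]) -> np.ndarray:
    """Bonferroni adjustment over one query family: min(1, p·m)."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * p.size)


@dataclass
class EnrichmentResult:
    """Per-(dataset, layer) AUC enrichment of one query gene set.

    ``table`` holds one row per (dataset, layer) with columns dataset, layer,
    auc, u_statistic, p_raw, p_adjusted, n_set, n_background, method, flag;
    ``mean_auc`` is the per-layer AUC averaged across the datasets that
    contain that layer. ``n_tests`` is the Bonferroni family size (the
    number of computed cells in this query).
    """

    table: pd.DataFrame
    mean_auc: pd.Series
    n_tests: int
    gene_set: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "gene_set": list(self.gene_set),
            "n_tests": self.n_tests,
            "cells": self.table.where(self.table.notna(), None).to_dict("records"),
            "mean_auc": {k: (None if pd.isna(v) else float(v))
                         for k, v in self.mean_auc.items()},
        }


def enrichment_table(
    matrices: list[LayerMatrix],
    gene_set: list[str],
    threshold_cpm: float = LOW_EXPRESSION_CPM,
) -> EnrichmentResult:
    """Layer-enrichment AUC of one gene set across harmonized datasets.

    Per matrix: low-expression filter, per-gene z-scoring, then per layer the
    set-vs-background AUC with its Mann–Whitney p. Bonferroni correction uses
    the whole family (every computed dataset × layer cell in this query).
    A matrix where the query cannot be evaluated contributes flagged rows
    rather than aborting the query.
    """
    if not matrices:
        raise ValueError("need at least one layer matrix")
    rows: list[dict] = []
    for m in matrices:
        try:
            filtered = filter_low_expression(m, threshold_cpm)
            z, _ = zscore_by_gene(filtered)
        except ValueError as exc:
            for layer in m.layer_labels:
                rows.append(_flagged_row(m.name, layer, str(exc)))
            continue
        for layer in z.layer_labels:
            try:
                auc, u, n_set, n_bg = layer_auc(z, gene_set, layer)
            except ValueError as exc:
                rows.append(_flagged_row(m.name, layer, str(exc)))
                continue
            ties = tie_structure(z.values[layer])
            p, method = mannwhitney_p(u, n_set, n_bg, ties)
            rows.append({
                "dataset": m.name, "layer": layer, "auc": auc, "u_statistic": u,
                "p_raw": p, "p_adjusted": np.nan, "n_set": n_set,
                "n_background": n_bg, "method": method, "flag": "",
            })
    table = pd.DataFrame(rows)
    computed = table["flag"] == ""
    m_tests = int(computed.sum())
    if m_tests:
        table.loc[computed, "p_adjusted"] = bonferroni(
            table.loc[computed, "p_raw"].to_numpy())
    mean_auc = (
        table[computed].groupby("layer", sort=False)["auc"].mean()
        .reindex([l for l in LAYER_ORDER if l in set(table["layer"])])
    )
    return EnrichmentResult(table, mean_auc, m_tests, list(gene_set))


def _flagged_row(dataset: str, layer: str, flag: str) -> dict:
    return {
        "dataset": dataset, "layer": layer, "auc": np.nan, "u_statistic": np.nan,
        "p_raw": np.nan, "p_adjusted": np.nan, "n_set": 0, "n_background": 0,
        "method": "", "flag": flag,
    }
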