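"""Static single-gene and multi-gene query reports with figure export.

Single-gene mode: a grouped bar plot of the gene's CPM across layers in
every dataset (log-scaled y), plus agreement statistics (Pearson r, p,
genome-wide percentile) between the bulk-role and spatial-role matrices.

Multi-gene mode: the AUC layer-enrichment heatmap across datasets (with a
cross-dataset mean row and significance asterisks at adjusted p < 0.05),
per-dataset expression views — a gene × layer heatmap for sets of 30 genes
or fewer, otherwise a dot plot with the set's per-layer median — and a text
summary of per-dataset gene coverage and agreement.

Figures are views of the report JSON, not recomputations: every number a
figure encodes is present in the JSON first. Rendering is deterministic
(fixed SVG hash salt, no embedded dates).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns

from . import stats
from .io_matrix import LAYER_ORDER, LayerMatrix

#: Gene-set size at and below which expression is drawn as a heatmap.
HEATMAP_MAX_GENES = 30

SIGNIFICANCE_ALPHA = 0.05

plt.rcParams["svg.hashsalt"] = "laminar"


@dataclass
class QueryReport:
    """Everything one query produced: stats, coverage, figure paths."""

    mode: str  # "single" | "multi"
    query: list[str]
    coverage: dict[str, list[str]]  # dataset name -> queried genes it assays
    correlation: dict | None = None
    enrichment: dict | None = None
    figures: list[str] = field(default_factory=list)
    summary: str = ""
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "mode": self.mode,
            "query": self.query,
            "coverage": self.coverage,
            "correlation": self.correlation,
            "enrichment": self.enrichment,
            "figures": self.figures,
            "summary": self.summary,
            "config": self.config,
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True,
                      default=_jsonify)
            fh.write("\n")


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        obj = obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _clean(x: float) -> float | None:
    x = float(x)
    return x if math.isfinite(x) else None


def _levenshtein(a: str, b: str, cap: int = 3) -> int:
    if abs(len(a) - len(b)) > cap:
        return cap
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        if min(cur) >= cap:
            return cap
        prev = cur
    return prev[-1]


def suggest_symbols(symbol: str, matrices: list[LayerMatrix],
                    max_distance: int = 2, limit: int = 5) -> list[str]:
    """Known symbols within edit distance ``max_distance`` of the query."""
    universe: set[str] = set()
    for m in matrices:
        universe.update(m.gene_ids)
    scored = sorted(
        (d, s) for s in universe
        if (d := _levenshtein(symbol, s, max_distance + 1)) <= max_distance
    )
    return [s for _, s in scored[:limit]]


def _coverage(genes: list[str], matrices: list[LayerMatrix]) -> dict[str, list[str]]:
    return {m.name: [g for g in genes if g in m.values.index] for m in matrices}


def _bulk_pair(matrices: list[LayerMatrix]
               ) -> tuple[LayerMatrix, LayerMatrix] | None:
    """The (bulk-role, spatial-role) pair agreement statistics compare."""
    bulk = [m for m in matrices if m.meta.get("role") == "bulk"]
    spatial = [m for m in matrices if m.meta.get("role") == "spatial"]
    if len(bulk) == 1 and len(spatial) == 1:
        return bulk[0], spatial[0]
    return None


def _correlation_dict(res: stats.CorrelationResult) -> dict:
    return {
        "query": res.query,
        "r": _clean(res.r),
        "p": _clean(res.p),
        "percentile": _clean(res.percentile),
        "n_layers": res.n_layers,
        "flags": res.flags,
        "per_gene_r": {g: _clean(v) for g, v in res.per_gene_r.items()},
        "missing": res.missing,
    }


# ---------------------------------------------------------------------------
# single gene


def single_gene_report(
    gene: str,
    matrices: list[LayerMatrix],
    out_dir: str | Path,
    fig_format: str = "svg",
    config: dict | None = None,
) -> QueryReport:
    """Bar-plot one gene's laminar profile and report cross-dataset agreement."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coverage = _coverage([gene], matrices)
    present = [m for m in matrices if coverage[m.name]]
    if not present:
        hints = suggest_symbols(gene, matrices)
        hint_txt = f"; did you mean {', '.join(hints)}?" if hints else ""
        raise KeyError(f"gene {gene!r} not assayed in any dataset{hint_txt}")

    correlation = None
    pair = _bulk_pair(matrices)
    if pair is not None and all(gene in m.values.index for m in pair):
        res = stats.gene_correlation(gene, *pair)
        correlation = _correlation_dict(res)

    report = QueryReport(
        mode="single", query=[gene],
        coverage={k: v for k, v in coverage.items()},
        correlation=correlation, config=dict(config or {}),
    )
    lines = [f"Gene {gene} assayed in {len(present)}/{len(matrices)} datasets: "
             + ", ".join(m.name for m in present) + "."]
    if correlation is not None:
        lines.append(
            f"Agreement ({pair[0].name} vs {pair[1].name}): "
            f"r = {correlation['r']:.3f} (p = {correlation['p']:.2g}, "
            f"n = {correlation['n_layers']} layers), "
            f"{correlation['percentile']:.0f}th percentile genome-wide.")
    else:
        lines.append("Agreement statistics unavailable "
                     "(gene absent from a bulk-role dataset or no bulk pair).")
    report.summary = "\n".join(lines)

    if fig_format != "none":
        fig_path = out_dir / f"{gene}_profile.{fig_format}"
        _plot_single_gene(gene, present, fig_path)
        report.figures.append(fig_path.name)
    report.write_json(out_dir / f"{gene}_report.json")
    (out_dir / f"{gene}_summary.txt").write_text(report.summary + "\n")
    return report


def _plot_single_gene(gene: str, matrices: list[LayerMatrix], path: Path) -> None:
    rows = []
    for m in matrices:
        for layer in m.layer_labels:
            rows.append({"dataset": m.name, "layer": layer,
                         "cpm": float(2 ** m.values.loc[gene, layer])})
    df = pd.DataFrame(rows)
    order = [l for l in LAYER_ORDER if l in set(df["layer"])]
    fig, ax = plt.subplots(figsize=(1.2 + 1.1 * len(order), 4))
    sns.barplot(df, x="layer", y="cpm", hue="dataset", order=order,
                palette="colorblind", ax=ax)
    ax.set_yscale("log")
    ax.set_ylabel("CPM (log scale)")
    ax.set_xlabel("cortical layer")
    ax.set_title(f"{gene} laminar expression")
    ax.legend(fontsize=8, frameon=False)
    fig.tight_layout()
    fig.savefig(path, metadata=_fig_metadata(path))
    plt.close(fig)


def _fig_metadata(path: Path) -> dict | None:
    if path.suffix == ".svg":
        return {"Date": None}
    return None


# ---------------------------------------------------------------------------
# multi gene


def multi_gene_report(
    genes: list[str],
    matrices: list[LayerMatrix],
    out_dir: str | Path,
    fig_format: str = "svg",
    config: dict | None = None,
) -> QueryReport:
    """AUC enrichment heatmap + expression views + agreement for a gene set."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    coverage = _coverage(genes, matrices)
    if not any(coverage.values()):
        raise KeyError(f"none of the {len(genes)} queried genes assayed anywhere")

    enrichment = stats.enrichment_table(matrices, genes)
    correlation = None
    pair = _bulk_pair(matrices)
    if pair is not None:
        try:
            correlation = _correlation_dict(stats.set_correlation(genes, *pair))
        except KeyError:
            correlation = None

    report = QueryReport(
        mode="multi", query=list(genes), coverage=coverage,
        correlation=correlation, enrichment=enrichment.to_dict(),
        config=dict(config or {}),
    )
    lines = [f"Queried {len(genes)} genes."]
    for name, covered in coverage.items():
        lines.append(f"  {name}: {len(covered)}/{len(genes)} genes assayed.")
    if correlation is not None and correlation["r"] is not None:
        lines.append(
            f"Mean agreement ({pair[0].name} vs {pair[1].name}): "
            f"r = {correlation['r']:.3f} (p = {correlation['p']:.2g}, "
            f"n = {correlation['n_layers']} layers), "
            f"{correlation['percentile']:.0f}th percentile genome-wide.")
    best = enrichment.mean_auc.dropna()
    if len(best):
        lines.append(f"Highest cross-dataset mean AUC: "
                     f"{best.idxmax()} ({best.max():.3f}).")
    report.summary = "\n".join(lines)

    if fig_format != "none":
        auc_path = out_dir / f"enrichment_auc.{fig_format}"
        _plot_auc_heatmap(enrichment, auc_path)
        report.figures.append(auc_path.name)
        for m in matrices:
            covered = coverage[m.name]
            if not covered:
                continue
            fig_path = out_dir / f"expression_{m.name}.{fig_format}"
            if len(genes) <= HEATMAP_MAX_GENES:
                _plot_expression_heatmap(m, covered, fig_path)
            else:
                _plot_expression_dotplot(m, covered, fig_path)
            report.figures.append(fig_path.name)

    enrichment.to_tsv(out_dir / "enrichment.tsv")
    report.write_json(out_dir / "set_report.json")
    (out_dir / "set_summary.txt").write_text(report.summary + "\n")
    return report


def expression_figure_kind(n_genes: int) -> str:
    """Branch rule for the expression view: heatmap up to 30 genes, else dots."""
    return "heatmap" if n_genes <= HEATMAP_MAX_GENES else "dotplot"


def _plot_auc_heatmap(enrichment: stats.EnrichmentResult, path: Path) -> None:
    wide = enrichment.table.pivot(index="dataset", columns="layer", values="auc")
    padj = enrichment.table.pivot(index="dataset", columns="layer",
                                  values="p_adjusted")
    layers = [l for l in LAYER_ORDER if l in wide.columns]
    wide, padj = wide[layers], padj[layers]
    wide.loc["mean"] = enrichment.mean_auc.reindex(layers)
    annot = wide.copy().astype(object)
    for ds in wide.index:
        for layer in layers:
            v = wide.loc[ds, layer]
            if pd.isna(v):
                annot.loc[ds, layer] = "–"
                continue
            star = ("*" if ds != "mean" and pd.notna(padj.loc[ds, layer])
                    and padj.loc[ds, layer] < SIGNIFICANCE_ALPHA else "")
            annot.loc[ds, layer] = f"{v:.2f}{star}"
    fig, ax = plt.subplots(
        figsize=(1.5 + 0.9 * len(layers), 1.0 + 0.6 * len(wide.index)))
    sns.heatmap(wide.astype(float), annot=annot, fmt="", cmap="RdBu_r",
                center=0.5, vmin=0, vmax=1, ax=ax,
                cbar_kws={"label": "AUC"})
    ax.set_title("layer enrichment (AUC); * adjusted p < "
                 f"{SIGNIFICANCE_ALPHA}")
    fig.tight_layout()
    fig.savefig(path, metadata=_fig_metadata(path))
    plt.close(fig)


def _plot_expression_heatmap(m: LayerMatrix, genes: list[str], path: Path) -> None:
    sub = m.values.loc[[g for g in genes if g in m.values.index]]
    fig, ax = plt.subplots(
        figsize=(1.5 + 0.7 * len(sub.columns), 1.0 + 0.3 * max(len(sub), 2)))
    sns.heatmap(sub, cmap="viridis", ax=ax, cbar_kws={"label": "log2 CPM"})
    ax.set_title(f"{m.name}: queried gene expression")
    fig.tight_layout()
    fig.savefig(path, metadata=_fig_metadata(path))
    plt.close(fig)


def _plot_expression_dotplot(m: LayerMatrix, genes: list[str], path: Path) -> None:
    sub = m.values.loc[[g for g in genes if g in m.values.index]]
    long = sub.melt(var_name="layer", value_name="log2_cpm", ignore_index=False)
    order = list(sub.columns)
    fig, ax = plt.subplots(figsize=(1.5 + 0.9 * len(order), 4))
    sns.stripplot(long, x="layer", y="log2_cpm", order=order, size=3,
                  alpha=0.5, color="0.4", jitter=0.25, ax=ax)
    medians = sub.median(axis=0)
    ax.plot(range(len(order)), medians[order], "D-", color="crimson",
            label="set median")
    ax.set_title(f"{m.name}: queried gene expression (n={len(sub)})")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, metadata=_fig_metadata(path))
    plt.close(fig)
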