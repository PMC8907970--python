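import numpy as np
import pandas as pd
import pytest

from laminar import CountTable, LayerMatrix


@pytest.fixture
def small_counts() -> CountTable:
    """4 genes x 4 samples with slice labels, two samples per slice."""
    counts = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [0.0, 0.0, 6.0, 0.0],
         [5.0, 5.0, 5.0, 5.0],
         [2.0, 4.0, 8.0, 16.0]],
        index=["GA", "GB", "GC", "GD"],
        columns=["s1a", "s1b", "s2a", "s2b"],
    )
    meta = pd.DataFrame(
        {"slice_label": ["S1", "S1", "S2", "S2"]},
        index=pd.Index(counts.columns, name="sample_id"),
    )
    return CountTable(counts, meta)


@pytest.fixture
def layer_matrix() -> LayerMatrix:
    """5 genes x 7 layers of log2-CPM-like values."""
    rng = np.random.default_rng(11)
    layers = ["L1", "L2", "L3", "L4", "L5", "L6", "WM"]
    values = pd.DataFrame(
        rng.normal(8, 2, (5, 7)),
        index=[f"G{i}" for i in range(5)],
        columns=layers,
    )
    return LayerMatrix(values, {"name": "toy", "role": "bulk"})


def make_layer_matrix(values: np.ndarray, genes, layers, **meta) -> LayerMatrix:
    return LayerMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=list(genes),
                     columns=list(layers)),
        meta,
    )


def brute_force_auc(z: pd.Series, gene_set: set) -> tuple[float, float]:
    """Ordered-pair counting oracle: for every (set, background) pair, count
    1 if the set gene's value is larger, 0.5 on a tie."""
    set_vals = [v for g, v in z.items() if g in gene_set]
    bg_vals = [v for g, v in z.items() if g not in gene_set]
    u = sum(1.0 if s > b else 0.5 if s == b else 0.0
            for s in set_vals for b in bg_vals)
    return u / (len(set_vals) * len(bg_vals)), u
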