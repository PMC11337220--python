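"""Edge-weight interpretation across a run ensemble.

Because a single training run's weights depend on initialization, influence
is read from the distribution of each active edge's weight over repeated
runs.  Two statistics are reported per edge: the signed mean (direction —
does the edge push toward or away from response) and the mean absolute
value (importance, used for ranking).  Only biologically declared
(mask = 1) edges exist, so every row of a summary is interpretable as a
specific gene-component, component-cell, or cell-role relationship.

Sign canonicalization.  For odd hidden activations (tanh, identity) the
network function is invariant under flipping any hidden node's inbound and
outbound weights (and bias) together, so the raw sign of an individual
weight is an accident of initialization — across repeated runs it is a coin
flip.  Signed readouts therefore use a canonical orientation: each
component and cell node is oriented so that the summed inbound weight from
the already-oriented previous layer is nonnegative (a node then "points
with" its markers), and each role node is oriented so that it pushes the
predicted response probability up.  Under this convention the cell->role
layer carries the end-to-end direction of each cell's marker program:
positive means the program as measured pushes toward response.  Absolute
values, and hence all rankings, are unaffected.  For relu the flip is not
an exact symmetry and canonicalization is merely a reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .experiments import RunEnsemble

#: layer name -> (weight-matrix index, row-label attr, column-label attr)
_LAYERS = {
    "gene_component": (0, "genes", "components"),
    "component_cell": (1, "components", "cells"),
    "cell_role": (2, "cells", "roles"),
    "role_output": (3, "roles", None),
}


@dataclass
class WeightSummary:
    """Per-active-edge weight statistics over an ensemble's runs.

    ``table`` has one row per active edge (source, target, mean, sd,
    mean_abs, rank_within_target); ``samples[i]`` holds edge *i*'s weight in
    every run, aligned with the table rows.
    """

    layer: str
    table: pd.DataFrame
    samples: np.ndarray
    n_runs: int


def _canonical_signs(model) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orientation (+-1) per component, cell, and role node (see module doc)."""
    w1, w2, w3, w4 = model.weights

    def sgn(v):
        s = np.sign(v)
        s[s == 0] = 1.0
        return s

    s_comp = sgn(w1.sum(axis=0))
    s_cell = sgn((s_comp[:, None] * w2).sum(axis=0))
    if w4.shape[1] == 1:
        s_role = sgn(w4[:, 0].copy())
    else:  # two-node softmax head: responder logit minus non-responder logit
        s_role = sgn(w4[:, 1] - w4[:, 0])
    return s_comp, s_cell, s_role


def _canonical_weights(model) -> list[np.ndarray]:
    s_comp, s_cell, s_role = _canonical_signs(model)
    w1, w2, w3, w4 = model.weights
    return [
        w1 * s_comp[None, :],
        s_comp[:, None] * w2 * s_cell[None, :],
        s_cell[:, None] * w3 * s_role[None, :],
        s_role[:, None] * w4,
    ]


def layer_weights(ensemble: RunEnsemble, layer: str,
                  canonical: bool = True) -> WeightSummary:
    """Collect per-run weights of every active edge in *layer*.

    With ``canonical`` (default) weights are sign-canonicalized per run so
    that signed means are comparable across runs; set False for the raw
    stored weights.  ``rank_within_target`` orders edges sharing a target
    node by descending mean absolute weight (1 = most influential), ties
    broken by source label.
    """
    if layer not in _LAYERS:
        raise ValueError(f"unknown layer {layer!r}; choose from {sorted(_LAYERS)}")
    if not ensemble.models:
        raise ValueError("ensemble holds no trained models (keep_models=False?)")
    idx, row_attr, col_attr = _LAYERS[layer]
    mask = ensemble.masks.all_masks()[idx]
    rows = list(getattr(ensemble.masks, row_attr))
    if col_attr is None:
        cols = [f"output_{j}" for j in range(mask.shape[1])]
    else:
        cols = list(getattr(ensemble.masks, col_attr))

    active = np.argwhere(mask == 1)
    per_run = [(_canonical_weights(m)[idx] if canonical else m.weights[idx])
               for m in ensemble.models]
    stacked = np.stack(per_run)  # runs x rows x cols
    samples = stacked[:, active[:, 0], active[:, 1]].T  # edges x runs

    table = pd.DataFrame({
        "layer": layer,
        "source": [rows[i] for i, _ in active],
        "target": [cols[j] for _, j in active],
        "mean": samples.mean(axis=1),
        "sd": samples.std(axis=1, ddof=1) if samples.shape[1] > 1 else 0.0,
        "mean_abs": np.abs(samples).mean(axis=1),
    })
    order = table.sort_values(["target", "mean_abs", "source"],
                              ascending=[True, False, True]).index
    ranks = pd.Series(0, index=table.index)
    for target, grp in table.loc[order].groupby("target", sort=False):
        ranks.loc[grp.index] = np.arange(1, len(grp) + 1)
    table["rank_within_target"] = ranks
    return WeightSummary(layer=layer, table=table, samples=samples,
                         n_runs=len(ensemble.models))


def rank_genes(ensemble: RunEnsemble, cell: str) -> pd.DataFrame:
    """Genes of *cell*'s components, ordered by mean absolute weight.

    A gene connected to several of the cell's components gets the sum of its
    edge importances (equal to the single edge weight in the usual
    one-membership case).  Ties are broken lexicographically.  The signed
    mean is carried along for direction.
    """
    if cell not in ensemble.masks.cells:
        raise ValueError(f"unknown cell {cell!r}; known: {list(ensemble.masks.cells)}")
    summary = layer_weights(ensemble, "gene_component")
    cell_components = {
        comp for comp, row in zip(ensemble.masks.components,
                                  ensemble.masks.component_cell)
        if row[list(ensemble.masks.cells).index(cell)] == 1
    }
    sub = summary.table[summary.table["target"].isin(cell_components)]
    if sub.empty:
        raise ValueError(f"cell {cell!r} has no active gene edges")
    agg = (sub.groupby("source")
           .agg(mean_abs=("mean_abs", "sum"), mean=("mean", "sum"),
                components=("target", lambda t: ",".join(sorted(t))))
           .reset_index().rename(columns={"source": "gene"}))
    agg = agg.sort_values(["mean_abs", "gene"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)
    agg.insert(0, "rank", np.arange(1, len(agg) + 1))
    agg.insert(1, "cell", cell)
    return agg


def export_summary(summary: WeightSummary, path: str | Path) -> None:
    """Write the per-edge table as TSV (round-trips means exactly via repr)."""
    if summary.table.empty:
        raise ValueError(f"layer {summary.layer!r} has no active edges to export")
    summary.table.to_csv(path, sep="\t", index=False,
                         float_format=lambda v: repr(float(v)))


def plot_distributions(summary: WeightSummary, path: str | Path,
                       max_edges: int = 40) -> None:
    """Violin plot of per-edge weight distributions across runs.

    Edges are ordered by descending mean absolute weight; at most
    *max_edges* are drawn.  Deterministic given the summary.
    """
    if summary.table.empty:
        raise ValueError(f"layer {summary.layer!r} has no active edges to plot")
    order = summary.table["mean_abs"].to_numpy().argsort()[::-1][:max_edges]
    data = [summary.samples[i] for i in order]
    labels = [f"{summary.table['source'].iloc[i]}→{summary.table['target'].iloc[i]}"
              for i in order]
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * len(data)), 4))
    ax.violinplot(data, showmeans=True, widths=0.8)
    ax.axhline(0.0, color="grey", lw=0.5)
    ax.set_xticks(np.arange(1, len(data) + 1))
    ax.set_xticklabels(labels, rotation=90, fontsize=6)
    ax.set_ylabel("edge weight")
    ax.set_title(f"{summary.layer} weights over {summary.n_runs} runs")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
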