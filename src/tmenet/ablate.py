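"""Cell-type ablation studies.

An ablation removes one cell type together with its components and its
exclusive marker genes (genes shared with surviving cells stay), retrains
the network over the same repeated train/test partitions as an all-cells
baseline, and asks two questions:

* how do the cell-to-role weights of the *surviving* cells shift — in
  particular those of the opposite role (do suppressive programs take up
  slack when a stimulatory cell disappears, and vice versa)?
* how much predictive performance (AUC, accuracy) is lost?

Pairing discipline: run *i* of every condition uses the identical train/test
partition (same split seed on the same sample set), so weight shifts and
metric drops are not confounded by partition noise.  Weight shifts are
tested with a two-sample Welch t-test over the per-run weight samples;
metric drops with a paired t-test over per-run metrics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .data_io import LabeledCohort
from .experiments import ComparisonResult, RunEnsemble, compare_models, repeat_runs
from .hierarchy import ROLES, HierarchySpec, remove_cell
from .network import TrainConfig


@dataclass
class AblationOutcome:
    """Result of removing one cell type, against a shared baseline."""

    removed_cell: str
    baseline: RunEnsemble
    ablated: RunEnsemble
    weight_deltas: pd.DataFrame  # cell, role, baseline_mean, ablated_mean, delta, t, p
    auc_comparison: ComparisonResult
    accuracy_comparison: ComparisonResult


def _cell_role_samples(ensemble: RunEnsemble, cell: str) -> np.ndarray:
    """Per-run weight of *cell*'s single active cell->role edge."""
    cells = list(ensemble.masks.cells)
    i = cells.index(cell)
    j = int(np.argmax(ensemble.masks.cell_role[i]))
    return np.array([m.weights[2][i, j] for m in ensemble.models])


def run_ablation(
    cohort: LabeledCohort,
    spec: HierarchySpec,
    cell: str,
    cfg: TrainConfig | None = None,
    n_runs: int = 100,
    baseline: RunEnsemble | None = None,
    ratio: float = 0.7,
) -> AblationOutcome:
    """Ablate *cell* and compare against the all-cells baseline.

    A precomputed *baseline* (from :func:`tmenet.experiments.repeat_runs`
    with the same cfg/n_runs) is reused when given — compute it once when
    ablating several cells.  The ablated condition reuses the baseline's
    split-seed sequence, so run *i* sees the identical partition in both
    conditions.
    """
    cfg = cfg or TrainConfig()
    if baseline is None:
        baseline = repeat_runs(cohort, spec, cfg, n_runs=n_runs, ratio=ratio)
    elif baseline.n_runs != n_runs or baseline.config.seed != cfg.seed:
        raise ValueError("supplied baseline was run with a different seed/n_runs")
    ablated_spec = remove_cell(spec, cell)
    ablated = repeat_runs(cohort, ablated_spec, cfg, n_runs=n_runs, ratio=ratio)
    assert ablated.split_seeds == baseline.split_seeds

    rows = []
    for surv in ablated_spec.cells:
        base_w = _cell_role_samples(baseline, surv.name)
        abl_w = _cell_role_samples(ablated, surv.name)
        if np.allclose(base_w, abl_w):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(abl_w, base_w, equal_var=False)
        rows.append({
            "cell": surv.name, "role": surv.role,
            "baseline_mean": base_w.mean(), "ablated_mean": abl_w.mean(),
            "delta": abl_w.mean() - base_w.mean(),
            "t": float(t), "p": float(p),
        })
    return AblationOutcome(
        removed_cell=cell,
        baseline=baseline,
        ablated=ablated,
        weight_deltas=pd.DataFrame(rows),
        auc_comparison=compare_models(
            (ablated.aucs, ablated.split_seeds), (baseline.aucs, baseline.split_seeds)
        ),
        accuracy_comparison=compare_models(
            (ablated.accuracies, ablated.split_seeds),
            (baseline.accuracies, baseline.split_seeds),
        ),
    )


def _check_shared_baseline(outcomes: list[AblationOutcome]) -> RunEnsemble:
    base = outcomes[0].baseline
    for o in outcomes[1:]:
        if (o.baseline.split_seeds != base.split_seeds
                or o.baseline.spec.cell_names() != base.spec.cell_names()):
            raise ValueError("ablation outcomes do not share a common baseline")
    return base


def ablation_matrix(
    outcomes: list[AblationOutcome], ablated_role: str | None = None
) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Cross tables: removed cell (rows) x surviving opposite-role cell (cols).

    Returns ``{role: (delta_table, p_table)}`` for each role with at least
    one ablated cell (restricted to *ablated_role* when given): rows are the
    ablated cells of that role, columns the surviving cells of the opposite
    role, entries the cell->role weight change (ablated minus baseline) and
    its Welch-t p-value.  A cell never appears as its own column.
    """
    if not outcomes:
        raise ValueError("no ablation outcomes given")
    base = _check_shared_baseline(outcomes)
    role_of = {c.name: c.role for c in base.spec.cells}
    result: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    roles = [ablated_role] if ablated_role else list(ROLES)
    for role in roles:
        picked = [o for o in outcomes if role_of[o.removed_cell] == role]
        if not picked:
            continue
        opposite = ROLES[1 - ROLES.index(role)]
        cols = [c.name for c in base.spec.cells if c.role == opposite]
        deltas, ps = [], []
        for o in picked:
            wd = o.weight_deltas.set_index("cell")
            deltas.append([wd.loc[c, "delta"] for c in cols])
            ps.append([wd.loc[c, "p"] for c in cols])
        index = [o.removed_cell for o in picked]
        result[role] = (
            pd.DataFrame(deltas, index=index, columns=cols),
            pd.DataFrame(ps, index=index, columns=cols),
        )
    return result


def performance_panels(outcomes: list[AblationOutcome]) -> dict[str, pd.DataFrame]:
    """Per-condition metric distributions, including the "all" baseline.

    Returns ``{"auc": table, "accuracy": table}``; each table has one row
    per run and one column per condition ("all" plus each removed cell).
    """
    if not outcomes:
        raise ValueError("no ablation outcomes given")
    base = _check_shared_baseline(outcomes)
    auc_cols = {"all": base.aucs}
    acc_cols = {"all": base.accuracies}
    for o in outcomes:
        auc_cols[o.removed_cell] = o.ablated.aucs
        acc_cols[o.removed_cell] = o.ablated.accuracies
    return {"auc": pd.DataFrame(auc_cols), "accuracy": pd.DataFrame(acc_cols)}


def plot_ablation_heatmap(delta: pd.DataFrame, pvals: pd.DataFrame,
                          path: str | Path) -> None:
    """Heatmap of weight changes annotated with t-test p-values."""
    fig, ax = plt.subplots(figsize=(1.2 * delta.shape[1] + 2, 0.8 * delta.shape[0] + 2))
    vmax = max(abs(delta.to_numpy()).max(), 1e-12)
    im = ax.imshow(delta.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(delta.shape[1]), delta.columns, rotation=45, ha="right")
    ax.set_yticks(range(delta.shape[0]), delta.index)
    for i in range(delta.shape[0]):
        for j in range(delta.shape[1]):
            ax.text(j, i, f"{delta.iat[i, j]:+.3f}\np={pvals.iat[i, j]:.2g}",
                    ha="center", va="center", fontsize=7)
    ax.set_xlabel("surviving cell")
    ax.set_ylabel("ablated cell")
    fig.colorbar(im, ax=ax, label="weight change (ablated − baseline)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
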