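"""Synthetic labelled cohorts with hierarchy-consistent signal.

The generator emulates a pan-cancer immune-checkpoint-inhibitor cohort on
the log2-TPM scale: marker genes of each cell type shift between responders
and non-responders in the direction the cell's immune role implies
(responders up-express immunostimulatory programs and down-express
immunosuppressive ones), while decoy genes carry no label information.
Expression for marker gene g of cell c in sample i is drawn

    Normal(mu0 + s_c * delta_c * y_i, sigma),   s_c = +1 stimulatory / -1 suppressive

then floored at 0 (log2(TPM + 1) is nonnegative).  A gene claimed by several
cells receives the sum of their shifts.  This is deliberately a Gaussian
log2-scale model, not a count-level simulation: the network consumes
log2-TPM, so count realism would add nothing the tests could detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .data_io import LabeledCohort
from .hierarchy import ROLES, HierarchySpec, validate_spec


@dataclass(frozen=True)
class SimConfig:
    """Conditions of one synthetic cohort.

    ``effect_sizes`` maps cell name -> delta_c in log2 units (cells absent
    from the mapping get 0, i.e. no planted signal).  ``noise_sd`` is the
    within-group standard deviation sigma; ``baseline`` mu0 is the grand
    mean of every gene.  ``n_decoy_genes`` uninformative genes named
    ``DECOY_0001, ...`` are appended after the hierarchy's gene universe.
    """

    spec: HierarchySpec
    n_samples: int = 400
    responder_fraction: float = 0.5
    effect_sizes: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = 1.0
    baseline: float = 5.0
    n_decoy_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        problems = validate_spec(self.spec)
        if problems:
            raise ValueError(f"invalid hierarchy spec: {problems[0]}")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        n_resp = round(self.n_samples * self.responder_fraction)
        if not 1 <= n_resp <= self.n_samples - 1:
            raise ValueError(
                "responder_fraction must yield at least one sample per class"
            )
        known = set(self.spec.cell_names())
        unknown = set(self.effect_sizes) - known
        if unknown:
            raise ValueError(f"effect_sizes name unknown cells: {sorted(unknown)}")


def _role_sign(role: str) -> float:
    return +1.0 if role == ROLES[0] else -1.0


def generate(cfg: SimConfig) -> LabeledCohort:
    """Draw one labelled cohort under *cfg*; deterministic given the seed.

    Labels are exactly round(n * responder_fraction) responders followed by
    non-responders in a seeded random sample order.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = list(cfg.spec.gene_universe())
    genes += [f"DECOY_{i + 1:04d}" for i in range(cfg.n_decoy_genes)]
    n, g = cfg.n_samples, len(genes)

    n_resp = round(n * cfg.responder_fraction)
    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=n_resp, replace=False)] = 1

    # per-gene responder shift: sum of s_c * delta_c over cells claiming it
    gene_pos = {name: j for j, name in enumerate(genes)}
    shift = np.zeros(g)
    for cell in cfg.spec.cells:
        delta = float(cfg.effect_sizes.get(cell.name, 0.0))
        if delta == 0.0:
            continue
        for gene in set(cell.genes()):
            shift[gene_pos[gene]] += _role_sign(cell.role) * delta

    mean = cfg.baseline + labels[:, None] * shift[None, :]
    expr = np.maximum(rng.normal(mean, cfg.noise_sd), 0.0)
    return LabeledCohort(
        expression=expr,
        sample_ids=tuple(f"S{i + 1:04d}" for i in range(n)),
        gene_ids=tuple(genes),
        labels=labels,
    )


def planted_truth(cfg: SimConfig) -> pd.DataFrame:
    """Ground-truth table of (cell, role, signed effect) for recovery scoring.

    One row per cell with a nonzero planted effect; ``signed_effect`` is
    s_c * delta_c, the expected responder-minus-non-responder mean shift of
    that cell's marker genes.
    """
    rows = []
    for cell in cfg.spec.cells:
        delta = float(cfg.effect_sizes.get(cell.name, 0.0))
        if delta != 0.0:
            rows.append(
                {"cell": cell.name, "role": cell.role,
                 "delta": delta, "signed_effect": _role_sign(cell.role) * delta}
            )
    return pd.DataFrame(rows, columns=["cell", "role", "delta", "signed_effect"])
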