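"""Expression-matrix and label I/O, normalization, and hierarchy alignment.

Cohorts are sample x gene matrices of log2-scale TPM values with a binary
response label per sample (1 = responder to immune checkpoint inhibition,
0 = non-responder).  Raw count/abundance matrices are brought onto that
scale with :func:`tpm_log2`: per-sample rescaling to transcripts-per-million
followed by log2(x + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchy import HierarchySpec

logger = logging.getLogger(__name__)

_LABEL_ALIASES = {"0": 0, "1": 1, "NR": 0, "R": 1}


class CohortError(ValueError):
    """Raised for malformed expression or label inputs."""


@dataclass(frozen=True)
class LabeledCohort:
    """Sample x gene expression with binary response labels.

    ``expression`` is samples-in-rows, log2-scale TPM; identifiers are unique
    and finite values are required throughout.
    """

    expression: np.ndarray
    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    labels: np.ndarray

    def __post_init__(self) -> None:
        expr = np.asarray(self.expression, dtype=float)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "expression", expr)
        object.__setattr__(self, "labels", labels.astype(int))
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        if expr.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise CohortError(
                f"expression shape {expr.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise CohortError("duplicate sample identifiers")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise CohortError("duplicate gene identifiers")
        if labels.shape != (len(self.sample_ids),):
            raise CohortError("labels length must equal the number of samples")
        if not np.isin(labels, (0, 1)).all():
            bad = labels[~np.isin(labels, (0, 1))][0]
            raise CohortError(f"non-binary label value {bad!r}")
        if not np.isfinite(expr).all():
            raise CohortError("expression contains non-finite values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expression, index=list(self.sample_ids),
                            columns=list(self.gene_ids))

    def subset_samples(self, idx: np.ndarray) -> "LabeledCohort":
        idx = np.asarray(idx)
        return LabeledCohort(
            expression=self.expression[idx],
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            gene_ids=self.gene_ids,
            labels=self.labels[idx],
        )


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def _parse_label(v, sample: str) -> int:
    key = str(v).strip().upper()
    if key not in _LABEL_ALIASES:
        raise CohortError(
            f"sample {sample!r}: label {v!r} is not one of 0/1/NR/R"
        )
    return _LABEL_ALIASES[key]


def read_cohort(expr_path: str | Path, labels_path: str | Path,
                orientation: str = "auto") -> LabeledCohort:
    """Read a cohort from a delimited expression matrix and a labels table.

    The expression file may be oriented samples-in-rows or genes-in-rows;
    with ``orientation="auto"`` the orientation whose sample axis overlaps
    the labels file is chosen (``"samples"``/``"genes"`` force it).  Samples
    present in only one file are dropped with a logged warning; zero overlap
    is an error.
    """
    expr = _read_table(expr_path)
    lab = _read_table(labels_path)
    if lab.shape[1] < 1:
        raise CohortError(f"{labels_path}: expected columns (sample_id, response)")
    label_map = {str(s).strip(): _parse_label(v, str(s))
                 for s, v in lab.iloc[:, 0].items()}

    expr.index = expr.index.map(lambda s: str(s).strip())
    expr.columns = expr.columns.map(lambda s: str(s).strip())
    if orientation == "auto":
        by_row = len(set(expr.index) & label_map.keys())
        by_col = len(set(expr.columns) & label_map.keys())
        orientation = "samples" if by_row >= by_col else "genes"
    if orientation == "genes":
        expr = expr.T
    elif orientation != "samples":
        raise CohortError(f"unknown orientation {orientation!r}")

    shared = [s for s in expr.index if s in label_map]
    if not shared:
        raise CohortError(
            f"no overlapping samples between {expr_path} and {labels_path}"
        )
    dropped = (set(expr.index) | label_map.keys()) - set(shared)
    if dropped:
        logger.warning("dropping %d sample(s) present in only one file: %s",
                       len(dropped), sorted(dropped))
    expr = expr.loc[shared]
    return LabeledCohort(
        expression=expr.to_numpy(dtype=float),
        sample_ids=tuple(expr.index),
        gene_ids=tuple(expr.columns),
        labels=np.array([label_map[s] for s in shared]),
    )


def write_cohort(cohort: LabeledCohort, expr_path: str | Path,
                 labels_path: str | Path) -> None:
    """Write a cohort in the delimited formats :func:`read_cohort` accepts."""
    sep = "," if str(expr_path).endswith(".csv") else "\t"
    cohort.to_frame().to_csv(expr_path, sep=sep, index_label="sample_id")
    sep = "," if str(labels_path).endswith(".csv") else "\t"
    pd.DataFrame({"response": cohort.labels}, index=list(cohort.sample_ids)).to_csv(
        labels_path, sep=sep, index_label="sample_id"
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


def tpm_log2(raw: np.ndarray) -> np.ndarray:
    """Per-sample TPM rescaling followed by log2(x + 1).

    Each row (sample) of the nonnegative *raw* matrix is rescaled to sum to
    1e6, then transformed elementwise.  The pseudocount of 1 keeps zeros at
    zero.  All-zero samples and negative entries are rejected.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise CohortError("raw expression must be nonnegative")
    totals = raw.sum(axis=-1, keepdims=True)
    if np.any(totals == 0):
        raise CohortError("all-zero sample: TPM normalization undefined")
    return np.log2(raw / totals * 1e6 + 1.0)


# ---------------------------------------------------------------------------
# Hierarchy alignment
# ---------------------------------------------------------------------------


def align_to_spec(cohort: LabeledCohort, spec: HierarchySpec,
                  missing_policy: str = "error") -> LabeledCohort:
    """Restrict *cohort* to the spec's gene universe, in mask row order.

    Genes outside the hierarchy are dropped.  Hierarchy genes absent from
    the cohort are an error by default; ``missing_policy="zero"`` imputes a
    zero column with a logged warning instead.  Idempotent.
    """
    universe = spec.gene_universe()
    have = {g: i for i, g in enumerate(cohort.gene_ids)}
    missing = [g for g in universe if g not in have]
    if missing:
        if missing_policy == "error":
            raise CohortError(
                f"cohort lacks {len(missing)} hierarchy gene(s): {missing}"
            )
        if missing_policy != "zero":
            raise CohortError(f"unknown missing_policy {missing_policy!r}")
        logger.warning("imputing zeros for %d missing gene(s): %s",
                       len(missing), missing)
    cols = np.zeros((cohort.n_samples, len(universe)))
    for j, g in enumerate(universe):
        if g in have:
            cols[:, j] = cohort.expression[:, have[g]]
    return LabeledCohort(
        expression=cols,
        sample_ids=cohort.sample_ids,
        gene_ids=universe,
        labels=cohort.labels,
    )
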