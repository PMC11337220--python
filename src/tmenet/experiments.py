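"""Evaluation protocol: 7:3 splits, repeated runs, metrics, and benchmarks.

The protocol evaluates a model over repeated stratified 7:3 train/test
partitions of one cohort; run *i* derives both its split seed and its
initialization seed from ``base_seed + i``, so two model variants evaluated
with the same base seed see identical partitions and can be compared with a
paired t-test.  The benchmark pits the masked network against classic
scikit-learn classifiers (KNN, RFC, DTC, GBC, ABC, GNB, QDA, SVM — library
default hyperparameters, recorded in the output metadata) and two dense
neural controls of identical layer sizes: FULL (no masks) and DropNN (FULL
plus dropout 0.2 on the gene layer only).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
from sklearn.ensemble import (AdaBoostClassifier, GradientBoostingClassifier,
                              RandomForestClassifier)
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from . import network
from .data_io import LabeledCohort, align_to_spec
from .hierarchy import HierarchySpec, MaskSet, build_masks
from .network import ModelState, TrainConfig

#: Canonical benchmark roster.
MODEL_NAMES = ("TME-NET", "KNN", "RFC", "DTC", "GBC", "ABC", "GNB", "QDA",
               "SVM", "FULL", "DropNN")

_NEURAL = {"TME-NET", "FULL", "DropNN"}


# ---------------------------------------------------------------------------
# Splitting and metrics
# ---------------------------------------------------------------------------


def split(cohort: LabeledCohort, ratio: float = 0.7, seed: int = 0,
          stratified: bool = True) -> tuple[LabeledCohort, LabeledCohort]:
    """Partition a cohort into train/test at *ratio*, stratified by label.

    Deterministic given the seed; train and test are disjoint and exhaustive.
    Stratification requires at least two members per class.
    """
    y = cohort.labels
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to split")
    if stratified and min(np.bincount(y)) < 2:
        raise ValueError("stratified split needs >= 2 samples per class")
    idx = np.arange(cohort.n_samples)
    tr, te = train_test_split(
        idx, train_size=ratio, random_state=seed,
        stratify=y if stratified else None,
    )
    return cohort.subset_samples(np.sort(tr)), cohort.subset_samples(np.sort(te))


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC; ties count one half.

    Equals the probability that a random responder's score exceeds a random
    non-responder's.  Undefined (rejected) when only one class is present.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def accuracy(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of correct hard calls at *threshold*."""
    calls = (np.asarray(scores, float) >= threshold).astype(int)
    return float(np.mean(calls == np.asarray(labels)))


# ---------------------------------------------------------------------------
# Repeated runs
# ---------------------------------------------------------------------------


@dataclass
class RunEnsemble:
    """Metrics and trained states over repeated train/test runs of one model."""

    model_name: str
    spec: HierarchySpec
    masks: MaskSet
    aucs: np.ndarray
    accuracies: np.ndarray
    models: list[ModelState]
    split_seeds: tuple[int, ...]
    config: TrainConfig

    @property
    def n_runs(self) -> int:
        return len(self.split_seeds)

    def summary(self) -> dict[str, float]:
        return {
            "auc_mean": float(self.aucs.mean()),
            "auc_sd": float(self.aucs.std(ddof=1)) if self.n_runs > 1 else 0.0,
            "accuracy_mean": float(self.accuracies.mean()),
            "accuracy_sd": float(self.accuracies.std(ddof=1)) if self.n_runs > 1 else 0.0,
        }


def _dense_masks(masks: MaskSet) -> MaskSet:
    """All-ones masks of identical layer sizes (the FULL/DropNN controls)."""
    return MaskSet(
        gene_component=np.ones_like(masks.gene_component),
        component_cell=np.ones_like(masks.component_cell),
        cell_role=np.ones_like(masks.cell_role),
        role_output=np.ones_like(masks.role_output),
        genes=masks.genes, components=masks.components,
        cells=masks.cells, roles=masks.roles,
    )


def repeat_runs(
    cohort: LabeledCohort,
    spec: HierarchySpec,
    cfg: TrainConfig | None = None,
    n_runs: int = 100,
    ratio: float = 0.7,
    stratified: bool = True,
    variant: str = "TME-NET",
    keep_models: bool = True,
) -> RunEnsemble:
    """Train and test *variant* over *n_runs* repeated splits.

    Run *i* uses split seed and init seed ``cfg.seed + i``.  The cohort is
    aligned to the hierarchy's gene universe first (decoys dropped).
    """
    cfg = cfg or TrainConfig()
    if variant not in _NEURAL:
        raise ValueError(f"unknown network variant {variant!r}")
    aligned = align_to_spec(cohort, spec)
    masks = build_masks(spec)
    run_masks = masks if variant == "TME-NET" else _dense_masks(masks)
    run_cfg = replace(cfg, dropout_first=0.2) if variant == "DropNN" else cfg

    aucs, accs, models, seeds = [], [], [], []
    for i in range(n_runs):
        seed = cfg.seed + i
        train, test = split(aligned, ratio=ratio, seed=seed, stratified=stratified)
        model = network.init_model(run_masks, seed=seed, activation=cfg.activation)
        trained, _ = network.fit(model, train, replace(run_cfg, seed=seed))
        p = network.forward(trained, test.expression)
        aucs.append(auc(p, test.labels))
        accs.append(accuracy(p, test.labels))
        if keep_models:
            models.append(trained)
        seeds.append(seed)
    return RunEnsemble(
        model_name=variant, spec=spec, masks=run_masks,
        aucs=np.asarray(aucs), accuracies=np.asarray(accs),
        models=models, split_seeds=tuple(seeds), config=cfg,
    )


# ---------------------------------------------------------------------------
# Benchmark
# ---------------------------------------------------------------------------


def _baseline(name: str, seed: int):
    if name == "KNN":
        return KNeighborsClassifier()
    if name == "RFC":
        return RandomForestClassifier(random_state=seed)
    if name == "DTC":
        return DecisionTreeClassifier(random_state=seed)
    if name == "GBC":
        return GradientBoostingClassifier(random_state=seed)
    if name == "ABC":
        return AdaBoostClassifier(random_state=seed)
    if name == "GNB":
        return GaussianNB()
    if name == "QDA":
        return QuadraticDiscriminantAnalysis()
    if name == "SVM":
        return SVC(random_state=seed)
    raise ValueError(f"unknown model name {name!r}; known: {list(MODEL_NAMES)}")


@dataclass
class BenchmarkTable:
    """Per-(model, run) metrics over a shared split sequence."""

    table: pd.DataFrame  # columns: model, run, seed, auc, accuracy
    metadata: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return (self.table.groupby("model")[["auc", "accuracy"]]
                .agg(["mean", "std"]))

    def ensemble_aucs(self, model: str) -> np.ndarray:
        sub = self.table[self.table["model"] == model].sort_values("run")
        if sub.empty:
            raise ValueError(f"model {model!r} not in benchmark")
        return sub["auc"].to_numpy()


def benchmark(
    cohort: LabeledCohort,
    spec: HierarchySpec,
    model_list: Sequence[str] = MODEL_NAMES,
    n_runs: int = 100,
    cfg: TrainConfig | None = None,
    ratio: float = 0.7,
    stratified: bool = True,
) -> BenchmarkTable:
    """Score every model in *model_list* on identical split sequences.

    All models — including the scikit-learn baselines — consume the same
    hierarchy-aligned gene matrix the masked network sees.  Baselines score
    test samples with ``predict_proba`` when available, otherwise with
    ``decision_function``; their accuracy uses the estimator's own
    ``predict``.
    """
    cfg = cfg or TrainConfig()
    for name in model_list:
        if name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {name!r}; known: {list(MODEL_NAMES)}")
    aligned = align_to_spec(cohort, spec)
    rows = []
    baseline_params: dict[str, dict] = {}
    for name in model_list:
        if name in _NEURAL:
            ens = repeat_runs(aligned, spec, cfg, n_runs=n_runs, ratio=ratio,
                              stratified=stratified, variant=name, keep_models=False)
            for i, seed in enumerate(ens.split_seeds):
                rows.append({"model": name, "run": i, "seed": seed,
                             "auc": ens.aucs[i], "accuracy": ens.accuracies[i]})
            continue
        for i in range(n_runs):
            seed = cfg.seed + i
            train, test = split(aligned, ratio=ratio, seed=seed, stratified=stratified)
            est = _baseline(name, seed)
            est.fit(train.expression, train.labels)
            if hasattr(est, "predict_proba"):
                scores = est.predict_proba(test.expression)[:, 1]
            else:
                scores = est.decision_function(test.expression)
            acc = float(np.mean(est.predict(test.expression) == test.labels))
            rows.append({"model": name, "run": i, "seed": seed,
                         "auc": auc(scores, test.labels), "accuracy": acc})
        baseline_params[name] = _baseline(name, cfg.seed).get_params()
    meta = {
        "n_runs": n_runs, "base_seed": cfg.seed, "ratio": ratio,
        "stratified": stratified, "train_config": vars(cfg),
        "baseline_hyperparameters": {k: {p: repr(v) for p, v in ps.items()}
                                     for k, ps in baseline_params.items()},
    }
    return BenchmarkTable(table=pd.DataFrame(rows), metadata=meta)


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    pvalue: float
    variant: str  # "paired" or "welch"


def compare_models(ens_a, ens_b) -> ComparisonResult:
    """t-test on per-run AUCs of two ensembles.

    Paired when both ensembles used the same split-seed sequence (detected
    automatically), Welch otherwise.  Arguments may be :class:`RunEnsemble`
    objects or plain ``(aucs, split_seeds)`` pairs.  Identical samples give
    (t=0, p=1) by convention rather than the 0/0 the raw formula produces.
    """
    def unpack(e):
        if isinstance(e, RunEnsemble):
            return e.aucs, e.split_seeds
        a, s = e
        return np.asarray(a, float), tuple(s)

    a, seeds_a = unpack(ens_a)
    b, seeds_b = unpack(ens_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("compare_models needs at least 2 runs per ensemble")
    paired = len(a) == len(b) and seeds_a == seeds_b
    if paired:
        diff = a - b
        if np.allclose(diff, 0.0):
            return ComparisonResult(0.0, 1.0, "paired")
        t, p = stats.ttest_rel(a, b)
        return ComparisonResult(float(t), float(p), "paired")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(float(t), float(p), "welch")
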