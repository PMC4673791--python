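"""Stratified cross-validation, accuracy, and per-rank reporting.

The headline metric is plain accuracy A = c / t (correct over tested).
Cross-validated accuracy is pooled: total correct over total tested across
all folds, which equals the fold-size-weighted mean of per-fold accuracies.

Discretization is fitted inside each training fold only, so the interval
bounds the learners see never leak information from the test fold. The
significance transforms are per-genome functions of that genome alone and
therefore need no fold handling.

Classes with a single member cannot be stratified and are excluded with a
warning; when the smallest class is smaller than the requested fold count,
the fold count is reduced to it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .discretization import fit_cutpoints
from .errors import UndefinedMetricError, ValidationError
from .kmer_features import FeatureMatrix, build_matrix, filter_rare_classes
from .part import part_fit
from .ripper import ripper_fit
from .rules import RuleModel, model_complexity
from .sequence_io import RANKS

LEARNERS: dict[str, Callable] = {"ripper": ripper_fit, "part": part_fit}


def accuracy(correct: int, total: int) -> float:
    """A = c / t, the fraction of correctly classified test sequences."""
    if total <= 0:
        raise UndefinedMetricError("accuracy is undefined for total = 0")
    if not 0 <= correct <= total:
        raise ValidationError(f"need 0 <= correct <= total, got {correct}/{total}")
    return correct / total


def stratified_folds(labels: Sequence, n_folds: int, seed: int) -> list[np.ndarray]:
    """Deterministic stratified fold assignment (test indices per fold).

    Samples of each class are shuffled and dealt round-robin, so per-class
    fold sizes differ by at most one and each sample appears in exactly one
    test fold.
    """
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    offset = 0
    for cls in sorted(set(labels)):
        idx = np.where(labels == cls)[0]
        idx = idx[rng.permutation(len(idx))]
        for i, j in enumerate(idx):
            folds[(offset + i) % n_folds].append(int(j))
        offset += len(idx)  # stagger classes so fold sizes stay balanced
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass
class CVResult:
    """Per-fold and aggregate cross-validation outcome at one rank."""

    rank: str
    learner: str
    n_folds: int
    seed: int
    fold_accuracies: list[float]
    fold_test_sizes: list[int]
    accuracy: float
    classes: list[str]
    confusion: np.ndarray  # true x predicted
    complexity: dict[str, float]
    models: list[RuleModel] = field(default_factory=list, repr=False)
    excluded_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rank": self.rank,
            "learner": self.learner,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "fold_accuracies": self.fold_accuracies,
            "fold_test_sizes": self.fold_test_sizes,
            "accuracy": self.accuracy,
            "classes": self.classes,
            "confusion": self.confusion.tolist(),
            "complexity": self.complexity,
            "excluded_ids": self.excluded_ids,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


def stratified_kfold_cv(
    matrix: FeatureMatrix,
    rank: str,
    learner: str = "ripper",
    n_folds: int = 10,
    seed: int = 0,
    discretizer: str = "mdl",
    n_intervals: int = 3,
    learner_params: dict | None = None,
    keep_models: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation of one rule learner at one rank."""
    if learner not in LEARNERS:
        raise ValidationError(f"unknown learner {learner!r}; options: {sorted(LEARNERS)}")
    if n_folds < 2:
        raise ValidationError(f"n_folds must be >= 2, got {n_folds}")
    if rank not in matrix.labels:
        raise ValidationError(f"no labels at rank {rank!r}")
    labels = matrix.labels[rank]

    sizes: dict[str, int] = {}
    for lab in labels:
        if lab is not None:
            sizes[lab] = sizes.get(lab, 0) + 1
    excluded = [
        matrix.sample_ids[j]
        for j, lab in enumerate(labels)
        if lab is None or sizes[lab] < 2
    ]
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} samples in singleton/unlabeled classes at "
            f"{rank!r}: cannot be both trained and tested",
            stacklevel=2,
        )
        keep = [j for j, sid in enumerate(matrix.sample_ids) if sid not in set(excluded)]
        matrix = matrix.subset_samples(keep)
        labels = matrix.labels[rank]
        sizes = {c: n for c, n in sizes.items() if n >= 2}
    if not sizes:
        raise ValidationError(f"no usable classes at rank {rank!r}")
    smallest = min(sizes.values())
    if smallest < n_folds:
        warnings.warn(
            f"smallest class has {smallest} members; reducing n_folds from "
            f"{n_folds} to {smallest}",
            stacklevel=2,
        )
        n_folds = smallest

    classes = sorted(sizes)
    class_index = {c: i for i, c in enumerate(classes)}
    y = np.asarray(labels, dtype=object)
    fit = LEARNERS[learner]
    params = dict(learner_params or {})

    folds = stratified_folds(labels, n_folds, seed)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    fold_acc: list[float] = []
    fold_sizes: list[int] = []
    models: list[RuleModel] = []
    complexities: list[dict] = []
    correct_total = 0
    for fold_id, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        train_idx = np.array(
            [j for j in range(matrix.n_samples) if j not in test_set], dtype=int
        )
        train = matrix.subset_samples(train_idx)
        cuts = fit_cutpoints(
            train.values, train.labels[rank], method=discretizer, n_intervals=n_intervals
        )
        model = fit(train, rank, cuts=cuts, seed=seed + fold_id, **params)
        complexities.append(model_complexity(model))
        if keep_models:
            models.append(model)
        fidx = matrix.feature_index()
        X_test = matrix.values[:, test_idx]
        preds = _predict_columns(model, X_test, fidx)
        truth = y[test_idx]
        n_correct = 0
        for t, p in zip(truth, preds):
            if p in class_index:
                confusion[class_index[t], class_index[p]] += 1
            if t == p:
                n_correct += 1
        correct_total += n_correct
        fold_acc.append(accuracy(n_correct, len(test_idx)))
        fold_sizes.append(len(test_idx))

    agg = accuracy(correct_total, matrix.n_samples)
    complexity = {
        key: float(np.mean([c[key] for c in complexities]))
        for key in ("n_rules", "mean_literals_per_rule", "n_distinct_kmers")
    }
    return CVResult(
        rank=rank,
        learner=learner,
        n_folds=n_folds,
        seed=seed,
        fold_accuracies=fold_acc,
        fold_test_sizes=fold_sizes,
        accuracy=agg,
        classes=classes,
        confusion=confusion,
        complexity=complexity,
        models=models,
        excluded_ids=excluded,
    )


def _predict_columns(model: RuleModel, X: np.ndarray, fidx: dict[str, int]) -> list[str]:
    """Vectorized decision-list prediction over matrix columns."""
    n = X.shape[1]
    preds = np.array([model.default_class] * n, dtype=object)
    undecided = np.ones(n, dtype=bool)
    for rule in model.rules:
        m = undecided.copy()
        for lit in rule.literals:
            if lit.feature not in fidx:
                raise ValidationError(f"matrix lacks feature {lit.feature!r}")
            v = X[fidx[lit.feature]]
            lm = np.zeros(n, dtype=bool)
            for lo, hi in lit.intervals:
                lm |= (v >= lo) & (v < hi)
            m &= lm
        preds[m] = rule.conclusion
        undecided &= ~m
        if not undecided.any():
            break
    return list(preds)


def per_rank_report(
    records,
    ranks: Sequence[str] | None = None,
    learners: Sequence[str] = ("ripper", "part"),
    k: int = 4,
    strand_mode: str = "both",
    score_config=None,
    min_specimens: int = 9,
    n_folds: int = 10,
    seed: int = 0,
    discretizer: str = "mdl",
    matrix: FeatureMatrix | None = None,
) -> pd.DataFrame:
    """Cross-validated percent accuracy per taxonomic rank and learner.

    Builds the feature matrix (unless one is passed), applies the
    rare-class filter per rank, runs CV for each learner, and returns a
    table with one row per rank and one column per learner plus the
    row-wise mean and standard deviation. Ranks with no usable classes get
    a ``-`` entry.
    """
    if matrix is None:
        matrix = build_matrix(records, k=k, strand_mode=strand_mode, score_config=score_config)
    if ranks is None:
        ranks = [r for r in RANKS if r in matrix.labels]
    rows = []
    for rank in ranks:
        row: dict[str, object] = {"level": rank}
        accs = []
        for learner in learners:
            try:
                filtered = filter_rare_classes(matrix, rank, min_specimens)
                if len({l for l in filtered.labels[rank] if l is not None}) < 2:
                    raise ValidationError("fewer than two usable classes")
                res = stratified_kfold_cv(
                    filtered, rank, learner=learner, n_folds=n_folds, seed=seed,
                    discretizer=discretizer, keep_models=False,
                )
            except ValidationError:
                row[learner] = "-"
                continue
            pct = 100.0 * res.accuracy
            row[learner] = round(pct, 2)
            accs.append(pct)
        row["avg"] = round(float(np.mean(accs)), 2) if accs else "-"
        row["std"] = round(float(np.std(accs)), 2) if accs else "-"
        rows.append(row)
    return pd.DataFrame(rows).set_index("level")


def write_report(report: pd.DataFrame, path: str | Path) -> None:
    report.to_csv(path, sep="\t")
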