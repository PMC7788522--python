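"""Evaluation protocol: classification rate, confusion matrix, independent
test evaluation, repeated stratified k-fold cross-validation with in-fold
balancing, and Mann-Whitney comparison of classification-rate samples.

The single performance measure is the classification rate — correctly
classified test instances over total test instances. For the
median-supplement methods, balancing is applied to the training data only:
inside cross-validation, each training split is balanced after the fold
assignment, so synthetic instances can never leak into a held-out fold.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import mannwhitneyu

from . import naive_bayes as nb
from . import random_forest as rf
from .supplement import BalancedTable, balance
from .tabular import LabeledTable, TabularError, UnlabeledTable

__all__ = [
    "METHODS",
    "ConfusionMatrix",
    "RateSample",
    "EvaluationReport",
    "classification_rate",
    "confusion_matrix",
    "sensitivity",
    "fit_method",
    "independent_test",
    "kfold_cv",
    "mann_whitney",
]

#: The four method switches: median-supplement and plain variants of each
#: backend. Plain variants skip balancing entirely.
METHODS = ("MSRandomForest", "MSNaiveBayes", "RandomForest", "NaiveBayes")


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts indexed (predicted level x true level)."""

    counts: np.ndarray
    class_levels: tuple[str, str]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (2, 2) or (c < 0).any():
            raise ValueError("confusion matrix must be 2x2 with counts >= 0")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def rate(self) -> float:
        return float(np.trace(self.counts)) / self.total

    def __str__(self) -> str:
        a, b = self.class_levels
        w = max(len(a), len(b), 9)
        lines = [f"{'predicted':<{w}}  {a:>{w}}  {b:>{w}}"]
        for i, lvl in enumerate(self.class_levels):
            lines.append(
                f"{lvl:<{w}}  {self.counts[i, 0]:>{w}}  {self.counts[i, 1]:>{w}}"
            )
        return "\n".join(lines)


@dataclass
class RateSample:
    """Per-fold classification rates pooled over CV repeats."""

    rates: np.ndarray
    method: str
    k: int
    repeats: int
    seed: int
    fold_records: list | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if ((self.rates < 0) | (self.rates > 1)).any():
            raise ValueError("classification rates must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return float(self.rates.mean())


@dataclass
class EvaluationReport:
    """Outcome of one train/test evaluation."""

    method: str
    predictions: np.ndarray
    class_levels: tuple[str, str]
    seed: int
    truth: np.ndarray | None = None
    confusion: ConfusionMatrix | None = None
    rate: float | None = None

    def summary_lines(self, delimiter: str = "\t") -> list[str]:
        lines = [delimiter.join(["method", self.method]),
                 delimiter.join(["seed", str(self.seed)]),
                 delimiter.join(["n_test", str(len(self.predictions))])]
        if self.rate is not None:
            lines.append(delimiter.join(["classification_rate", f"{self.rate:.6f}"]))
        if self.confusion is not None:
            a, b = self.class_levels
            lines.append(delimiter.join(["confusion", "true_" + a, "true_" + b]))
            for i, lvl in enumerate(self.class_levels):
                lines.append(
                    delimiter.join(
                        ["predicted_" + lvl]
                        + [str(int(x)) for x in self.confusion.counts[i]]
                    )
                )
        return lines


def classification_rate(predicted, truth) -> float:
    """Correctly classified instances over total instances."""
    p = np.asarray(predicted, dtype=object)
    t = np.asarray(truth, dtype=object)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("cannot compute a rate on empty inputs")
    return float(np.mean(p == t))


def confusion_matrix(predicted, truth, class_levels) -> ConfusionMatrix:
    """Cross-tabulate counts with rows = predicted, columns = truth."""
    levels = tuple(str(c) for c in class_levels)
    p = np.asarray(predicted, dtype=object)
    t = np.asarray(truth, dtype=object)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    unknown = (set(p) | set(t)) - set(levels)
    if unknown:
        raise ValueError(f"labels outside class_levels: {sorted(unknown)}")
    counts = np.zeros((2, 2), dtype=np.int64)
    for i, pl in enumerate(levels):
        for j, tl in enumerate(levels):
            counts[i, j] = int(np.sum((p == pl) & (t == tl)))
    return ConfusionMatrix(counts, (levels[0], levels[1]))


def sensitivity(predicted, truth, level: str) -> float:
    """Recall of one class: correct calls of `level` over its true count."""
    p = np.asarray(predicted, dtype=object)
    t = np.asarray(truth, dtype=object)
    pos = t == str(level)
    if not pos.any():
        raise ValueError(f"no true instances of class {level!r}")
    return float(np.mean(p[pos] == str(level)))


def _derived_seeds(seed: int) -> tuple[int, int]:
    """(balance_seed, model_seed) derived deterministically from seed.

    The model seed does not depend on whether balancing happens, so a
    median-supplement method on already-balanced data coincides exactly
    with its plain counterpart at the same seed.
    """
    state = np.random.SeedSequence(seed).generate_state(2)
    return int(state[0] % 2**31), int(state[1] % 2**31)


def fit_method(
    train: LabeledTable,
    method: str,
    seed: int = 0,
    median_scope: str = "all",
    n_trees: int = 500,
    mtry: int | None = None,
    min_node_size: int = 1,
    scale_floor: float | None = None,
):
    """Fit one of the four methods; returns (model, balanced_train_or_None).

    MS* methods balance the training table first (median-scaled synthetic
    minority instances); plain methods train on the table as given.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose one of {METHODS}")
    balance_seed, model_seed = _derived_seeds(seed)
    balanced: BalancedTable | None = None
    fit_table: LabeledTable = train
    if method.startswith("MS"):
        balanced = balance(train, balance_seed, median_scope=median_scope)
        fit_table = balanced
    if method.endswith("NaiveBayes"):
        model = nb.fit_nb(fit_table, scale_floor=scale_floor)
    else:
        model = rf.fit_forest(
            fit_table,
            n_trees=n_trees,
            mtry=mtry,
            min_node_size=min_node_size,
            seed=model_seed,
        )
    return model, balanced


def _predict(model, instances) -> np.ndarray:
    if isinstance(model, nb.NBModel):
        return nb.predict_nb(model, instances)
    return rf.predict_forest(model, instances)


def independent_test(
    train: LabeledTable,
    test: UnlabeledTable | LabeledTable,
    method: str,
    seed: int = 0,
    truth=None,
    **fit_kwargs,
) -> EvaluationReport:
    """Train on `train` (balanced first for MS methods), score `test`.

    Truth labels may be passed explicitly or carried by a labelled test
    table; when available, the report includes the confusion matrix and
    classification rate.
    """
    if isinstance(test, LabeledTable):
        if truth is None:
            truth = test.labels
        test = test.unlabeled()
    if list(test.attribute_names) != list(train.attribute_names):
        raise TabularError("test attributes do not match the training table")
    model, _ = fit_method(train, method, seed=seed, **fit_kwargs)
    predictions = _predict(model, test)
    report = EvaluationReport(
        method=method,
        predictions=predictions,
        class_levels=(train.class_levels[0], train.class_levels[1]),
        seed=int(seed),
    )
    if truth is not None:
        truth = np.asarray([str(x) for x in truth], dtype=object)
        report.truth = truth
        report.confusion = confusion_matrix(predictions, truth, train.class_levels)
        report.rate = classification_rate(predictions, truth)
    return report


def _stratified_folds(
    labels: np.ndarray, levels, k: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Deal each class's shuffled indices round-robin into k folds."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for level in levels:
        idx = np.nonzero(labels == level)[0]
        if idx.size < k:
            raise ValueError(
                f"class {level!r} has {idx.size} instances, fewer than k={k}"
            )
        idx = rng.permutation(idx)
        for pos, row in enumerate(idx):
            folds[pos % k].append(int(row))
    return [np.sort(np.asarray(f, dtype=np.int64)) for f in folds]


def _subset(table: LabeledTable, idx: np.ndarray) -> LabeledTable:
    return LabeledTable(
        list(table.attribute_names),
        table.values[idx],
        table.labels[idx],
        class_levels=table.class_levels,
        label_name=table.label_name,
    )


def kfold_cv(
    table: LabeledTable,
    method: str,
    k: int,
    repeats: int = 10,
    seed: int = 0,
    collect_folds: bool = False,
    **fit_kwargs,
) -> RateSample:
    """Repeated stratified k-fold cross-validation.

    For each fold, MS methods balance the k-1 training folds only; the
    held-out fold is always drawn from the original table, so it can never
    contain synthetic instances. One classification rate is recorded per
    held-out fold, pooled over `repeats` repetitions with seeds derived
    from `seed`. With ``collect_folds=True`` each fold's record — held-out
    indices, truth, predictions, and the balanced training table for MS
    methods — is attached for auditing.
    """
    table.require_binary()
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    root = np.random.SeedSequence(seed)
    fold_seq, eval_seq = root.spawn(2)
    fold_rngs = [np.random.default_rng(s) for s in fold_seq.spawn(repeats)]
    eval_seeds = eval_seq.generate_state(repeats * k) % 2**31

    rates = []
    records: list[dict] = []
    for r in range(repeats):
        folds = _stratified_folds(table.labels, table.class_levels, k, fold_rngs[r])
        for f, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(table.n_instances), test_idx)
            train = _subset(table, train_idx)
            test = _subset(table, test_idx)
            fold_seed = int(eval_seeds[r * k + f])
            model, balanced = fit_method(train, method, seed=fold_seed, **fit_kwargs)
            predictions = _predict(model, test.unlabeled())
            rates.append(classification_rate(predictions, test.labels))
            if collect_folds:
                records.append(
                    {
                        "repeat": r,
                        "fold": f,
                        "test_indices": test_idx,
                        "truth": test.labels,
                        "predictions": predictions,
                        "balanced_train": balanced,
                    }
                )
    return RateSample(
        rates=np.asarray(rates),
        method=method,
        k=k,
        repeats=repeats,
        seed=int(seed),
        fold_records=records if collect_folds else None,
    )


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparison of two rate samples.

    Returns (U, p) with U counting pairs where a beats b. The p-value uses
    exact enumeration when min(n_a, n_b) <= 8 and the pooled sample is
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if min(a.size, b.size) <= 8 and tie_free:
        res = mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        res = mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    return float(res.statistic), float(res.pvalue)
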