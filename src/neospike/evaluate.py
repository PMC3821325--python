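"""Confusion-matrix metrics and the repeated cross-validation protocol.

Metrics are reported in percent: accuracy = 100·(TP+TN)/(TP+FP+TN+FN) in
the two-class case (trace/total for multi-class), sensitivity =
100·TP/(TP+FN) and specificity = 100·TN/(TN+FP).

The evaluation protocol is stratified k-fold cross-validation (default
4 folds) repeated (default 10 times) with per-repeat reshuffling: within a
repeat, each fold serves once as the test set, the pooled test predictions
of the k folds give that repeat's test metrics, and the repeat's training
accuracy is the mean of the k training-set accuracies.  Reported values
are mean ± sample SD over the repeats.

A three-class result over {single_spike, spike_slow_wave, non_spike} can be
collapsed into a *pseudo-two-class* result by merging the two spike classes
into one positive class; confusions between the two spike classes then
count as correct, so the merged accuracy can never be lower than the
three-class accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .boost import AdaBoostM1
from .io import LABELS3

__all__ = [
    "ConfusionMatrix",
    "EvalReport",
    "confusion",
    "accuracy",
    "sensitivity_specificity",
    "pseudo_two_class",
    "merge_spike_labels",
    "cross_validate",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count table indexed by (true label, predicted label)."""

    counts: np.ndarray
    label_set: tuple

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        n = len(self.label_set)
        if c.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n} for {n} labels")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        labels = list(self.label_set)
        return pd.DataFrame(self.counts, index=labels, columns=labels)


def confusion(truth: Sequence, pred: Sequence, label_set: Sequence) -> ConfusionMatrix:
    """Tally a confusion matrix; rows are true labels, columns predictions."""
    truth = np.asarray(truth)
    pred = np.asarray(pred)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction lengths differ")
    known = set(label_set)
    unknown = (set(truth.tolist()) | set(pred.tolist())) - known
    if unknown:
        raise ValueError(f"labels outside the declared label set: {sorted(unknown)}")
    if truth.size == 0:
        c = np.zeros((len(label_set), len(label_set)), dtype=int)
    else:
        c = _sk_confusion(truth, pred, labels=list(label_set))
    return ConfusionMatrix(c, tuple(label_set))


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent of correct classifications, 100 · trace / total."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * float(np.trace(cm.counts)) / cm.total


def sensitivity_specificity(
    cm: ConfusionMatrix, positive_label
) -> tuple[float, float]:
    """Two-class sensitivity 100·TP/(TP+FN) and specificity 100·TN/(TN+FP)."""
    if len(cm.label_set) != 2:
        raise ValueError("sensitivity/specificity require a two-class matrix")
    if positive_label not in cm.label_set:
        raise ValueError(f"unknown positive label {positive_label!r}")
    p = cm.label_set.index(positive_label)
    n = 1 - p
    tp, fn = cm.counts[p, p], cm.counts[p, n]
    tn, fp = cm.counts[n, n], cm.counts[n, p]
    if tp + fn == 0:
        raise ValueError("no positives: sensitivity undefined")
    if tn + fp == 0:
        raise ValueError("no negatives: specificity undefined")
    return 100.0 * tp / (tp + fn), 100.0 * tn / (tn + fp)


def merge_spike_labels(labels: Sequence, merged_label: str = "spike") -> np.ndarray:
    """Map both spike classes onto one positive class, keep non_spike."""
    arr = np.asarray(labels, dtype=object)
    out = np.where(np.isin(arr, ("single_spike", "spike_slow_wave")), merged_label, arr)
    return out.astype(str)


def pseudo_two_class(cm3: ConfusionMatrix, merged_label: str = "spike") -> ConfusionMatrix:
    """Collapse a three-class matrix into two classes by merging the spike rows/columns.

    Totals are preserved; spike-vs-spike-with-slow-wave confusions become
    correct classifications of the merged positive class.
    """
    if set(cm3.label_set) != set(LABELS3):
        raise ValueError(f"expected label set {LABELS3}, got {cm3.label_set}")
    spike_ix = [cm3.label_set.index(l) for l in ("single_spike", "spike_slow_wave")]
    non_ix = cm3.label_set.index("non_spike")
    c = cm3.counts
    merged = np.array(
        [
            [c[np.ix_(spike_ix, spike_ix)].sum(), c[spike_ix, non_ix].sum()],
            [c[non_ix, spike_ix].sum(), c[non_ix, non_ix]],
        ],
        dtype=int,
    )
    return ConfusionMatrix(merged, (merged_label, "non_spike"))


@dataclass
class EvalReport:
    """Mean ± SD of the evaluation metrics over the repeated CV runs.

    ``metrics`` maps metric name → (mean, sample SD), both in percent;
    ``per_repeat`` keeps the underlying per-repeat values and
    ``test_confusions`` the pooled test confusion matrix of every repeat.
    """

    mode: str
    feature_set: str
    folds: int
    repeats: int
    n_examples: int
    n_fits: int
    metrics: dict
    per_repeat: dict = field(repr=False)
    test_confusions: list = field(repr=False)

    def summary(self) -> str:
        head = (
            f"Repeated cross-validation report ({self.mode}-class mode, "
            f"{self.feature_set})"
        )
        lines = [
            head,
            "=" * len(head),
            f"examples {self.n_examples}, {self.folds}-fold x {self.repeats} repeats "
            f"({self.n_fits} model fits)",
        ]
        for name, (mean, sd) in self.metrics.items():
            lines.append(f"{name:<22s} {mean:5.1f} +/- {sd:.1f} %")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "feature_set": self.feature_set,
            "folds": self.folds,
            "repeats": self.repeats,
            "n_examples": self.n_examples,
            "metrics": {k: {"mean": m, "sd": s} for k, (m, s) in self.metrics.items()},
        }


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return float(values.mean()), sd


def cross_validate(
    features,
    labels,
    *,
    mode: str = "three",
    feature_set: str = "",
    folds: int = 4,
    repeats: int = 10,
    seed: int = 0,
    rounds: int = 100,
    max_depth: int = 1,
    positive_label: str = "spike",
) -> EvalReport:
    """Repeated stratified k-fold cross-validation of the boosted classifier.

    Modes
    -----
    ``"two"``
        ``labels`` holds two classes; reports accuracy (train/test),
        sensitivity and specificity for ``positive_label``.
    ``"three"``
        ``labels`` holds the three pattern classes; reports accuracy only.
    ``"pseudo"``
        Trains the three-class classifier but evaluates the confusion
        matrices after merging the two spike classes.
    """
    if mode not in ("two", "three", "pseudo"):
        raise ValueError(f"unknown mode {mode!r}")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(str)
    label_set = tuple(sorted(np.unique(y))) if mode == "two" else LABELS3
    if mode != "two" and set(np.unique(y)) - set(LABELS3):
        raise ValueError(f"three-class modes expect labels from {LABELS3}")
    counts = pd.Series(y).value_counts()
    if (counts < folds).any():
        small = counts[counts < folds]
        raise ValueError(
            f"every class needs >= folds={folds} members; too small: {dict(small)}"
        )

    merged = mode == "pseudo"
    per_repeat: dict[str, list] = {
        "accuracy_train": [],
        "accuracy_test": [],
        "sensitivity_test": [],
        "specificity_test": [],
    }
    test_cms = []
    n_fits = 0
    for r in range(repeats):
        # repeat-specific shuffle seed, derived reproducibly from (seed, r)
        rs = int(np.random.SeedSequence([seed, r]).generate_state(1)[0] % (2**31))
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rs)
        pooled_truth: list = []
        pooled_pred: list = []
        train_accs = []
        for train_ix, test_ix in skf.split(X, y):
            res = AdaBoostM1(
                X[train_ix],
                y[train_ix],
                label_set=label_set,
                rounds=rounds,
                max_depth=max_depth,
                seed=seed,
            ).fit()
            n_fits += 1
            pred_train = np.asarray(res.predict_batch(X[train_ix]))
            pred_test = np.asarray(res.predict_batch(X[test_ix]))
            if merged:
                cm_train = confusion(
                    merge_spike_labels(y[train_ix]),
                    merge_spike_labels(pred_train),
                    (positive_label, "non_spike"),
                )
            else:
                cm_train = confusion(y[train_ix], pred_train, label_set)
            train_accs.append(accuracy(cm_train))
            pooled_truth.extend(y[test_ix])
            pooled_pred.extend(pred_test)
        if merged:
            cm_test = confusion(
                merge_spike_labels(pooled_truth),
                merge_spike_labels(pooled_pred),
                (positive_label, "non_spike"),
            )
        else:
            cm_test = confusion(pooled_truth, pooled_pred, label_set)
        test_cms.append(cm_test)
        per_repeat["accuracy_train"].append(float(np.mean(train_accs)))
        per_repeat["accuracy_test"].append(accuracy(cm_test))
        if mode != "three":
            sens, spec = sensitivity_specificity(cm_test, positive_label)
            per_repeat["sensitivity_test"].append(sens)
            per_repeat["specificity_test"].append(spec)

    metric_names = ["accuracy_train", "accuracy_test"]
    if mode != "three":
        metric_names += ["sensitivity_test", "specificity_test"]
    metrics = {name: _mean_sd(np.asarray(per_repeat[name])) for name in metric_names}
    return EvalReport(
        mode=mode,
        feature_set=feature_set,
        folds=folds,
        repeats=repeats,
        n_examples=int(X.shape[0]),
        n_fits=n_fits,
        metrics=metrics,
        per_repeat={k: np.asarray(v) for k, v in per_repeat.items() if v},
        test_confusions=test_cms,
    )
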