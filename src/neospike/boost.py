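"""Stage 2b — multi-class AdaBoost.M1 over shallow decision-tree weak learners.

AdaBoost.M1 trains T weak classifiers sequentially on a reweighted sample.
At round t the weighted error is

    ε_t = Σ_i p_i^t · I(h_t(x_i) ≠ y_i),

the confidence ratio is β_t = ε_t / (1 − ε_t), the weights of correctly
classified examples are multiplied by β_t and the vector renormalized, so
difficult examples gain weight.  A new observation is labelled by the
weighted vote

    h_f(x) = argmax_y Σ_t log(1/β_t) · I(h_t(x) = y).

Weak learners are depth-limited CART trees (depth-1 stumps by default, the
canonical AdaBoost.M1 base classifier).  Rounds with ε_t ≥ 1/2 are
discarded and training stops; a round with ε_t = 0 is kept (with ε clamped
before forming β) and training stops, since the weight update would
degenerate.

The module follows the model/results idiom: build an :class:`AdaBoostM1`
from data, call :meth:`AdaBoostM1.fit`, and use the returned
:class:`AdaBoostM1Results` for prediction, diagnostics and serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

__all__ = ["AdaBoostM1", "AdaBoostM1Results", "train_weak"]

_EPS_CLAMP = 1e-10


def train_weak(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    max_depth: int = 1,
    seed: int = 0,
) -> DecisionTreeClassifier:
    """Fit one depth-limited CART tree on the weighted sample.

    Training is deterministic given identical inputs and seed (the seed
    only breaks ties between equally good splits).
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be non-negative and sum to 1")
    tree = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
    tree.fit(X, y, sample_weight=weights)
    return tree


class AdaBoostM1:
    """AdaBoost.M1 model specification bound to a training sample.

    Parameters
    ----------
    features : (n, d) array-like
        Feature matrix; all values must be finite.
    labels : (n,) sequence
        Class labels.  At least two classes must be present.
    label_set : sequence of str, optional
        Ordered label set; the order is the vote tie-break order.
        Defaults to the sorted unique labels.
    rounds : int
        Maximum number of boosting rounds (default 100).
    max_depth : int
        Depth limit of the weak trees (default 1, i.e. stumps).
    seed : int
        Seed for tie-breaking inside tree training.
    """

    def __init__(
        self,
        features,
        labels,
        *,
        label_set: Sequence[str] | None = None,
        rounds: int = 100,
        max_depth: int = 1,
        seed: int = 0,
    ) -> None:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(labels)
        if X.shape[0] != y.shape[0]:
            raise ValueError("features and labels disagree in length")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training examples")
        if not np.all(np.isfinite(X)):
            raise ValueError("features contain non-finite values")
        present = set(np.unique(y).tolist())
        if len(present) < 2:
            raise ValueError("need at least 2 classes to boost")
        if label_set is None:
            label_set = sorted(present)
        elif not present <= set(label_set):
            raise ValueError("labels outside the declared label set")
        if rounds < 1:
            raise ValueError("rounds must be >= 1")
        self.X = X
        self.y = y
        self.label_set = tuple(label_set)
        self.rounds = int(rounds)
        self.max_depth = int(max_depth)
        self.seed = int(seed)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        feature_cols: Sequence[str],
        label_col: str = "label",
        **kwargs,
    ) -> "AdaBoostM1":
        return cls(df[list(feature_cols)].to_numpy(float), df[label_col].to_numpy(), **kwargs)

    def fit(self) -> "AdaBoostM1Results":
        """Run the boosting loop and return the fitted ensemble."""
        n = self.X.shape[0]
        w = np.full(n, 1.0 / n)
        learners: list[DecisionTreeClassifier] = []
        betas: list[float] = []
        weight_history: list[np.ndarray] = []
        for t in range(self.rounds):
            h = train_weak(self.X, self.y, w, max_depth=self.max_depth, seed=self.seed)
            miss = h.predict(self.X) != self.y
            eps_raw = float(w[miss].sum())
            if eps_raw >= 0.5:
                if not learners:
                    # degenerate sample: no weak learner beats chance; keep
                    # the single tree with a clamped confidence so the
                    # ensemble is still usable
                    eps = 0.5 - _EPS_CLAMP
                    learners.append(h)
                    betas.append(eps / (1.0 - eps))
                    weight_history.append(w.copy())
                break
            eps = float(np.clip(eps_raw, _EPS_CLAMP, 0.5 - _EPS_CLAMP))
            beta = eps / (1.0 - eps)
            learners.append(h)
            betas.append(beta)
            w = w.copy()
            w[~miss] *= beta
            w /= w.sum()
            weight_history.append(w.copy())
            if eps_raw == 0.0:
                break
        return AdaBoostM1Results(
            model=self,
            learners=learners,
            betas=np.asarray(betas),
            weight_history=weight_history,
        )


@dataclass
class AdaBoostM1Results:
    """Fitted AdaBoost.M1 ensemble.

    Attributes
    ----------
    learners : list of fitted trees
    betas : ndarray
        Per-round confidence ratios β_t ∈ (0, 1); vote weight is log(1/β_t).
    weight_history : list of ndarray
        Normalized example weights after each retained round's update.
    """

    model: AdaBoostM1
    learners: list
    betas: np.ndarray
    weight_history: list

    @property
    def label_set(self) -> tuple:
        return self.model.label_set

    @property
    def rounds_used(self) -> int:
        return len(self.learners)

    def _votes(self, X: np.ndarray) -> np.ndarray:
        """(n, n_labels) matrix of accumulated log(1/β) votes."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"feature length mismatch: model expects {self.model.X.shape[1]}, "
                f"got {X.shape[1]}"
            )
        pos = {lab: j for j, lab in enumerate(self.label_set)}
        scores = np.zeros((X.shape[0], len(self.label_set)))
        for h, beta in zip(self.learners, self.betas):
            alpha = np.log(1.0 / beta)
            pred = h.predict(X)
            for i, lab in enumerate(pred):
                scores[i, pos[lab]] += alpha
        return scores

    def predict(self, features) -> str:
        """Label a single observation by the weighted vote (Eq.-4 style);
        exact ties go to the earlier label in ``label_set``."""
        scores = self._votes(np.asarray(features, dtype=float).reshape(1, -1))
        return self.label_set[int(np.argmax(scores[0]))]

    def predict_batch(self, features) -> list:
        """Elementwise, order-preserving prediction over rows."""
        if isinstance(features, pd.DataFrame):
            features = features.to_numpy(float)
        X = np.asarray(features, dtype=float)
        if X.size == 0:
            return []
        scores = self._votes(X)
        return [self.label_set[j] for j in np.argmax(scores, axis=1)]

    def training_accuracy(self) -> float:
        """Fraction of training examples the full vote classifies correctly."""
        pred = np.asarray(self.predict_batch(self.model.X))
        return float(np.mean(pred == self.model.y))

    def staged_training_error(self) -> np.ndarray:
        """Training error of the vote truncated after 1, 2, ... rounds."""
        errors = []
        for t in range(1, self.rounds_used + 1):
            partial = AdaBoostM1Results(
                model=self.model,
                learners=self.learners[:t],
                betas=self.betas[:t],
                weight_history=self.weight_history[:t],
            )
            pred = np.asarray(partial.predict_batch(self.model.X))
            errors.append(float(np.mean(pred != self.model.y)))
        return np.asarray(errors)

    def summary(self) -> str:
        """Plain-text fit summary."""
        lines = [
            "AdaBoost.M1 results",
            "===================",
            f"examples            {self.model.X.shape[0]}",
            f"features            {self.model.X.shape[1]}",
            f"classes             {', '.join(map(str, self.label_set))}",
            f"weak-tree depth     {self.model.max_depth}",
            f"rounds requested    {self.model.rounds}",
            f"rounds used         {self.rounds_used}",
            f"beta range          [{self.betas.min():.4g}, {self.betas.max():.4g}]",
            f"training accuracy   {100 * self.training_accuracy():.1f}%",
        ]
        return "\n".join(lines)

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        """Serialize the ensemble (label set, per-round trees, betas)."""
        payload = {
            "label_set": list(self.label_set),
            "n_features": int(self.model.X.shape[1]),
            "max_depth": self.model.max_depth,
            "betas": self.betas.tolist(),
            "trees": [_tree_to_dict(h) for h in self.learners],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "AdaBoostM1Results":
        """Rebuild a predict-only ensemble from :meth:`to_json` output."""
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        stub = AdaBoostM1.__new__(AdaBoostM1)
        stub.label_set = tuple(payload["label_set"])
        stub.max_depth = payload["max_depth"]
        stub.rounds = len(payload["betas"])
        stub.seed = 0
        stub.X = np.zeros((0, payload["n_features"]))
        stub.y = np.zeros(0)
        learners = [_SerializedTree(d) for d in payload["trees"]]
        return cls(
            model=stub,
            learners=learners,
            betas=np.asarray(payload["betas"]),
            weight_history=[],
        )


def _tree_to_dict(tree: DecisionTreeClassifier) -> dict:
    t = tree.tree_
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": t.threshold.tolist(),
        "leaf_label": [str(tree.classes_[int(np.argmax(v[0]))]) for v in t.value],
    }


class _SerializedTree:
    """Predict-only decision tree rebuilt from its JSON description."""

    def __init__(self, d: dict) -> None:
        self.left = d["children_left"]
        self.right = d["children_right"]
        self.feature = d["feature"]
        self.threshold = d["threshold"]
        self.leaf_label = d["leaf_label"]

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = []
        for row in np.asarray(X, dtype=float):
            node = 0
            while self.left[node] != -1:
                node = (
                    self.left[node]
                    if row[self.feature[node]] <= self.threshold[node]
                    else self.right[node]
                )
            out.append(self.leaf_label[node])
        return np.asarray(out)
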