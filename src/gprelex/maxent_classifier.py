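"""Binary maximum-entropy (logistic) relation classifier.

The model is an L2-regularized logistic regression over sparse binary
indicator features, with count-based feature selection.  The objective is the
*mean* log-loss plus ``(l2_strength / 2) * ||w||^2``, which makes the fitted
decision function invariant under duplicating the training set.  The fit is
delegated to scikit-learn's deterministic LBFGS solver; feature selection,
vectorization, prediction, and JSON serialization are implemented here, and
prediction recomputes the logistic posterior from the stored weights so that
a serialization round-trip reproduces predictions bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from sklearn.linear_model import LogisticRegression

POSITIVE, NEGATIVE = "positive", "negative"


class ClassifierError(ValueError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    min_count: int = 2
    l2_strength: float = 0.01  # per-instance weight decay on the mean loss
    seed: int = 0
    class_weight: Optional[str] = None  # None or "balanced"


@dataclass(frozen=True)
class Prediction:
    label: str
    confidence: float  # posterior of the predicted label, in [0.5, 1]

    @property
    def p_positive(self) -> float:
        return self.confidence if self.label == POSITIVE else 1.0 - self.confidence


@dataclass
class TrainedModel:
    feature_names: list[str]  # selected features, sorted; name -> column order
    weights: np.ndarray  # shape (n_features,), positive-class orientation
    bias: float
    train_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.bias):
            raise ClassifierError("non-finite model weights")
        self._index = {name: i for i, name in enumerate(self.feature_names)}

    def decision(self, features: dict[str, float]) -> float:
        z = self.bias
        for name, value in features.items():
            col = self._index.get(name)
            if col is not None:
                z += self.weights[col] * value
        return z

    def posterior_positive(self, features: dict[str, float]) -> float:
        z = self.decision(features)
        # numerically stable logistic
        if z >= 0:
            return 1.0 / (1.0 + np.exp(-z))
        e = np.exp(z)
        return e / (1.0 + e)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "feature_names": self.feature_names,
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "train_meta": self.train_meta,
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "TrainedModel":
        payload = json.loads(text)
        return cls(
            feature_names=payload["feature_names"],
            weights=np.array(payload["weights"], dtype=np.float64),
            bias=payload["bias"],
            train_meta=payload.get("train_meta", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        return cls.from_json(Path(path).read_text(encoding="utf-8"))


def select_features(
    instances: Sequence[tuple[dict[str, float], str]], min_count: int
) -> set[str]:
    """Features occurring in at least ``min_count`` training instances."""
    if not instances:
        raise ClassifierError("empty training set")
    if min_count < 1:
        raise ClassifierError("min_count must be >= 1")
    counts: dict[str, int] = {}
    for features, _ in instances:
        for name in features:
            counts[name] = counts.get(name, 0) + 1
    return {name for name, c in counts.items() if c >= min_count}


def _vectorize(
    instances: Sequence[dict[str, float]], index: dict[str, int]
) -> sparse.csr_matrix:
    rows, cols, vals = [], [], []
    for r, features in enumerate(instances):
        for name, value in features.items():
            c = index.get(name)
            if c is not None:
                rows.append(r)
                cols.append(c)
                vals.append(value)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(instances), len(index)), dtype=np.float64
    )


def train(
    instances: Sequence[tuple[dict[str, float], str]],
    config: TrainConfig = TrainConfig(),
) -> TrainedModel:
    """Fit the logistic model on labelled sparse feature vectors.

    ``instances`` are ``(features, label)`` pairs with labels
    positive/negative; both classes must be present.
    """
    labels = [label for _, label in instances]
    for required in (POSITIVE, NEGATIVE):
        if required not in labels:
            raise ClassifierError(f"training set has no {required} instances")
    selected = sorted(select_features(instances, config.min_count))
    index = {name: i for i, name in enumerate(selected)}
    X = _vectorize([f for f, _ in instances], index)
    y = np.array([1 if label == POSITIVE else 0 for label in labels])
    n = len(instances)
    # mean-loss objective: sklearn's C = 1 / (n * lambda)
    C = 1.0 / (n * config.l2_strength)
    clf = LogisticRegression(
        C=C,
        solver="lbfgs",
        max_iter=5000,
        tol=1e-10,
        random_state=config.seed,
        class_weight=config.class_weight,
    )
    clf.fit(X, y)
    return TrainedModel(
        feature_names=selected,
        weights=clf.coef_[0],
        bias=float(clf.intercept_[0]),
        train_meta={
            "n_pos": int(y.sum()),
            "n_neg": int(n - y.sum()),
            "min_count": config.min_count,
            "l2_strength": config.l2_strength,
            "seed": config.seed,
        },
    )


def predict(model: TrainedModel, features: dict[str, float]) -> Prediction:
    """Label and posterior confidence for one instance; unseen features ignored."""
    p_pos = float(model.posterior_positive(features))
    if p_pos >= 0.5:
        return Prediction(POSITIVE, p_pos)
    return Prediction(NEGATIVE, 1.0 - p_pos)
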