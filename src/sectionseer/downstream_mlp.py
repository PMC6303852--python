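"""MLP classification head over frozen sentence embeddings.

The semi-supervised sent2vec pipeline freezes the unsupervised sentence
vectors and trains a single-hidden-layer perceptron (100 neurons, ReLU,
Adam, early stop on training-loss plateau) on top. The head is standard
machinery, so it delegates to scikit-learn's MLPClassifier; this module
pins the label order and tie-breaking conventions used everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier


@dataclass
class MLPHead:
    """Trained head plus the canonical label order its outputs follow."""

    clf: MLPClassifier
    label_order: tuple[str, ...]

    @property
    def hidden_size(self) -> int:
        return self.clf.hidden_layer_sizes[0]


def train_mlp_head(
    embeddings: np.ndarray,
    labels: Sequence[str],
    label_order: Sequence[str],
    hidden: int = 100,
    seed: int = 0,
    max_iter: int = 200,
) -> MLPHead:
    """Fit the head on frozen embeddings; the input array is not modified."""
    X = np.asarray(embeddings, dtype=np.float64)
    if X.shape[0] != len(labels):
        raise ValueError(
            f"{X.shape[0]} embeddings but {len(labels)} labels"
        )
    if X.shape[0] == 0:
        raise ValueError("training set must be non-empty")
    order = tuple(label_order)
    y = np.fromiter((order.index(l) for l in labels), dtype=np.int64)
    clf = MLPClassifier(
        hidden_layer_sizes=(hidden,),
        activation="relu",
        solver="adam",
        random_state=seed,
        max_iter=max_iter,
        n_iter_no_change=10,
    )
    clf.fit(X, y)
    return MLPHead(clf, order)


def mlp_predict_proba(head: MLPHead, embeddings: np.ndarray) -> np.ndarray:
    """Probability matrix over the full canonical label order (classes the
    head never saw in training get probability zero)."""
    X = np.asarray(embeddings, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != head.clf.n_features_in_:
        raise ValueError(
            f"expected embeddings of dimension {head.clf.n_features_in_}"
        )
    raw = head.clf.predict_proba(X)
    k = len(head.label_order)
    out = np.zeros((X.shape[0], k), dtype=np.float64)
    for col, cls in enumerate(head.clf.classes_):
        out[:, int(cls)] = raw[:, col]
    return out


def mlp_predict(head: MLPHead, embeddings: np.ndarray) -> list[str]:
    """Argmax labels, ties broken toward the lowest canonical label index."""
    probs = mlp_predict_proba(head, embeddings)
    return [head.label_order[i] for i in probs.argmax(axis=1)]
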