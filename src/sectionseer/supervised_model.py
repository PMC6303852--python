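"""The shallow two-matrix embedding classifier.

A sentence's normalized feature bag is mapped to a hidden state by averaging
rows of an embedding table V (one row per unigram or hashed n-gram bucket),
then linearly to k class logits by an output table U, followed by a softmax.
Training minimizes the mean negative log-likelihood by plain per-example SGD
with a learning rate decaying linearly to zero, reshuffling each epoch from
a seeded generator — bit-reproducible in single-threaded mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import _kernels
from .corpus_io import CANONICAL_LABELS, Corpus
from .features import (
    DEFAULT_BUCKETS,
    FeatureBag,
    Vocabulary,
    build_vocab,
    encode_bag,
    encode_dataset,
    n_features,
)


@dataclass
class TrainConfig:
    """Supervised training hyperparameters.

    ``dim`` is the embedding dimension h, ``n_max`` the largest word n-gram
    size (1 = pure bag of words), ``lr`` the initial learning rate (decays
    linearly to 0), ``buckets`` the hashed n-gram table size, ``min_count``
    the vocabulary frequency threshold, and ``threads`` must stay 1 for
    reproducibility (kept for interface parity).
    """

    dim: int = 20
    n_max: int = 1
    epochs: int = 5
    lr: float = 0.1
    buckets: int = DEFAULT_BUCKETS
    min_count: int = 1
    seed: int = 1
    threads: int = 1

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")


@dataclass
class EmbeddingModel:
    """Parameter container: V (n_features x h) and U (k x h)."""

    V: np.ndarray
    U: np.ndarray
    label_order: tuple[str, ...] = ()

    @property
    def h(self) -> int:
        return self.V.shape[1]

    @property
    def k(self) -> int:
        return self.U.shape[0]

    @property
    def n_features(self) -> int:
        return self.V.shape[0]


def init_model(
    n_feat: int,
    h: int,
    k: int,
    seed: int = 0,
    label_order: Optional[Sequence[str]] = None,
) -> EmbeddingModel:
    """Fresh model: V i.i.d. uniform on [-1/h, 1/h], U zeros."""
    if n_feat <= 0 or h <= 0 or k <= 0:
        raise ValueError("model sizes must be positive")
    rng = np.random.default_rng(seed)
    V = rng.uniform(-1.0 / h, 1.0 / h, size=(n_feat, h))
    U = np.zeros((k, h), dtype=np.float64)
    order = tuple(label_order) if label_order is not None else tuple(str(c) for c in range(k))
    return EmbeddingModel(V, U, order)


def _check_bag(model: EmbeddingModel, bag: FeatureBag) -> None:
    if len(bag.ids) and (bag.ids.min() < 0 or bag.ids.max() >= model.n_features):
        raise IndexError("feature id out of range for this model")


def sentence_vector(model: EmbeddingModel, bag: FeatureBag) -> np.ndarray:
    """Weighted average of the embedding rows of the bag's features.

    Weights are already normalized, so this is sum(w_f * V[f]); an empty bag
    maps to the zero vector."""
    _check_bag(model, bag)
    if bag.is_empty:
        return np.zeros(model.h, dtype=np.float64)
    return bag.weights @ model.V[bag.ids]


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def predict_proba(model: EmbeddingModel, bag: FeatureBag) -> np.ndarray:
    """Class probability vector softmax(U @ sentence_vector)."""
    return softmax(model.U @ sentence_vector(model, bag))


def predict_label(model: EmbeddingModel, bag: FeatureBag) -> str:
    """Argmax label; ties broken toward the lowest index in label order."""
    p = predict_proba(model, bag)
    return model.label_order[int(np.argmax(p))]


def _label_index(model: EmbeddingModel, label) -> int:
    if isinstance(label, str):
        return model.label_order.index(label)
    return int(label)


def supervised_loss(model: EmbeddingModel, dataset: Sequence[tuple]) -> float:
    """Mean negative log-likelihood over (FeatureBag, label) pairs."""
    if len(dataset) == 0:
        raise ValueError("dataset must be non-empty")
    total = 0.0
    for bag, label in dataset:
        logits = model.U @ sentence_vector(model, bag)
        m = logits.max()
        lse = m + np.log(np.exp(logits - m).sum())
        total += lse - logits[_label_index(model, label)]
    return total / len(dataset)


def supervised_grads(
    model: EmbeddingModel, bag: FeatureBag, label
) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Analytic gradient of the single-example NLL w.r.t. U and the touched
    rows of V. Returns (dU, {feature id: dV_row})."""
    y = _label_index(model, label)
    hid = sentence_vector(model, bag)
    p = softmax(model.U @ hid)
    g = p.copy()
    g[y] -= 1.0
    dU = np.outer(g, hid)
    ghid = model.U.T @ g
    dV = {int(f): w * ghid for f, w in zip(bag.ids, bag.weights)}
    return dU, dV


def fit_bags(
    indptr: np.ndarray,
    indices: np.ndarray,
    weights: np.ndarray,
    labels: np.ndarray,
    n_feat: int,
    label_order: Sequence[str],
    config: TrainConfig,
    init_V: Optional[np.ndarray] = None,
) -> tuple[EmbeddingModel, list[float]]:
    """Train on a CSR-encoded dataset; returns (model, per-epoch NLL).

    ``init_V`` (e.g. a pre-trained table from :mod:`unsupervised_pretrain`)
    must have shape (n_feat, dim); it is copied, never mutated.
    """
    k = len(label_order)
    n = len(labels)
    if n == 0:
        raise ValueError("training set must be non-empty")
    model = init_model(n_feat, config.dim, k, config.seed, label_order)
    if init_V is not None:
        if init_V.shape != (n_feat, config.dim):
            raise ValueError(
                f"init_V shape {init_V.shape} != {(n_feat, config.dim)}"
            )
        model.V = np.array(init_V, dtype=np.float64)
    rng = np.random.default_rng(config.seed)
    labels64 = np.asarray(labels, dtype=np.int64)
    t_total = config.epochs * n
    losses: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n).astype(np.int64)
        _kernels.supervised_epoch(
            indptr, indices, weights, labels64, order,
            model.V, model.U, config.lr, epoch * n, t_total,
        )
        losses.append(
            float(_kernels.dataset_nll(indptr, indices, weights, labels64, model.V, model.U))
        )
    return model, losses


def _labels_from(sentences, label_order: Optional[Sequence[str]]) -> tuple[str, ...]:
    seen: list[str] = []
    for s in sentences:
        if s.label is None:
            raise ValueError("supervised training requires labeled sentences")
        if s.label not in seen:
            seen.append(s.label)
    if label_order is not None:
        order = tuple(label_order)
    elif set(seen) <= set(CANONICAL_LABELS):
        order = CANONICAL_LABELS
    else:
        order = tuple(seen)
    missing = set(seen) - set(order)
    if missing:
        raise ValueError(f"labels {missing} not in label order {order}")
    return order


@dataclass
class TextClassifier:
    """A trained model bundled with its vocabulary and configuration."""

    model: EmbeddingModel
    vocab: Vocabulary
    config: TrainConfig
    epoch_losses: list[float] = field(default_factory=list)

    def encode(self, tokens: Sequence[str]) -> FeatureBag:
        return encode_bag(tokens, self.vocab, self.config.n_max, self.config.buckets)

    def predict_proba(self, token_lists: Sequence[Sequence[str]]) -> np.ndarray:
        indptr, indices, weights = encode_dataset(
            token_lists, self.vocab, self.config.n_max, self.config.buckets
        )
        logits = _kernels.dataset_logits(
            indptr, indices, weights, self.model.V, self.model.U
        )
        return softmax(logits)

    def predict(self, token_lists: Sequence[Sequence[str]]) -> list[str]:
        probs = self.predict_proba(token_lists)
        order = self.model.label_order
        return [order[i] for i in probs.argmax(axis=1)]

    def export_vectors(self, path: Union[str, Path]) -> None:
        """Plain-text word-vector export: header 'count dim', then one line
        per unigram token (hashed n-gram buckets have no token spelling)."""
        V = self.model.V
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"{self.vocab.size} {self.model.h}\n")
            for token, i in self.vocab.index.items():
                vec = " ".join(repr(float(x)) for x in V[i])
                fh.write(f"{token} {vec}\n")

    def save(self, path: Union[str, Path]) -> None:
        """Versioned binary container with shapes, label order, vocabulary
        and both parameter matrices."""
        meta = {
            "format_version": 1,
            "label_order": list(self.model.label_order),
            "config": self.config.__dict__,
            "vocab_min_count": self.vocab.min_count,
        }
        with open(path, "wb") as fh:
            np.savez(
                fh,
                V=self.model.V,
                U=self.model.U,
                vocab_tokens=np.array(self.vocab.tokens, dtype=object),
                vocab_counts=self.vocab.counts,
                meta=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
                epoch_losses=np.asarray(self.epoch_losses, dtype=np.float64),
            )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TextClassifier":
        with np.load(path, allow_pickle=True) as data:
            meta = json.loads(bytes(data["meta"]).decode("utf-8"))
            if meta.get("format_version") != 1:
                raise ValueError("unsupported model container version")
            tokens = [str(t) for t in data["vocab_tokens"]]
            vocab = Vocabulary(
                {t: i for i, t in enumerate(tokens)},
                data["vocab_counts"].astype(np.int64),
                meta["vocab_min_count"],
            )
            config = TrainConfig(**meta["config"])
            model = EmbeddingModel(
                data["V"].astype(np.float64),
                data["U"].astype(np.float64),
                tuple(meta["label_order"]),
            )
            losses = [float(x) for x in data["epoch_losses"]]
        return cls(model, vocab, config, losses)


def train_supervised(
    data: Union[Corpus, Sequence],
    config: TrainConfig,
    init_V: Optional[np.ndarray] = None,
    vocab: Optional[Vocabulary] = None,
    label_order: Optional[Sequence[str]] = None,
) -> TextClassifier:
    """Train the classifier on a labeled corpus or sentence list.

    ``data`` may be a :class:`Corpus` or any sequence of objects with
    ``tokens`` and ``label`` (e.g. augmented sentences). A vocabulary is
    built with ``config.min_count`` unless one is supplied; ``init_V``
    (matching the resulting feature space) seeds the embedding table for
    semi-supervised training.
    """
    if isinstance(data, Corpus):
        sentences = list(data.iter_sentences())
        if label_order is None and data.label_set:
            label_order = data.label_set
    else:
        sentences = list(data)
    order = _labels_from(sentences, label_order)
    if vocab is None:
        vocab = build_vocab(sentences, config.min_count)
    indptr, indices, weights = encode_dataset(
        (s.tokens for s in sentences), vocab, config.n_max, config.buckets
    )
    y = np.fromiter((order.index(s.label) for s in sentences), dtype=np.int64)
    n_feat = n_features(vocab, config.n_max, config.buckets)
    model, losses = fit_bags(
        indptr, indices, weights, y, n_feat, order, config, init_V
    )
    return TextClassifier(model, vocab, config, losses)
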