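"""Unsupervised n-gram vector pre-training with negative sampling.

Vectors are learned by predicting each in-vocabulary target word from the
average embedding of a context:

* ``fixed-window`` (CBOW-style): up to ``window`` tokens each side;
* ``whole-sentence`` (sent2vec-style): all remaining tokens of the sentence,
  optionally including word n-grams.

The per-pair loss is the standard negative-sampling objective

    softplus(-u_t . v_ctx) + sum_neg softplus(+u_n . v_ctx),

i.e. maximize log sigma(u_t . v) for the observed target and
log sigma(-u_n . v) for words drawn from a smoothed unigram noise
distribution (freq^power, power 0.75 by default). Labels are never read:
pre-training operates on the token streams alone.

The learned table transfers into the supervised classifier via
:func:`transfer_init` and yields additive sentence embeddings via
:func:`sent2vec_embed`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

from . import _kernels
from .corpus_io import Corpus, Sentence
from .features import (
    DEFAULT_BUCKETS,
    FeatureBag,
    Vocabulary,
    build_vocab,
    encode_bag,
    n_features,
)
from .supervised_model import EmbeddingModel, sentence_vector


@dataclass
class PretrainConfig:
    """Unsupervised training hyperparameters (library-convention defaults:
    5 negatives, window 5, power 0.75, lr 0.05 decaying to 0, min_count 5).
    """

    dim: int = 20
    n_max: int = 1
    epochs: int = 5
    lr: float = 0.05
    negatives: int = 5
    window: int = 5
    mode: str = "whole-sentence"  # or "fixed-window"
    power: float = 0.75
    min_count: int = 5
    buckets: int = DEFAULT_BUCKETS
    seed: int = 1

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.mode not in ("whole-sentence", "fixed-window"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class NoiseDistribution:
    """Smoothed unigram distribution over the vocabulary for negatives."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.cdf = np.cumsum(self.probs)


def build_noise_distribution(vocab: Vocabulary, power: float = 0.75) -> NoiseDistribution:
    """p(w) proportional to freq(w)**power, normalized over the vocabulary."""
    if vocab.size == 0:
        raise ValueError("vocabulary is empty")
    p = vocab.counts.astype(np.float64) ** power
    return NoiseDistribution(p / p.sum())


def sample_negatives(
    dist: NoiseDistribution, count: int, exclude: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``count`` word ids from ``dist``, resampling draws equal to
    ``exclude``. Deterministic under a seeded generator."""
    if count < 1:
        raise ValueError("count must be >= 1")
    if len(dist.probs) == 1 and exclude == 0:
        raise ValueError("cannot exclude the only word in the vocabulary")
    out = np.searchsorted(dist.cdf, rng.random(count)).astype(np.int64)
    while True:
        mask = out == exclude
        n_bad = int(mask.sum())
        if n_bad == 0:
            return out
        out[mask] = np.searchsorted(dist.cdf, rng.random(n_bad))


@dataclass
class ContextPair:
    """A prediction instance: target word id plus its context feature bag."""

    target: int
    context: FeatureBag
    mode: str


def make_context_pairs(
    sentence: Union[Sentence, Sequence[str]],
    vocab: Vocabulary,
    mode: str = "whole-sentence",
    window: int = 5,
    n_max: int = 1,
    buckets: int = DEFAULT_BUCKETS,
) -> list[ContextPair]:
    """One pair per in-vocabulary token position with a non-empty context.

    Fixed-window contexts hold up to ``window`` in-vocabulary unigrams each
    side of the target; whole-sentence contexts hold the bag of n-grams of
    the sentence with the target occurrence removed. The target is never in
    its own context bag's defining token sequence.
    """
    tokens = sentence.tokens if isinstance(sentence, Sentence) else list(sentence)
    pairs: list[ContextPair] = []
    for t, tok in enumerate(tokens):
        wid = vocab.id_of(tok)
        if wid is None:
            continue
        if mode == "fixed-window":
            ctx_tokens = [
                tokens[j]
                for j in range(max(0, t - window), min(len(tokens), t + window + 1))
                if j != t
            ]
            bag = encode_bag(ctx_tokens, vocab, 1, buckets)
        elif mode == "whole-sentence":
            remaining = list(tokens[:t]) + list(tokens[t + 1 :])
            bag = encode_bag(remaining, vocab, n_max, buckets)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if not bag.is_empty:
            pairs.append(ContextPair(int(wid), bag, mode))
    return pairs


def unsupervised_loss(
    model: EmbeddingModel, pair: ContextPair, negatives: Sequence[int]
) -> float:
    """softplus(-u_t . v_ctx) + sum over negatives of softplus(+u_n . v_ctx)."""
    v = sentence_vector(model, pair.context)
    loss = float(np.logaddexp(0.0, -model.U[pair.target] @ v))
    for w in negatives:
        loss += float(np.logaddexp(0.0, model.U[int(w)] @ v))
    return loss


def unsupervised_grads(
    model: EmbeddingModel, pair: ContextPair, negatives: Sequence[int]
) -> tuple[dict[int, np.ndarray], dict[int, np.ndarray]]:
    """Analytic gradients of :func:`unsupervised_loss` w.r.t. the touched
    rows of U and V. Returns ({output id: dU_row}, {feature id: dV_row})."""
    v = sentence_vector(model, pair.context)
    dU: dict[int, np.ndarray] = {}
    gctx = np.zeros(model.h)
    for wid, label in [(pair.target, 1.0)] + [(int(w), 0.0) for w in negatives]:
        g = 1.0 / (1.0 + np.exp(-model.U[wid] @ v)) - label
        dU[wid] = dU.get(wid, 0.0) + g * v
        gctx += g * model.U[wid]
    dV = {int(f): w * gctx for f, w in zip(pair.context.ids, pair.context.weights)}
    return dU, dV


def _pairs_to_csr(
    pairs: Sequence[ContextPair],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    indptr = np.zeros(len(pairs) + 1, dtype=np.int64)
    ids = []
    weights = []
    targets = np.empty(len(pairs), dtype=np.int64)
    for i, p in enumerate(pairs):
        ids.append(p.context.ids)
        weights.append(p.context.weights)
        targets[i] = p.target
        indptr[i + 1] = indptr[i] + len(p.context.ids)
    indices = np.concatenate(ids) if ids else np.empty(0, dtype=np.int64)
    w = np.concatenate(weights) if weights else np.empty(0, dtype=np.float64)
    return indptr, indices.astype(np.int64), w.astype(np.float64), targets


def _fast_unigram_pairs(
    token_lists: Sequence[Sequence[str]], vocab: Vocabulary, mode: str, window: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pair construction for the unigram-context case."""
    indptr_parts = [np.zeros(1, dtype=np.int64)]
    idx_parts: list[np.ndarray] = []
    w_parts: list[np.ndarray] = []
    tgt_parts: list[np.ndarray] = []
    index = vocab.index
    for tokens in token_lists:
        ids = np.array(
            [i for i in (index.get(t) for t in tokens) if i is not None],
            dtype=np.int64,
        )
        L = ids.size
        if L < 2:
            continue
        if mode == "whole-sentence":
            # context of position t = all other ids, uniform weights
            tiled = np.broadcast_to(ids, (L, L))
            mask = ~np.eye(L, dtype=bool)
            ctx = tiled[mask].reshape(L, L - 1)
            idx_parts.append(ctx.ravel())
            w_parts.append(np.full(L * (L - 1), 1.0 / (L - 1)))
            tgt_parts.append(ids)
            indptr_parts.append(np.full(L, L - 1, dtype=np.int64))
        else:
            rows = []
            lens_list = []
            keep = []
            for t in range(L):
                lo, hi = max(0, t - window), min(L, t + window + 1)
                row = np.concatenate([ids[lo:t], ids[t + 1 : hi]])
                if row.size == 0:
                    continue
                rows.append(row)
                lens_list.append(row.size)
                keep.append(t)
                w_parts.append(np.full(row.size, 1.0 / row.size))
            if not rows:
                continue
            idx_parts.append(np.concatenate(rows))
            tgt_parts.append(ids[np.asarray(keep, dtype=np.int64)])
            indptr_parts.append(np.asarray(lens_list, dtype=np.int64))
    if not tgt_parts:
        return (
            np.zeros(1, dtype=np.int64),
            np.empty(0, dtype=np.int64),
            np.empty(0, dtype=np.float64),
            np.empty(0, dtype=np.int64),
        )
    indptr = np.cumsum(np.concatenate(indptr_parts))
    return (
        indptr.astype(np.int64),
        np.concatenate(idx_parts),
        np.concatenate(w_parts),
        np.concatenate(tgt_parts),
    )


def pretrain_vectors(
    corpus: Corpus, config: PretrainConfig
) -> tuple[np.ndarray, Vocabulary, list[float]]:
    """Learn an embedding table from an unlabeled (or label-stripped) corpus.

    Returns (V, vocabulary, per-epoch mean pair loss). V has one row per
    retained unigram, plus the hashed n-gram bucket region when
    ``config.n_max >= 2`` — the same feature-space layout the supervised
    model uses, so the table can be transferred directly.
    """
    token_lists = [s.tokens for s in corpus.iter_sentences()]  # labels ignored
    vocab = build_vocab(token_lists, config.min_count)
    if vocab.size == 0:
        raise ValueError("vocabulary is empty after min_count filtering")
    if config.n_max == 1 or config.mode == "fixed-window":
        indptr, indices, weights, targets = _fast_unigram_pairs(
            token_lists, vocab, config.mode, config.window
        )
    else:
        pairs: list[ContextPair] = []
        for tokens in token_lists:
            pairs.extend(
                make_context_pairs(
                    tokens, vocab, config.mode, config.window, config.n_max, config.buckets
                )
            )
        indptr, indices, weights, targets = _pairs_to_csr(pairs)
    n_pairs = targets.size
    if n_pairs == 0:
        raise ValueError("no context pairs (all sentences too short or OOV)")
    n_feat = n_features(vocab, config.n_max, config.buckets)
    rng = np.random.default_rng(config.seed)
    V = rng.uniform(-1.0 / config.dim, 1.0 / config.dim, size=(n_feat, config.dim))
    U = np.zeros((vocab.size, config.dim), dtype=np.float64)
    dist = build_noise_distribution(vocab, config.power)
    t_total = config.epochs * n_pairs
    losses: list[float] = []
    for epoch in range(config.epochs):
        order = rng.permutation(n_pairs).astype(np.int64)
        negs = np.searchsorted(
            dist.cdf, rng.random((n_pairs, config.negatives))
        ).astype(np.int64)
        bad = negs == targets[:, None]
        while bad.any():
            negs[bad] = np.searchsorted(dist.cdf, rng.random(int(bad.sum())))
            bad = negs == targets[:, None]
        total = _kernels.negative_sampling_epoch(
            indptr, indices, weights, targets, negs, order,
            V, U, config.lr, epoch * n_pairs, t_total,
        )
        losses.append(float(total) / n_pairs)
    return V, vocab, losses


def sent2vec_embed(
    V: np.ndarray,
    vocab: Vocabulary,
    tokens: Sequence[str],
    n_max: int = 1,
    buckets: int = DEFAULT_BUCKETS,
) -> np.ndarray:
    """Additive sentence embedding: the mean of the embeddings of the
    sentence's unigrams and n-grams (with multiplicity); zero vector when
    nothing is in vocabulary."""
    bag = encode_bag(tokens, vocab, n_max, buckets)
    if bag.is_empty:
        return np.zeros(V.shape[1], dtype=np.float64)
    return bag.weights @ V[bag.ids]


def embed_sentences(
    V: np.ndarray,
    vocab: Vocabulary,
    token_lists: Sequence[Sequence[str]],
    n_max: int = 1,
    buckets: int = DEFAULT_BUCKETS,
) -> np.ndarray:
    """Stack of :func:`sent2vec_embed` rows for many sentences."""
    out = np.zeros((len(token_lists), V.shape[1]), dtype=np.float64)
    for i, tokens in enumerate(token_lists):
        out[i] = sent2vec_embed(V, vocab, tokens, n_max, buckets)
    return out


def transfer_init(
    pretrained_V: np.ndarray,
    pretrained_vocab: Vocabulary,
    sup_vocab: Vocabulary,
    dim: int,
    n_max: int = 1,
    buckets: int = DEFAULT_BUCKETS,
    seed: int = 0,
) -> np.ndarray:
    """Build a supervised init table from pre-trained vectors.

    Rows for tokens shared between the two vocabularies are copied from the
    pre-trained table; unseen tokens get a fresh uniform init. When both
    feature spaces carry a hashed n-gram region of the same size, that
    region is copied wholesale (bucket ids are vocabulary-independent).
    """
    if pretrained_V.shape[1] != dim:
        raise ValueError(
            f"pretrained dimension {pretrained_V.shape[1]} != configured {dim}"
        )
    n_feat = n_features(sup_vocab, n_max, buckets)
    rng = np.random.default_rng(seed)
    V = rng.uniform(-1.0 / dim, 1.0 / dim, size=(n_feat, dim))
    for token, i in sup_vocab.index.items():
        j = pretrained_vocab.id_of(token)
        if j is not None:
            V[i] = pretrained_V[j]
    pre_has_buckets = pretrained_V.shape[0] > pretrained_vocab.size
    if n_max >= 2 and pre_has_buckets:
        pre_buckets = pretrained_V.shape[0] - pretrained_vocab.size
        if pre_buckets == buckets:
            V[sup_vocab.size :] = pretrained_V[pretrained_vocab.size :]
    return V


def save_vectors(path: Union[str, Path], vocab: Vocabulary, V: np.ndarray) -> None:
    """Standard plain-text word-vector format: 'count dim' header, then one
    token + floats line per unigram."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{vocab.size} {V.shape[1]}\n")
        for token, i in vocab.index.items():
            fh.write(token + " " + " ".join(repr(float(x)) for x in V[i]) + "\n")


def load_vectors(path: Union[str, Path]) -> tuple[np.ndarray, Vocabulary]:
    """Read a plain-text word-vector file back into (V, vocabulary).

    Frequencies are not stored in the format; counts are set to 1."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().split()
        count, dim = int(header[0]), int(header[1])
        V = np.empty((count, dim), dtype=np.float64)
        index: dict[str, int] = {}
        for i in range(count):
            parts = fh.readline().rstrip("\n").split(" ")
            index[parts[0]] = i
            V[i] = [float(x) for x in parts[1 : dim + 1]]
    vocab = Vocabulary(index, np.ones(count, dtype=np.int64), 1)
    return V, vocab
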