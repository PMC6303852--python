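"""Vocabulary construction and normalized bag-of-n-grams encoding.

Unigrams get exact, dense ids ``0..|V|-1`` (declaration order of first
appearance, frequency-thresholded by ``min_count``). Word n-grams for
``2 <= n <= n_max`` are hashed into a fixed number of buckets occupying ids
``|V| .. |V|+buckets-1`` (the hashing trick), so the feature space stays
bounded while still capturing local word order. Each sentence becomes a
normalized bag: feature weights are occurrence counts divided by the total
count, summing to one.

Hashing is FNV-1a composed over per-token FNV-1a digests of the token
strings, so a given n-gram lands in the same bucket regardless of which
vocabulary is in play — a property the semi-supervised transfer relies on.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .corpus_io import Corpus

DEFAULT_BUCKETS = 2_000_000

_FNV_OFFSET = 0xCBF29CE484222325
_FNV_PRIME = 0x100000001B3
_MASK64 = (1 << 64) - 1


@dataclass
class Vocabulary:
    """Dense token -> id mapping with retained-token frequencies."""

    index: dict[str, int]
    counts: np.ndarray  # int64 frequency per retained id
    min_count: int = 1

    @property
    def size(self) -> int:
        return len(self.index)

    @property
    def tokens(self) -> list[str]:
        return list(self.index.keys())

    def id_of(self, token: str) -> Optional[int]:
        return self.index.get(token)

    def save(self, path: Union[str, Path]) -> None:
        """Two-column plain-text table: token <TAB> count, one row per id."""
        with open(path, "w", encoding="utf-8") as fh:
            for token, i in self.index.items():
                fh.write(f"{token}\t{int(self.counts[i])}\n")

    @classmethod
    def load(cls, path: Union[str, Path], min_count: int = 1) -> "Vocabulary":
        index: dict[str, int] = {}
        counts: list[int] = []
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                token, _, count = line.rstrip("\n").partition("\t")
                index[token] = len(counts)
                counts.append(int(count))
        return cls(index, np.asarray(counts, dtype=np.int64), min_count)


def _iter_token_lists(source) -> Iterable[Sequence[str]]:
    if isinstance(source, Corpus):
        for sent in source.iter_sentences():
            yield sent.tokens
        return
    for item in source:
        yield item.tokens if hasattr(item, "tokens") else item


def build_vocab(source, min_count: int = 1) -> Vocabulary:
    """Count tokens and retain those with frequency >= ``min_count``.

    ``source`` may be a :class:`Corpus`, an iterable of sentences
    (anything with ``.tokens``), or an iterable of raw token sequences.
    Ids follow first-appearance order, so two builds over the same corpus
    yield identical mappings.
    """
    freq: dict[str, int] = {}
    n_sentences = 0
    for tokens in _iter_token_lists(source):
        n_sentences += 1
        for t in tokens:
            freq[t] = freq.get(t, 0) + 1
    if n_sentences == 0:
        raise ValueError("cannot build a vocabulary from an empty corpus")
    index: dict[str, int] = {}
    counts: list[int] = []
    for token, c in freq.items():
        if c >= min_count:
            index[token] = len(counts)
            counts.append(c)
    return Vocabulary(index, np.asarray(counts, dtype=np.int64), min_count)


def _fnv1a_bytes(data: bytes) -> int:
    h = _FNV_OFFSET
    for b in data:
        h = ((h ^ b) * _FNV_PRIME) & _MASK64
    return h


@lru_cache(maxsize=1 << 20)
def _token_hash(token: str) -> int:
    return _fnv1a_bytes(token.encode("utf-8"))


def hash_ngram(tokens: Sequence[str], buckets: int) -> int:
    """Deterministic bucket id in ``[0, buckets)`` for a word n-gram."""
    if buckets <= 0:
        raise ValueError("buckets must be positive")
    h = _FNV_OFFSET
    for t in tokens:
        h = ((h ^ _token_hash(t)) * _FNV_PRIME) & _MASK64
    return h % buckets


@dataclass
class FeatureBag:
    """Normalized sparse bag: ids below the vocabulary size are unigrams,
    ids at or above it are hashed n-gram buckets. Weights sum to 1 unless
    the bag is empty."""

    ids: np.ndarray  # int64
    weights: np.ndarray  # float64

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def is_empty(self) -> bool:
        return len(self.ids) == 0


def _bag_counts(
    tokens: Sequence[str], vocab: Vocabulary, n_max: int, buckets: int
) -> dict[int, int]:
    counts: dict[int, int] = {}
    index = vocab.index
    for t in tokens:
        i = index.get(t)
        if i is not None:
            counts[i] = counts.get(i, 0) + 1
    if n_max >= 2:
        base = vocab.size
        for n in range(2, n_max + 1):
            for start in range(len(tokens) - n + 1):
                b = base + hash_ngram(tokens[start : start + n], buckets)
                counts[b] = counts.get(b, 0) + 1
    return counts


def encode_bag(
    tokens: Sequence[str],
    vocab: Vocabulary,
    n_max: int = 1,
    buckets: int = DEFAULT_BUCKETS,
) -> FeatureBag:
    """Encode a token sequence as a normalized bag of features.

    In-vocabulary unigrams keep their exact ids; n-grams (2..n_max) over the
    full token stream — out-of-vocabulary tokens included, since they still
    occupy n-gram slots — are hashed into buckets. Duplicate features keep
    multiplicity before normalization. All-OOV or empty input yields an
    empty (valid) bag.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    counts = _bag_counts(tokens, vocab, n_max, buckets)
    if not counts:
        return FeatureBag(np.empty(0, dtype=np.int64), np.empty(0, dtype=np.float64))
    ids = np.fromiter(counts.keys(), dtype=np.int64, count=len(counts))
    w = np.fromiter(counts.values(), dtype=np.float64, count=len(counts))
    return FeatureBag(ids, w / w.sum())


def n_features(vocab: Vocabulary, n_max: int, buckets: int = DEFAULT_BUCKETS) -> int:
    """Total feature-space size for a vocabulary and n-gram setting."""
    return vocab.size + (buckets if n_max >= 2 else 0)


def encode_dataset(
    token_lists: Iterable[Sequence[str]],
    vocab: Vocabulary,
    n_max: int = 1,
    buckets: int = DEFAULT_BUCKETS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Encode many sentences into CSR arrays (indptr, indices, weights).

    Row ``i`` of the implied sparse matrix is the normalized feature bag of
    sentence ``i``; empty bags become empty rows.
    """
    indptr = [0]
    all_ids: list[np.ndarray] = []
    all_w: list[np.ndarray] = []
    for tokens in token_lists:
        bag = encode_bag(tokens, vocab, n_max, buckets)
        all_ids.append(bag.ids)
        all_w.append(bag.weights)
        indptr.append(indptr[-1] + len(bag.ids))
    indices = (
        np.concatenate(all_ids) if all_ids else np.empty(0, dtype=np.int64)
    )
    weights = np.concatenate(all_w) if all_w else np.empty(0, dtype=np.float64)
    return (
        np.asarray(indptr, dtype=np.int64),
        indices.astype(np.int64, copy=False),
        weights.astype(np.float64, copy=False),
    )
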