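"""Synthetic structured-abstract corpora with known generative structure.

Every other module is testable without external data because this generator
reproduces the structural premises the classifier exploits in real
structured abstracts:

* sections appear in a canonical rhetorical order (background/objective
  block, then methods, results, conclusions), so sentence position
  correlates with label;
* each label has its own discriminative token pool, mixed with a large
  shared pool (emission probability ``delta`` for discriminative tokens);
* background and objective draw a fraction ``epsilon`` of their
  discriminative mass from a common confusable pool, mimicking how those
  two rhetorical roles blur into each other in real abstracts;
* class supports are skewed toward methods/results, as in the benchmark.

Tokens are synthetic strings (``w12``, ``obj3``, ``bo7``, ...); the
classifier is lexical-statistical, so distributional structure suffices and
the pools are disjoint by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .corpus_io import CANONICAL_LABELS, Abstract, Corpus, Sentence

#: Order in which sections are emitted inside an abstract.
SECTION_ORDER = ("BACKGROUND", "OBJECTIVE", "METHODS", "RESULTS", "CONCLUSIONS")

_POOL_PREFIX = {
    "OBJECTIVE": "obj",
    "BACKGROUND": "bg",
    "METHODS": "met",
    "RESULTS": "res",
    "CONCLUSIONS": "con",
}


def _default_section_counts() -> dict:
    # (presence probability, min sentences, max sentences) per section;
    # means work out to supports of roughly 12/10/31/31/15 percent —
    # methods+results dominate, as in the real benchmark. Block sizes are
    # variable so sentence index only partially determines the label.
    return {
        "BACKGROUND": (0.8, 1, 3),
        "OBJECTIVE": (0.9, 1, 2),
        "METHODS": (1.0, 2, 6),
        "RESULTS": (1.0, 2, 6),
        "CONCLUSIONS": (0.95, 1, 3),
    }


@dataclass
class SyntheticSpec:
    """Generative parameters for a structured-abstract corpus.

    ``delta`` is the probability a token is drawn from the sentence label's
    discriminative pool (otherwise from the shared pool); ``epsilon`` is the
    fraction of background/objective discriminative draws taken from their
    common confusable pool. Same spec + seed always yields the same corpus.
    """

    n_abstracts: int = 500
    section_counts: dict = field(default_factory=_default_section_counts)
    sentence_length: tuple[int, int] = (5, 12)
    shared_pool: int = 5000
    label_pool: int = 1000
    confusable_pool: int = 1000
    delta: float = 0.3
    epsilon: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError("epsilon must be in [0, 1]")
        for lab, (p, lo, hi) in self.section_counts.items():
            if not 0.0 <= p <= 1.0 or lo > hi or lo < 0:
                raise ValueError(f"invalid section counts for {lab}")

    @property
    def mean_sentences_per_abstract(self) -> float:
        return sum(
            p * (lo + hi) / 2.0 for p, lo, hi in self.section_counts.values()
        )

    @property
    def expected_sentences(self) -> float:
        return self.n_abstracts * self.mean_sentences_per_abstract


def default_spec(scale: str = "small") -> SyntheticSpec:
    """Preset specs: 'small' (~500 abstracts, unit tests) or 'medium'
    (~5000 abstracts, experiment-scale runs)."""
    if scale == "small":
        return SyntheticSpec(n_abstracts=500)
    if scale == "medium":
        return SyntheticSpec(n_abstracts=5000)
    raise ValueError(f"unknown scale {scale!r} (expected 'small' or 'medium')")


def _sentence_tokens(
    label: str, length: int, spec: SyntheticSpec, rng: np.random.Generator
) -> tuple[str, ...]:
    is_disc = rng.random(length) < spec.delta
    shared_ids = rng.integers(0, spec.shared_pool, size=length)
    pool_ids = rng.integers(0, spec.label_pool, size=length)
    if label in ("BACKGROUND", "OBJECTIVE"):
        confusable = rng.random(length) < spec.epsilon
        conf_ids = rng.integers(0, spec.confusable_pool, size=length)
    else:
        confusable = np.zeros(length, dtype=bool)
        conf_ids = pool_ids
    prefix = _POOL_PREFIX[label]
    tokens = []
    for i in range(length):
        if not is_disc[i]:
            tokens.append(f"w{shared_ids[i]}")
        elif confusable[i]:
            tokens.append(f"bo{conf_ids[i]}")
        else:
            tokens.append(f"{prefix}{pool_ids[i]}")
    return tuple(tokens)


def generate_corpus(spec: SyntheticSpec, seed: Optional[int] = None) -> Corpus:
    """Generate a labeled corpus from ``spec`` (seed defaults to spec.seed).

    Sections appear in canonical order; every abstract has at least one
    sentence (methods/results sections are always present).
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    lo_len, hi_len = spec.sentence_length
    abstracts = []
    for a in range(spec.n_abstracts):
        sentences: list[Sentence] = []
        for label in SECTION_ORDER:
            presence, lo, hi = spec.section_counts[label]
            if rng.random() >= presence:
                continue
            count = int(rng.integers(lo, hi + 1))
            for _ in range(count):
                length = int(rng.integers(lo_len, hi_len + 1))
                tokens = _sentence_tokens(label, length, spec, rng)
                sentences.append(Sentence(tokens, label, len(sentences)))
        if not sentences:  # unreachable with default presence=1 sections
            length = int(rng.integers(lo_len, hi_len + 1))
            sentences.append(
                Sentence(_sentence_tokens("METHODS", length, spec, rng), "METHODS", 0)
            )
        abstracts.append(Abstract(f"synth{a:06d}", sentences))
    return Corpus(abstracts, CANONICAL_LABELS)
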