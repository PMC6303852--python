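"""Sentence-context and position token augmentation.

A bag-of-n-grams classifier cannot see where a sentence sits inside its
abstract, yet rhetorical sections appear in a near-canonical order. This
module injects that sequential signal into the token stream itself: a
numeric position token (``pos_3`` for the third sentence) and the tokens of
up to ``window`` neighboring sentences on each side, each neighbor token
tagged with an offset prefix (``-1_`` for the directly preceding sentence,
``+2_`` for the sentence after next, ...). Neighbors outside the abstract are
simply omitted. The classifier is then trained on this enhanced token
sequence with its standard bag model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from .corpus_io import Abstract, Corpus


@dataclass(frozen=True)
class AugmentConfig:
    """Which parts of the augmentation to apply.

    ``window=0`` together with ``include_position=False`` reproduces the
    plain single-sentence model. ``relative_position`` swaps the raw 1-based
    index for a length-relative decile token; off by default.
    """

    window: int = 2
    include_position: bool = True
    include_context: bool = True
    relative_position: bool = False

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be non-negative")


#: The four ablation variants studied with the full model.
SINGLE_SENTENCE = AugmentConfig(window=0, include_position=False, include_context=False)
NO_POSITION = AugmentConfig(window=2, include_position=False, include_context=True)
NO_CONTEXT = AugmentConfig(window=2, include_position=True, include_context=False)
FULL = AugmentConfig(window=2, include_position=True, include_context=True)


@dataclass(frozen=True)
class AugmentedSentence:
    """A sentence with context/position tokens spliced around its own tokens."""

    tokens: tuple[str, ...]
    label: Optional[str]
    source: tuple[str, int]  # (abstract id, sentence index)


def position_token(index: int, n_sentences: int, relative: bool = False) -> str:
    """Token encoding the 1-based position of sentence ``index``."""
    if relative:
        decile = math.ceil(10 * (index + 1) / n_sentences)
        return f"posrel_{decile}"
    return f"pos_{index + 1}"


def augment_sentence(
    abstract: Abstract, index: int, config: AugmentConfig = FULL
) -> AugmentedSentence:
    """Build the enhanced representation of sentence ``index`` of ``abstract``.

    Layout: preceding context sentences (most distant first, tokens prefixed
    ``-w_`` ... ``-1_``), then the position token, then the target sentence's
    tokens unmodified, then trailing contexts prefixed ``+1_`` ... ``+w_``.
    """
    n = len(abstract.sentences)
    if not 0 <= index < n:
        raise IndexError(f"sentence index {index} out of range for abstract of {n}")
    target = abstract.sentences[index]
    out: list[str] = []
    if config.include_context:
        for off in range(-config.window, 0):
            j = index + off
            if j >= 0:
                prefix = f"{off:+d}_"
                out.extend(prefix + t for t in abstract.sentences[j].tokens)
    if config.include_position:
        out.append(position_token(index, n, config.relative_position))
    out.extend(target.tokens)
    if config.include_context:
        for off in range(1, config.window + 1):
            j = index + off
            if j < n:
                prefix = f"{off:+d}_"
                out.extend(prefix + t for t in abstract.sentences[j].tokens)
    return AugmentedSentence(tuple(out), target.label, (abstract.id, index))


def augment_corpus(corpus: Corpus, config: AugmentConfig = FULL) -> list[AugmentedSentence]:
    """Augment every sentence of ``corpus``, in corpus order."""
    out: list[AugmentedSentence] = []
    for abstract in corpus.abstracts:
        for i in range(len(abstract.sentences)):
            out.append(augment_sentence(abstract, i, config))
    return out


def strip_prefix(token: str) -> tuple[int, str]:
    """Recover (offset, original token) from a context token; offset 0 for
    unprefixed tokens. The position token maps to offset 0 unchanged."""
    head, sep, rest = token.partition("_")
    if sep and head and (head[0] in "+-"):
        try:
            return int(head), rest
        except ValueError:
            pass
    return 0, token
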