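"""Reading, writing and normalizing sentence-labelled abstract corpora.

The on-disk dialect mirrors the public PubMed-RCT benchmark layout:

* each abstract starts with a ``###<id>`` header line,
* each sentence is one line, ``LABEL<TAB>sentence text`` when labelled or
  plain text for unlabeled (pre-training) corpora,
* abstracts are separated by a blank line.

Text normalization is deliberately minimal: lower-casing plus padding every
ASCII punctuation character with whitespace, then whitespace splitting.
Numbers and rare words are kept; decimal numbers split at the period.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

#: Canonical rhetorical label order (fixed so confusion matrices are
#: comparable across runs and with the published benchmark).
CANONICAL_LABELS: tuple[str, ...] = (
    "OBJECTIVE",
    "BACKGROUND",
    "METHODS",
    "RESULTS",
    "CONCLUSIONS",
)

_PUNCT_TABLE = str.maketrans({c: f" {c} " for c in string.punctuation})


class ParseError(ValueError):
    """Raised when a corpus file does not follow the expected dialect."""


class LabelError(ValueError):
    """Raised when a sentence carries a label outside the allowed set."""


def normalize_text(raw: str) -> list[str]:
    """Normalize raw sentence text into a token list.

    Lower-cases, separates every ASCII punctuation character into its own
    token, and splits on whitespace. Empty input yields an empty list.
    Non-ASCII characters are treated as ordinary word characters.

    >>> normalize_text("Aspirin reduced pain.")
    ['aspirin', 'reduced', 'pain', '.']
    """
    return raw.lower().translate(_PUNCT_TABLE).split()


@dataclass(frozen=True)
class Sentence:
    """One normalized sentence; ``label`` is ``None`` in unlabeled corpora."""

    tokens: tuple[str, ...]
    label: Optional[str] = None
    index: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tokens", tuple(self.tokens))


@dataclass
class Abstract:
    """An ordered sequence of sentences sharing an opaque identifier."""

    id: str
    sentences: list[Sentence] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sentences)


@dataclass
class Corpus:
    """An ordered collection of abstracts plus a fixed label order."""

    abstracts: list[Abstract] = field(default_factory=list)
    label_set: tuple[str, ...] = ()

    def iter_sentences(self) -> Iterator[Sentence]:
        for abstract in self.abstracts:
            yield from abstract.sentences

    @property
    def n_sentences(self) -> int:
        return sum(len(a) for a in self.abstracts)

    def without_labels(self) -> "Corpus":
        """Copy of the corpus with every label stripped (for pre-training)."""
        abstracts = [
            Abstract(a.id, [Sentence(s.tokens, None, s.index) for s in a.sentences])
            for a in self.abstracts
        ]
        return Corpus(abstracts, ())

    def validate(self) -> None:
        labels = set(self.label_set)
        for abstract in self.abstracts:
            if not abstract.sentences:
                raise ValueError(f"abstract {abstract.id!r} has no sentences")
            for i, sent in enumerate(abstract.sentences):
                if sent.index != i:
                    raise ValueError(
                        f"abstract {abstract.id!r}: sentence index {sent.index} != {i}"
                    )
                if not sent.tokens:
                    raise ValueError(f"abstract {abstract.id!r}: empty sentence {i}")
                if sent.label is not None and sent.label not in labels:
                    raise LabelError(
                        f"abstract {abstract.id!r}: label {sent.label!r} not in label set"
                    )


def _finish_abstract(
    abstracts: list[Abstract], raw: Optional[tuple[str, list[Sentence]]]
) -> None:
    if raw is None:
        return
    aid, sentences = raw
    if sentences:  # abstracts with no retained sentences are dropped
        abstracts.append(Abstract(aid, sentences))


def read_rct_corpus(
    path: Union[str, Path],
    labeled: bool = True,
    label_set: Optional[Sequence[str]] = None,
    normalize: bool = True,
) -> Corpus:
    """Parse a corpus file in the PubMed-RCT text dialect.

    Parameters
    ----------
    path:
        File to read (UTF-8).
    labeled:
        When true, every sentence line must be ``LABEL<TAB>text``; when
        false, lines are plain sentence text.
    label_set:
        Optional canonical label order. When given, any label outside it
        raises :class:`LabelError`; when omitted, labels are collected in
        order of first appearance.
    normalize:
        When false, split on whitespace only — for files that are already
        tokenized, e.g. the output of the context-augmentation step, whose
        offset prefixes (``-1_``) must not be re-split at punctuation.
    """
    text = Path(path).read_text(encoding="utf-8")
    allowed = None if label_set is None else set(label_set)
    seen_labels: list[str] = []
    abstracts: list[Abstract] = []
    current: Optional[tuple[str, list[Sentence]]] = None

    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            _finish_abstract(abstracts, current)
            current = None
            continue
        if line.startswith("###"):
            _finish_abstract(abstracts, current)
            current = (line[3:].strip(), [])
            continue
        if current is None:  # headerless block: synthesize an id
            current = (f"a{len(abstracts)}", [])
        aid, sentences = current
        if labeled:
            if "\t" not in line:
                raise ParseError(
                    f"{path}: line {lineno}: expected LABEL<TAB>text, got {line!r}"
                )
            label, raw = line.split("\t", 1)
            label = label.strip()
            if allowed is not None and label not in allowed:
                raise LabelError(
                    f"{path}: line {lineno}: unknown label {label!r}"
                )
            if label not in seen_labels:
                seen_labels.append(label)
        else:
            label, raw = None, line
        tokens = normalize_text(raw) if normalize else raw.split()
        if tokens:
            sentences.append(Sentence(tuple(tokens), label, len(sentences)))
    _finish_abstract(abstracts, current)

    if label_set is not None:
        order = tuple(label_set)
    else:
        order = tuple(seen_labels)
    return Corpus(abstracts, order)


def write_rct_corpus(corpus: Corpus, path: Union[str, Path]) -> None:
    """Write ``corpus`` in the PubMed-RCT dialect.

    The emitted file re-reads to an identical corpus (round-trip identity on
    normalized corpora, given the same ``label_set`` on re-read).
    """
    lines: list[str] = []
    for abstract in corpus.abstracts:
        lines.append(f"###{abstract.id}")
        for sent in abstract.sentences:
            text = " ".join(sent.tokens)
            if sent.label is None:
                lines.append(text)
            else:
                lines.append(f"{sent.label}\t{text}")
        lines.append("")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
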