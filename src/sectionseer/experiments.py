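"""Frozen experiment protocols for the synthetic-corpus studies.

Two studies mirror the evaluation design of the augmentation and
semi-supervised analyses, at a scale that runs in minutes on one CPU:

* :func:`ablation_experiment` — train the four preprocessing variants
  (full augmentation, position removed, context removed, single sentence)
  on an 80/20 abstract-level split and compare test weighted F1, median
  over a few training seeds.
* :func:`semi_supervised_experiment` — pre-train n-gram vectors on the
  whole corpus without labels, then compare from-scratch supervised
  training against pre-trained initialization (and optionally the frozen
  sentence-embedding + MLP pipeline) across labeled training-set sizes.

Model settings are fixed here so tests and scripts measure the same thing:
dim 20, unigram features (synthetic tokens are i.i.d. within a sentence, so
word n-grams carry no signal on these corpora), 8 supervised epochs for the
ablation, 10 for the low-label runs, and 60 pre-training epochs — the
pre-training corpus here is ~0.5M tokens, orders of magnitude smaller than
the corpora word-vector defaults assume, so the epoch count is scaled up to
keep the total number of updates in the regime where the negative-sampling
objective moves past its frequency-only plateau.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .context_augment import FULL, NO_CONTEXT, NO_POSITION, SINGLE_SENTENCE, augment_corpus
from .corpus_io import Corpus
from .evaluation import CurveResult, evaluate_classifier, learning_curve
from .supervised_model import TrainConfig, train_supervised
from .unsupervised_pretrain import PretrainConfig, pretrain_vectors

ABLATION_VARIANTS = {
    "full": FULL,
    "no_position": NO_POSITION,
    "no_context": NO_CONTEXT,
    "single_sentence": SINGLE_SENTENCE,
}

ABLATION_CONFIG = TrainConfig(dim=20, n_max=1, epochs=8, lr=0.1)
CURVE_SUP_CONFIG = TrainConfig(dim=20, n_max=1, epochs=10, lr=0.1)
CURVE_PRE_CONFIG = PretrainConfig(dim=20, n_max=1, epochs=60, lr=0.05)


def split_by_abstract(
    corpus: Corpus, train_frac: float = 0.8, seed: int = 0
) -> tuple[Corpus, Corpus]:
    """Shuffle abstracts and split, keeping abstracts intact (context
    augmentation needs whole abstracts)."""
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(corpus.abstracts))
    cut = int(train_frac * len(idx))
    train = Corpus([corpus.abstracts[i] for i in idx[:cut]], corpus.label_set)
    test = Corpus([corpus.abstracts[i] for i in idx[cut:]], corpus.label_set)
    return train, test


def ablation_experiment(
    corpus: Corpus,
    seed: int = 1,
    n_seeds: int = 3,
    train_frac: float = 0.8,
    config: Optional[TrainConfig] = None,
) -> pd.DataFrame:
    """Test weighted F1 per preprocessing variant, per training seed.

    The abstract-level split is fixed once from ``seed``; training seeds
    vary. Returns a tidy frame (variant, seed, f1); medians via
    ``df.groupby("variant")["f1"].median()``.
    """
    config = config if config is not None else ABLATION_CONFIG
    train, test = split_by_abstract(corpus, train_frac, seed)
    rows = []
    for variant, aug_config in ABLATION_VARIANTS.items():
        aug_train = augment_corpus(train, aug_config)
        aug_test = augment_corpus(test, aug_config)
        for s in range(n_seeds):
            clf = train_supervised(
                aug_train,
                replace(config, seed=seed + s),
                label_order=corpus.label_set,
            )
            report = evaluate_classifier(clf, aug_test)
            rows.append({"variant": variant, "seed": seed + s, "f1": report.weighted_f1})
    return pd.DataFrame(rows)


def ablation_medians(table: pd.DataFrame) -> dict[str, float]:
    return table.groupby("variant")["f1"].median().to_dict()


def semi_supervised_experiment(
    corpus: Corpus,
    sizes: Sequence[int] = (500, 20000),
    replicates: int = 5,
    setups: Sequence[str] = ("supervised", "pretrained"),
    test_size: int = 20000,
    seed: int = 1,
    sup_config: Optional[TrainConfig] = None,
    pre_config: Optional[PretrainConfig] = None,
    pretrained: Optional[tuple] = None,
) -> CurveResult:
    """Learning-curve comparison on single sentences (no augmentation).

    Vectors are pre-trained once on the full corpus with labels stripped
    (pass ``pretrained=(V, vocab)`` to reuse a table across calls).
    """
    sup_config = sup_config if sup_config is not None else CURVE_SUP_CONFIG
    pre_config = pre_config if pre_config is not None else CURVE_PRE_CONFIG
    if pretrained is None and any(s != "supervised" for s in setups):
        V, vocab, _ = pretrain_vectors(
            corpus.without_labels(), replace(pre_config, seed=seed)
        )
        pretrained = (V, vocab)
    return learning_curve(
        corpus,
        sizes=sizes,
        replicates=replicates,
        setups=setups,
        test_size=test_size,
        seed=seed,
        sup_config=sup_config,
        pre_config=pre_config,
        pretrained=pretrained,
    )
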