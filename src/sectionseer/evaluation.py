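"""Evaluation and experiment harness.

Confusion matrices and support-weighted F1 (the headline metric: per-class
F1 scores weighted by how frequently each label occurs), exhaustive
hyperparameter grid search, and the semi-supervised learning-curve protocol:
sample a labeled training set of a given size, a disjoint test set, run each
classifier setup on identical splits, and report the median weighted F1 over
replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion_matrix

from .corpus_io import Corpus
from .downstream_mlp import mlp_predict, train_mlp_head
from .features import build_vocab
from .supervised_model import TextClassifier, TrainConfig, train_supervised
from .unsupervised_pretrain import (
    PretrainConfig,
    embed_sentences,
    pretrain_vectors,
    transfer_init,
)


def confusion_matrix(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    label_order: Sequence[str],
) -> np.ndarray:
    """k x k count matrix, rows = true label, columns = predicted label."""
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label sequences differ in length")
    known = set(label_order)
    for lab in true_labels:
        if lab not in known:
            raise ValueError(f"unknown true label {lab!r}")
    for lab in predicted_labels:
        if lab not in known:
            raise ValueError(f"unknown predicted label {lab!r}")
    return _sk_confusion_matrix(
        true_labels, predicted_labels, labels=list(label_order)
    ).astype(np.int64)


def per_class_metrics(cm: np.ndarray) -> pd.DataFrame:
    """Precision, recall, F1 and support per class from a count matrix.

    recall_i = cm[i,i]/rowsum_i, precision_i = cm[i,i]/colsum_i, F1 their
    harmonic mean; zero denominators yield 0 by convention.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or (cm < 0).any():
        raise ValueError("confusion matrix must be square and non-negative")
    diag = np.diag(cm).astype(np.float64)
    rowsum = cm.sum(axis=1).astype(np.float64)
    colsum = cm.sum(axis=0).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        recall = np.where(rowsum > 0, diag / rowsum, 0.0)
        precision = np.where(colsum > 0, diag / colsum, 0.0)
        denom = precision + recall
        f1 = np.where(denom > 0, 2 * precision * recall / denom, 0.0)
    return pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": cm.sum(axis=1).astype(np.int64),
        }
    )


def weighted_f1_from_cm(cm: np.ndarray) -> float:
    """Support-weighted F1 computed from a count matrix."""
    metrics = per_class_metrics(cm)
    n = metrics["support"].sum()
    if n == 0:
        raise ValueError("empty confusion matrix")
    return float((metrics["support"] / n * metrics["f1"]).sum())


def weighted_f1(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    label_order: Sequence[str],
) -> float:
    """Support-weighted F1 of a prediction run, in [0, 1]."""
    if len(true_labels) == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    return weighted_f1_from_cm(
        confusion_matrix(true_labels, predicted_labels, label_order)
    )


@dataclass
class EvalReport:
    """Confusion matrix plus derived metrics for one evaluation run."""

    label_order: tuple[str, ...]
    cm: np.ndarray
    per_class: pd.DataFrame
    weighted_f1: float
    n: int

    def to_dict(self) -> dict:
        return {
            "label_order": list(self.label_order),
            "confusion_matrix": self.cm.tolist(),
            "per_class": {
                lab: {
                    "precision": float(self.per_class["precision"][i]),
                    "recall": float(self.per_class["recall"][i]),
                    "f1": float(self.per_class["f1"][i]),
                    "support": int(self.per_class["support"][i]),
                }
                for i, lab in enumerate(self.label_order)
            },
            "weighted_f1": self.weighted_f1,
            "n": self.n,
        }


def evaluate_predictions(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    label_order: Sequence[str],
) -> EvalReport:
    cm = confusion_matrix(true_labels, predicted_labels, label_order)
    metrics = per_class_metrics(cm)
    return EvalReport(
        tuple(label_order), cm, metrics, weighted_f1_from_cm(cm), len(true_labels)
    )


def evaluate_classifier(clf: TextClassifier, sentences: Sequence) -> EvalReport:
    """Evaluate a trained classifier on labeled sentences (anything with
    ``tokens`` and ``label``)."""
    y_true = [s.label for s in sentences]
    y_pred = clf.predict([s.tokens for s in sentences])
    return evaluate_predictions(y_true, y_pred, clf.model.label_order)


def grid_search(
    train_sentences: Sequence,
    valid_sentences: Sequence,
    dims: Sequence[int] = (10, 20, 50),
    n_maxes: Sequence[int] = (1, 2, 3, 4),
    epochs_list: Sequence[int] = tuple(range(1, 9)),
    base_config: Optional[TrainConfig] = None,
    seed: int = 1,
) -> tuple[TrainConfig, pd.DataFrame]:
    """Exhaustive sweep over dim x n_max x epochs, scored by validation
    weighted F1. Ties break toward smaller dim, then n_max, then epochs.
    Returns the winning config and the full results table."""
    if not (len(dims) and len(n_maxes) and len(epochs_list)):
        raise ValueError("grid must be non-empty")
    base = base_config if base_config is not None else TrainConfig()
    rows = []
    best: Optional[TrainConfig] = None
    best_f1 = -1.0
    for dim in sorted(dims):
        for n_max in sorted(n_maxes):
            for epochs in sorted(epochs_list):
                config = replace(base, dim=dim, n_max=n_max, epochs=epochs, seed=seed)
                clf = train_supervised(train_sentences, config)
                report = evaluate_classifier(clf, valid_sentences)
                rows.append(
                    {"dim": dim, "n_max": n_max, "epochs": epochs, "f1": report.weighted_f1}
                )
                if report.weighted_f1 > best_f1:
                    best_f1 = report.weighted_f1
                    best = config
    return best, pd.DataFrame(rows)


@dataclass
class CurveResult:
    """Tidy learning-curve results: one row per (size, setup, replicate)."""

    table: pd.DataFrame

    @property
    def medians(self) -> pd.DataFrame:
        return (
            self.table.groupby(["size", "setup"], sort=True)["f1"]
            .median()
            .reset_index()
        )

    def median(self, size: int, setup: str) -> float:
        t = self.table
        vals = t[(t["size"] == size) & (t["setup"] == setup)]["f1"]
        return float(vals.median())


SETUPS = ("supervised", "pretrained", "sent2vec_mlp")


def _run_setup(
    setup: str,
    train_sents,
    test_sents,
    label_order,
    sup_config: TrainConfig,
    pre_config: PretrainConfig,
    pretrained,
    mlp_hidden: int,
    run_seed: int,
) -> float:
    y_true = [s.label for s in test_sents]
    config = replace(sup_config, seed=run_seed)
    if setup == "supervised":
        clf = train_supervised(train_sents, config, label_order=label_order)
        y_pred = clf.predict([s.tokens for s in test_sents])
    elif setup == "pretrained":
        V_pre, vocab_pre = pretrained
        vocab = build_vocab(train_sents, config.min_count)
        init_V = transfer_init(
            V_pre, vocab_pre, vocab, config.dim, config.n_max, config.buckets,
            seed=run_seed,
        )
        clf = train_supervised(
            train_sents, config, init_V=init_V, vocab=vocab, label_order=label_order
        )
        y_pred = clf.predict([s.tokens for s in test_sents])
    elif setup == "sent2vec_mlp":
        V_pre, vocab_pre = pretrained
        X_tr = embed_sentences(
            V_pre, vocab_pre, [s.tokens for s in train_sents],
            pre_config.n_max, pre_config.buckets,
        )
        X_te = embed_sentences(
            V_pre, vocab_pre, [s.tokens for s in test_sents],
            pre_config.n_max, pre_config.buckets,
        )
        head = train_mlp_head(
            X_tr, [s.label for s in train_sents], label_order,
            hidden=mlp_hidden, seed=run_seed,
        )
        y_pred = mlp_predict(head, X_te)
    else:
        raise ValueError(f"unknown setup {setup!r}")
    return weighted_f1(y_true, y_pred, label_order)


def learning_curve(
    corpus: Corpus,
    sizes: Sequence[int],
    replicates: int = 5,
    setups: Sequence[str] = SETUPS,
    test_size: int = 20000,
    seed: int = 0,
    sup_config: Optional[TrainConfig] = None,
    pre_config: Optional[PretrainConfig] = None,
    pretrained: Optional[tuple] = None,
    mlp_hidden: int = 100,
) -> CurveResult:
    """Semi-supervised learning-curve experiment on single sentences.

    For each training-set size and replicate, sample ``size`` labeled
    sentences without replacement and a disjoint test set of ``test_size``
    sentences (sampling ignores abstract boundaries); every setup inside a
    replicate sees the identical split. Pre-training (when any setup needs
    it) runs once on the full corpus with labels stripped, unless a
    ``pretrained`` (V, vocabulary) pair is supplied.
    """
    for setup in setups:
        if setup not in SETUPS:
            raise ValueError(f"unknown setup {setup!r}")
    sup_config = sup_config if sup_config is not None else TrainConfig()
    pre_config = pre_config if pre_config is not None else PretrainConfig()
    sentences = list(corpus.iter_sentences())
    n = len(sentences)
    sizes = sorted(sizes)
    if max(sizes) + test_size > n:
        raise ValueError(
            f"corpus has {n} sentences; need >= {max(sizes) + test_size}"
        )
    label_order = corpus.label_set
    needs_pretrain = any(s in ("pretrained", "sent2vec_mlp") for s in setups)
    if needs_pretrain and pretrained is None:
        V_pre, vocab_pre, _ = pretrain_vectors(corpus.without_labels(), pre_config)
        pretrained = (V_pre, vocab_pre)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(sizes) * replicates)
    rows = []
    for si, size in enumerate(sizes):
        for rep in range(replicates):
            child = children[si * replicates + rep]
            rng = np.random.default_rng(child)
            run_seed = int(child.generate_state(1)[0] % (2**31))
            perm = rng.permutation(n)
            train_sents = [sentences[i] for i in perm[:size]]
            test_sents = [sentences[i] for i in perm[size : size + test_size]]
            for setup in setups:
                f1 = _run_setup(
                    setup, train_sents, test_sents, label_order,
                    sup_config, pre_config, pretrained, mlp_hidden, run_seed,
                )
                rows.append(
                    {"size": size, "setup": setup, "replicate": rep, "f1": f1}
                )
    return CurveResult(pd.DataFrame(rows))
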