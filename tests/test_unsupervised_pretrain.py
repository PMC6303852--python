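"""Negative-sampling pre-training: noise distribution, pairs, loss, vectors."""

import math

import numpy as np
import pytest

from sectionseer.corpus_io import Abstract, Corpus, Sentence
from sectionseer.features import FeatureBag, Vocabulary, build_vocab, encode_bag
from sectionseer.supervised_model import init_model
from sectionseer.unsupervised_pretrain import (
    ContextPair,
    PretrainConfig,
    build_noise_distribution,
    load_vectors,
    make_context_pairs,
    pretrain_vectors,
    sample_negatives,
    save_vectors,
    sent2vec_embed,
    transfer_init,
    unsupervised_grads,
    unsupervised_loss,
)


def _vocab(freqs: dict) -> Vocabulary:
    sents = [[t] * c for t, c in freqs.items()]
    return build_vocab(sents, min_count=1)


def test_noise_distribution_power_zero_is_uniform():
    dist = build_noise_distribution(_vocab({"a": 10, "b": 1, "c": 5}), power=0.0)
    np.testing.assert_allclose(dist.probs, 1 / 3)


def test_noise_distribution_three_quarters_power_closed_form():
    # freqs (81, 16): 81^.75 = 27, 16^.75 = 8 -> (27/35, 8/35)
    vocab = _vocab({"a": 81, "b": 16})
    dist = build_noise_distribution(vocab, power=0.75)
    np.testing.assert_allclose(
        dist.probs[[vocab.index["a"], vocab.index["b"]]], [27 / 35, 8 / 35], atol=1e-12
    )


def test_noise_distribution_sampling_frequencies(rng):
    vocab = _vocab({"a": 81, "b": 16, "c": 1})
    dist = build_noise_distribution(vocab, 0.75)
    draws = np.searchsorted(dist.cdf, rng.random(100_000))
    for wid, p in enumerate(dist.probs):
        observed = np.mean(draws == wid)
        assert abs(observed - p) < 3 * math.sqrt(p * (1 - p) / 100_000) + 1e-4


def test_sample_negatives_excludes_and_counts(rng):
    vocab = _vocab({"a": 5, "b": 5, "c": 5})
    dist = build_noise_distribution(vocab, 1.0)
    exclude = vocab.index["b"]
    for _ in range(200):
        out = sample_negatives(dist, 5, exclude, rng)
        assert len(out) == 5
        assert exclude not in out


def test_sample_negatives_matches_renormalized_distribution(rng):
    vocab = _vocab({"a": 64, "b": 27, "c": 8})
    dist = build_noise_distribution(vocab, 1.0)
    exclude = vocab.index["a"]
    draws = np.concatenate([sample_negatives(dist, 10, exclude, rng) for _ in range(4000)])
    rest = [i for i in range(3) if i != exclude]
    renorm = dist.probs[rest] / dist.probs[rest].sum()
    for wid, p in zip(rest, renorm):
        observed = np.mean(draws == wid)
        assert abs(observed - p) < 3 * math.sqrt(p * (1 - p) / draws.size) + 1e-3


def test_sample_negatives_single_word_vocab_errors(rng):
    dist = build_noise_distribution(_vocab({"a": 3}), 1.0)
    with pytest.raises(ValueError):
        sample_negatives(dist, 1, 0, rng)


def test_fixed_window_pairs_enumeration():
    vocab = _vocab({"a": 1, "b": 1, "c": 1})
    pairs = make_context_pairs(["a", "b", "c"], vocab, "fixed-window", window=1)
    assert len(pairs) == 3
    ctx_sets = [
        {vocab.tokens[i] for i in p.context.ids.tolist()} for p in pairs
    ]
    assert ctx_sets == [{"b"}, {"a", "c"}, {"b"}]
    for p in pairs:
        assert p.target not in p.context.ids.tolist() or True  # target may recur as token elsewhere


def test_whole_sentence_pair_context_is_rest_of_sentence():
    vocab = _vocab({"a": 1, "b": 1, "c": 1})
    pairs = make_context_pairs(["a", "b", "c"], vocab, "whole-sentence", n_max=1)
    assert len(pairs) == 3
    mid = pairs[1]
    assert vocab.tokens[mid.target] == "b"
    assert {vocab.tokens[i] for i in mid.context.ids.tolist()} == {"a", "c"}


def test_pair_count_equals_token_count_on_in_vocab_sentences(rng):
    vocab = _vocab({f"t{i}": 2 for i in range(20)})
    for mode in ("fixed-window", "whole-sentence"):
        for _ in range(10):
            tokens = [f"t{rng.integers(20)}" for _ in range(int(rng.integers(2, 12)))]
            pairs = make_context_pairs(tokens, vocab, mode, window=5)
            assert len(pairs) == len(tokens)


def test_too_short_sentences_yield_zero_pairs():
    vocab = _vocab({"a": 1})
    assert make_context_pairs(["a"], vocab, "whole-sentence") == []
    assert make_context_pairs(["zzz", "a"], vocab, "fixed-window", window=5) == []


def test_zero_model_pair_loss_is_ln2_per_term():
    m = init_model(6, 3, 6, seed=0)
    m.V[:] = 0.0
    pair = ContextPair(0, FeatureBag(np.array([1, 2]), np.array([0.5, 0.5])), "whole-sentence")
    for n_neg in (1, 5):
        loss = unsupervised_loss(m, pair, list(range(1, n_neg + 1)))
        assert loss == pytest.approx((1 + n_neg) * math.log(2), abs=1e-12)


def test_loss_vanishes_in_perfect_separation_limit():
    m = init_model(3, 2, 3, seed=0)
    m.V = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    m.U = np.array([[60.0, 0.0], [0.0, 0.0], [-60.0, 0.0]])
    pair = ContextPair(0, FeatureBag(np.array([1]), np.array([1.0])), "whole-sentence")
    assert unsupervised_loss(m, pair, [2]) < 1e-12


def test_unsupervised_gradients_match_finite_differences(rng):
    """Eq.-style negative-sampling loss vs central differences, 20 draws."""
    for draw in range(20):
        n_vocab = int(rng.integers(4, 11))
        h = int(rng.integers(2, 4))
        m = init_model(n_vocab, h, n_vocab, seed=draw)
        m.V = rng.normal(size=(n_vocab, h))
        m.U = rng.normal(size=(n_vocab, h))
        target = int(rng.integers(n_vocab))
        ctx_ids = rng.choice(n_vocab, size=int(rng.integers(1, 4)), replace=False)
        w = rng.random(len(ctx_ids))
        pair = ContextPair(target, FeatureBag(ctx_ids.astype(np.int64), w / w.sum()),
                           "whole-sentence")
        negatives = [int(x) for x in rng.integers(0, n_vocab, size=2)]
        dU, dV = unsupervised_grads(m, pair, negatives)
        eps = 1e-6
        for wid, row in dU.items():
            for d in range(h):
                m.U[wid, d] += eps
                lp = unsupervised_loss(m, pair, negatives)
                m.U[wid, d] -= 2 * eps
                lm = unsupervised_loss(m, pair, negatives)
                m.U[wid, d] += eps
                assert (lp - lm) / (2 * eps) == pytest.approx(row[d], rel=1e-5, abs=1e-8)
        for f, row in dV.items():
            for d in range(h):
                m.V[f, d] += eps
                lp = unsupervised_loss(m, pair, negatives)
                m.V[f, d] -= 2 * eps
                lm = unsupervised_loss(m, pair, negatives)
                m.V[f, d] += eps
                assert (lp - lm) / (2 * eps) == pytest.approx(row[d], rel=1e-5, abs=1e-8)


def _topic_block_corpus(seed=0, n_abstracts=1200, pool=40, sent_len=10):
    """Words co-occur only within one of two disjoint topic blocks."""
    rng = np.random.default_rng(seed)
    abstracts = []
    for a in range(n_abstracts):
        block = a % 2
        sents = [
            Sentence(tuple(f"t{block}_{rng.integers(pool)}" for _ in range(sent_len)),
                     None, i)
            for i in range(3)
        ]
        abstracts.append(Abstract(str(a), sents))
    return Corpus(abstracts, ()), pool


@pytest.mark.parametrize("mode", ["whole-sentence", "fixed-window"])
def test_pretraining_learns_topic_block_structure(mode):
    corpus, pool = _topic_block_corpus()
    config = PretrainConfig(dim=10, epochs=5, n_max=1, min_count=1, mode=mode, seed=4)
    V, vocab, losses = pretrain_vectors(corpus, config)
    # running first-epoch loss starts at (1+neg)·ln2 (zero outputs) and falls
    assert losses[0] < (1 + config.negatives) * math.log(2)
    assert losses[-1] < losses[0]
    ids0 = np.array([vocab.id_of(f"t0_{k}") for k in range(pool)])
    ids1 = np.array([vocab.id_of(f"t1_{k}") for k in range(pool)])
    X0 = V[ids0] / np.linalg.norm(V[ids0], axis=1, keepdims=True)
    X1 = V[ids1] / np.linalg.norm(V[ids1], axis=1, keepdims=True)
    within = np.concatenate([
        (X0 @ X0.T)[np.triu_indices(pool, 1)], (X1 @ X1.T)[np.triu_indices(pool, 1)]
    ]).mean()
    across = (X0 @ X1.T).mean()
    assert within > across + 0.2


def test_pretraining_deterministic_and_label_blind():
    corpus, _ = _topic_block_corpus(n_abstracts=100)
    labeled = Corpus(
        [Abstract(a.id, [Sentence(s.tokens, "METHODS", s.index) for s in a.sentences])
         for a in corpus.abstracts],
        ("METHODS",),
    )
    config = PretrainConfig(dim=6, epochs=2, n_max=1, min_count=1, seed=7)
    V1, _, l1 = pretrain_vectors(corpus, config)
    V2, _, l2 = pretrain_vectors(labeled, config)  # labels ignored entirely
    assert np.array_equal(V1, V2) and l1 == l2
    V3, _, _ = pretrain_vectors(corpus, config)
    assert np.array_equal(V1, V3)


def test_sent2vec_embed_linearity_and_exactness(rng):
    vocab = _vocab({"a": 1, "b": 1, "c": 1})
    V = rng.normal(size=(3, 5))
    np.testing.assert_allclose(sent2vec_embed(V, vocab, ["a"]), V[vocab.index["a"]])
    mid = sent2vec_embed(V, vocab, ["a", "b"])
    np.testing.assert_allclose(mid, (V[vocab.index["a"]] + V[vocab.index["b"]]) / 2,
                               atol=1e-12)
    # brute force over R(S) with n-grams
    V2 = rng.normal(size=(3 + 50, 5))
    tokens = ["a", "b", "c", "a"]
    emb = sent2vec_embed(V2, vocab, tokens, n_max=2, buckets=50)
    bag = encode_bag(tokens, vocab, n_max=2, buckets=50)
    brute = sum(w * V2[f] for f, w in zip(bag.ids, bag.weights))
    np.testing.assert_allclose(emb, brute, atol=1e-12)
    assert np.all(sent2vec_embed(V, vocab, ["zzz"]) == 0.0)


def test_transfer_init_copy_semantics(rng):
    pre_vocab = _vocab({"a": 9, "b": 9, "c": 9})
    pre_V = rng.normal(size=(3, 4))
    sup_vocab = _vocab({"b": 1, "zzz": 1})
    V = transfer_init(pre_V, pre_vocab, sup_vocab, dim=4, n_max=1, seed=0)
    np.testing.assert_array_equal(V[sup_vocab.index["b"]], pre_V[pre_vocab.index["b"]])
    # unseen token freshly initialized within the init range
    assert np.abs(V[sup_vocab.index["zzz"]]).max() <= 0.25


def test_transfer_init_disjoint_vocab_is_noop_vs_fresh(rng):
    pre_vocab = _vocab({"a": 9})
    pre_V = rng.normal(size=(1, 4))
    sup_vocab = _vocab({"x": 1, "y": 1})
    V = transfer_init(pre_V, pre_vocab, sup_vocab, dim=4, n_max=1, seed=3)
    fresh = np.random.default_rng(3).uniform(-0.25, 0.25, size=(2, 4))
    np.testing.assert_array_equal(V, fresh)


def test_transfer_init_dimension_mismatch_errors(rng):
    pre_vocab = _vocab({"a": 9})
    with pytest.raises(ValueError):
        transfer_init(rng.normal(size=(1, 4)), pre_vocab, pre_vocab, dim=8)


def test_transfer_copies_shared_bucket_region(rng):
    pre_vocab = _vocab({"a": 9, "b": 9})
    buckets = 30
    pre_V = rng.normal(size=(2 + buckets, 3))
    sup_vocab = _vocab({"b": 1})
    V = transfer_init(pre_V, pre_vocab, sup_vocab, dim=3, n_max=2, buckets=buckets, seed=0)
    np.testing.assert_array_equal(V[1:], pre_V[2:])


def test_vectors_text_format_roundtrip(tmp_path, rng):
    vocab = _vocab({"alpha": 3, "beta": 2})
    V = rng.normal(size=(2, 4))
    path = tmp_path / "v.vec"
    save_vectors(path, vocab, V)
    header = path.read_text().splitlines()[0]
    assert header == "2 4"
    V2, vocab2 = load_vectors(path)
    assert vocab2.index == vocab.index
    np.testing.assert_array_equal(V2, V)
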