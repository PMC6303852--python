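"""Additive sentence embeddings from pre-trained vectors.

A sentence embedding is the mean of its token (and n-gram) embeddings.
Raw embedding clouds are anisotropic (every vector shares a large common
direction), so similarities are read after centering; sentences of the same
rhetorical role then sit measurably closer than sentences of different roles.
"""

import numpy as np

from sectionseer import PretrainConfig, generate_corpus
from sectionseer.synthetic_corpus import SyntheticSpec
from sectionseer.unsupervised_pretrain import embed_sentences, pretrain_vectors

corpus = generate_corpus(SyntheticSpec(n_abstracts=2000), seed=5)
V, vocab, _ = pretrain_vectors(
    corpus.without_labels(), PretrainConfig(dim=20, epochs=100, seed=0)
)

sents = list(corpus.iter_sentences())[:4000]
X = embed_sentences(V, vocab, [s.tokens for s in sents])
X = X - X.mean(axis=0)  # remove the common direction
X = X / np.maximum(np.linalg.norm(X, axis=1, keepdims=True), 1e-12)
labels = np.array([s.label for s in sents])

print("mean cosine similarity between centered sentence embeddings:")
for lab in corpus.label_set:
    A = X[labels == lab][:150]
    within = (A @ A.T)[np.triu_indices(len(A), 1)].mean()
    across = (A @ X[labels != lab][:150].T).mean()
    print(f"  {lab:12s} within={within:+.3f}  vs other labels={across:+.3f}")
print("\nwithin-label similarity exceeds across-label similarity for every")
print("role; background/objective cluster weakly because they draw half of")
print("their discriminative tokens from a shared confusable pool.")
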