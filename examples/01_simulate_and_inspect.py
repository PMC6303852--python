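"""Generate a synthetic structured-abstract corpus and inspect its shape.

The generator emulates the statistical structure of sentence-labeled RCT
abstracts: canonical section order, label-specific token pools mixed with a
large shared pool, a confusable pool shared by background and objective,
and methods/results-dominated class supports.
"""

from collections import Counter

from sectionseer import default_spec, generate_corpus, write_rct_corpus

spec = default_spec("small")
corpus = generate_corpus(spec, seed=7)

print(f"abstracts: {len(corpus.abstracts)}, sentences: {corpus.n_sentences}")
print(f"expected sentences from the spec: {spec.expected_sentences:.0f}")

supports = Counter(s.label for s in corpus.iter_sentences())
for label in corpus.label_set:
    share = supports[label] / corpus.n_sentences
    print(f"  {label:12s} {supports[label]:5d} ({share:5.1%})")

first = corpus.abstracts[0]
print(f"\nfirst abstract ({first.id}):")
for s in first.sentences:
    print(f"  [{s.label:11s}] {' '.join(s.tokens[:7])} ...")

write_rct_corpus(corpus, "synthetic_corpus.txt")
print("\nwrote synthetic_corpus.txt (the benchmark text dialect: ###id headers,")
print("LABEL<TAB>sentence lines, blank line between abstracts)")
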