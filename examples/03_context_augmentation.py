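"""Inject sentence position and neighboring-sentence tokens into the bag.

A bag model cannot see where a sentence sits in its abstract. The
augmentation adds a numeric position token (pos_3) and the tokens of the
two sentences on each side, each tagged with an offset prefix (-1_, +2_,
...), so the standard bag model can exploit sentence order.
"""

from sectionseer import (
    FULL,
    TrainConfig,
    ablation_experiment,
    ablation_medians,
    augment_sentence,
    generate_corpus,
)
from sectionseer.synthetic_corpus import SyntheticSpec

corpus = generate_corpus(SyntheticSpec(n_abstracts=2000), seed=9)

ab = corpus.abstracts[0]
aug = augment_sentence(ab, index=2, config=FULL)
print("augmented third sentence (label", aug.label, "):")
print(" ", " ".join(aug.tokens[:14]), "...")
print("  context tokens carry their offset prefix; pos_3 encodes position.\n")

table = ablation_experiment(corpus, seed=1, n_seeds=3,
                            config=TrainConfig(dim=20, n_max=1, epochs=8))
print("ablation (median test weighted F1 over 3 training seeds):")
for variant, f1 in sorted(ablation_medians(table).items(), key=lambda kv: -kv[1]):
    print(f"  {variant:16s} {f1:.3f}")
print("\nthe position token lifts F1 well above the single-sentence model.")
print("the window-2 context variants multiply the vocabulary roughly five-")
print("fold, so at this corpus size they are data-starved; the experiment-")
print("scale study (scripts/acceptance.py, 5000 abstracts) and docs/methods.md")
print("discuss how the variants compare when each has enough data.")
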