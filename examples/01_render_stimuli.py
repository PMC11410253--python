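"""Render word stimuli and the probe sets used throughout the package.

Generates a handful of word images with varying font/size/offset/case,
plus the single-letter grid and a bigram set, and prints what was made.
"""

from ortholens.lexicon import ALPHABET
from ortholens.stimgen import (DEFAULT_CANVAS, make_bigram_set,
                               make_single_letter_grid, make_training_set,
                               render_word)

stim = render_word("pain", "dejavu-sans", size_pt=50, offset=(12, -8),
                   case="upper")
print(f"rendered {stim.text!r} -> image {stim.image.shape}, "
      f"ink fraction {(stim.image < 0.5).mean():.4f}")

train, test = make_training_set(["pain", "vent", "maison"],
                                n_train_per_word=5, n_test_per_word=2,
                                seed=0)
print(f"\ntraining manifest ({len(train)} variants):")
print(train.manifest[["text", "font", "size", "dx", "dy", "case"]]
      .head(6).to_string(index=False))
# each row is one sampled variant; size/dx/dy are uniform draws from the
# configured ranges (sizes shrink automatically when a word would not fit)

letters = make_single_letter_grid(ALPHABET)
print(f"\nsingle-letter grid: {len(letters)} stimuli "
      f"({len(ALPHABET)} letters x {DEFAULT_CANVAS.n_slots} slots)")

bigrams = make_bigram_set(ALPHABET, 49, seed=0)
print(f"bigram set: {len(bigrams)} stimuli -> "
      f"{49 * 48 // 2} unordered pairs for dissimilarity analysis")
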