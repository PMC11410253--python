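"""Letter-by-position encoding models and the three position schemes.

Builds the design-matrix rows for "WORD" under the left-aligned,
word-centered and edge-aligned schemes, then fits all three schemes to
synthetic units with edge-anchored tuning: the generative (edge-aligned)
scheme should win the cross-validated comparison.
"""

import numpy as np

from ortholens.encoding import build_design_matrix, compare_schemes
from ortholens.lexicon import ALPHABET, random_words

print("slot assignment for 'WORD' (slots printed 1-based):")
for scheme in ("left_aligned", "word_centered", "edge_aligned"):
    dm = build_design_matrix(["WORD"], scheme)
    cols = np.nonzero(dm.X[0])[0]
    feats = [(ALPHABET[c % 26], c // 26 + 1) for c in cols]
    feats.sort(key=lambda t: "word".index(t[0]))
    print(f"  {scheme:>13}: " + "  ".join(f"{l.upper()}@{s}"
                                          for l, s in feats))

rng = np.random.default_rng(0)
words = random_words(250, rng)
dm = build_design_matrix(words, "edge_aligned")
Y = np.empty((len(words), 6))
for u in range(6):
    j1 = dm.feature_index(ALPHABET[rng.integers(26)], int(rng.integers(2)))
    j2 = dm.feature_index(ALPHABET[rng.integers(26)],
                          int(rng.integers(6, 8)))
    Y[:, u] = 2 * dm.X[:, j1] + 1.5 * dm.X[:, j2] + \
        rng.normal(0, 0.02, len(words))

table = compare_schemes(Y, words, seed=0)
print("\ncross-validated fit (Pearson r on held-out words) per scheme:")
print(table[["cv_r_left_aligned", "cv_r_word_centered",
             "cv_r_edge_aligned", "winner"]].round(3).to_string(index=False))
print("\nunits were generated with edge-anchored tuning, so edge_aligned "
      "should win every row")
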