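"""The factorial and spaced probe designs.

The factorial design crosses absolute word position (rows) with the
ordinal position of a single preferred letter (columns): a unit with a
fixed retinotopic receptive field lights up along a diagonal of this
matrix, while a genuine ordinal-position unit lights up a column.  The
spaced design inserts blanks between letters to separate genuine ordinal
coding from "space bigram" coding (a letter next to a blank).
"""

from ortholens.stimgen import make_factorial_probe, make_spaced_probe

design = make_factorial_probe("o", "x")
print(f"factorial design: {design.n_rows} word positions x "
      f"{design.n_cols} ordinal positions = {len(design.stimuli)} stimuli")
for r in range(design.n_rows):
    print("  " + "  ".join(design.stimulus(r, c).text
                           for c in range(design.n_cols)))

spaced = make_spaced_probe("o", "x")
print(f"\nspaced design: {spaced.n_rows} x {spaced.n_cols} = "
      f"{len(spaced.stimuli)} stimuli (every letter is blank-adjacent)")
for r in range(spaced.n_rows):
    print("  " + "  ".join(spaced.stimulus(r, c).text
                           for c in range(spaced.n_cols)))
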