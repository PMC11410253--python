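# Methods

`ortholens` dissects how convolutional networks trained to read develop
an invariant letter-by-ordinal-position code. This note documents the
models, the analysis procedures, the synthetic-data generators, the
numerical choices, and what the desk-scale experiments do and do not
show.

## Stimuli

Words are rendered dark-on-light on a square canvas (default 224 px)
with TrueType fonts. Training variants sample font, point size
(30–70 pt), horizontal offset (±50 px), vertical offset (±30 px) and
case (upper/lower/capitalised) uniformly; test variants use a disjoint
font list so recognition must generalise across typefaces. Mirror
flips are never applied (mirrored words are not valid reading stimuli).
When a sampled (word, size, offset) combination would push ink off the
canvas, the sampler deterministically shrinks the size by 10% steps
until the ink bounding box fits and records the final size in the
manifest; the low-level renderer instead refuses out-of-canvas ink, so
the manifest is always replayable.

Fonts come from matplotlib's bundled DejaVu/STIX families (freely
redistributable); a substitution table maps the commercial fonts
common in reading studies (Arial, Times New Roman, Comic Sans, Courier,
Calibri) to metric-similar open faces.

Probe stimuli live on a frame of 8 equal-width slots centred on the
canvas; `'-'` marks a blank slot and deposits no ink. The factorial
probe embeds one preferred letter in a string of unpreferred letters:
5 word positions × 4 ordinal positions = 20 stimuli ("oxxx----" …
"----xxxo"). The spaced probe separates 3 letters by single blanks
(4 × 3 = 12 stimuli, "x-o-x" family). The single-letter grid presents
every letter at every slot (26 × 8 = 208 stimuli). Bigram sets render
two-glyph strings at the canvas centre; dissimilarity analyses use all
C(n, 2) unordered pairs (49 bigrams → 1176 pairs).

The inter-letter slot geometry (8 fixed-width slots, a word occupying
contiguous slots) is our construction: it makes retinotopic position
well defined for the probe designs. Real typesetting uses proportional
advances, so probe stimuli are slightly more regular than the training
words.

The category localizer contrasts words against four procedurally drawn
object categories (faces, houses, bodies, tools — parametric line
drawings with seeded jitter plus random interior strokes). The interior
texture matters: photographic object categories carry fine-scale
structure, and without it any high-spatial-frequency unit would
trivially prefer rendered text, inflating apparent word selectivity in
untrained networks. The drawings are stand-ins, not naturalistic
images; they provide a non-word contrast and a phase-1 object task,
nothing more.

## Network and training

The model is a four-block feedforward network in the CORnet-Z family:
each block is convolution → rectification → 3×3 stride-2 max-pool, with
block names V1, V2, V4, IT; V1 uses a 7×7 stride-2 kernel, later blocks
3×3 stride-1. A global average pool over IT ("avgIT") feeds a fully
connected readout. With default widths (64, 128, 256, 512) and 224-px
input the block outputs are V1 64×56×56, V2 128×28×28, V4 256×14×14,
IT 512×7×7.

The network and its training loop are implemented directly on numpy:
im2col convolution, max-pooling with cached argmax, explicit backward
passes, SGD with momentum 0.9 on softmax cross-entropy. Gradients are
verified against central finite differences in the test suite. The
learning-rate schedule is step decay: ×0.1 every 10 epochs from 0.01
(the standard "StepLR with default gamma" schedule; a literal linear
decrease would contradict the stated gamma).

Literacy is modelled in two phases. Phase 1 trains on objects only
(the **illiterate** network). The readout is then extended with word
categories — new rows drawn from a zero-mean, σ=10⁻³ normal so
pre-extension logits are preserved exactly — and the whole network is
retrained jointly on objects plus words (the **literate** network). The
illiterate control continues object-only training for the same number
of epochs, so both networks see equal optimisation time. Augmentation
is a random crop retaining ≥90% of the image followed by resize; no
flips. Inputs are normalised as (x − 0.5)/0.25.

## Probing suite

**Word-selective units.** A unit is word selective when its mean
response to word images exceeds the mean response to *every* non-word
category by k standard deviations (default k = 3), with the standard
deviation taken per category across that category's stimuli — the
strict per-category reading of the localizer contrast. Responses are
raw post-rectification activations. The criterion is invariant to
adding a constant to a unit's responses and equivariant under positive
scaling.

**Letter tuning.** Each selective unit's 26×8 single-letter response
table is collapsed by a max over slots; the argmax/argmin letters are
its most/least preferred letters and parameterise its probe designs.

**Encoding models.** Unit responses Y over a word set are fit as
Y = Xb with X a binary words × (26·8) matrix under one of three
position schemes — left-aligned, word-centered, edge-aligned (initial
letters anchored to the word start, final letters to its end; for odd
lengths the first ⌈L/2⌉ letters anchor left). Features are slot-major
(feature = 26·slot + letter rank, alphabet a–z after case folding).
b is estimated with LassoCV (penalty chosen by internal 5-fold CV, 30
alphas); model fit cv_r is the mean across 5 outer shuffled folds of
the Pearson correlation between held-out predictions and responses.
Pooling held-out predictions across folds before correlating was
rejected: the pooled statistic carries a negative finite-sample bias
(≈ −0.13 at n = 200) from anti-correlated fold means, visibly shifting
the permutation null away from zero; the per-fold average is unbiased
under permutation. Folds whose held-out responses are constant are
skipped (they carry no correlation signal). Since all three schemes
have identical parameter counts, cv_r is directly comparable across
them; the winner is the argmax, with ties flagged when the top two are
within 0.02.

**Position tuning.** Per unit, coefficients are reshaped to 26×8 and
averaged over letters; units are grouped by the argmax slot of the
resulting length-8 profile, each profile is normalised by its own
maximum, and profiles are averaged within group. Units with all-zero
coefficients are dropped with a warning.

**Response profiles.** The factorial response matrix is binarized at
min + 0.3·(max − min); units with a maximum response below an exclusion
threshold (default 5, in the default network's activation units;
configurable because narrower networks have smaller activations) are
excluded, as are constant matrices. Categories follow run-counting on
the binary support:

* some column entirely ones → **ordinal** position coding;
* a run ≥ 3 along exactly one of the two diagonal directions →
  **retinotopic** coding (requiring a unique direction rejects dense
  alternating patterns, e.g. checkerboards, that carry solid runs along
  both diagonals);
* a row run ≥ 3 → **word position** coding;
* otherwise **mixed**; priority column > diagonal > row.

The exact run thresholds and tie-breaks are underdetermined in the
literature; this rule is declared, vectorised for whole populations,
and pinned against an independent loop-based enumerator over all 2²⁰
binary 5×4 matrices in the test suite. Because the threshold is
relative, categorization is invariant under positive affine rescaling
of the raw matrix (above exclusion).

**Spaced reclassification.** Candidates are units that look
ordinal-like on the unspaced design — full ordinal columns, or the
partial columns typical of narrow-RF edge units (which the rule above
labels mixed); units that were clearly retinotopic or word-position
return "other". On the spaced design (every letter blank-adjacent) a
genuine ordinal unit keeps a single-column support (≥2 rows), whereas a
space-bigram unit follows its preferred letter's retinotopic slot: its
support spans ≥2 columns while the letter slot (row + 2·col) stays
within a ≤2-slot window. Everything else is "other".

**Connectivity attribution.** For a target unit, each input channel is
scored by (summed 3×3 kernel weights) × (drive), where drive is the
maximum response, over the unit's 20 probe stimuli, of any
word-selective input unit of that channel inside the target's effective
receptive field. Weight *summation* (not a norm) is deliberate:
rectified inputs are nonnegative, so negative weights can only
suppress. Channels with no selective unit in the RF get drive 0 and a
flag. Positive products are reported as excitatory, negative as
inhibitory (top 2 each by default). The same code path serves any
adjacent layer pair. Effective receptive fields come from exact
interval backprojection through the intervening pool/conv geometry
(clipped at borders); a central IT unit maps to a 5×5 box on V4.

**V1 spectra.** Each first-layer kernel's 2-D Fourier amplitude
(summed over input channels) gives a peak radial frequency; filters are
classed low/high by a median split across filters — a parameter-free
convention, since no principled frequency cutoff exists for learned
kernels.

**Dissimilarity.** d = 1 − Pearson r between vectorized activation
patterns of two stimuli at a layer (all units of the layer).
Zero-variance stimuli are dropped with a warning. Network comparisons
use a paired two-sided t-test over matched pair values, with a seeded
sign-flip permutation test (1000 shuffles) reported alongside, since
the original analyses state p-values without naming a test.

## Synthetic units

The synthetic-unit generator plants tuning of known kind — retinotopic
(gaussian slot tuning), ordinal from word start or end, space-bigram
left/right (preferred letter blank-adjacent inside a retinotopic
window), letter-invariant, word-position, or mixtures — as pure
functions of the symbolic slot layout, never of pixels. This
decouples validation of every analysis stage from training
stochasticity. Defaults: gain 10 (safely above the exclusion threshold
of 5), additive gaussian noise truncated at zero to mimic rectified
activations. Population sampling draws per-unit positions only from
ranges the probe designs can disambiguate (central slots 2–5 for
retinotopic units; RF slots where both designs place a word edge for
space-bigram units) — planted tuning at the extreme slots is a blind
spot of the 5×4 design itself, not of the classifier.

What passing synthetic-recovery tests shows: the analysis chain
(binarize → categorize → spaced reclassify, and the encoding-model
comparison) returns the generating label under its own model
assumptions, exactly at zero noise and ≥95% at noise of 10% of gain.
What it does not show: that trained-network units are as cleanly tuned
as the planted ones, or that the generator's tuning families exhaust
real unit behaviour.

## Desk-scale literacy experiment

The full-scale regime (≈1.3M object images, 1000 words, 224-px canvas,
tens of GPU-epochs) is far beyond a desktop CPU; the package instead
fixes a scaled profile chosen once: 64-px canvas with proportionally
scaled offset/size ranges, widths (24, 48, 96, 192), 20 French words ×
200 training / 10 test variants, 4 procedural object categories × 200
images, 4 phase-1 and 12 phase-2 epochs, batch 32. Probing uses the
full 400-word/100-per-category localizer (forward passes are cheap and
the larger sample stabilises the per-category standard deviations of
the 3-SD contrast), the 49-bigram set, and response profiles for up to
40 selective units per layer; the profile exclusion threshold is 0.1 in
this narrower network's activation units. One literate/illiterate pair
trains and probes in roughly three and a half minutes of CPU time; the
experiment suite runs three seeds.

At this scale the experiment reproduces the *qualitative* signatures of
literacy — more word-selective avgIT units than the illiterate control,
higher mean bigram dissimilarity from V4 onward, and a nonzero fraction
of ordinal-position units in IT/avgIT — and these are what the tests
assert. The full-scale percentages (e.g. 13.6% selective units in
avgIT, 83.1% ordinal) are observations of the full-scale regime and are
not expected, nor asserted, at desk scale. Word test accuracy on
held-out fonts reached 0.71–0.84 across pilot seeds at this scale
(generalising from two training fonts to three unseen typefaces at
64 px is the binding constraint; the full-scale regime reports ≈88%);
the regression threshold is set at 0.65 to leave seed-to-seed margin.
Because the per-seed counts of avgIT word-selective units are small,
the literate-vs-illiterate selectivity contrast is assessed over the
three seeds jointly (majority of seeds plus the seed total) rather
than demanded strictly of every seed.

## Known limitations

* The object categories are parametric drawings; illiterate networks
  retain some incidental text responsiveness that photographic
  training data would further suppress.
* Slot-frame probes assume fixed-width letter positions; proportional
  fonts misalign slightly with slot centres.
* The categorizer's run thresholds are declared conventions; other
  reasonable conventions shift category boundaries for marginal units.
* Activation-maximisation visualisation of preferred stimuli is out of
  scope; connectivity reports identify channels and tuning tables
  instead.
* Non-Latin scripts render only if the registered fonts cover the
  glyphs; shaping and diacritic placement are not implemented.
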