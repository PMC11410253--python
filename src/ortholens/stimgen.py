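"""Synthetic word-image stimuli.

All stimuli used by the training and probing pipelines are generated here:

* word images with variable font / size / case / spatial offset, for
  training and testing word recognition;
* factorial probe designs that cross absolute word position with the
  ordinal position of a single preferred letter (used to dissociate
  retinotopic from ordinal position codes);
* spaced probe designs where letters are separated by blank slots (used
  to dissociate blank-space coding from genuine ordinal coding);
* single-letter grids (one letter at one of the 8 string slots);
* bigram sets for representational-dissimilarity analyses;
* a category localizer set (words vs procedurally drawn faces, houses,
  bodies and tools) for identifying word-selective units.

Glyphs are drawn dark on a light background.  Strings live in a frame of
``n_slots`` equal-width slots centred on the canvas; the character ``'-'``
denotes a blank slot and is rendered as truly empty (no ink).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw

from . import objects
from .fonts import TEST_FONTS, TRAIN_FONTS, has_glyph, load_font

BLANK = "-"
CASES = ("upper", "lower", "mixed")


class MissingGlyphError(ValueError):
    """Raised when a font cannot render a requested glyph."""


class InkOverflowError(ValueError):
    """Raised when rendered ink would fall outside the canvas."""


# --------------------------------------------------------------------------
# canvas configuration


@dataclass(frozen=True)
class CanvasConfig:
    """Geometry and sampling ranges for stimulus rendering.

    Defaults follow the full-scale regime: 224 px canvas, horizontal
    offsets in [-50, 50] px, vertical offsets in [-30, 30] px and font
    sizes in [30, 70] pt.  ``scaled`` builds a proportionally shrunk
    profile for CPU-friendly experiments.
    """

    size: int = 224
    n_slots: int = 8
    offset_x: float = 50.0
    offset_y: float = 30.0
    size_min: float = 30.0
    size_max: float = 70.0

    @property
    def slot_width(self) -> float:
        return self.size / self.n_slots

    @property
    def probe_size_pt(self) -> float:
        # glyph size that comfortably fits one slot
        return 0.85 * self.slot_width

    def scaled(self, size: int) -> "CanvasConfig":
        f = size / self.size
        return replace(
            self, size=size,
            offset_x=self.offset_x * f, offset_y=self.offset_y * f,
            size_min=self.size_min * f, size_max=self.size_max * f,
        )


DEFAULT_CANVAS = CanvasConfig()


# --------------------------------------------------------------------------
# stimulus container


@dataclass
class RenderedStimulus:
    """One image plus the generative metadata that produced it."""

    image: np.ndarray  # (H, W, 3) float32 in [0, 1]
    text: str
    font_id: str
    size_pt: float
    offset: tuple[float, float]
    case: str
    slots: tuple[str, ...] | None = None  # glyph-per-slot layout, if slotted
    label: str | None = None

    def __post_init__(self) -> None:
        h, w, c = self.image.shape
        if h != w or c != 3:
            raise ValueError(f"expected square 3-channel image, got {self.image.shape}")


@dataclass
class ProbeDesign:
    """Factorial stimulus matrix for one preferred/unpreferred letter pair.

    Rows vary absolute word position on the canvas; columns vary the
    ordinal position of the single preferred letter within the string.
    Stimuli are stored row-major.
    """

    preferred_letter: str
    unpreferred_letter: str
    n_rows: int
    n_cols: int
    frame_slots: int
    spaced: bool
    stimuli: list[RenderedStimulus] = field(repr=False)

    def stimulus(self, row: int, col: int) -> RenderedStimulus:
        """0-based row/column lookup."""
        return self.stimuli[row * self.n_cols + col]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                s = self.stimulus(r, c)
                rows.append({"row": r + 1, "col": c + 1, "text": s.text})
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# low-level rendering


def _blank_canvas(size: int) -> Image.Image:
    return Image.new("L", (size, size), color=255)


def _to_array(img: Image.Image) -> np.ndarray:
    a = np.asarray(img, dtype=np.float32) / 255.0
    return np.repeat(a[:, :, None], 3, axis=2)


def _check_glyphs(text: str, font_id: str, size_px: float) -> None:
    for g in text:
        if g == BLANK or g.isspace():
            continue
        if not has_glyph(font_id, g):
            raise MissingGlyphError(
                f"font {font_id!r} has no glyph for {g!r}"
            )


def _apply_case(text: str, case: str) -> str:
    if case == "upper":
        return text.upper()
    if case == "lower":
        return text.lower()
    if case == "mixed":
        return text.capitalize()
    raise ValueError(f"unknown case {case!r}; expected one of {CASES}")


_MEASURE_DRAW = ImageDraw.Draw(Image.new("L", (4, 4)))


def _anchored_bbox(text: str, font_id: str, size_pt: float,
                   cx: float, cy: float) -> tuple[float, float, float, float]:
    """Ink bbox of ``text`` centred ("mm" anchor) at (cx, cy)."""
    font = load_font(font_id, int(round(size_pt)))
    return _MEASURE_DRAW.textbbox((cx, cy), text, font=font, anchor="mm")


def measure_word(text: str, font_id: str, size_pt: float) -> tuple[float, float]:
    """Ink bounding-box (width, height) of ``text`` at the given size."""
    l, t, r, b = _anchored_bbox(text, font_id, size_pt, 0.0, 0.0)
    return r - l, b - t


def render_word(text: str, font_id: str, size_pt: float,
                offset: tuple[float, float] = (0.0, 0.0),
                case: str = "lower",
                canvas: CanvasConfig = DEFAULT_CANVAS) -> RenderedStimulus:
    """Render a word centred on the canvas plus an (dx, dy) offset.

    Deterministic for fixed arguments and font files.  Raises
    :class:`MissingGlyphError` if the font lacks a glyph and
    :class:`InkOverflowError` if ink would leave the canvas.
    """
    if not text.strip(BLANK + " "):
        raise ValueError("text is empty after stripping blanks")
    dx, dy = offset
    if abs(dx) > canvas.offset_x or abs(dy) > canvas.offset_y:
        raise ValueError(
            f"offset {offset} outside configured range "
            f"(±{canvas.offset_x}, ±{canvas.offset_y})"
        )
    # sizes below size_min are legal (the dataset sampler shrinks long
    # words to fit); sizes above the configured maximum are not
    if not 0 < size_pt <= canvas.size_max:
        raise ValueError(
            f"size {size_pt} outside (0, {canvas.size_max}]"
        )
    shown = _apply_case(text, case)
    _check_glyphs(shown, font_id, size_pt)
    img = _blank_canvas(canvas.size)
    draw = ImageDraw.Draw(img)
    font = load_font(font_id, int(round(size_pt)))
    cx, cy = canvas.size / 2 + dx, canvas.size / 2 + dy
    l, t, r, b = _anchored_bbox(shown, font_id, size_pt, cx, cy)
    if l < 0 or t < 0 or r > canvas.size or b > canvas.size:
        raise InkOverflowError(
            f"{shown!r} at size {size_pt} offset {offset} exceeds "
            f"{canvas.size}px canvas (bbox {(l, t, r, b)})"
        )
    draw.text((cx, cy), shown, font=font, anchor="mm", fill=0)
    return RenderedStimulus(
        image=_to_array(img), text=shown, font_id=font_id,
        size_pt=float(size_pt), offset=(float(dx), float(dy)), case=case,
    )


def render_slots(slots: tuple[str, ...] | str,
                 font_id: str | None = None,
                 size_pt: float | None = None,
                 canvas: CanvasConfig = DEFAULT_CANVAS,
                 case: str = "lower") -> RenderedStimulus:
    """Render a slotted string: each glyph centred within its slot.

    ``slots`` is one glyph per slot ('-' = blank).  An all-blank frame is
    legal and yields a zero-ink canvas.  This is the renderer used for
    probe, single-letter and bigram stimuli, where retinotopic position
    must be well defined.
    """
    slots = tuple(slots)
    if len(slots) != canvas.n_slots:
        raise ValueError(f"expected {canvas.n_slots} slots, got {len(slots)}")
    font_id = font_id or TRAIN_FONTS[0]
    size_pt = size_pt if size_pt is not None else canvas.probe_size_pt
    shown = tuple(_apply_case(g, case) if g != BLANK else g for g in slots)
    _check_glyphs("".join(g for g in shown if g != BLANK), font_id, size_pt)
    img = _blank_canvas(canvas.size)
    draw = ImageDraw.Draw(img)
    font = load_font(font_id, int(round(size_pt)))
    w = canvas.slot_width
    cy = canvas.size / 2
    for i, g in enumerate(shown):
        if g == BLANK:
            continue
        cx = (i + 0.5) * w
        l, t, r, b = draw.textbbox((cx, cy), g, font=font, anchor="mm")
        if l < 0 or t < 0 or r > canvas.size or b > canvas.size:
            raise InkOverflowError(f"glyph {g!r} in slot {i} exceeds canvas")
        draw.text((cx, cy), g, font=font, anchor="mm", fill=0)
    return RenderedStimulus(
        image=_to_array(img), text="".join(shown), font_id=font_id,
        size_pt=float(size_pt), offset=(0.0, 0.0), case=case, slots=shown,
    )


# --------------------------------------------------------------------------
# probe designs


def _slot_layout(frame_slots: int, positions: dict[int, str]) -> tuple[str, ...]:
    slots = [BLANK] * frame_slots
    for pos, glyph in positions.items():
        slots[pos] = glyph
    return tuple(slots)


def factorial_layouts(preferred: str, unpreferred: str,
                      frame_slots: int = 8,
                      word_len: int = 4) -> list[tuple[str, ...]]:
    """Symbolic slot layouts of the factorial design, row-major.

    Shared by the image renderer and the synthetic-unit generator, so
    analyses can be validated on symbolic strings without rendering.
    """
    n_rows = frame_slots - word_len + 1
    if n_rows < 1:
        raise InkOverflowError(
            f"frame of {frame_slots} slots too small for {word_len}-letter word"
        )
    layouts = []
    for r in range(n_rows):
        for c in range(word_len):
            positions = {r + k: (preferred if k == c else unpreferred)
                         for k in range(word_len)}
            layouts.append(_slot_layout(frame_slots, positions))
    return layouts


def spaced_layouts(preferred: str, unpreferred: str,
                   frame_slots: int = 8,
                   n_letters: int = 3) -> list[tuple[str, ...]]:
    """Symbolic slot layouts of the spaced design, row-major."""
    span = 2 * n_letters - 1
    n_rows = frame_slots - span + 1
    if n_rows < 1:
        raise InkOverflowError(
            f"frame of {frame_slots} slots too small for spaced span {span}"
        )
    layouts = []
    for r in range(n_rows):
        for c in range(n_letters):
            positions = {r + 2 * k: (preferred if k == c else unpreferred)
                         for k in range(n_letters)}
            layouts.append(_slot_layout(frame_slots, positions))
    return layouts


def word_layout(word: str, n_slots: int = 8,
                placement: str = "centered") -> tuple[str, ...]:
    """Slot layout of a plain word ('centered' or 'left')."""
    L = len(word)
    if L > n_slots:
        raise ValueError(f"word {word!r} longer than {n_slots} slots")
    start = (n_slots - L) // 2 if placement == "centered" else 0
    return _slot_layout(n_slots, {start + i: g for i, g in enumerate(word)})


def make_factorial_probe(preferred: str, unpreferred: str,
                         frame_slots: int = 8,
                         word_len: int = 4,
                         canvas: CanvasConfig = DEFAULT_CANVAS,
                         font_id: str | None = None,
                         size_pt: float | None = None) -> ProbeDesign:
    """5x4 factorial design: word position (rows) x ordinal position (cols).

    Row r (0-based) starts the ``word_len``-letter string at slot r; column
    c places the single preferred letter at ordinal position c within the
    string; all other letters are the unpreferred one, remaining slots
    blank.  With an 8-slot frame and 4-letter strings this yields the
    canonical 20-stimulus set ("oxxx----" family).
    """
    if preferred == unpreferred:
        raise ValueError("preferred and unpreferred letters must differ")
    layouts = factorial_layouts(preferred, unpreferred, frame_slots, word_len)
    stimuli = [render_slots(lay, font_id, size_pt, canvas) for lay in layouts]
    return ProbeDesign(
        preferred_letter=preferred, unpreferred_letter=unpreferred,
        n_rows=frame_slots - word_len + 1, n_cols=word_len,
        frame_slots=frame_slots, spaced=False, stimuli=stimuli,
    )


def make_spaced_probe(preferred: str, unpreferred: str,
                      frame_slots: int = 8,
                      n_letters: int = 3,
                      canvas: CanvasConfig = DEFAULT_CANVAS,
                      font_id: str | None = None,
                      size_pt: float | None = None) -> ProbeDesign:
    """4x3 spaced design: every adjacent letter pair separated by a blank.

    The three letters occupy slots p, p+2, p+4 ("x-o-x" pattern); rows
    shift the whole pattern one slot at a time, columns move the preferred
    letter across the three ordinal positions.
    """
    if preferred == unpreferred:
        raise ValueError("preferred and unpreferred letters must differ")
    layouts = spaced_layouts(preferred, unpreferred, frame_slots, n_letters)
    stimuli = [render_slots(lay, font_id, size_pt, canvas) for lay in layouts]
    return ProbeDesign(
        preferred_letter=preferred, unpreferred_letter=unpreferred,
        n_rows=frame_slots - (2 * n_letters - 1) + 1, n_cols=n_letters,
        frame_slots=frame_slots, spaced=True, stimuli=stimuli,
    )


def make_single_letter_grid(alphabet: str,
                            frame_slots: int = 8,
                            canvas: CanvasConfig = DEFAULT_CANVAS,
                            font_id: str | None = None,
                            size_pt: float | None = None
                            ) -> list[RenderedStimulus]:
    """One stimulus per (letter, slot) pair, letter-major order.

    A 26-letter alphabet with 8 slots yields the 208-stimulus grid used
    to find each unit's most and least preferred letter.
    """
    if not alphabet:
        raise ValueError("alphabet is empty")
    if frame_slots != canvas.n_slots:
        canvas = replace(canvas, n_slots=frame_slots)
    stimuli = []
    for letter in alphabet:
        for slot in range(frame_slots):
            layout = _slot_layout(frame_slots, {slot: letter})
            stimuli.append(render_slots(layout, font_id, size_pt, canvas))
    return stimuli


def make_bigram_set(alphabet_or_glyphs, n_bigrams: int | None = None,
                    seed: int = 0,
                    canvas: CanvasConfig = DEFAULT_CANVAS,
                    font_id: str | None = None,
                    size_pt: float | None = None) -> list[RenderedStimulus]:
    """Two-glyph stimuli rendered at the canvas centre.

    Pass either an explicit list of 2-character strings, or an alphabet
    plus ``n_bigrams`` to sample that many distinct letter pairs
    (seeded).  Downstream dissimilarity analyses use all C(n, 2)
    unordered stimulus pairs.
    """
    items = list(alphabet_or_glyphs)
    if all(len(s) == 2 for s in items) and n_bigrams is None:
        bigrams = items
    else:
        if n_bigrams is None or n_bigrams < 2:
            raise ValueError("need n_bigrams >= 2")
        pairs = ["".join(p) for p in itertools.product(items, repeat=2)]
        if n_bigrams > len(pairs):
            raise ValueError("more bigrams requested than distinct pairs")
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=n_bigrams, replace=False)
        bigrams = [pairs[i] for i in sorted(idx)]
    mid = canvas.n_slots // 2
    stimuli = []
    for bg in bigrams:
        layout = _slot_layout(canvas.n_slots, {mid - 1: bg[0], mid: bg[1]})
        stimuli.append(render_slots(layout, font_id, size_pt, canvas))
    return stimuli


# --------------------------------------------------------------------------
# training / test word datasets


@dataclass
class WordDataset:
    """Manifest-backed word image set; images rendered lazily."""

    manifest: pd.DataFrame
    canvas: CanvasConfig

    def __len__(self) -> int:
        return len(self.manifest)

    def render(self, i: int) -> RenderedStimulus:
        row = self.manifest.iloc[i]
        stim = render_word(
            row["text"], row["font"], row["size"],
            (row["dx"], row["dy"]), row["case"], self.canvas,
        )
        stim.label = row["label"]
        return stim

    def images(self, indices=None) -> np.ndarray:
        """Stacked (N, H, W, 3) float32 image array."""
        idx = range(len(self)) if indices is None else indices
        return np.stack([self.render(i).image for i in idx])

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["label"].to_numpy()


def _fit_size(text: str, font_id: str, size: float, dx: float, dy: float,
              canvas: CanvasConfig) -> float:
    """Largest size <= requested at which the ink box stays on canvas."""
    cx, cy = canvas.size / 2 + dx, canvas.size / 2 + dy
    while size >= 2:
        l, t, r, b = _anchored_bbox(text, font_id, size, cx, cy)
        if l >= 0 and t >= 0 and r <= canvas.size and b <= canvas.size:
            return size
        size *= 0.9
    raise InkOverflowError(f"{text!r} cannot fit on a {canvas.size}px canvas")


def make_training_set(words, n_train_per_word: int = 1300,
                      n_test_per_word: int = 50,
                      fonts_train=TRAIN_FONTS, fonts_test=TEST_FONTS,
                      seed: int = 0,
                      canvas: CanvasConfig = DEFAULT_CANVAS,
                      vary_case: bool = True) -> tuple[WordDataset, WordDataset]:
    """Sample train/test word variants; returns (train, test) datasets.

    Variant parameters (font, size, offset, case) are drawn uniformly
    from the canvas config ranges with the given seed; train and test
    font lists must be disjoint.  The sampled size is deterministically
    reduced when the word would not fit at the sampled offset; the final
    size is what the manifest records.
    """
    words = list(words)
    if not words:
        raise ValueError("word list is empty")
    if not fonts_train or not fonts_test:
        raise ValueError("font list is empty")
    if set(fonts_train) & set(fonts_test):
        raise ValueError("train and test fonts must be disjoint")
    rng = np.random.default_rng(seed)

    def sample(word: str, fonts, n: int, split: str) -> list[dict]:
        rows = []
        for _ in range(n):
            font = fonts[rng.integers(len(fonts))]
            size = float(rng.uniform(canvas.size_min, canvas.size_max))
            dx = float(rng.uniform(-canvas.offset_x, canvas.offset_x))
            dy = float(rng.uniform(-canvas.offset_y, canvas.offset_y))
            case = CASES[rng.integers(len(CASES))] if vary_case else "lower"
            shown = _apply_case(word, case)
            size = _fit_size(shown, font, size, dx, dy, canvas)
            rows.append({
                "text": word, "font": font, "size": size, "dx": dx,
                "dy": dy, "case": case, "label": word, "split": split,
            })
        return rows

    train_rows: list[dict] = []
    test_rows: list[dict] = []
    for word in words:
        train_rows += sample(word, list(fonts_train), n_train_per_word, "train")
        test_rows += sample(word, list(fonts_test), n_test_per_word, "test")
    return (
        WordDataset(pd.DataFrame(train_rows), canvas),
        WordDataset(pd.DataFrame(test_rows), canvas),
    )


# --------------------------------------------------------------------------
# category localizer


LOCALIZER_CATEGORIES = ("word", "face", "house", "body", "tool")


def make_localizer_set(n_words: int = 400, n_per_category: int = 100,
                       seed: int = 0,
                       words=None,
                       canvas: CanvasConfig = DEFAULT_CANVAS,
                       fonts=TRAIN_FONTS) -> list[RenderedStimulus]:
    """Word images plus four procedurally drawn non-word categories.

    The non-word categories (faces, houses, bodies, tools) are simple
    parametric line drawings — they only need to provide a non-word
    contrast for the selectivity localizer, not photographic realism.
    Returns a flat labelled stimulus list.
    """
    from .lexicon import FRENCH_WORDS

    rng = np.random.default_rng(seed)
    words = list(words) if words is not None else list(FRENCH_WORDS)
    stimuli: list[RenderedStimulus] = []
    fonts = list(fonts)
    for _ in range(n_words):
        word = words[rng.integers(len(words))]
        font = fonts[rng.integers(len(fonts))]
        size = float(rng.uniform(canvas.size_min, canvas.size_max))
        dx = float(rng.uniform(-canvas.offset_x, canvas.offset_x))
        dy = float(rng.uniform(-canvas.offset_y, canvas.offset_y))
        case = CASES[rng.integers(len(CASES))]
        shown = _apply_case(word, case)
        size = _fit_size(shown, font, size, dx, dy, canvas)
        stim = render_word(word, font, size, (dx, dy), case, canvas)
        stim.label = "word"
        stimuli.append(stim)
    for category in LOCALIZER_CATEGORIES[1:]:
        for _ in range(n_per_category):
            img = objects.draw_category(category, rng, canvas.size)
            stimuli.append(RenderedStimulus(
                image=img, text="", font_id="", size_pt=0.0,
                offset=(0.0, 0.0), case="lower", label=category,
            ))
    return stimuli


def manifest_to_csv(dataset: WordDataset, path) -> None:
    dataset.manifest.to_csv(path, index=False)


def save_stimuli_png(stimuli, directory, prefix: str = "stim") -> list[str]:
    """Write stimuli as PNG files; returns the written paths."""
    import os

    os.makedirs(directory, exist_ok=True)
    paths = []
    for i, s in enumerate(stimuli):
        img = Image.fromarray((s.image[:, :, 0] * 255).astype(np.uint8))
        path = os.path.join(directory, f"{prefix}_{i:04d}.png")
        img.save(path)
        paths.append(path)
    return paths


def probe_design_to_json(design: ProbeDesign) -> str:
    """Serialize a probe design (metadata + slot layouts) as JSON."""
    import json

    return json.dumps({
        "preferred_letter": design.preferred_letter,
        "unpreferred_letter": design.unpreferred_letter,
        "n_rows": design.n_rows,
        "n_cols": design.n_cols,
        "frame_slots": design.frame_slots,
        "spaced": design.spaced,
        "stimuli": [{"row": r + 1, "col": c + 1,
                     "slots": list(design.stimulus(r, c).slots)}
                    for r in range(design.n_rows)
                    for c in range(design.n_cols)],
    }, indent=2)
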