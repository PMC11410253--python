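"""Stimulus generation: rendering contracts, probe algebra, dataset sampling."""

import math

import numpy as np
import pytest

from ortholens import stimgen
from ortholens.fonts import TEST_FONTS, TRAIN_FONTS
from ortholens.stimgen import (BLANK, DEFAULT_CANVAS, InkOverflowError,
                               MissingGlyphError, make_bigram_set,
                               make_factorial_probe, make_localizer_set,
                               make_single_letter_grid, make_spaced_probe,
                               make_training_set, render_slots, render_word)


class TestRenderWord:
    def test_shape_and_range(self):
        s = render_word("word", "dejavu-sans", 50)
        assert s.image.shape == (224, 224, 3)
        assert s.image.min() >= 0 and s.image.max() <= 1
        assert (s.image < 0.5).any()  # some dark ink

    def test_deterministic(self):
        a = render_word("pain", "dejavu-serif", 42, (10, -5), "upper")
        b = render_word("pain", "dejavu-serif", 42, (10, -5), "upper")
        np.testing.assert_array_equal(a.image, b.image)

    def test_dark_on_light(self):
        s = render_word("air", "dejavu-sans", 60)
        # background (corner) is light, ink darker than background
        assert s.image[0, 0, 0] == 1.0
        assert s.image.min() < 0.5

    def test_case_transform(self):
        assert render_word("mot", "dejavu-sans", 40, case="upper").text == "MOT"
        assert render_word("mot", "dejavu-sans", 40, case="mixed").text == "Mot"

    def test_offset_and_size_validation(self):
        with pytest.raises(ValueError):
            render_word("mot", "dejavu-sans", 40, offset=(60, 0))
        with pytest.raises(ValueError):
            render_word("mot", "dejavu-sans", 99)
        with pytest.raises(ValueError):
            render_word("---", "dejavu-sans", 40)

    def test_ink_overflow_raises(self):
        # 8 wide letters at max size cannot fit at an extreme offset
        with pytest.raises(InkOverflowError):
            render_word("mmmmmmmm", "dejavu-sans", 70, offset=(50, 30))

    def test_missing_glyph_named_in_error(self):
        with pytest.raises(MissingGlyphError, match="glyph"):
            render_word("a\U0001058Cb", "dejavu-sans", 40)


class TestSlotRendering:
    def test_blank_frame_has_zero_ink(self):
        s = render_slots((BLANK,) * 8)
        assert s.image.min() == 1.0  # fully white canvas

    def test_slotted_determinism(self):
        a = render_slots(tuple("ox" + BLANK * 6))
        b = render_slots(tuple("ox" + BLANK * 6))
        np.testing.assert_array_equal(a.image, b.image)

    def test_ink_confined_to_slot(self):
        # glyph in slot 0 leaves the right half of the canvas white
        s = render_slots(tuple("o" + BLANK * 7))
        assert s.image[:, 112:, :].min() == 1.0


class TestFactorialProbe:
    def test_counts_and_strings(self):
        p = make_factorial_probe("o", "x")
        assert len(p.stimuli) == 20
        assert (p.n_rows, p.n_cols) == (5, 4)
        assert p.stimulus(0, 0).text == "oxxx----"
        assert p.stimulus(0, 1).text == "xoxx----"
        assert p.stimulus(4, 3).text == "----xxxo"

    def test_every_stimulus_composition(self):
        p = make_factorial_probe("o", "x")
        for s in p.stimuli:
            assert s.text.count("o") == 1
            assert s.text.count("x") == 3
            assert s.text.count(BLANK) == 4

    def test_rows_shift_by_one_slot(self):
        p = make_factorial_probe("o", "x")
        for r in range(1, p.n_rows):
            prev = p.stimulus(r - 1, 0).text
            cur = p.stimulus(r, 0).text
            assert cur == BLANK + prev[:-1]

    def test_identical_letters_rejected(self):
        with pytest.raises(ValueError):
            make_factorial_probe("o", "o")

    def test_frame_too_small(self):
        with pytest.raises(InkOverflowError):
            stimgen.factorial_layouts("o", "x", frame_slots=3, word_len=4)


class TestSpacedProbe:
    def test_counts_and_structure(self):
        p = make_spaced_probe("o", "x")
        assert len(p.stimuli) == 12
        assert (p.n_rows, p.n_cols) == (4, 3)
        for s in p.stimuli:
            letters = [i for i, g in enumerate(s.slots) if g != BLANK]
            assert len(letters) == 3
            assert letters[1] - letters[0] == 2  # one blank between letters
            assert letters[2] - letters[1] == 2

    def test_rows_shift_whole_pattern(self):
        p = make_spaced_probe("o", "x")
        for r in range(1, p.n_rows):
            prev = p.stimulus(r - 1, 1).text
            assert p.stimulus(r, 1).text == BLANK + prev[:-1]

    def test_one_preferred_letter_each(self):
        p = make_spaced_probe("o", "x")
        assert all(s.text.count("o") == 1 for s in p.stimuli)


class TestSingleLetterGrid:
    def test_full_alphabet_count(self):
        stims = make_single_letter_grid("abcdefghijklmnopqrstuvwxyz")
        assert len(stims) == 208
        assert all(sum(g != BLANK for g in s.slots) == 1 for s in stims)

    def test_minimal_grid(self):
        assert len(make_single_letter_grid("q", frame_slots=1,
                                           canvas=DEFAULT_CANVAS)) == 1

    def test_empty_alphabet_rejected(self):
        with pytest.raises(ValueError):
            make_single_letter_grid("")


class TestBigramSet:
    @pytest.mark.parametrize("n,pairs", [(49, 1176), (25, 300), (2, 1)])
    def test_counts(self, n, pairs):
        stims = make_bigram_set("abcdefg", n, seed=0)
        assert len(stims) == n
        assert math.comb(n, 2) == pairs

    def test_explicit_bigrams(self):
        stims = make_bigram_set(["ab", "cd"])
        assert [s.text.strip(BLANK) for s in stims] == ["ab", "cd"]

    def test_seed_determinism(self):
        a = make_bigram_set("abcdef", 5, seed=3)
        b = make_bigram_set("abcdef", 5, seed=3)
        assert [s.text for s in a] == [s.text for s in b]


class TestTrainingSet:
    def test_counts_and_manifest(self, scaled_canvas):
        train, test = make_training_set(["air", "mot"], 12, 4, seed=0,
                                        canvas=scaled_canvas)
        assert len(train) == 24 and len(test) == 8
        assert set(train.manifest["split"]) == {"train"}
        assert (train.manifest.groupby("label").size() == 12).all()

    def test_seed_reproducibility(self, scaled_canvas):
        a, _ = make_training_set(["air"], 10, 2, seed=7, canvas=scaled_canvas)
        b, _ = make_training_set(["air"], 10, 2, seed=7, canvas=scaled_canvas)
        assert a.manifest.equals(b.manifest)

    def test_sampled_ranges(self, scaled_canvas):
        train, test = make_training_set(["air", "vie"], 30, 10, seed=1,
                                        canvas=scaled_canvas)
        for m in (train.manifest, test.manifest):
            assert m["dx"].abs().max() <= scaled_canvas.offset_x
            assert m["dy"].abs().max() <= scaled_canvas.offset_y
            assert m["size"].max() <= scaled_canvas.size_max

    def test_font_split(self, scaled_canvas):
        train, test = make_training_set(["air"], 10, 10, seed=0,
                                        canvas=scaled_canvas)
        assert set(train.manifest["font"]) <= set(TRAIN_FONTS)
        assert set(test.manifest["font"]) <= set(TEST_FONTS)

    def test_input_validation(self, scaled_canvas):
        with pytest.raises(ValueError):
            make_training_set([], 5, 5, canvas=scaled_canvas)
        with pytest.raises(ValueError):
            make_training_set(["air"], 5, 5, fonts_train=("dejavu-sans",),
                              fonts_test=("dejavu-sans",),
                              canvas=scaled_canvas)
        with pytest.raises(ValueError):
            make_training_set(["air"], 5, 5, fonts_train=(),
                              canvas=scaled_canvas)

    def test_rendered_images_match_canvas(self, scaled_canvas):
        train, _ = make_training_set(["maison"], 3, 1, seed=0,
                                     canvas=scaled_canvas)
        imgs = train.images()
        assert imgs.shape == (3, 64, 64, 3)


class TestLocalizer:
    def test_counts_and_labels(self, scaled_canvas):
        stims = make_localizer_set(20, 5, seed=0, canvas=scaled_canvas)
        assert len(stims) == 20 + 4 * 5
        labels = [s.label for s in stims]
        assert labels.count("word") == 20
        for cat in ("face", "house", "body", "tool"):
            assert labels.count(cat) == 5

    def test_seed_determinism(self, scaled_canvas):
        a = make_localizer_set(5, 2, seed=4, canvas=scaled_canvas)
        b = make_localizer_set(5, 2, seed=4, canvas=scaled_canvas)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.image, y.image)

    def test_labels_partition(self, scaled_canvas):
        stims = make_localizer_set(6, 3, seed=1, canvas=scaled_canvas)
        assert all(s.label in stimgen.LOCALIZER_CATEGORIES for s in stims)


class TestSerialization:
    def test_probe_design_json_round_trip(self):
        import json
        design = make_factorial_probe("o", "x")
        payload = json.loads(stimgen.probe_design_to_json(design))
        assert payload["n_rows"] == 5 and payload["n_cols"] == 4
        assert payload["stimuli"][0]["slots"][:4] == ["o", "x", "x", "x"]

    def test_save_stimuli_png(self, tmp_path, scaled_canvas):
        stims = [render_word("mot", "dejavu-sans", 12, canvas=scaled_canvas)]
        paths = stimgen.save_stimuli_png(stims, tmp_path)
        assert len(paths) == 1
        from PIL import Image
        assert Image.open(paths[0]).size == (64, 64)
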