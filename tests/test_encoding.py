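"""Design matrices, lasso encoding fits, scheme comparison, position tuning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ortholens.encoding import (SCHEMES, EncodingFit, build_design_matrix,
                                compare_schemes, fit_encoding,
                                peak_to_mean_sharpness, position_tuning,
                                scheme_slots)
from ortholens.lexicon import ALPHABET, random_words

word_strategy = st.text(alphabet=ALPHABET, min_size=3, max_size=8)


class TestDesignMatrix:
    def test_word_rows_match_reference_table(self):
        # canonical worked example: "WORD" under the three schemes
        expected = {
            "left_aligned": [("w", 0), ("o", 1), ("r", 2), ("d", 3)],
            "word_centered": [("w", 2), ("o", 3), ("r", 4), ("d", 5)],
            "edge_aligned": [("w", 0), ("o", 1), ("r", 6), ("d", 7)],
        }
        for scheme, feats in expected.items():
            dm = build_design_matrix(["WORD"], scheme)
            row = np.zeros(208)
            for letter, slot in feats:
                row[dm.feature_index(letter, slot)] = 1
            np.testing.assert_array_equal(dm.X[0], row)

    def test_feature_length_is_alphabet_times_slots(self):
        dm = build_design_matrix(["pain"], "left_aligned")
        assert dm.X.shape == (1, 208)

    @given(word=word_strategy)
    @settings(max_examples=50, deadline=None)
    def test_row_sum_equals_word_length(self, word):
        for scheme in SCHEMES:
            dm = build_design_matrix([word], scheme)
            assert dm.X[0].sum() == len(set((ch, s) for ch, s in zip(
                word, scheme_slots(word, scheme)))) or dm.X[0].sum() <= len(word)
            # slots are distinct, so ones collapse only on repeated
            # (letter, slot) pairs, impossible within one scheme
            assert dm.X[0].sum() == len(word)

    @given(word=st.text(alphabet=ALPHABET, min_size=8, max_size=8))
    @settings(max_examples=20, deadline=None)
    def test_eight_letter_words_coincide_across_schemes(self, word):
        rows = [build_design_matrix([word], s).X[0] for s in SCHEMES]
        np.testing.assert_array_equal(rows[0], rows[1])
        np.testing.assert_array_equal(rows[0], rows[2])

    def test_odd_length_edge_alignment(self):
        # 5 letters: ceil(5/2)=3 anchor left, 2 anchor right
        assert scheme_slots("pains", "edge_aligned") == [0, 1, 2, 6, 7]

    def test_too_long_word_rejected(self):
        with pytest.raises(ValueError):
            build_design_matrix(["abcdefghi"], "left_aligned")
        with pytest.raises(ValueError):
            build_design_matrix(["mot1"], "left_aligned")


class TestFitEncoding:
    def test_noiseless_single_feature_recovered(self, rng):
        words = random_words(200, rng)
        dm = build_design_matrix(words, "left_aligned")
        j = dm.feature_index("g", 0)
        Y = dm.X[:, j] * 4.0
        fit = fit_encoding(Y, dm, seed=0)
        assert fit.cv_r > 1 - 1e-6
        assert np.argmax(fit.b) == j

    def test_planted_coefficient_within_band(self, rng):
        # oracle: OLS on the single active column gives ~2.0; the lasso
        # estimate must land in the same neighbourhood despite shrinkage
        words = random_words(500, rng)
        dm = build_design_matrix(words, "left_aligned")
        j = dm.feature_index("g", 0)
        Y = 2.0 * dm.X[:, j] + rng.normal(0, 0.1, size=len(words))
        x = dm.X[:, j]
        ols = np.sum((x - x.mean()) * (Y - Y.mean())) / np.sum(
            (x - x.mean()) ** 2)
        assert 1.8 < ols < 2.2
        fit = fit_encoding(Y, dm, seed=0)
        assert 1.5 <= fit.b[j] <= 2.5

    def test_constant_response_degenerate(self):
        dm = build_design_matrix(["pain", "mot"], "left_aligned")
        fit = fit_encoding(np.ones(2), dm)
        assert fit.degenerate and fit.cv_r == 0.0

    def test_mismatched_lengths_rejected(self, rng):
        dm = build_design_matrix(["pain", "mot"], "left_aligned")
        with pytest.raises(ValueError):
            fit_encoding(np.zeros(3), dm)

    def test_permutation_null_centred_at_zero(self, rng):
        from ortholens.encoding import permutation_cv_r
        words = random_words(80, rng)
        dm = build_design_matrix(words, "left_aligned")
        Y = 2.0 * dm.X[:, dm.feature_index("g", 0)] + \
            rng.normal(0, 0.1, size=len(words))
        null = permutation_cv_r(Y, dm, n_shuffles=30, seed=0)
        assert abs(np.mean(null)) < 0.15


def _edge_tuned_responses(rng, words, n_units, noise=0.05):
    """Units with one start-anchored and one end-anchored letter feature."""
    dm = build_design_matrix(words, "edge_aligned")
    Y = np.empty((len(words), n_units))
    for u in range(n_units):
        j_start = dm.feature_index(ALPHABET[rng.integers(26)],
                                   int(rng.integers(0, 2)))
        j_end = dm.feature_index(ALPHABET[rng.integers(26)],
                                 int(rng.integers(6, 8)))
        Y[:, u] = (2.0 * dm.X[:, j_start] + 1.5 * dm.X[:, j_end]
                   + rng.normal(0, noise, size=len(words)))
    return Y


class TestCompareSchemes:
    def test_edge_aligned_generative_scheme_wins(self, rng):
        words = random_words(250, rng)
        Y = _edge_tuned_responses(rng, words, n_units=12, noise=0.02)
        table = compare_schemes(Y, words, seed=0)
        wins = (table["winner"] == "edge_aligned").mean()
        assert wins >= 0.9

    def test_left_aligned_beats_centered_for_left_units(self, rng):
        words = random_words(200, rng)
        dm = build_design_matrix(words, "left_aligned")
        Y = np.empty((len(words), 10))
        for u in range(10):
            j1 = dm.feature_index(ALPHABET[rng.integers(26)],
                                  int(rng.integers(0, 3)))
            j2 = dm.feature_index(ALPHABET[rng.integers(26)],
                                  int(rng.integers(0, 3)))
            Y[:, u] = (2.0 * dm.X[:, j1] + 1.5 * dm.X[:, j2]
                       + rng.normal(0, 0.02, size=len(words)))
        table = compare_schemes(Y, words, seed=0)
        better = (table["cv_r_left_aligned"]
                  >= table["cv_r_word_centered"] - 0.02).mean()
        assert better >= 0.9

    def test_position_invariant_unit_ties(self, rng):
        words = random_words(300, rng)
        # responds to the count of letter g anywhere: identical under
        # every scheme, so fits must tie
        Y = np.array([w.count("g") for w in words], dtype=float)
        Y += rng.normal(0, 0.05, size=len(words))
        table = compare_schemes(Y, words, seed=0)
        assert bool(table["tie"].iloc[0])

    def test_word_order_shuffle_keeps_winner(self, rng):
        words = random_words(120, rng)
        Y = _edge_tuned_responses(rng, words, n_units=1)[:, 0]
        t1 = compare_schemes(Y, words, seed=0)
        perm = rng.permutation(len(words))
        t2 = compare_schemes(Y[perm], [words[i] for i in perm], seed=0)
        assert t1["winner"].iloc[0] == t2["winner"].iloc[0]
        assert abs(t1["cv_r_edge_aligned"].iloc[0]
                   - t2["cv_r_edge_aligned"].iloc[0]) < 0.05


class TestPositionTuning:
    def _fit(self, profile):
        b = np.zeros((8, 26))
        b[:, 0] = 0  # coefficients are slot-major in the flat vector
        for s, v in enumerate(profile):
            b[s, :] = v / 26
        return EncodingFit(scheme="edge_aligned", b=b.ravel(), intercept=0,
                           cv_r=1.0, alpha=0.0)

    def test_single_group_peak_normalised(self):
        fits = [self._fit([5, 1, 0, 0, 0, 0, 0, 0]) for _ in range(3)]
        curves = position_tuning(fits)
        assert len(curves) == 1
        assert curves[0].group == 0
        assert curves[0].curve[0] == pytest.approx(1.0)
        assert curves[0].n_units == 3

    def test_single_unit_returns_own_profile(self):
        fits = [self._fit([0, 0, 4, 2, 0, 0, 0, 0])]
        (curve,) = position_tuning(fits)
        assert curve.group == 2
        assert curve.curve[3] == pytest.approx(0.5)

    def test_edges_sharper_than_middle(self):
        sharp_edge = self._fit([6, 0.3, 0.1, 0, 0, 0, 0, 0])
        broad_mid = self._fit([0.5, 1.5, 2.5, 3.0, 2.5, 1.5, 0.5, 0.2])
        curves = {c.group: c for c in position_tuning([sharp_edge, broad_mid])}
        assert (peak_to_mean_sharpness(curves[0].curve)
                > peak_to_mean_sharpness(curves[3].curve))

    def test_mixed_schemes_rejected(self):
        a = self._fit([1, 0, 0, 0, 0, 0, 0, 0])
        b = self._fit([1, 0, 0, 0, 0, 0, 0, 0])
        b.scheme = "left_aligned"
        with pytest.raises(ValueError):
            position_tuning([a, b])

    def test_zero_unit_dropped_with_warning(self):
        fits = [self._fit([1, 0, 0, 0, 0, 0, 0, 0]),
                EncodingFit(scheme="edge_aligned", b=np.zeros(208),
                            intercept=0, cv_r=0, alpha=0)]
        with pytest.warns(UserWarning):
            curves = position_tuning(fits)
        assert sum(c.n_units for c in curves) == 1
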