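"""Word-selective unit localizer and per-unit letter tuning.

A unit is word selective when its mean response to word images exceeds
the mean response to every non-word category (faces, houses, bodies,
tools) by ``k_sd`` standard deviations, with the standard deviation
taken per category across that category's stimuli — the strict reading
of the fMRI-style localizer contrast.  Responses are raw
post-rectification activations; no normalisation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .store import ActivationStore, UnitAddress


@dataclass
class LocalizerResult:
    unit: UnitAddress
    mean_word: float
    per_category: dict[str, tuple[float, float]]  # name -> (mean, sd)
    selective: bool
    k_sd: float


@dataclass
class LetterTuning:
    unit: UnitAddress
    response_table: np.ndarray  # (n_letters, n_slots)
    alphabet: str
    best_letter: str
    worst_letter: str

    @property
    def per_letter_max(self) -> np.ndarray:
        return self.response_table.max(axis=1)


def selective_mask(word_responses: np.ndarray,
                   category_responses: dict[str, np.ndarray],
                   k_sd: float = 3.0) -> np.ndarray:
    """Vectorised localizer over a population.

    ``word_responses`` is (n_word_stimuli, n_units); each category array
    is (n_category_stimuli, n_units).  Returns a boolean unit mask.
    """
    if not category_responses:
        raise ValueError("need at least one non-word category")
    for name, arr in category_responses.items():
        if arr.shape[0] < 2:
            raise ValueError(f"category {name!r} needs >=2 stimuli for an sd")
        if arr.shape[1] != word_responses.shape[1]:
            raise ValueError(
                f"unit count mismatch for category {name!r}: "
                f"{arr.shape[1]} vs {word_responses.shape[1]}"
            )
    mw = word_responses.mean(axis=0)
    mask = np.ones(word_responses.shape[1], dtype=bool)
    for arr in category_responses.values():
        mask &= mw > arr.mean(axis=0) + k_sd * arr.std(axis=0, ddof=0)
    return mask


def find_word_selective(word_store: ActivationStore,
                        category_stores: dict[str, ActivationStore],
                        layer: str, k_sd: float = 3.0
                        ) -> list[LocalizerResult]:
    """Localizer on one recorded layer; returns a result per unit."""
    words = word_store.flat(layer)
    cats = {name: s.flat(layer) for name, s in category_stores.items()}
    mask = selective_mask(words, cats, k_sd)
    mw = words.mean(axis=0)
    stats = {name: (a.mean(axis=0), a.std(axis=0, ddof=0))
             for name, a in cats.items()}
    addresses = word_store.unit_addresses(layer)
    return [
        LocalizerResult(
            unit=addr, mean_word=float(mw[i]),
            per_category={n: (float(m[i]), float(s[i]))
                          for n, (m, s) in stats.items()},
            selective=bool(mask[i]), k_sd=k_sd,
        )
        for i, addr in enumerate(addresses)
    ]


def localize_from_labelled(store: ActivationStore, labels, layer: str,
                           word_label: str = "word", k_sd: float = 3.0
                           ) -> np.ndarray:
    """Selective-unit mask from a single labelled localizer recording."""
    labels = np.asarray(labels)
    flat = store.flat(layer)
    words = flat[labels == word_label]
    cats = {lab: flat[labels == lab]
            for lab in np.unique(labels) if lab != word_label}
    return selective_mask(words, cats, k_sd)


def letter_tuning(unit: UnitAddress, single_letter_store: ActivationStore,
                  alphabet: str, n_slots: int = 8) -> LetterTuning:
    """Best / least preferred letter from the letter-by-slot grid.

    The store must hold responses to the full (letter, slot) grid in
    letter-major order (the order :func:`stimgen.make_single_letter_grid`
    produces).  Preference is the max response over slots per letter.
    """
    resp = single_letter_store.unit_responses(unit)
    expected = len(alphabet) * n_slots
    if resp.shape[0] != expected:
        missing = expected - resp.shape[0]
        raise ValueError(
            f"single-letter store has {resp.shape[0]} stimuli, expected "
            f"{expected} ({len(alphabet)} letters x {n_slots} slots; "
            f"{missing} missing)"
        )
    table = resp.reshape(len(alphabet), n_slots)
    per_letter = table.max(axis=1)
    return LetterTuning(
        unit=unit, response_table=table, alphabet=alphabet,
        best_letter=alphabet[int(per_letter.argmax())],
        worst_letter=alphabet[int(per_letter.argmin())],
    )


def count_selective_by_layer(masks_by_layer: dict[str, np.ndarray]
                             ) -> pd.DataFrame:
    """Counts, totals and percentages of selective units per layer."""
    rows = []
    for layer, mask in masks_by_layer.items():
        mask = np.asarray(mask, dtype=bool)
        n_sel, n_tot = int(mask.sum()), int(mask.size)
        rows.append({
            "layer": layer, "n_selective": n_sel, "n_units": n_tot,
            "percent": 100.0 * n_sel / n_tot if n_tot else 0.0,
        })
    return pd.DataFrame(rows)


def results_to_frame(results: list[LocalizerResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        row = {"unit": str(r.unit), "mean_word": r.mean_word,
               "selective": r.selective, "k_sd": r.k_sd}
        for name, (m, s) in r.per_category.items():
            row[f"mean_{name}"] = m
            row[f"sd_{name}"] = s
        rows.append(row)
    return pd.DataFrame(rows)
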