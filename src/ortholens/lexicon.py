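"""Small word lists and pseudo-word generators.

The analyses only require alphabetic strings of length 3-8; the embedded
list contains frequent accent-free French words so that scaled training
runs on realistic orthography.
"""

from __future__ import annotations

import numpy as np

ALPHABET = "abcdefghijklmnopqrstuvwxyz"

#: frequent French words, 3-8 letters, no diacritics
FRENCH_WORDS = (
    "air", "ami", "bas", "bon", "car", "ciel", "cinq", "coin", "corps",
    "dans", "deux", "dire", "donc", "eau", "elle", "encore", "enfant",
    "entre", "faire", "femme", "fil", "fin", "fleur", "fois", "fort",
    "grand", "gris", "haut", "heure", "homme", "jamais", "jardin", "jour",
    "lettre", "livre", "loin", "long", "main", "maison", "matin", "mer",
    "mois", "monde", "mot", "nuit", "pain", "partir", "petit", "peur",
    "place", "porte", "pour", "prendre", "propre", "quand", "rien", "rouge",
    "sans", "soir", "soleil", "table", "temps", "terre", "train", "trois",
    "vent", "vers", "vie", "ville", "voir", "vrai",
)


def default_words(n: int) -> tuple[str, ...]:
    """First ``n`` words of the embedded lexicon."""
    if n > len(FRENCH_WORDS):
        raise ValueError(f"only {len(FRENCH_WORDS)} embedded words available")
    return FRENCH_WORDS[:n]


def random_words(n: int, rng: np.random.Generator,
                 min_len: int = 3, max_len: int = 8,
                 alphabet: str = ALPHABET) -> list[str]:
    """Uniform random letter strings (distinct), for encoding-model inputs."""
    letters = np.array(list(alphabet))
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        length = int(rng.integers(min_len, max_len + 1))
        w = "".join(rng.choice(letters, size=length))
        if w not in seen:
            seen.add(w)
            out.append(w)
    return out
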