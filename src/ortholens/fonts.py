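"""Font registry for stimulus rendering.

Word stimuli are rendered with TrueType fonts shipped inside matplotlib's
data directory (DejaVu and STIX families), so no font files need to be
bundled or downloaded.  The registry maps short, stable identifiers to
absolute TTF paths and records which common commercial font each one
stands in for.
"""

from __future__ import annotations

import functools
import os

import matplotlib
from PIL import ImageFont

#: open substitutes for the commercial fonts typically used in word-reading
#: stimulus sets (metrically similar, freely redistributable)
FONT_SUBSTITUTIONS = {
    "Arial": "dejavu-sans",
    "Times New Roman": "dejavu-serif",
    "Comic Sans": "stix-general",
    "Courier": "dejavu-mono",
    "Calibri": "dejavu-sans-oblique",
}

_TTF_FILES = {
    "dejavu-sans": "DejaVuSans.ttf",
    "dejavu-serif": "DejaVuSerif.ttf",
    "dejavu-mono": "DejaVuSansMono.ttf",
    "dejavu-sans-oblique": "DejaVuSans-Oblique.ttf",
    "stix-general": "STIXGeneral.ttf",
    "dejavu-sans-bold": "DejaVuSans-Bold.ttf",
    "dejavu-serif-italic": "DejaVuSerif-Italic.ttf",
}

#: default train/test split; the two lists are disjoint so that held-out
#: stimuli probe font-invariant recognition
TRAIN_FONTS = ("dejavu-sans", "dejavu-serif")
TEST_FONTS = ("dejavu-mono", "dejavu-sans-oblique", "stix-general")


def font_path(font_id: str) -> str:
    """Absolute path of the TTF file behind a registered ``font_id``."""
    try:
        fname = _TTF_FILES[font_id]
    except KeyError:
        raise KeyError(
            f"unknown font id {font_id!r}; registered: {sorted(_TTF_FILES)}"
        ) from None
    path = os.path.join(matplotlib.get_data_path(), "fonts", "ttf", fname)
    if not os.path.exists(path):  # pragma: no cover - depends on install
        raise FileNotFoundError(path)
    return path


@functools.lru_cache(maxsize=256)
def load_font(font_id: str, size_px: int) -> ImageFont.FreeTypeFont:
    """Load (and cache) a FreeType font at an integer pixel size."""
    return ImageFont.truetype(font_path(font_id), int(size_px))


@functools.lru_cache(maxsize=16)
def _charmap(font_id: str) -> frozenset[int]:
    from fontTools.ttLib import TTFont  # bundled with matplotlib

    with TTFont(font_path(font_id)) as f:
        return frozenset(f.getBestCmap())


def has_glyph(font_id: str, glyph: str) -> bool:
    """True when the font's character map covers the code point."""
    return ord(glyph) in _charmap(font_id)


def registered_fonts() -> tuple[str, ...]:
    return tuple(sorted(_TTF_FILES))
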