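"""Procedural non-word object categories for the localizer and for
phase-1 (pre-literacy) object training.

Each generator draws a parametric dark-on-light line drawing with seeded
jitter in position, scale and internal proportions: textured blobs with
eyes/mouth for faces, rectilinear composites for houses, articulated
silhouettes for bodies, and elongated handled shapes for tools.  These
are deliberately simple: the pipeline only needs discriminable non-word
categories, not naturalistic images.
"""

from __future__ import annotations

import numpy as np
from PIL import Image, ImageDraw


def _canvas(size: int) -> tuple[Image.Image, ImageDraw.ImageDraw]:
    img = Image.new("L", (size, size), color=255)
    return img, ImageDraw.Draw(img)


def _finish(img: Image.Image) -> np.ndarray:
    a = np.asarray(img, dtype=np.float32) / 255.0
    return np.repeat(a[:, :, None], 3, axis=2)


def _frame(rng: np.random.Generator, size: int) -> tuple[float, float, float]:
    """Random object centre and scale, kept well inside the canvas."""
    s = size * rng.uniform(0.25, 0.42)
    cx = size / 2 + rng.uniform(-0.12, 0.12) * size
    cy = size / 2 + rng.uniform(-0.12, 0.12) * size
    return cx, cy, s


def _texture(d: ImageDraw.ImageDraw, rng: np.random.Generator,
             cx: float, cy: float, s: float, n: tuple[int, int] = (15, 40)
             ) -> None:
    """Short random strokes inside the object region.

    Photographic object categories carry fine-scale surface texture;
    without it, line drawings differ from rendered text in their
    spatial-frequency content alone, which would make any
    high-frequency-tuned unit look spuriously "word selective"."""
    for _ in range(int(rng.integers(*n))):
        a = rng.uniform(0, 2 * np.pi)
        r = np.sqrt(rng.uniform()) * s
        x, y = cx + r * np.cos(a), cy + r * np.sin(a)
        ln = s * rng.uniform(0.04, 0.15)
        b = rng.uniform(0, np.pi)
        shade = int(rng.integers(0, 140))
        d.line([(x - ln * np.cos(b), y - ln * np.sin(b)),
                (x + ln * np.cos(b), y + ln * np.sin(b))],
               fill=shade, width=1)


def draw_face(rng: np.random.Generator, size: int) -> np.ndarray:
    img, d = _canvas(size)
    cx, cy, s = _frame(rng, size)
    rx, ry = s * rng.uniform(0.8, 1.0), s
    lw = max(1, size // 64)
    d.ellipse([cx - rx, cy - ry, cx + rx, cy + ry], outline=0, width=lw)
    # sparse texture dots inside the head outline
    for _ in range(int(rng.integers(10, 25))):
        a, r = rng.uniform(0, 2 * np.pi), np.sqrt(rng.uniform()) * 0.9
        px, py = cx + r * rx * np.cos(a), cy + r * ry * np.sin(a)
        d.point((px, py), fill=160)
    ex = rx * rng.uniform(0.35, 0.5)
    ey = ry * rng.uniform(0.25, 0.4)
    er = max(lw, s * 0.08)
    for sx in (-1, 1):
        d.ellipse([cx + sx * ex - er, cy - ey - er,
                   cx + sx * ex + er, cy - ey + er], fill=0)
    my = cy + ry * rng.uniform(0.35, 0.55)
    mw = rx * rng.uniform(0.4, 0.7)
    d.arc([cx - mw, my - s * 0.2, cx + mw, my + s * 0.2], 20, 160,
          fill=0, width=lw)
    _texture(d, rng, cx, cy, 0.8 * s)
    return _finish(img)


def draw_house(rng: np.random.Generator, size: int) -> np.ndarray:
    img, d = _canvas(size)
    cx, cy, s = _frame(rng, size)
    w, h = s * rng.uniform(0.9, 1.1), s * rng.uniform(0.7, 0.9)
    lw = max(1, size // 64)
    x0, y0, x1, y1 = cx - w, cy - h + s * 0.3, cx + w, cy + h
    d.rectangle([x0, y0, x1, y1], outline=0, width=lw)
    peak = y0 - s * rng.uniform(0.5, 0.8)
    d.polygon([(x0, y0), (cx, peak), (x1, y0)], outline=0, width=lw)
    # windows and a door
    for sx in (-1, 1):
        wx = cx + sx * w * 0.5
        ww = w * rng.uniform(0.18, 0.26)
        wy = y0 + (y1 - y0) * 0.3
        d.rectangle([wx - ww, wy - ww, wx + ww, wy + ww], outline=0, width=lw)
    dw = w * rng.uniform(0.15, 0.22)
    d.rectangle([cx - dw, y1 - h * 0.7, cx + dw, y1], outline=0, width=lw)
    _texture(d, rng, cx, cy, 0.8 * s)
    return _finish(img)


def draw_body(rng: np.random.Generator, size: int) -> np.ndarray:
    img, d = _canvas(size)
    cx, cy, s = _frame(rng, size)
    lw = max(2, size // 40)
    # torso
    tw, th = s * 0.35, s * 0.8
    d.ellipse([cx - tw, cy - th, cx + tw, cy + th * 0.2], outline=0, width=lw)
    # head
    hr = s * rng.uniform(0.2, 0.28)
    d.ellipse([cx - hr, cy - th - 2 * hr, cx + hr, cy - th], outline=0, width=lw)
    # articulated limbs: two segments each, random joint angles
    for sx in (-1, 1):
        for y_anchor, base in ((cy - th * 0.7, np.pi / 2), (cy + th * 0.15, np.pi / 2)):
            a1 = base + sx * rng.uniform(0.2, 1.0)
            a2 = a1 + sx * rng.uniform(-0.6, 0.6)
            L = s * rng.uniform(0.45, 0.65)
            x0, y0 = cx + sx * tw * 0.9, y_anchor
            x1, y1 = x0 + L * np.cos(a1) * sx, y0 + L * np.sin(a1)
            x2, y2 = x1 + L * np.cos(a2) * sx, y1 + L * np.sin(a2)
            d.line([(x0, y0), (x1, y1), (x2, y2)], fill=0, width=lw)
    _texture(d, rng, cx, cy, 0.9 * s)
    return _finish(img)


def draw_tool(rng: np.random.Generator, size: int) -> np.ndarray:
    img, d = _canvas(size)
    cx, cy, s = _frame(rng, size)
    lw = max(1, size // 64)
    angle = rng.uniform(0, np.pi)
    ca, sa = np.cos(angle), np.sin(angle)
    # elongated handle
    hl, hw = s * rng.uniform(1.0, 1.3), s * rng.uniform(0.08, 0.14)
    px, py = -sa, ca
    x0, y0 = cx - hl * ca, cy - hl * sa
    x1, y1 = cx + hl * 0.4 * ca, cy + hl * 0.4 * sa
    d.polygon([(x0 + hw * px, y0 + hw * py), (x1 + hw * px, y1 + hw * py),
               (x1 - hw * px, y1 - hw * py), (x0 - hw * px, y0 - hw * py)],
              outline=0, width=lw)
    # head: trapezoid or disc at the working end
    hs = s * rng.uniform(0.3, 0.5)
    if rng.uniform() < 0.5:
        d.polygon([(x1 + hs * px, y1 + hs * py),
                   (x1 - hs * px, y1 - hs * py),
                   (x1 + hs * 0.6 * ca - hs * 0.5 * px,
                    y1 + hs * 0.6 * sa - hs * 0.5 * py),
                   (x1 + hs * 0.6 * ca + hs * 0.5 * px,
                    y1 + hs * 0.6 * sa + hs * 0.5 * py)],
                  outline=0, width=lw)
    else:
        d.ellipse([x1 - hs, y1 - hs, x1 + hs, y1 + hs], outline=0, width=lw)
    _texture(d, rng, cx, cy, 0.9 * s)
    return _finish(img)


_GENERATORS = {
    "face": draw_face,
    "house": draw_house,
    "body": draw_body,
    "tool": draw_tool,
}

CATEGORIES = tuple(_GENERATORS)


def draw_category(category: str, rng: np.random.Generator,
                  size: int) -> np.ndarray:
    try:
        gen = _GENERATORS[category]
    except KeyError:
        raise KeyError(f"unknown category {category!r}; have {CATEGORIES}")
    return gen(rng, size)


def make_object_set(n_per_category: int, seed: int, size: int,
                    categories=CATEGORIES):
    """(images (N,H,W,3), labels (N,)) across the procedural categories."""
    rng = np.random.default_rng(seed)
    images, labels = [], []
    for cat in categories:
        for _ in range(n_per_category):
            images.append(draw_category(cat, rng, size))
            labels.append(cat)
    return np.stack(images), np.asarray(labels)
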