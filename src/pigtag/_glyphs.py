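"""Bundled stroke-drawn digit font (seven-segment style).

Shared by the scene renderer (which prints tag IDs with it) and the
reference digit detector (which correlates against the same glyph shapes
as templates).  Drawing is pure numpy rectangle fills, so rendering is
bit-identical across platforms and needs no system font.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

# segment letters: a top, b top-right, c bottom-right, d bottom,
# e bottom-left, f top-left, g middle
_SEGMENTS: dict[int, str] = {
    0: "abcdef",
    1: "bc",
    2: "abged",
    3: "abgcd",
    4: "fgbc",
    5: "afgcd",
    6: "afgedc",
    7: "abc",
    8: "abcdefg",
    9: "abcfgd",
}


def glyph_mask(digit: int, cell_w: int = 14, cell_h: int = 22, stroke: int = 3) -> np.ndarray:
    """Boolean ink mask of one digit in a ``cell_h x cell_w`` cell."""
    if digit not in _SEGMENTS:
        raise ValueError(f"digit must be 0-9, got {digit}")
    m = np.zeros((cell_h, cell_w), dtype=bool)
    t = stroke
    mid0 = (cell_h - t) // 2
    half = cell_h // 2
    for seg in _SEGMENTS[digit]:
        if seg == "a":
            m[0:t, :] = True
        elif seg == "d":
            m[cell_h - t :, :] = True
        elif seg == "g":
            m[mid0 : mid0 + t, :] = True
        elif seg == "f":
            m[0:half, 0:t] = True
        elif seg == "e":
            m[half:, 0:t] = True
        elif seg == "b":
            m[0:half, cell_w - t :] = True
        elif seg == "c":
            m[half:, cell_w - t :] = True
    return m


def ink_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    """Tight (x0, y0, x1, y1) half-open bbox of True pixels."""
    ys, xs = np.nonzero(mask)
    return int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1


@lru_cache(maxsize=None)
def digit_templates(cell_w: int = 20, cell_h: int = 32, stroke: int = 5,
                    margin: int = 3) -> dict[int, np.ndarray]:
    """Float templates (ink=1, background=0): tight ink bbox plus a
    background margin.

    The margin keeps every template non-constant (the "1" glyph's tight
    bbox is a solid bar, which would have zero variance and break
    normalized correlation) and penalizes candidates with adjacent ink.
    """
    out = {}
    for d in range(10):
        m = glyph_mask(d, cell_w=cell_w, cell_h=cell_h, stroke=stroke)
        x0, y0, x1, y1 = ink_bbox(m)
        out[d] = np.pad(m[y0:y1, x0:x1].astype(np.float64), margin)
    return out
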