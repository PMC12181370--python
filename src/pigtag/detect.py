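"""Detection-backend contract and the deterministic reference detector.

The identification cascade needs four detector roles: ``pig`` (bright
bodies on a dark background), ``tag`` (bright tag faces), ``pin`` (the
dark, near-circular fastener landmark on a tag crop) and ``digit`` (the
printed glyphs, classes 0-9).  Any backend exposing ``detect(image) ->
[BBox]`` can serve a role; the bundled reference backend is a classical
detector — intensity thresholding, connected components, geometric gating,
and normalized cross-correlation against the bundled glyph templates for
digits — that is exact on the synthetic scenes and fully deterministic.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage
from skimage.feature import match_template
from skimage.transform import resize

from ._glyphs import digit_templates
from .annotations_io import BBox, from_pixels

__all__ = [
    "DetectorConfig",
    "DetectorBackend",
    "ROLES",
    "iou",
    "suppress",
    "reference_detect",
    "make_reference_backends",
]

ROLES = ("pig", "tag", "pin", "digit")

# intensity gates on the uint8 scale (synthetic palette: background 60,
# pig body 120, tag face 230, ink < 35)
PIG_THRESHOLD = 92.0
TAG_THRESHOLD = 180.0
DARK_THRESHOLD = 90.0
# the pin fastener is near-black, well below the printed digit ink; a
# component whose darkest pixel is below this is the pin, not a glyph
PIN_DARK = 18.0

# pin gate: a filled disc has bbox fill ratio pi/4 ~ 0.785 and aspect ~ 1
PIN_FILL_MIN = 0.60
PIN_ASPECT = (0.65, 1.55)

# the "1" glyph is a solid bar, so a component claiming that class must
# fill most of its bbox; thin diagonal streaks (motion-smeared fragments
# of other glyphs) correlate well with a bar but fill far less of theirs
BAR_FILL_MIN = 0.42

CLASS_NAMES = {
    "pig": ["pig"],
    "tag": ["tag"],
    "pin": ["pin"],
    "digit": [str(d) for d in range(10)],
}


@dataclasses.dataclass(frozen=True)
class DetectorConfig:
    """Inference thresholds shared by all roles."""

    conf_threshold: float = 0.25
    iou_suppress: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.conf_threshold <= 1):
            raise ValueError("conf_threshold must be in [0, 1]")
        if not (0 < self.iou_suppress <= 1):
            raise ValueError("iou_suppress must be in (0, 1]")


@dataclasses.dataclass(frozen=True)
class DetectorBackend:
    """A named detection backend for one role."""

    name: str
    class_names: tuple
    detect: Callable[[np.ndarray], list[BBox]]


def iou(a: BBox, b: BBox) -> float:
    """Intersection over union of two normalized boxes; 0 for zero-area union."""
    ax0, ay0 = a.cx - a.w / 2, a.cy - a.h / 2
    ax1, ay1 = a.cx + a.w / 2, a.cy + a.h / 2
    bx0, by0 = b.cx - b.w / 2, b.cy - b.h / 2
    bx1, by1 = b.cx + b.w / 2, b.cy + b.h / 2
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.w * a.h + b.w * b.h - inter
    return float(inter / union) if union > 0 else 0.0


def suppress(boxes: Sequence[BBox], iou_suppress: float) -> list[BBox]:
    """Greedy same-class non-maximum suppression, highest confidence first.

    Output is sorted by confidence descending; any kept pair of the same
    class overlaps below the threshold.
    """
    order = sorted(boxes, key=lambda b: -b.conf)
    kept: list[BBox] = []
    for cand in order:
        if all(k.cls != cand.cls or iou(k, cand) < iou_suppress for k in kept):
            kept.append(cand)
    return kept


def _check_grayscale(image: np.ndarray) -> np.ndarray:
    if image.ndim != 2:
        raise ValueError(
            "reference_detect expects a 2-D grayscale image; "
            "run identify.preprocess_frame first"
        )
    return np.asarray(image, dtype=np.float64)


def _components(mask: np.ndarray):
    """Yield (slice_y, slice_x, area, comp_mask) for each connected component."""
    labels, n = ndimage.label(mask)
    for sl in ndimage.find_objects(labels):
        if sl is None:
            continue
        comp = labels[sl] > 0
        # restrict to the single label dominating this slice
        lab_vals = labels[sl][comp]
        lab = np.bincount(lab_vals).argmax()
        comp = labels[sl] == lab
        yield sl[0], sl[1], int(comp.sum()), comp


def _bright_boxes(img: np.ndarray, threshold: float, min_area_frac: float,
                  max_area_frac: float = 0.8) -> list[tuple]:
    h, w = img.shape
    out = []
    # fill enclosed holes (printed ink, glyph interiors) so a body or tag
    # face is one solid component
    mask = ndimage.binary_fill_holes(img > threshold)
    for sy, sx, area, comp in _components(mask):
        if area < min_area_frac * h * w or area > max_area_frac * h * w:
            continue
        bw, bh = sx.stop - sx.start, sy.stop - sy.start
        fill = area / (bw * bh)
        out.append(((sx.start, sy.start, sx.stop, sy.stop), fill, comp))
    return out


def _pin_like(bw: int, bh: int, fill: float) -> bool:
    aspect = bw / bh
    return PIN_ASPECT[0] <= aspect <= PIN_ASPECT[1] and fill >= PIN_FILL_MIN


def _classify_digit(patch: np.ndarray) -> tuple[int, float]:
    """NCC-classify one dark component's grayscale patch against the glyph set.

    The inverted intensity patch (ink bright, face dark) is rescaled so
    its height matches the template cell (all ten glyphs span the full
    cell height — this normalizes scale exactly, so no scale search is
    needed) and correlated at every shift of a padded canvas.  Matching
    the raw intensities rather than a binarized mask matters for
    degraded frames: re-binarizing a motion-smeared glyph manufactures a
    crisp shape that correlates spuriously well, while the gray patch
    keeps the smear and scores low.  Classes whose tight-bbox aspect is
    far from the component's are skipped.
    """
    templates = digit_templates()
    ch, cw = patch.shape
    comp_aspect = cw / ch
    best_cls, best_corr = -1, -np.inf
    target_h = 32
    target_w = max(2, round(cw * target_h / ch))
    cand = resize(patch.max() - patch, (target_h, target_w),
                  order=1, preserve_range=True, anti_aliasing=False)
    for cls, tmpl in templates.items():
        th_, tw_ = tmpl.shape
        # aspect gate against the glyph ink itself, not the padded canvas
        # (the background margin badly skews narrow glyphs like the "1" bar)
        ys, xs = np.nonzero(tmpl)
        t_aspect = (xs.max() - xs.min() + 1) / (ys.max() - ys.min() + 1)
        if not (0.55 * t_aspect <= comp_aspect <= 1.8 * t_aspect):
            continue
        pad_h = max(target_h, th_) + 8
        pad_w = max(target_w, tw_) + 8
        canvas = np.zeros((pad_h, pad_w))
        oy = (pad_h - target_h) // 2
        ox = (pad_w - target_w) // 2
        canvas[oy : oy + target_h, ox : ox + target_w] = cand
        corr = match_template(canvas, tmpl).max()
        if corr > best_corr:
            best_corr, best_cls = corr, cls
    if best_cls < 0:
        return -1, 0.0
    return best_cls, float(np.clip(best_corr, 0.0, 1.0))


def reference_detect(image: np.ndarray, role: str, cfg: DetectorConfig | None = None) -> list[BBox]:
    """Detect objects of one role in a grayscale image.

    Returns suppressed, confidence-filtered boxes in normalized
    coordinates.  Deterministic: identical image and config give identical
    boxes.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
    cfg = cfg or DetectorConfig()
    img = _check_grayscale(image)
    h, w = img.shape
    boxes: list[BBox] = []

    if role == "pig":
        for rect, fill, _ in _bright_boxes(img, PIG_THRESHOLD, min_area_frac=0.002):
            conf = float(np.clip(fill / (np.pi / 4), 0.0, 1.0))
            boxes.append(from_pixels(rect, w, h, cls=0, conf=conf))
    elif role == "tag":
        for rect, fill, _ in _bright_boxes(img, TAG_THRESHOLD, min_area_frac=0.0004,
                                           max_area_frac=0.6):
            conf = float(np.clip(fill * 1.2, 0.0, 1.0))
            boxes.append(from_pixels(rect, w, h, cls=0, conf=conf))
    elif role == "pin":
        for sy, sx, area, comp in _components(img < DARK_THRESHOLD):
            bw, bh = sx.stop - sx.start, sy.stop - sy.start
            fill = area / (bw * bh)
            if area < 12 or area > 0.05 * h * w:
                continue
            if img[sy, sx][comp].min() >= PIN_DARK:
                continue  # printed ink, not the fastener
            if not _pin_like(bw, bh, fill):
                continue
            conf = float(np.clip(fill / (np.pi / 4), 0.0, 1.0))
            # sub-pixel landmark: center the box on the component centroid,
            # which is far more accurate than the bbox center for the
            # downstream rotation angle
            cy_rel, cx_rel = ndimage.center_of_mass(comp)
            ccx, ccy = sx.start + cx_rel + 0.5, sy.start + cy_rel + 0.5
            boxes.append(BBox(cls=0, cx=ccx / w, cy=ccy / h,
                              w=bw / w, h=bh / h, conf=conf))
    else:  # digit
        for sy, sx, area, comp in _components(img < DARK_THRESHOLD):
            bw, bh = sx.stop - sx.start, sy.stop - sy.start
            if bh < 8 or area < 20 or area > 0.25 * h * w:
                continue
            if img[sy, sx][comp].min() < PIN_DARK:
                continue  # the fastener, not a glyph
            cls, conf = _classify_digit(img[sy, sx])
            if cls < 0:
                continue
            if cls == 1 and area / (bw * bh) < BAR_FILL_MIN:
                continue  # a bar glyph must be solid; see BAR_FILL_MIN
            boxes.append(from_pixels((sx.start, sy.start, sx.stop, sy.stop), w, h,
                                     cls=cls, conf=conf))

    boxes = [b for b in boxes if b.conf >= cfg.conf_threshold]
    return suppress(boxes, cfg.iou_suppress)


def make_reference_backends(cfg: DetectorConfig | None = None) -> dict[str, DetectorBackend]:
    """Reference backends for all four cascade roles."""
    cfg = cfg or DetectorConfig()
    return {
        role: DetectorBackend(
            name=f"reference-{role}",
            class_names=tuple(CLASS_NAMES[role]),
            detect=(lambda img, _r=role: reference_detect(img, _r, cfg)),
        )
        for role in ROLES
    }
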