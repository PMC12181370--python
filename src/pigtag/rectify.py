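"""Rotation correction of ear-tag crops by pin alignment.

A tag crop is rectified by rotating it about its center until the
detected pin landmark c1 lands on the top-center of the crop — formally,
until the Euclidean distance D between c1 and the midpoint of the upper
image border c2 = (W/2, 0) is minimized.  Because rotation keeps c1 on a
circle of radius ||c1 - c0|| about the crop center c0 = (W/2, H/2), the
minimizer is analytic: rotate c1 onto the ray from c0 through c2, leaving
the residual D = | ||c1 - c0|| - H/2 |.

Angles are in degrees, positive counter-clockwise on screen (y down),
wrapped to (-180, 180].
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from skimage.transform import resize, rotate

from .annotations_io import BBox

__all__ = ["RotationResult", "optimal_rotation_angle", "rotate_crop", "rectify_tag"]

logger = logging.getLogger(__name__)

ROTATION_FILL = 114.0
DIGIT_INPUT_SIZE = 120
# below this fraction of min(W, H), c1 is too close to the center for the
# angle to be numerically meaningful
DEGENERATE_EPS_FRAC = 0.01


@dataclasses.dataclass(frozen=True)
class RotationResult:
    """Outcome of the pin-alignment optimization for one tag crop."""

    angle_deg: float
    c1: tuple[float, float]
    c2: tuple[float, float]
    residual_D: float
    degenerate: bool


def optimal_rotation_angle(c1: tuple[float, float], width: int, height: int) -> RotationResult:
    """Closed-form angle that rotates ``c1`` about the crop center onto the
    upward ray toward c2 = (W/2, 0), minimizing D(angle) globally.

    A pin within 1% of min(W, H) of the crop center is degenerate: rotation
    cannot reduce D, so angle 0 is returned with the flag set.
    """
    if width < 2 or height < 2:
        raise ValueError("crop must be at least 2x2")
    x, y = float(c1[0]), float(c1[1])
    if not (0 <= x <= width and 0 <= y <= height):
        raise ValueError(f"c1={c1} outside crop bounds {width}x{height}")
    c0 = (width / 2.0, height / 2.0)
    c2 = (width / 2.0, 0.0)
    vx, vy = x - c0[0], y - c0[1]
    r = float(np.hypot(vx, vy))
    residual = abs(r - height / 2.0)
    eps = DEGENERATE_EPS_FRAC * min(width, height)
    if r < eps:
        return RotationResult(0.0, (x, y), c2, residual, True)
    # angle of v from the "up" direction (0, -1), positive CCW on screen
    angle = float(np.degrees(np.arctan2(vx, -vy)))
    if angle <= -180.0:
        angle += 360.0
    return RotationResult(angle, (x, y), c2, residual, False)


def rotate_crop(
    image: np.ndarray,
    angle_deg: float,
    out_size: int | None = DIGIT_INPUT_SIZE,
) -> np.ndarray:
    """Rotate a grayscale crop about its center, expanding the canvas.

    Bilinear interpolation, constant fill 114 outside the source.  The
    result is letterboxed to a square and resized to ``out_size`` (the
    digit-model input) unless ``out_size`` is None.
    """
    if not np.isfinite(angle_deg):
        raise ValueError("angle must be finite")
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("rotate_crop expects a 2-D grayscale crop")
    ang = angle_deg % 360.0
    if ang != 0.0:
        img = rotate(img, ang, resize=True, order=1, cval=ROTATION_FILL,
                     preserve_range=True)
    if out_size is not None:
        img = _square_resize(img, out_size)
    return img


def _square_resize(img: np.ndarray, out_size: int) -> np.ndarray:
    """Letterbox to square with fill 114, then resize to out_size."""
    h, w = img.shape
    side = max(h, w)
    if h != w:
        canvas = np.full((side, side), ROTATION_FILL)
        oy, ox = (side - h) // 2, (side - w) // 2
        canvas[oy : oy + h, ox : ox + w] = img
        img = canvas
    if side != out_size:
        img = resize(img, (out_size, out_size), order=1, preserve_range=True)
    return img


def rectify_tag(
    tag_crop: np.ndarray,
    pin_boxes: list[BBox],
    out_size: int | None = DIGIT_INPUT_SIZE,
) -> tuple[np.ndarray, RotationResult]:
    """Rectify one tag crop using its detected pin.

    The highest-confidence pin box provides c1.  With no pin the crop
    passes through unrotated, flagged degenerate, so near-upright tags
    remain readable.
    """
    img = np.asarray(tag_crop, dtype=np.float64)
    h, w = img.shape
    if not pin_boxes:
        res = RotationResult(0.0, (w / 2.0, h / 2.0), (w / 2.0, 0.0), h / 2.0, True)
        return rotate_crop(img, 0.0, out_size=out_size), res
    best = max(pin_boxes, key=lambda b: b.conf)
    c1 = (best.cx * w, best.cy * h)
    res = optimal_rotation_angle(c1, w, h)
    logger.debug("rectify: pin=(%.1f, %.1f) angle=%.2f deg residual=%.2f%s",
                 c1[0], c1[1], res.angle_deg, res.residual_D,
                 " (degenerate)" if res.degenerate else "")
    return rotate_crop(img, res.angle_deg, out_size=out_size), res
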