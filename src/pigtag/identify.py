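"""Per-frame identification cascade and ID-proposal assembly.

One frame flows through four detection stages: pigs are detected on the
preprocessed 640x640 grayscale frame; each pig crop is searched for ear
tags (several tags per crop are allowed — resting animals often bring
tags close together); each tag crop is rectified via its detected pin;
digits are detected on the rectified crop and assembled left-to-right
into a two-digit ID proposal.  Duplicate IDs within one frame keep only
the highest-confidence proposal.

All crops are letterboxed (aspect-preserving, fill 114) rather than
stretched, so digit glyphs keep their aspect ratio for template matching.
Every crop records its affine transform back to source coordinates, so a
proposal's tag box is reported in the original frame.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .annotations_io import BBox, to_pixels
from .detect import DARK_THRESHOLD, PIN_DARK, DetectorBackend, DetectorConfig, iou
from .rectify import rectify_tag

__all__ = [
    "AffineMap",
    "IDProposal",
    "Rejection",
    "FrameResult",
    "preprocess_frame",
    "crop_and_square",
    "assemble_id",
    "verify_glyphs",
    "dedup_proposals",
    "run_pipeline",
    "write_results_tsv",
]

logger = logging.getLogger(__name__)

FRAME_SIZE = 640
LETTERBOX_FILL = 114.0
# ITU-R BT.601 luma weights
_LUMA = np.array([0.299, 0.587, 0.114])

# per-stage crop sizes: pig crops feed the tag detector at 640, tag crops
# feed the pin detector at 320, rectified crops feed the digit detector at 120
OUT_SIZE_PIG = 640
OUT_SIZE_TAG = 320
DIGIT_INPUT = 120

ID_MIN, ID_MAX = 10, 99

# proposal verification on the rectified crop: the two printed glyphs sit
# on one row, so their ink heights must agree, and together they must
# account for nearly all non-fastener ink — leftover ink means a glyph
# fragmented (typically under motion smear) and the read is untrustworthy
GLYPH_HEIGHT_RATIO_MIN = 0.85
GLYPH_INK_EXPLAINED_MIN = 0.85


@dataclasses.dataclass(frozen=True)
class AffineMap:
    """Uniform-scale affine map from processed coordinates to source ones:
    ``source = (x / scale + tx, y / scale + ty)``."""

    scale: float
    tx: float
    ty: float

    def to_source(self, x: float, y: float) -> tuple[float, float]:
        return x / self.scale + self.tx, y / self.scale + self.ty

    def from_source(self, x: float, y: float) -> tuple[float, float]:
        return (x - self.tx) * self.scale, (y - self.ty) * self.scale

    def then(self, outer: "AffineMap") -> "AffineMap":
        """Map through self, then through ``outer`` (self's source frame)."""
        return AffineMap(
            scale=self.scale * outer.scale,
            tx=self.tx / outer.scale + outer.tx,
            ty=self.ty / outer.scale + outer.ty,
        )

    def box_to_source(
        self, box: BBox, proc_shape: tuple[int, int], src_shape: tuple[int, int]
    ) -> BBox:
        """Map a normalized box from the processed frame to the source frame."""
        ph, pw = proc_shape
        sh, sw = src_shape
        x0, y0 = self.to_source((box.cx - box.w / 2) * pw, (box.cy - box.h / 2) * ph)
        x1, y1 = self.to_source((box.cx + box.w / 2) * pw, (box.cy + box.h / 2) * ph)
        return BBox(
            cls=box.cls,
            cx=np.clip((x0 + x1) / 2 / sw, 0.0, 1.0),
            cy=np.clip((y0 + y1) / 2 / sh, 0.0, 1.0),
            w=min((x1 - x0) / sw, 1.0),
            h=min((y1 - y0) / sh, 1.0),
            conf=box.conf,
        )


@dataclasses.dataclass(frozen=True)
class IDProposal:
    """An assembled two-digit ID with its provenance."""

    id_str: str
    value: int
    conf: float
    frame_index: int
    tag_box: BBox
    digit_confs: tuple[float, float]


@dataclasses.dataclass(frozen=True)
class Rejection:
    reason: str  # no_digits | wrong_digit_count | out_of_range | low_confidence
    frame_index: int
    detail: str = ""


@dataclasses.dataclass
class FrameResult:
    frame_index: int
    proposals: list[IDProposal]
    rejected: list[Rejection]
    error: str | None = None


def _to_gray(frame: np.ndarray) -> np.ndarray:
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim == 3:
        frame = frame @ _LUMA
    if frame.ndim != 2:
        raise ValueError(f"expected 2-D or 3-channel image, got shape {frame.shape}")
    return frame


def preprocess_frame(frame: np.ndarray) -> tuple[np.ndarray, AffineMap]:
    """Convert to grayscale and letterbox to 640x640 (fill 114).

    Returns the processed frame and the affine map from processed to
    source pixel coordinates.
    """
    gray = _to_gray(frame)
    h, w = gray.shape
    if h == 0 or w == 0:
        raise ValueError("empty frame")
    if (h, w) == (FRAME_SIZE, FRAME_SIZE):
        return gray, AffineMap(1.0, 0.0, 0.0)
    scale = min(FRAME_SIZE / w, FRAME_SIZE / h)
    new_w, new_h = max(1, round(w * scale)), max(1, round(h * scale))
    resized = resize(gray, (new_h, new_w), order=1, preserve_range=True)
    canvas = np.full((FRAME_SIZE, FRAME_SIZE), LETTERBOX_FILL)
    px, py = (FRAME_SIZE - new_w) // 2, (FRAME_SIZE - new_h) // 2
    canvas[py : py + new_h, px : px + new_w] = resized
    return canvas, AffineMap(scale, -px / scale, -py / scale)


def crop_and_square(
    frame: np.ndarray, box: BBox, out_size: int
) -> tuple[np.ndarray, AffineMap]:
    """Crop a box, letterbox it square (fill 114), and resize to out_size.

    Returns the crop and the affine map from crop to frame coordinates.
    The crop is sampled at sub-pixel precision (bilinear), so the box
    center lands exactly on the crop center — the downstream rotation
    estimate relies on that alignment.  Degenerate boxes are padded to a
    one-pixel window; a box fully outside the frame raises.
    """
    h, w = frame.shape
    bw_px = max(box.w * w, 1.0)
    bh_px = max(box.h * h, 1.0)
    cx_px, cy_px = box.cx * w, box.cy * h
    x0, y0 = cx_px - bw_px / 2, cy_px - bh_px / 2
    if x0 + bw_px <= 0 or x0 >= w or y0 + bh_px <= 0 or y0 >= h:
        raise ValueError(f"box {box} lies outside the {w}x{h} frame")
    side = max(bw_px, bh_px)
    scale = out_size / side
    ox = (out_size - bw_px * scale) / 2
    oy = (out_size - bh_px * scale) / 2
    # output pixel centers mapped back to frame coordinates (pixel i
    # covers [i, i+1), center i + 0.5; map_coordinates indexes centers)
    centers = np.arange(out_size) + 0.5
    src_x = (centers - ox) / scale + x0
    src_y = (centers - oy) / scale + y0
    yy, xx = np.meshgrid(src_y - 0.5, src_x - 0.5, indexing="ij")
    crop = ndimage.map_coordinates(
        np.asarray(frame, dtype=np.float64), [yy, xx],
        order=1, mode="constant", cval=LETTERBOX_FILL,
    )
    # letterbox bands outside the box content
    in_x = (centers >= ox) & (centers <= out_size - ox)
    in_y = (centers >= oy) & (centers <= out_size - oy)
    crop[~(in_y[:, None] & in_x[None, :])] = LETTERBOX_FILL
    return crop, AffineMap(scale, x0 - ox / scale, y0 - oy / scale)


def assemble_id(
    digit_boxes: Sequence[BBox],
    frame_index: int = 0,
    tag_box: BBox | None = None,
    n_digits: int = 2,
    value_range: tuple[int, int] = (ID_MIN, ID_MAX),
) -> IDProposal | Rejection:
    """Assemble suppressed digit detections into an ID proposal.

    Digits are ordered by their horizontal centers; exactly ``n_digits``
    must survive and the value must fall in ``value_range``.  The
    proposal's confidence is the minimum digit confidence (an ID is only
    as reliable as its weakest digit).  Rejections are data, not errors.
    """
    if not digit_boxes:
        return Rejection("no_digits", frame_index)
    if len(digit_boxes) != n_digits:
        return Rejection("wrong_digit_count", frame_index,
                         f"got {len(digit_boxes)} digits")
    ordered = sorted(digit_boxes, key=lambda b: b.cx)
    id_str = "".join(str(b.cls) for b in ordered)
    value = int(id_str)
    if not (value_range[0] <= value <= value_range[1]):
        return Rejection("out_of_range", frame_index, f"value {value}")
    confs = tuple(b.conf for b in ordered)
    placeholder = tag_box if tag_box is not None else BBox(0, 0.5, 0.5, 1.0, 1.0)
    return IDProposal(
        id_str=id_str.zfill(n_digits),
        value=value,
        conf=min(confs),
        frame_index=frame_index,
        tag_box=placeholder,
        digit_confs=confs,
    )


def verify_glyphs(rect_crop: np.ndarray, digit_boxes: Sequence[BBox]) -> tuple[bool, str]:
    """Integrity check of an assembled read against its rectified crop.

    Maps each accepted digit box to the dark connected component under
    it, then requires (a) the glyph ink heights to agree within
    ``GLYPH_HEIGHT_RATIO_MIN`` (the digits share one printed row) and
    (b) the accepted components to explain at least
    ``GLYPH_INK_EXPLAINED_MIN`` of all non-fastener ink in the crop.
    Motion smear that fragments a glyph fails one of these: the surviving
    streak is the wrong height, or the unread fragments leave ink behind.
    Returns (ok, detail).
    """
    img = np.asarray(rect_crop, dtype=np.float64)
    h, w = img.shape
    mask = img < DARK_THRESHOLD
    labels, n = ndimage.label(mask)
    if n == 0:
        return False, "no ink in rectified crop"
    objects = ndimage.find_objects(labels)
    areas = np.bincount(labels.ravel(), minlength=n + 1)

    glyph_labels: list[int] = []
    for box in digit_boxes:
        cx = int(np.clip(round(box.cx * w), 0, w - 1))
        cy = int(np.clip(round(box.cy * h), 0, h - 1))
        lab = int(labels[cy, cx])
        if lab == 0:
            # box center may sit in a glyph hole; take the dominant
            # component inside the box instead
            x0, y0, x1, y1 = to_pixels(box, w, h)
            vals = labels[y0:y1, x0:x1]
            vals = vals[vals > 0]
            if vals.size == 0:
                return False, "no ink under digit box"
            lab = int(np.bincount(vals).argmax())
        glyph_labels.append(lab)
    if len(set(glyph_labels)) != len(glyph_labels):
        return False, "digits share one ink component"

    heights = [objects[lab - 1][0].stop - objects[lab - 1][0].start
               for lab in glyph_labels]
    ratio = min(heights) / max(heights)
    if ratio < GLYPH_HEIGHT_RATIO_MIN:
        return False, f"glyph height mismatch ({ratio:.2f})"

    fastener_area = sum(
        int(areas[lab])
        for lab in range(1, n + 1)
        if img[objects[lab - 1]][labels[objects[lab - 1]] == lab].min() < PIN_DARK
    )
    explained = sum(int(areas[lab]) for lab in glyph_labels)
    denom = max(int(mask.sum()) - fastener_area, 1)
    frac = explained / denom
    if frac < GLYPH_INK_EXPLAINED_MIN:
        return False, f"unexplained ink ({frac:.2f} explained)"
    return True, ""


def dedup_proposals(proposals: Sequence[IDProposal]) -> list[IDProposal]:
    """Keep one proposal per id_str: the highest-confidence one.

    Ties break toward the larger tag box, then the earlier occurrence.
    Output sorted by id_str.  Idempotent.
    """
    best: dict[str, tuple] = {}
    for i, p in enumerate(proposals):
        key = p.id_str
        rank = (p.conf, p.tag_box.w * p.tag_box.h, -i)
        if key not in best or rank > best[key][0]:
            best[key] = (rank, p)
    return [best[k][1] for k in sorted(best)]


def _suppress_digits(boxes: Sequence[BBox], iou_thr: float) -> list[BBox]:
    """Greedy NMS across ALL digit classes (one glyph must yield one read)."""
    kept: list[BBox] = []
    for cand in sorted(boxes, key=lambda b: -b.conf):
        if all(iou(k, cand) < iou_thr for k in kept):
            kept.append(cand)
    return kept


def run_pipeline(
    frames: Iterable[np.ndarray],
    backends: Mapping[str, DetectorBackend],
    cfg: DetectorConfig | None = None,
    out_size_pig: int = OUT_SIZE_PIG,
    out_size_tag: int = OUT_SIZE_TAG,
    digit_input: int = DIGIT_INPUT,
) -> list[FrameResult]:
    """Run the full cascade over frames; one FrameResult per frame.

    Results depend only on the frame itself (no state across frames).  A
    backend failure marks the frame with an error and the run continues.
    """
    cfg = cfg or DetectorConfig()
    missing = [r for r in ("pig", "tag", "pin", "digit") if r not in backends]
    if missing:
        raise ValueError(f"missing backends for roles: {missing}")
    results: list[FrameResult] = []
    for idx, frame in enumerate(frames):
        try:
            results.append(_run_frame(idx, frame, backends, cfg,
                                      out_size_pig, out_size_tag, digit_input))
        except Exception as exc:  # noqa: BLE001 - isolate per-frame failures
            logger.exception("frame %d failed", idx)
            results.append(FrameResult(idx, [], [], error=str(exc)))
    return results


def _run_frame(idx, frame, backends, cfg, out_size_pig, out_size_tag, digit_input):
    src_shape = np.asarray(frame).shape[:2]
    proc, t_frame = preprocess_frame(frame)
    proposals: list[IDProposal] = []
    rejected: list[Rejection] = []
    for pig_box in backends["pig"].detect(proc):
        pig_crop, t_pig = crop_and_square(proc, pig_box, out_size_pig)
        t_pig_src = t_pig.then(t_frame)
        for tag_box in backends["tag"].detect(pig_crop):
            tag_src = t_pig_src.box_to_source(tag_box, pig_crop.shape, src_shape)
            tag_crop, _t_tag = crop_and_square(pig_crop, tag_box, out_size_tag)
            pins = backends["pin"].detect(tag_crop)
            rect_crop, rot = rectify_tag(tag_crop, pins, out_size=digit_input)
            digits = _suppress_digits(backends["digit"].detect(rect_crop),
                                      cfg.iou_suppress)
            out = assemble_id(digits, frame_index=idx, tag_box=tag_src)
            if isinstance(out, IDProposal):
                ok, detail = verify_glyphs(rect_crop, digits)
                if not ok:
                    rejected.append(Rejection("low_confidence", idx, detail))
                    continue
                logger.debug("frame %d: tag at (%.3f, %.3f) -> ID %s conf %.2f "
                             "(rot %.1f deg)", idx, tag_src.cx, tag_src.cy,
                             out.id_str, out.conf, rot.angle_deg)
                proposals.append(out)
            else:
                rejected.append(out)
    return FrameResult(idx, dedup_proposals(proposals), rejected)


def write_results_tsv(results: Sequence[FrameResult], path, frame_shapes=None) -> None:
    """Write ``frame<TAB>id<TAB>conf<TAB>x0,y0,x1,y1`` rows (source pixels)."""
    with open(path, "w") as fh:
        for res in results:
            shape = None
            if frame_shapes is not None:
                shape = frame_shapes[res.frame_index]
            for p in res.proposals:
                if shape is not None:
                    h, w = shape
                    rect = to_pixels(p.tag_box, w, h)
                else:
                    rect = (p.tag_box.cx - p.tag_box.w / 2,
                            p.tag_box.cy - p.tag_box.h / 2,
                            p.tag_box.cx + p.tag_box.w / 2,
                            p.tag_box.cy + p.tag_box.h / 2)
                coords = ",".join(f"{v:.1f}" if isinstance(v, float) else str(v)
                                  for v in rect)
                fh.write(f"{res.frame_index}\t{p.id_str}\t{p.conf:.4f}\t{coords}\n")
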