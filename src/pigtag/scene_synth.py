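"""Seeded synthetic renderer of pen-view scenes with exhaustive ground truth.

Scenes emulate top-down pen views: elliptical pig bodies on a darker
background, each optionally bearing a rounded-rectangle ear tag printed
with a two-digit ID (10-99) and a pin landmark, at a known in-plane
rotation.  Every scene is rendered from a single integer seed through one
generator instance, so identical specs produce bit-identical images.

The tag is painted analytically: each scene pixel near the tag is mapped
into the tag's local (unrotated) frame by the inverse rotation and looked
up in crisp local masks.  Ground-truth coordinates therefore follow the
exact same rotation math that the painter uses.

Optional corruptions emulate the failure causes seen in real pen footage:
linear motion blur, pixelation, partial tag occlusion, and exposure error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import os
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from . import annotations_io as aio
from ._glyphs import glyph_mask

__all__ = [
    "CorruptionSpec",
    "SceneSpec",
    "GroundTruth",
    "PlacementError",
    "render_scene",
    "generate_dataset",
    "rotate_point",
    "COMBINED_CLASS_MAP",
]

# intensity palette (uint8 scale)
BACKGROUND = 60.0
PIG_BODY = 120.0
TAG_FACE = 230.0
DIGIT_INK = 30.0
PIN_INK = 0.0  # the metal fastener reads near-black, darker than print ink
OCCLUDER = 150.0
BG_NOISE = 8.0
PIG_NOISE = 10.0

# tag geometry at unit scale (min scene dimension 640)
TAG_W, TAG_H = 64, 44
TAG_CORNER_R = 6
PIN_CENTER = (32.0, 7.0)
PIN_R = 4.0
DIGIT_CELL = (14, 22)  # w, h
DIGIT_STROKE = 4
DIGIT_ROW_Y0 = 15
DIGIT_GAP = 8  # between the two cells

# combined label-class layout for written datasets
COMBINED_CLASS_MAP: dict[int, str] = {0: "pig", 1: "tag", 2: "pin"}
COMBINED_CLASS_MAP.update({3 + d: str(d) for d in range(10)})
DIGIT_CLASS_OFFSET = 3


class PlacementError(RuntimeError):
    """Raised when non-overlapping pig placement fails after bounded retries."""


@dataclasses.dataclass(frozen=True)
class CorruptionSpec:
    """Image corruptions; the defaults (0, 1, 0, 1) produce a clean scene."""

    motion_blur_px: int = 0
    pixelation_factor: float = 1.0
    occlusion_fraction: float = 0.0
    exposure_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.motion_blur_px < 0:
            raise ValueError("motion_blur_px must be >= 0")
        if self.pixelation_factor < 1:
            raise ValueError("pixelation_factor must be >= 1")
        if not (0 <= self.occlusion_fraction < 1):
            raise ValueError("occlusion_fraction must be in [0, 1)")
        if self.exposure_factor <= 0:
            raise ValueError("exposure_factor must be > 0")

    @property
    def is_clean(self) -> bool:
        return (
            self.motion_blur_px == 0
            and self.pixelation_factor == 1.0
            and self.occlusion_fraction == 0.0
            and self.exposure_factor == 1.0
        )


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Parameters of one rendered scene."""

    width: int = 640
    height: int = 640
    n_pigs: int = 3
    tags_per_pig: int = 1
    id_pool: tuple = tuple(range(10, 100))
    rotation_range: tuple[float, float] = (-60.0, 60.0)
    corruption: CorruptionSpec = CorruptionSpec()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("scene dimensions must be >= 64")
        if self.n_pigs < 0:
            raise ValueError("n_pigs must be >= 0")
        if self.tags_per_pig not in (0, 1):
            raise ValueError("tags_per_pig must be 0 or 1")
        for i in self.id_pool:
            if not (10 <= i <= 99):
                raise ValueError(f"id {i} outside [10, 99]")
        lo, hi = self.rotation_range
        if lo > hi:
            raise ValueError("rotation_range must satisfy lo <= hi")


@dataclasses.dataclass
class GroundTruth:
    """Complete per-scene truth for every pipeline stage."""

    pig_boxes: list[aio.BBox]
    tag_boxes: list[aio.BBox]
    pin_points: list[tuple[float, float]]
    digit_boxes: list[aio.BBox]  # class = digit value 0-9; two per tag
    tag_rotations: list[float]
    tag_ids: list[str]


def rotate_point(
    p: tuple[float, float],
    angle_deg: float,
    center: tuple[float, float],
    out_center: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Rotate a point counter-clockwise on screen (y down) about ``center``.

    ``out_center`` relocates the rotation center in the output frame (used
    when an accompanying image rotation expands its canvas).
    """
    if out_center is None:
        out_center = center
    th = np.deg2rad(angle_deg)
    dx, dy = p[0] - center[0], p[1] - center[1]
    return (
        out_center[0] + dx * np.cos(th) + dy * np.sin(th),
        out_center[1] - dx * np.sin(th) + dy * np.cos(th),
    )


def _tag_dims(s: float) -> tuple[int, int]:
    """Local tag raster dimensions at scale ``s``."""
    return max(8, round(TAG_W * s)), max(6, round(TAG_H * s))


def _digit_layout(s: float, tw: int):
    cw = max(4, round(DIGIT_CELL[0] * s))
    ch = max(6, round(DIGIT_CELL[1] * s))
    stroke = max(1, round(DIGIT_STROKE * s))
    gap = max(2, round(DIGIT_GAP * s))
    y0 = round(DIGIT_ROW_Y0 * s)
    x0_left = tw // 2 - gap // 2 - cw
    x0_right = tw // 2 + gap - gap // 2
    return cw, ch, stroke, y0, (x0_left, x0_right)


def _paint_tag(
    img: np.ndarray,
    center: tuple[float, float],
    angle_deg: float,
    tag_id: int,
    s: float,
) -> tuple[list[tuple[float, float, float, float]], tuple[float, float]]:
    """Paint one rotated tag; return digit cell rects (scene aabb) and pin point."""
    tw, th = _tag_dims(s)
    cw, ch, stroke, y0, xs0 = _digit_layout(s, tw)
    ink = np.zeros((th, tw), dtype=bool)
    digit_rects_local = []
    for d_char, x0 in zip(f"{tag_id:02d}", xs0):
        g = glyph_mask(int(d_char), cell_w=cw, cell_h=ch, stroke=stroke)
        ink[y0 : y0 + ch, x0 : x0 + cw] |= g
        digit_rects_local.append((x0, y0, x0 + cw, y0 + ch))

    h_img, w_img = img.shape
    lc = (tw / 2.0, th / 2.0)
    half_diag = np.hypot(tw, th) / 2.0 + 2
    x_lo = max(0, int(center[0] - half_diag))
    x_hi = min(w_img, int(np.ceil(center[0] + half_diag)) + 1)
    y_lo = max(0, int(center[1] - half_diag))
    y_hi = min(h_img, int(np.ceil(center[1] + half_diag)) + 1)
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi].astype(np.float64)
    # inverse rotation at pixel centers: scene -> local (continuous coords)
    th_r = np.deg2rad(-angle_deg)
    dx, dy = xx + 0.5 - center[0], yy + 0.5 - center[1]
    lx = lc[0] + dx * np.cos(th_r) + dy * np.sin(th_r)
    ly = lc[1] - dx * np.sin(th_r) + dy * np.cos(th_r)
    # face and pin are evaluated analytically at the continuous local
    # coordinates, so the painted shapes are exact discretizations of the
    # rotated geometry (a pixel is painted iff its center lies inside);
    # the glyph ink is a raster mask, sampled by nearest local pixel
    r = TAG_CORNER_R * s
    fx = np.clip(lx, r, tw - r)
    fy = np.clip(ly, r, th - r)
    on_face = (lx - fx) ** 2 + (ly - fy) ** 2 <= r**2
    on_pin = (lx - PIN_CENTER[0] * s) ** 2 + (ly - PIN_CENTER[1] * s) ** 2 <= (PIN_R * s) ** 2
    ix = np.floor(lx).astype(int)
    iy = np.floor(ly).astype(int)
    valid = (ix >= 0) & (ix < tw) & (iy >= 0) & (iy < th)
    ixc = np.clip(ix, 0, tw - 1)
    iyc = np.clip(iy, 0, th - 1)
    on_ink = valid & ink[iyc, ixc]
    roi = img[y_lo:y_hi, x_lo:x_hi]
    roi[on_face] = TAG_FACE
    roi[on_ink & on_face] = DIGIT_INK
    roi[on_pin & on_face] = PIN_INK

    def scene_aabb(rect_local):
        x0, y0_, x1, y1 = rect_local
        corners = [(x0, y0_), (x1, y0_), (x1, y1), (x0, y1)]
        pts = [
            rotate_point((px - lc[0] + center[0], py - lc[1] + center[1]), angle_deg, center)
            for px, py in corners
        ]
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        return (min(xs), min(ys), max(xs), max(ys))

    tag_aabb = scene_aabb((0, 0, tw, th))
    digit_aabbs = [scene_aabb(r) for r in digit_rects_local]
    pin_pt = rotate_point(
        (PIN_CENTER[0] * s - lc[0] + center[0], PIN_CENTER[1] * s - lc[1] + center[1]),
        angle_deg,
        center,
    )
    return tag_aabb, digit_aabbs, pin_pt


def _place_pigs(spec: SceneSpec, rng: np.random.Generator, s: float):
    """Sample non-overlapping pig ellipses; bounded retries per pig."""
    pigs = []  # (cx, cy, a, b, phi, ext_x, ext_y)
    for _ in range(spec.n_pigs):
        placed = False
        for _attempt in range(200):
            a = rng.uniform(80, 100) * s
            b = rng.uniform(48, 62) * s
            phi = rng.uniform(0, 180.0)
            phi_r = np.deg2rad(phi)
            ext_x = np.sqrt((a * np.cos(phi_r)) ** 2 + (b * np.sin(phi_r)) ** 2)
            ext_y = np.sqrt((a * np.sin(phi_r)) ** 2 + (b * np.cos(phi_r)) ** 2)
            if 2 * ext_x + 4 > spec.width or 2 * ext_y + 4 > spec.height:
                continue
            cx = rng.uniform(ext_x + 2, spec.width - ext_x - 2)
            cy = rng.uniform(ext_y + 2, spec.height - ext_y - 2)
            ok = True
            for (ocx, ocy, _, _, _, oex, oey) in pigs:
                if abs(cx - ocx) < ext_x + oex + 4 and abs(cy - ocy) < ext_y + oey + 4:
                    ok = False
                    break
            if ok:
                pigs.append((cx, cy, a, b, phi, ext_x, ext_y))
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {spec.n_pigs} non-overlapping pigs "
                f"in {spec.width}x{spec.height} (seed={spec.seed})"
            )
    return pigs


def _apply_corruption(
    img: np.ndarray,
    spec: CorruptionSpec,
    tag_aabbs: Sequence[tuple[float, float, float, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    from scipy.ndimage import uniform_filter1d
    from skimage.transform import resize

    if spec.occlusion_fraction > 0:
        f = np.sqrt(spec.occlusion_fraction)
        for (x0, y0, x1, y1) in tag_aabbs:
            cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
            hw, hh = (x1 - x0) / 2 * f, (y1 - y0) / 2 * f
            xa, xb = int(cx - hw), int(np.ceil(cx + hw))
            ya, yb = int(cy - hh), int(np.ceil(cy + hh))
            img[max(0, ya) : yb, max(0, xa) : xb] = OCCLUDER
    if spec.motion_blur_px > 1:
        img = uniform_filter1d(img, size=int(spec.motion_blur_px), axis=1, mode="nearest")
    if spec.pixelation_factor > 1:
        h, w = img.shape
        small = (max(1, round(h / spec.pixelation_factor)), max(1, round(w / spec.pixelation_factor)))
        img = resize(
            resize(img, small, order=1, preserve_range=True, anti_aliasing=False),
            (h, w),
            order=0,
            preserve_range=True,
            anti_aliasing=False,
        )
    if spec.exposure_factor != 1.0:
        img = img * spec.exposure_factor
    return img


def render_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one scene; returns a uint8 grayscale image and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    s = min(spec.width, spec.height) / 640.0
    img = BACKGROUND + rng.uniform(-BG_NOISE, BG_NOISE, size=(spec.height, spec.width))

    pigs = _place_pigs(spec, rng, s)
    truth = GroundTruth([], [], [], [], [], [])
    yy_full, xx_full = np.mgrid[0 : spec.height, 0 : spec.width]

    # ear-tag IDs are unique per pen: draw without replacement while the
    # pool lasts
    pool = np.asarray(sorted(spec.id_pool))
    n_tags = len(pigs) if spec.tags_per_pig == 1 else 0
    if n_tags > 0:
        if len(pool) >= n_tags:
            scene_ids = rng.choice(pool, size=n_tags, replace=False)
        else:
            scene_ids = rng.choice(pool, size=n_tags, replace=True)
    id_iter = iter(scene_ids) if n_tags else iter(())

    tag_aabbs_px = []
    for (cx, cy, a, b, phi, ext_x, ext_y) in pigs:
        phi_r = np.deg2rad(phi)
        x_lo, x_hi = max(0, int(cx - ext_x) - 1), min(spec.width, int(np.ceil(cx + ext_x)) + 2)
        y_lo, y_hi = max(0, int(cy - ext_y) - 1), min(spec.height, int(np.ceil(cy + ext_y)) + 2)
        # ellipse test at pixel centers, matching the continuous-coordinate
        # convention of the ground-truth boxes
        xs = xx_full[y_lo:y_hi, x_lo:x_hi] + 0.5 - cx
        ys = yy_full[y_lo:y_hi, x_lo:x_hi] + 0.5 - cy
        u = xs * np.cos(phi_r) + ys * np.sin(phi_r)
        v = -xs * np.sin(phi_r) + ys * np.cos(phi_r)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        roi = img[y_lo:y_hi, x_lo:x_hi]
        noise = rng.uniform(-PIG_NOISE, PIG_NOISE, size=roi.shape)
        roi[inside] = PIG_BODY + noise[inside]
        truth.pig_boxes.append(
            aio.from_pixels((cx - ext_x, cy - ext_y, cx + ext_x, cy + ext_y), spec.width, spec.height)
        )
        if spec.tags_per_pig == 1:
            angle = float(rng.uniform(spec.rotation_range[0], spec.rotation_range[1]))
            tag_id = int(next(id_iter))
            tag_aabb, digit_aabbs, pin_pt = _paint_tag(img, (cx, cy), angle, tag_id, s)
            tag_aabbs_px.append(tag_aabb)
            truth.tag_boxes.append(aio.from_pixels(tag_aabb, spec.width, spec.height, cls=0))
            for d_char, rect in zip(f"{tag_id:02d}", digit_aabbs):
                truth.digit_boxes.append(
                    aio.from_pixels(rect, spec.width, spec.height, cls=int(d_char))
                )
            truth.pin_points.append(pin_pt)
            truth.tag_rotations.append(angle)
            truth.tag_ids.append(f"{tag_id:02d}")

    img = _apply_corruption(img, spec.corruption, tag_aabbs_px, rng)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, truth


def truth_to_labels(truth: GroundTruth, width: int, height: int) -> list[aio.BBox]:
    """Flatten ground truth into the combined class layout (pig/tag/pin/digits)."""
    out: list[aio.BBox] = []
    for b in truth.pig_boxes:
        out.append(dataclasses.replace(b, cls=0))
    for b in truth.tag_boxes:
        out.append(dataclasses.replace(b, cls=1))
    for (px, py) in truth.pin_points:
        r = PIN_R
        out.append(aio.from_pixels((px - r, py - r, px + r, py + r), width, height, cls=2))
    for b in truth.digit_boxes:
        out.append(dataclasses.replace(b, cls=DIGIT_CLASS_OFFSET + b.cls))
    return out


def generate_dataset(
    spec: SceneSpec,
    n_scenes: int,
    out_dir: str | os.PathLike,
    overwrite: bool = False,
) -> list[tuple[str, int, int]]:
    """Render ``n_scenes`` scenes to ``out_dir`` (PNG + YOLO labels + manifest).

    Per-scene seeds are drawn from ``spec.seed`` so every scene can be
    replayed individually.  Returns the manifest: (filename, seed, n_tags)
    per scene, also written as tab-separated ``manifest.tsv``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise FileExistsError(f"{out} is not empty; pass overwrite=True to replace")
    out.mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(spec.seed)
    scene_seeds = master.integers(0, 2**31 - 1, size=n_scenes)
    manifest: list[tuple[str, int, int]] = []
    all_ids: list[list[str]] = []
    for i, sd in enumerate(scene_seeds):
        sc = dataclasses.replace(spec, seed=int(sd))
        img, truth = render_scene(sc)
        name = f"scene_{i:05d}"
        iio.imwrite(out / f"{name}.png", img)
        aio.write_labels(out / f"{name}.txt", truth_to_labels(truth, sc.width, sc.height))
        manifest.append((f"{name}.png", int(sd), len(truth.tag_ids)))
        all_ids.append(list(truth.tag_ids))
    aio.write_class_map(out / "classes.tsv", COMBINED_CLASS_MAP)
    with open(out / "manifest.tsv", "w") as fh:
        for name, sd, n_tags in manifest:
            fh.write(f"{name}\t{sd}\t{n_tags}\n")
    with open(out / "ids.tsv", "w") as fh:
        for i, ids in enumerate(all_ids):
            fh.write(" ".join([str(i)] + ids) + "\n")
    return manifest


def manifest_checksum(out_dir: str | os.PathLike) -> str:
    """SHA-256 over the manifest plus every listed image, for replay checks."""
    out = Path(out_dir)
    h = hashlib.sha256()
    with open(out / "manifest.tsv", "rb") as fh:
        data = fh.read()
    h.update(data)
    for line in data.decode().splitlines():
        name = line.split("\t")[0]
        with open(out / name, "rb") as fh:
            h.update(fh.read())
    return h.hexdigest()
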