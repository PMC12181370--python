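"""Bounding-box label I/O, coordinate conversions, and dataset splitting.

Labels use the YOLO text dialect: one object per line, ``cls cx cy w h
[conf]``, with center/extent coordinates normalized to [0, 1] relative to
the image size.  Pixel rectangles are 0-based, half-open, origin at the
top-left corner, x rightward and y downward.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "BBox",
    "DatasetSplit",
    "LabelError",
    "read_labels",
    "write_labels",
    "to_pixels",
    "from_pixels",
    "read_class_map",
    "write_class_map",
    "split_dataset",
    "write_split",
]

_COORD_TOL = 1e-6


class LabelError(ValueError):
    """Raised for malformed or out-of-range label data."""


@dataclasses.dataclass(frozen=True)
class BBox:
    """Axis-aligned box in normalized center format.

    Parameters
    ----------
    cls : int
        Non-negative class id.
    cx, cy : float
        Box center, normalized to [0, 1].
    w, h : float
        Box extent, normalized, in (0, 1].
    conf : float
        Confidence in [0, 1]; ground truth uses 1.0.
    """

    cls: int
    cx: float
    cy: float
    w: float
    h: float
    conf: float = 1.0

    def __post_init__(self) -> None:
        if self.cls < 0:
            raise LabelError(f"negative class id {self.cls}")
        for name in ("cx", "cy", "w", "h", "conf"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise LabelError(f"non-finite {name}={v}")
        if self.w <= 0 or self.h <= 0:
            raise LabelError(f"non-positive extent w={self.w} h={self.h}")
        # box must intersect the unit square
        if (
            self.cx + self.w / 2 <= -_COORD_TOL
            or self.cx - self.w / 2 >= 1 + _COORD_TOL
            or self.cy + self.h / 2 <= -_COORD_TOL
            or self.cy - self.h / 2 >= 1 + _COORD_TOL
        ):
            raise LabelError("box does not intersect the unit square")
        if not (-_COORD_TOL <= self.conf <= 1 + _COORD_TOL):
            raise LabelError(f"confidence {self.conf} outside [0, 1]")


@dataclasses.dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/val/test partition of item identifiers."""

    train: tuple
    val: tuple
    test: tuple

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.val), len(self.test))


def read_labels(path: str | os.PathLike, n_cols: int = 5) -> list[BBox]:
    """Read a YOLO-dialect label file.

    ``n_cols`` is 5 (``cls cx cy w h``, conf defaults to 1.0) or 6 (with a
    trailing confidence column).  Blank lines are ignored; order is
    preserved.  A malformed line raises :class:`LabelError` naming the line
    number; coordinates outside [0, 1] beyond 1e-6 raise as well.
    """
    if n_cols not in (5, 6):
        raise LabelError(f"n_cols must be 5 or 6, got {n_cols}")
    boxes: list[BBox] = []
    with open(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != n_cols:
                raise LabelError(
                    f"{path}:{lineno}: expected {n_cols} fields, got {len(parts)}"
                )
            try:
                cls = int(parts[0])
                vals = [float(p) for p in parts[1:]]
            except ValueError as exc:
                raise LabelError(f"{path}:{lineno}: {exc}") from exc
            cx, cy, w, h = vals[:4]
            for name, v in zip(("cx", "cy", "w", "h"), (cx, cy, w, h)):
                if v < -_COORD_TOL or v > 1 + _COORD_TOL:
                    raise LabelError(
                        f"{path}:{lineno}: {name}={v} outside [0, 1]"
                    )
            conf = vals[4] if n_cols == 6 else 1.0
            try:
                boxes.append(BBox(cls, cx, cy, w, h, conf))
            except LabelError as exc:
                raise LabelError(f"{path}:{lineno}: {exc}") from exc
    return boxes


def write_labels(
    path: str | os.PathLike, boxes: Iterable[BBox], with_conf: bool = False
) -> None:
    """Write boxes in the YOLO dialect, 6-decimal fixed point."""
    with open(path, "w") as fh:
        for b in boxes:
            line = f"{b.cls} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}"
            if with_conf:
                line += f" {b.conf:.6f}"
            fh.write(line + "\n")


def to_pixels(
    b: BBox, width: int, height: int
) -> tuple[int, int, int, int]:
    """Convert a normalized box to a half-open pixel rectangle (x0, y0, x1, y1).

    The rectangle is clipped to the image bounds.
    """
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be >= 1")
    x0 = int(round((b.cx - b.w / 2) * width))
    x1 = int(round((b.cx + b.w / 2) * width))
    y0 = int(round((b.cy - b.h / 2) * height))
    y1 = int(round((b.cy + b.h / 2) * height))
    x0, x1 = max(0, x0), min(width, x1)
    y0, y1 = max(0, y0), min(height, y1)
    return x0, y0, x1, y1


def from_pixels(
    rect: tuple[float, float, float, float],
    width: int,
    height: int,
    cls: int = 0,
    conf: float = 1.0,
) -> BBox:
    """Convert a half-open pixel rectangle (x0, y0, x1, y1) to a normalized box."""
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be >= 1")
    x0, y0, x1, y1 = rect
    return BBox(
        cls=cls,
        cx=(x0 + x1) / 2 / width,
        cy=(y0 + y1) / 2 / height,
        w=max(x1 - x0, 1e-9) / width,
        h=max(y1 - y0, 1e-9) / height,
        conf=conf,
    )


def read_class_map(path: str | os.PathLike) -> dict[int, str]:
    """Read a tab-separated ``id<TAB>name`` class-map file."""
    out: dict[int, str] = {}
    with open(path, "r") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            ident, name = line.split("\t")
            out[int(ident)] = name
    return out


def write_class_map(path: str | os.PathLike, class_map: dict[int, str]) -> None:
    with open(path, "w") as fh:
        for ident in sorted(class_map):
            fh.write(f"{ident}\t{class_map[ident]}\n")


def split_dataset(
    items: Sequence,
    ratio: tuple[int, int, int] = (8, 1, 1),
    seed: int = 0,
) -> DatasetSplit:
    """Shuffle ``items`` by ``seed`` and partition by ``ratio``.

    Subset sizes use largest-remainder rounding: each subset gets
    ``floor(|items| * r_i / sum(r))`` items, and the leftover items go to
    the subsets with the largest fractional remainders (ties broken by
    subset order train, val, test).  Deterministic per seed.
    """
    if len(items) < 3:
        raise ValueError("need at least 3 items to split")
    total_ratio = sum(ratio)
    if total_ratio <= 0:
        raise ValueError("ratio must have positive total")
    n = len(items)
    exact = [n * r / total_ratio for r in ratio]
    sizes = [int(np.floor(e)) for e in exact]
    remainders = [e - s for e, s in zip(exact, sizes)]
    leftover = n - sum(sizes)
    # stable: larger remainder first, then subset order
    order = sorted(range(3), key=lambda i: (-remainders[i], i))
    for i in order[:leftover]:
        sizes[i] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    shuffled = [items[i] for i in perm]
    train = tuple(shuffled[: sizes[0]])
    val = tuple(shuffled[sizes[0] : sizes[0] + sizes[1]])
    test = tuple(shuffled[sizes[0] + sizes[1] :])
    return DatasetSplit(train=train, val=val, test=test)


def write_split(split: DatasetSplit, out_dir: str | os.PathLike) -> None:
    """Write ``train.txt``, ``val.txt`` and ``test.txt`` list files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("train", "val", "test"):
        with open(out / f"{name}.txt", "w") as fh:
            for item in getattr(split, name):
                fh.write(f"{item}\n")
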