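"""Optional learned-model detection backends.

The core pipeline only needs the :class:`~pigtag.detect.DetectorBackend`
contract (``detect(image) -> [BBox]``), so a trained model can replace
the classical reference detector for any role.  This module wraps
``ultralytics`` YOLO models behind that contract.  The dependency is
imported lazily inside the factory — importing :mod:`pigtag` or running
the reference pipeline never requires it.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .annotations_io import BBox
from .detect import ROLES, DetectorBackend, DetectorConfig

__all__ = ["make_ultralytics_backend", "make_ultralytics_backends"]


def make_ultralytics_backend(
    weights_path: str,
    role: str,
    cfg: DetectorConfig | None = None,
) -> DetectorBackend:
    """Wrap one ultralytics YOLO model as a backend for ``role``.

    Raises ImportError when the optional ``ultralytics`` package is not
    installed.
    """
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
    from ultralytics import YOLO  # deferred optional import

    cfg = cfg or DetectorConfig()
    model = YOLO(weights_path)
    class_names = tuple(model.names[k] for k in sorted(model.names))

    def detect(image: np.ndarray) -> list[BBox]:
        img = np.asarray(image)
        if img.ndim == 2:  # models expect 3-channel input
            img = np.stack([img] * 3, axis=-1)
        h, w = img.shape[:2]
        results = model.predict(
            img.astype(np.uint8), conf=cfg.conf_threshold, iou=cfg.iou_suppress,
            verbose=False,
        )
        boxes: list[BBox] = []
        for res in results:
            for xyxy, cls, conf in zip(
                res.boxes.xyxy.tolist(),
                res.boxes.cls.tolist(),
                res.boxes.conf.tolist(),
            ):
                x0, y0, x1, y1 = xyxy
                boxes.append(BBox(
                    cls=int(cls),
                    cx=(x0 + x1) / 2 / w,
                    cy=(y0 + y1) / 2 / h,
                    w=max(x1 - x0, 1e-9) / w,
                    h=max(y1 - y0, 1e-9) / h,
                    conf=float(conf),
                ))
        return boxes

    return DetectorBackend(name=f"ultralytics-{role}", class_names=class_names,
                           detect=detect)


def make_ultralytics_backends(
    weights: Mapping[str, str],
    cfg: DetectorConfig | None = None,
) -> dict[str, DetectorBackend]:
    """Backends for several roles from a role -> weights-path mapping."""
    return {role: make_ultralytics_backend(path, role, cfg)
            for role, path in weights.items()}
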