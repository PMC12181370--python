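"""Lighting-robustness image variants: under/overexposure and retinex.

Underexposure scales pixel values by a factor drawn from (0.4, 0.6),
overexposure amplifies by a factor from (1.1, 1.3), and single-scale
retinex (SSR) compares the logarithm of the image against the logarithm
of its Gaussian-blurred counterpart, normalizing uneven illumination
while preserving structure.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["LightingSpec", "expose", "single_scale_retinex", "perturb_dataset"]

UNDER_RANGE = (0.4, 0.6)
OVER_RANGE = (1.1, 1.3)
DEFAULT_SSR_SIGMA = 80.0


@dataclasses.dataclass(frozen=True)
class LightingSpec:
    """One perturbation mode with its draw range and seed."""

    mode: str  # under | over | ssr
    factor_range: tuple[float, float] | None = None
    ssr_sigma: float = DEFAULT_SSR_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("under", "over", "ssr"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.factor_range is None:
            default = {"under": UNDER_RANGE, "over": OVER_RANGE, "ssr": None}[self.mode]
            object.__setattr__(self, "factor_range", default)
        if self.factor_range is not None and self.factor_range[0] > self.factor_range[1]:
            raise ValueError("factor_range must satisfy lo <= hi")
        if self.ssr_sigma <= 0:
            raise ValueError("ssr_sigma must be > 0")


def expose(image: np.ndarray, factor: float) -> np.ndarray:
    """Multiply intensities by ``factor``, round half-to-even, clip to [0, 255]."""
    if factor <= 0:
        raise ValueError("factor must be > 0")
    out = np.rint(np.asarray(image, dtype=np.float64) * factor)
    return np.clip(out, 0, 255).astype(np.uint8)


def single_scale_retinex(image: np.ndarray, sigma: float = DEFAULT_SSR_SIGMA) -> np.ndarray:
    """SSR: R = log(I + 1) - log(G_sigma(I) + 1), min-max rescaled to [0, 255].

    Computed in floating point with reflective boundary handling.  A
    constant input has R identically zero, which rescales to all zeros.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    r = ssr_response(image, sigma)
    lo, hi = r.min(), r.max()
    if hi - lo < 1e-12:
        return np.zeros(r.shape, dtype=np.uint8)
    scaled = (r - lo) / (hi - lo) * 255.0
    return np.clip(np.rint(scaled), 0, 255).astype(np.uint8)


def ssr_response(image: np.ndarray, sigma: float) -> np.ndarray:
    """Pre-rescale retinex response (float), for numeric checks."""
    img = np.asarray(image, dtype=np.float64)
    blurred = gaussian_filter(img, sigma=sigma, mode="reflect")
    return np.log(img + 1.0) - np.log(blurred + 1.0)


def perturb_dataset(
    in_dir: str | os.PathLike,
    out_dir: str | os.PathLike,
    spec: LightingSpec,
) -> list[tuple[str, str, float]]:
    """Perturb every image in ``in_dir`` per ``spec``; copy labels unchanged.

    Each image gets one factor drawn uniformly from the mode's range (SSR
    applies the filter instead).  Writes an assignment log
    ``filename<TAB>mode<TAB>factor`` as ``augment_log.tsv`` and returns
    the same records.  Deterministic per seed.
    """
    src = Path(in_dir)
    dst = Path(out_dir)
    dst.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    log: list[tuple[str, str, float]] = []
    images = sorted(p for p in src.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    for path in images:
        img = iio.imread(path)
        if spec.mode == "ssr":
            out = single_scale_retinex(img, spec.ssr_sigma)
            factor = float(spec.ssr_sigma)
        else:
            factor = float(rng.uniform(*spec.factor_range))
            out = expose(img, factor)
        iio.imwrite(dst / path.name, out)
        label = path.with_suffix(".txt")
        if label.exists():
            (dst / label.name).write_text(label.read_text())
        log.append((path.name, spec.mode, factor))
    with open(dst / "augment_log.tsv", "w") as fh:
        for name, mode, factor in log:
            fh.write(f"{name}\t{mode}\t{factor:.6f}\n")
    return log
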