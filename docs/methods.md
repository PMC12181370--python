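# Methods

## Scene model

Scenes are 640×640 grayscale (uint8) renderings of a fixed intensity
palette: background 60 ± 8 uniform noise, pig body 120 ± 10, tag face
230, printed digit ink 30, fastener pin 0, occluder 150, letterbox fill
114. Pigs are non-overlapping rotated filled ellipses (semi-axes 80–100
× 48–62 px, seeded placement with bounded retries; impossible
placements raise an error naming the seed). Each pig optionally carries
one ear tag: a rounded-rectangle face (64×44 px at unit scale) with a
dark pin disc (radius 4, centered at (32, 7) on the local "up" axis)
and two digit glyphs in 14×22 cells, rotated about the tag center by a
per-tag angle drawn from `rotation_range`.

Digits use a bundled seven-segment-style stroke font drawn with pure
numpy rectangle fills, so rendering is bit-identical across platforms.
IDs are two digits (10–99), drawn without replacement per scene while
the pool lasts.

**Coordinate convention.** All geometry lives in continuous pixel
coordinates where pixel `i` covers `[i, i+1)` with center `i + 0.5`;
boxes are half-open. The renderer evaluates every analytic shape (pig
ellipse, tag face, pin disc) at pixel centers after inverse-rotating
them to local tag coordinates, so the painted raster is the exact
discretization of the rotated geometry and agrees with the reported
ground truth (boxes, pin point, rotation angle) with no half-pixel
offset. This alignment is what lets the pin-based rotation estimate
reach sub-degree accuracy (see below).

**Corruptions** (applied in order): occlusion (centered gray rectangle
covering a fraction of each tag's area), horizontal motion blur (length
`motion_blur_px` uniform filter), pixelation (bilinear downsample +
nearest upsample by `pixelation_factor`), exposure (multiplicative
intensity scale, clipped to [0, 255]).

## Identification cascade

Per frame: grayscale conversion (BT.601 luma) and aspect-preserving
letterboxing to 640×640 (fill 114); pig detection; per-pig crop to
640×640; tag detection; per-tag crop to 320×320; pin detection;
rotation rectification; digit detection on the rectified crop resized
to 120×120; left-to-right assembly into a two-digit proposal.

Crops are sampled at sub-pixel precision (bilinear, via an exact affine
through `scipy.ndimage.map_coordinates`) so the box center lands
exactly on the crop center — the rotation formula assumes the tag's
rotation center is the crop center. Every crop records its affine back
to frame coordinates, so proposals report tag boxes in the original
frame.

**Rotation.** With crop size W×H, crop center c0 = (W/2, H/2), pin
center c1, and target c2 = (W/2, 0), the rotation bringing c1 as close
as possible to c2 about c0 is closed-form: θ = atan2(vx, −vy) with
v = c1 − c0 (positive = counter-clockwise on screen, y down). The
residual D = | ‖v‖ − H/2 | is reported; ‖v‖ < 1 % · min(W, H) is
degenerate (rotation cannot change D) and returns angle 0. On clean
rendered tag crops (cut on the ground-truth tag box at 320×320), the
estimated angle matches the negative of the true tag rotation within
1° (measured max 0.85°, mean 0.25° over 100 scenes); through the full
detection cascade the integer component bounds of the *detected* tag
box add up to ~2°, which does not affect digit reading.

**Reference detector.** Deterministic and classical: pig and tag roles
threshold bright regions (92 / 180) with hole filling and area/fill
gates; the pin role takes dark components (< 90) whose darkest pixel is
near-black (< 18, separating the fastener from printed ink) with
disc-like fill and aspect, and reports a sub-pixel landmark via the
component centroid. Digit components are classified by normalized
cross-correlation of the **inverted grayscale patch** (not a
re-binarized mask — binarizing a motion-smeared glyph manufactures a
spuriously crisp shape that correlates too well) against the bundled
glyph templates, height-normalized to the template cell (all glyphs
span the full cell height, so one scale suffices). Gates: component
aspect must be near the glyph *ink* aspect, and a class-"1" claim must
fill ≥ 0.42 of its bbox (diagonal smear streaks correlate with the bar
but are far less solid).

**Verification.** An assembled ID is accepted only if the two digit
components pass a glyph-integrity check on the rectified crop: their
ink heights agree within ratio 0.85 (one printed row), and together
they explain ≥ 85 % of all non-fastener ink (leftover ink means a
glyph fragmented, typically under motion smear, and the read is
untrustworthy). Failing proposals become `low_confidence` rejections.
Duplicate IDs within a frame keep the highest-confidence proposal. A
proposal's confidence is the minimum digit confidence.

## Evaluation

- **Matching** is greedy Pascal-VOC style: predictions in descending
  confidence, each matched to the unmatched ground truth of maximal
  IoU ≥ threshold.
- **PR curves** have one point per distinct confidence (cumulative
  counts), recall non-increasing in the threshold.
- **Average precision** is the literal sum
  Σₖ (R(k) − R(k+1)) · P(k) with sentinel R(m) = 0, verified against
  independent brute-force threshold enumeration to 1e-9. mAP averages
  classes at IoU 0.50 and over 0.50:0.95 in steps of 0.05.
- **Use-case counting** compares the predicted and true ID multisets
  per frame (Counter intersection); precision = TP/(TP+FP),
  recall = TP/(TP+FN). Per-ID reports add detection frequency and the
  average gap between consecutive frames containing the ID.

## Lighting

Exposure perturbation multiplies intensities by a seeded per-image
factor: under-exposure U(0.4, 0.6), over-exposure U(1.1, 1.3), clipped
to [0, 255]. The single-scale retinex response is
log(I + 1) − log(G_σ(I) + 1) with a Gaussian surround (σ default 80,
`scipy.ndimage.gaussian_filter`, reflective boundaries, truncation 4.0
→ radius int(4σ + 0.5)), optionally min–max rescaled; it is exactly
zero (pre-rescale) on constant input and matches a direct separable
spatial convolution to better than 1e-3.

## Dataset tooling

YOLO-dialect labels (`cls cx cy w h [conf]`, 6 decimals, normalized,
one file per image), a combined class layout (pig, tag, pin, digits
0–9), SHA-256 dataset checksums over the manifest plus image bytes,
and a seeded largest-remainder 8:1:1 split (e.g. 9281 items →
7425/928/928; fewer than 3 items refuse to split).

## Problem sizes and limitations

- Rendering costs ~13 ms per scene; the full cascade ~0.3 s per scene.
  The test suite (~165 tests) runs in ~90 s; the acceptance script
  in ~50 s.
- The corruption-monotonicity unit test checks blur levels {0, 3, 7,
  15} over 30 scenes per level as a runtime compromise; the acceptance
  suite exercises 100 scenes per condition for clean vs blur-7.
- The reference detector is exact only for the synthetic palette; real
  footage requires learned backends via the adapter
  (`pigtag.adapters.make_ultralytics_backend`), which any
  `detect(image) -> [BBox]` implementation can replace.
- Motion blur ≥ 7 px fragments glyphs beyond reliable reading; the
  design goal under heavy blur is precision of emitted IDs (measured
  ≥ 0.95 at blur 7), accepting a steep recall drop (~0.2).
- All seeds are < 2³¹; per-study streams are spawned from a single
  `numpy.random.SeedSequence`, so every reported number is reproducible
  bit-for-bit.
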