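"""Command-line entry point tying the modules into one workflow.

Subcommands: ``synth`` (render a labeled synthetic dataset), ``identify``
(run the four-stage cascade over a directory of frames), ``augment``
(lighting-robustness variants), ``evaluate`` (detection or ID-level
metrics) and ``split`` (8:1:1 dataset splitting).

Options may come from a flat key-value YAML config file; explicit
command-line flags win.  Every run writes a ``run_manifest.json`` beside
its outputs (config snapshot, seed, versions) so it can be replayed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from pathlib import Path

import click
import imageio.v3 as iio
import numpy as np
import yaml

from . import __version__
from . import annotations_io as aio
from . import evalmetrics, identify, lighting, scene_synth
from .detect import DetectorConfig, make_reference_backends

logger = logging.getLogger("pigtag")


def _setup_logging(verbose: int) -> None:
    level = logging.WARNING - 10 * min(verbose, 2)
    logging.basicConfig(stream=sys.stderr, level=level,
                        format="%(levelname)s %(name)s: %(message)s")


def _load_config(path: str | None) -> dict:
    if not path:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise click.UsageError("config file must be a flat key-value mapping")
    return cfg


def _write_manifest(out_dir: Path, subcommand: str, params: dict) -> None:
    import scipy
    import skimage

    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "subcommand": subcommand,
        "params": params,
        "versions": {
            "pigtag": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


@click.group()
@click.option("-v", "--verbose", count=True, help="Increase log verbosity.")
def main(verbose: int) -> None:
    """Sequential ear-tag identification pipeline for pigs."""
    _setup_logging(verbose)


@main.command()
@click.option("--n", "n_scenes", type=int, default=10, show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--n-pigs", type=int, default=3, show_default=True)
@click.option("--motion-blur", type=int, default=0, show_default=True)
@click.option("--pixelation", type=float, default=1.0, show_default=True)
@click.option("--occlusion", type=float, default=0.0, show_default=True)
@click.option("--exposure", type=float, default=1.0, show_default=True)
@click.option("--overwrite", is_flag=True)
def synth(n_scenes, seed, out_dir, n_pigs, motion_blur, pixelation,
          occlusion, exposure, overwrite) -> None:
    """Render a synthetic labeled dataset of pen scenes."""
    spec = scene_synth.SceneSpec(
        n_pigs=n_pigs,
        seed=seed,
        corruption=scene_synth.CorruptionSpec(
            motion_blur_px=motion_blur,
            pixelation_factor=pixelation,
            occlusion_fraction=occlusion,
            exposure_factor=exposure,
        ),
    )
    manifest = scene_synth.generate_dataset(spec, n_scenes, out_dir, overwrite=overwrite)
    _write_manifest(Path(out_dir), "synth", {
        "n": n_scenes, "seed": seed, "spec": dataclasses.asdict(spec)})
    click.echo(f"wrote {len(manifest)} scenes to {out_dir}")


@main.command("identify")
@click.option("--frames", "frames_dir", type=click.Path(exists=True), required=True)
@click.option("--backend", default="reference", show_default=True)
@click.option("--config", "config_path", type=click.Path(exists=True), default=None)
@click.option("--out", "out_path", type=click.Path(), required=True)
def identify_cmd(frames_dir, backend, config_path, out_path) -> None:
    """Run the four-stage cascade over a directory of frames."""
    cfg_file = _load_config(config_path)
    backend = cfg_file.get("backend", backend)
    if backend != "reference":
        raise click.UsageError(f"unknown backend {backend!r} (only 'reference' is bundled)")
    det_cfg = DetectorConfig(
        conf_threshold=float(cfg_file.get("conf_threshold", 0.25)),
        iou_suppress=float(cfg_file.get("iou_suppress", 0.5)),
    )
    paths = sorted(
        p for p in Path(frames_dir).iterdir()
        if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not paths:
        raise click.UsageError(f"no image frames found in {frames_dir}")
    frames = [iio.imread(p) for p in paths]
    shapes = [f.shape[:2] for f in frames]
    results = identify.run_pipeline(
        frames,
        make_reference_backends(det_cfg),
        det_cfg,
        out_size_pig=int(cfg_file.get("out_size_pig", identify.OUT_SIZE_PIG)),
        out_size_tag=int(cfg_file.get("out_size_tag", identify.OUT_SIZE_TAG)),
    )
    identify.write_results_tsv(results, out_path, frame_shapes=shapes)
    _write_manifest(Path(out_path).parent, "identify", {
        "frames": str(frames_dir), "backend": backend,
        "conf_threshold": det_cfg.conf_threshold,
        "iou_suppress": det_cfg.iou_suppress,
        "n_frames": len(paths)})
    n_props = sum(len(r.proposals) for r in results)
    click.echo(f"{len(paths)} frames, {n_props} ID proposals -> {out_path}")


@main.command()
@click.option("--mode", type=click.Choice(["under", "over", "ssr"]), required=True)
@click.option("--in", "in_dir", type=click.Path(exists=True), required=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--sigma", type=float, default=lighting.DEFAULT_SSR_SIGMA, show_default=True)
def augment(mode, in_dir, out_dir, seed, sigma) -> None:
    """Write lighting-perturbed copies of a dataset."""
    spec = lighting.LightingSpec(mode=mode, ssr_sigma=sigma, seed=seed)
    log = lighting.perturb_dataset(in_dir, out_dir, spec)
    _write_manifest(Path(out_dir), "augment", {
        "mode": mode, "seed": seed, "sigma": sigma, "n_images": len(log)})
    click.echo(f"perturbed {len(log)} images ({mode}) -> {out_dir}")


@main.command()
@click.option("--pred", "pred_path", type=click.Path(exists=True), required=True)
@click.option("--truth", "truth_dir", type=click.Path(exists=True), required=True)
@click.option("--mode", type=click.Choice(["detection", "usecase"]), required=True)
@click.option("--out", "out_path", type=click.Path(), required=True)
def evaluate(pred_path, truth_dir, mode, out_path) -> None:
    """Score predictions against ground truth labels."""
    if mode == "usecase":
        report = _evaluate_usecase(Path(pred_path), Path(truth_dir))
    else:
        report = _evaluate_detection(Path(pred_path), Path(truth_dir))
    with open(out_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    _write_manifest(Path(out_path).parent, "evaluate", {
        "pred": str(pred_path), "truth": str(truth_dir), "mode": mode})
    click.echo(json.dumps({k: v for k, v in report.items() if not isinstance(v, dict)},
                          sort_keys=True))


def _read_results_tsv(path: Path) -> dict[int, list[str]]:
    out: dict[int, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            frame, id_str = line.split("\t")[:2]
            out.setdefault(int(frame), []).append(id_str)
    return out


def _evaluate_usecase(pred_path: Path, truth_dir: Path) -> dict:
    preds = _read_results_tsv(pred_path)
    truth_file = truth_dir / "ids.tsv"
    if not truth_file.exists():
        raise click.UsageError(f"usecase mode needs {truth_file} (frame<TAB>ids)")
    truths: dict[int, list[str]] = {}
    with open(truth_file) as fh:
        for line in fh:
            parts = line.split()
            truths[int(parts[0])] = parts[1:]
    frames = sorted(truths)
    counts = evalmetrics.usecase_counts(
        [preds.get(f, []) for f in frames],
        [truths[f] for f in frames],
    )
    per_id_frames: dict[str, list[int]] = {}
    for f in frames:
        for id_ in preds.get(f, []):
            per_id_frames.setdefault(id_, []).append(f)
    gaps = evalmetrics.frame_gap_table(per_id_frames)
    return {
        "tp": counts.tp, "fp": counts.fp, "fn": counts.fn,
        "precision": evalmetrics.precision(counts),
        "recall": evalmetrics.recall(counts),
        "per_id": {k: {"frequency": f, "avg_frame_gap": g} for k, (f, g) in gaps.items()},
    }


def _evaluate_detection(pred_dir: Path, truth_dir: Path) -> dict:
    preds, truths = [], []
    for tf in sorted(truth_dir.glob("*.txt")):
        if tf.name in ("ids.tsv",):
            continue
        truths.extend(aio.read_labels(tf, n_cols=5))
        pf = pred_dir / tf.name if pred_dir.is_dir() else pred_dir
        if pf.exists():
            preds.extend(aio.read_labels(pf, n_cols=6))
    res = evalmetrics.mean_ap(preds, truths)
    return {
        "map50": res.map50,
        "map50_95": res.map50_95,
        "per_class_ap": {str(k): v for k, v in res.per_class_ap.items()},
    }


@main.command()
@click.option("--items", "items_path", type=click.Path(exists=True), required=True,
              help="Directory of items or a text file listing one item per line.")
@click.option("--ratio", default="8:1:1", show_default=True)
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_dir", type=click.Path(), required=True)
def split(items_path, ratio, seed, out_dir) -> None:
    """Split items 8:1:1 into train/val/test list files."""
    p = Path(items_path)
    if p.is_dir():
        items = sorted(f.name for f in p.iterdir() if f.suffix.lower() == ".png")
    else:
        items = [line.strip() for line in p.read_text().splitlines() if line.strip()]
    parts = tuple(int(x) for x in ratio.split(":"))
    if len(parts) != 3:
        raise click.UsageError("ratio must look like 8:1:1")
    ds = aio.split_dataset(items, ratio=parts, seed=seed)
    aio.write_split(ds, out_dir)
    _write_manifest(Path(out_dir), "split", {
        "items": str(items_path), "ratio": ratio, "seed": seed,
        "sizes": list(ds.sizes)})
    click.echo(f"split sizes: {ds.sizes}")


if __name__ == "__main__":
    main()
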