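"""End-to-end orchestration: simulate -> train -> infer -> postprocess -> score.

Also provides the training-free Gabor baseline (ridge enhancement +
adaptive thresholding + star-convex splitting) and a seeded synthetic
benchmark that emits a median-F1 report per enabled method.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from . import core, evalmetrics, postprocess, preprocess, simgen

log = logging.getLogger("cyclecell")


# ---------------------------------------------------------------------------
# Configuration


@dataclass
class SimParams:
    shape: tuple = (256, 256)
    n_islands: int = 2
    density: float = 0.0045
    min_distance: float = 10.0
    membrane_width: int = 3
    n_samples: int = 400
    noise: dict = field(default_factory=lambda: dataclasses.asdict(simgen.NoiseParams()))


@dataclass
class PostprocessParams:
    threshold: float = 0.5
    min_alpha: float = 12.0
    max_hole_area: int = 40
    expected_radius: float = 8.0
    layer: str = "SS"
    backend: str = "fallback"


@dataclass
class MetricParams:
    d: float = 10.0


@dataclass
class PipelineConfig:
    """One configuration object for every stage; round-trips through YAML."""

    input_dir: Optional[str] = None
    output_dir: str = "cyclecell_out"
    rng_seed: int = 0
    sim: SimParams = field(default_factory=SimParams)
    gan: core.GanConfig = field(default_factory=core.desk_config)
    post: PostprocessParams = field(default_factory=PostprocessParams)
    metric: MetricParams = field(default_factory=MetricParams)
    roi: bool = True
    enhance_mode: str = "gabor"

    def to_yaml(self, path=None) -> str:
        def conv(obj):
            if dataclasses.is_dataclass(obj):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        text = yaml.safe_dump(conv(self), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        is_path = isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source)
        if is_path and Path(source).exists():
            data = yaml.safe_load(Path(source).read_text())
        else:
            data = yaml.safe_load(source)
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sim = SimParams(**{**data.pop("sim", {})})
        sim.shape = tuple(sim.shape)
        gan = core.GanConfig(**data.pop("gan", {}))
        post = PostprocessParams(**data.pop("post", {}))
        metric = MetricParams(**data.pop("metric", {}))
        return cls(sim=sim, gan=gan, post=post, metric=metric, **data)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.time()
            out = fn(*args, **kwargs)
            log.info("stage=%s wall_s=%.2f", name, time.time() - t0)
            return out

        return wrapper

    return deco


# ---------------------------------------------------------------------------
# Synthetic pools


def make_training_pools(cfg: PipelineConfig, n_rcm: int, n_gabor: int,
                        n_binary: int, shape=None):
    """Generate the three unpaired training pools from the simulator.

    Domain A: noisy renderings, locally normalised; domain C: the same kind
    of renderings, membrane-enhanced; domain B: clean binary membranes. The
    pools are unpaired by construction (distinct per-sample seeds).
    """
    shape = shape or tuple(cfg.sim.shape)
    noise = simgen.NoiseParams(**cfg.sim.noise)
    n_islands = cfg.sim.n_islands if min(shape) >= 128 else 1
    base = cfg.rng_seed

    def sample(idx):
        return simgen.generate_training_sample(
            shape=shape, n_islands=n_islands, density=cfg.sim.density,
            min_distance=cfg.sim.min_distance,
            membrane_width=cfg.sim.membrane_width, rng_seed=base, index=idx)

    rcm, gabor, binary = [], [], []
    idx = 0
    for _ in range(n_rcm):
        s = sample(idx)
        img = simgen.render_synthetic_rcm(s, noise, rng_seed=base + 7919 + idx)
        rcm.append(preprocess.local_normalize(img))
        idx += 1
    for _ in range(n_gabor):
        s = sample(idx)
        img = simgen.render_synthetic_rcm(s, noise, rng_seed=base + 7919 + idx)
        gabor.append(preprocess.enhance_membranes(img, mode=cfg.enhance_mode))
        idx += 1
    for _ in range(n_binary):
        s = sample(idx)
        binary.append(s.binary.astype(np.float64))
        idx += 1
    return rcm, gabor, binary


def make_validation_set(cfg: PipelineConfig, n_images: int, shape=None):
    """Held-out renderings with their true cell centers."""
    shape = shape or tuple(cfg.sim.shape)
    noise = simgen.NoiseParams(**cfg.sim.noise)
    n_islands = cfg.sim.n_islands if min(shape) >= 128 else 1
    base = cfg.rng_seed + 104729  # offset the validation stream
    images, centers = [], []
    for i in range(n_images):
        s = simgen.generate_training_sample(
            shape=shape, n_islands=n_islands, density=cfg.sim.density,
            min_distance=cfg.sim.min_distance,
            membrane_width=cfg.sim.membrane_width, rng_seed=base, index=i)
        img = simgen.render_synthetic_rcm(s, noise, rng_seed=base + i)
        images.append(preprocess.local_normalize(img))
        centers.append(s.centers.points)
    return images, centers


# ---------------------------------------------------------------------------
# Inference chains


def postprocess_chain(prob_map: np.ndarray, post: PostprocessParams):
    """threshold -> close contour -> fill holes -> split -> area filter."""
    binary = np.asarray(prob_map) >= post.threshold
    closed = postprocess.close_tissue_contour(binary, min_alpha=post.min_alpha)
    filled = postprocess.fill_small_holes(closed, post.max_hole_area)
    labels = postprocess.split_star_convex(
        filled, backend=post.backend, expected_radius=post.expected_radius)
    labels = postprocess.filter_by_area(labels, post.layer)
    return labels


def infer_and_extract_centers(image: np.ndarray, nets: core.NetworkSet,
                              post: Optional[PostprocessParams] = None,
                              layer: Optional[str] = None):
    post = post or PostprocessParams()
    if layer is not None:
        post = dataclasses.replace(post, layer=layer)
    prob = core.infer_binary(np.asarray(image, dtype=np.float64), nets)
    labels = postprocess_chain(prob, post)
    return postprocess.labels_to_centers(labels).points


@_stage("run_dual_cyclegan")
def run_dual_cyclegan(cfg: PipelineConfig, images: Sequence[np.ndarray],
                      nets: core.NetworkSet, save_dir: Optional[str] = None):
    """Full detection chain per image; returns (centers, labels) lists.

    Images larger than the model input size are covered with overlapping
    tiles (stride half a patch) whose probability maps are averaged.
    """
    size = nets.cfg.image_size
    all_centers, all_labels = [], []
    for i, raw in enumerate(images):
        img = np.asarray(raw, dtype=np.float64)
        if cfg.roi:
            roi = preprocess.extract_roi(img)
            img = img * roi.mask
        norm = preprocess.local_normalize(img)
        if norm.shape == (size, size):
            prob = core.infer_binary(norm, nets)
        else:
            tiles = preprocess.tile_for_inference(norm, size, size // 2)
            probs = [(core.infer_binary(t, nets), off) for t, off in tiles]
            prob, _ = preprocess.stitch_patches(probs, norm.shape)
        labels = postprocess_chain(prob, cfg.post)
        centers = postprocess.labels_to_centers(labels)
        all_centers.append(centers.points)
        all_labels.append(labels)
        if save_dir is not None:
            _save_outputs(save_dir, i, centers.points, labels)
    return all_centers, all_labels


@_stage("run_baseline_gabor")
def run_baseline_gabor(cfg: PipelineConfig, images: Sequence[np.ndarray],
                       save_dir: Optional[str] = None):
    """Training-free baseline: ROI -> Gabor -> adaptive threshold -> split."""
    all_centers = []
    for i, raw in enumerate(images):
        img = np.asarray(raw, dtype=np.float64)
        if cfg.roi:
            roi = preprocess.extract_roi(img)
            img = img * roi.mask
        enhanced = preprocess.enhance_membranes(img, mode="gabor")
        binary = preprocess.binarize_enhanced(enhanced)
        labels = postprocess.split_star_convex(
            binary, backend=cfg.post.backend,
            expected_radius=cfg.post.expected_radius)
        labels = postprocess.filter_by_area(labels, cfg.post.layer)
        centers = postprocess.labels_to_centers(labels)
        all_centers.append(centers.points)
        if save_dir is not None:
            _save_outputs(save_dir, i, centers.points, labels)
    return all_centers


def _save_outputs(save_dir, index, centers, labels):
    import pandas as pd
    import tifffile

    out = Path(save_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(centers, columns=["row", "col"]).to_csv(
        out / f"image_{index:04d}_centers.csv", index=False)
    tifffile.imwrite(out / f"image_{index:04d}_labels.tif",
                     labels.labels.astype(np.uint16))


# ---------------------------------------------------------------------------
# Benchmark


def _dropout_recovery_f1(cfg: PipelineConfig, n_replicates: int,
                         dropout: float = 0.2):
    results = []
    for rep in range(n_replicates):
        s = simgen.generate_training_sample(
            shape=tuple(cfg.sim.shape), n_islands=cfg.sim.n_islands,
            density=cfg.sim.density, min_distance=cfg.sim.min_distance,
            membrane_width=cfg.sim.membrane_width,
            rng_seed=cfg.rng_seed + 31337, index=rep)
        rng = simgen.sample_rng(cfg.rng_seed + 31337, 1000 + rep)
        binary = s.binary.copy()
        fg = np.argwhere(binary)
        drop = fg[rng.random(len(fg)) < dropout]
        binary[drop[:, 0], drop[:, 1]] = False
        labels = postprocess_chain(binary.astype(float), cfg.post)
        pred = postprocess.labels_to_centers(labels)
        results.append(evalmetrics.match_detections(
            pred, s.centers.points, d=cfg.metric.d))
    return evalmetrics.summarize_images(results)


@_stage("run_synthetic_benchmark")
def run_synthetic_benchmark(cfg: PipelineConfig, methods=("postprocess_only",),
                            n_images: int = 10,
                            nets: Optional[core.NetworkSet] = None) -> dict:
    """Seeded synthetic benchmark; one median-F1 row per enabled method.

    ``postprocess_only`` degrades simulator membranes with 20% random pixel
    dropout and scores the post-processing chain alone; ``baseline`` runs the
    Gabor pipeline on noisy renderings; ``dual_cyclegan`` scores a supplied
    trained model on held-out renderings.
    """
    report = {"seed": cfg.rng_seed, "d": cfg.metric.d, "methods": {}}
    for method in methods:
        if method == "postprocess_only":
            summary = _dropout_recovery_f1(cfg, n_replicates=n_images)
        elif method == "baseline":
            size = tuple(cfg.sim.shape)
            images, centers = make_validation_set(cfg, n_images, shape=size)
            # baseline consumes raw renderings, not normalised ones
            noise = simgen.NoiseParams(**cfg.sim.noise)
            raw = []
            base = cfg.rng_seed + 104729
            for i in range(n_images):
                s = simgen.generate_training_sample(
                    shape=size, n_islands=cfg.sim.n_islands,
                    density=cfg.sim.density, min_distance=cfg.sim.min_distance,
                    membrane_width=cfg.sim.membrane_width, rng_seed=base, index=i)
                raw.append(simgen.render_synthetic_rcm(s, noise, rng_seed=base + i))
            preds = run_baseline_gabor(cfg, raw)
            results = [evalmetrics.match_detections(p, g, d=cfg.metric.d)
                       for p, g in zip(preds, centers)]
            summary = evalmetrics.summarize_images(results)
        elif method == "dual_cyclegan":
            if nets is None:
                raise ValueError("method 'dual_cyclegan' needs a trained NetworkSet")
            size = nets.cfg.image_size
            images, centers = make_validation_set(cfg, n_images, shape=(size, size))
            results = []
            for img, gt in zip(images, centers):
                pred = infer_and_extract_centers(img, nets, post=cfg.post)
                results.append(evalmetrics.match_detections(pred, gt, d=cfg.metric.d))
            summary = evalmetrics.summarize_images(results)
        else:
            raise ValueError(f"unknown benchmark method {method!r}")
        report["methods"][method] = {
            "median_f1": summary["median_f1"],
            "std_f1": summary["std_f1"],
            "n_images": summary["n_images"],
        }
    return report
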