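"""End-to-end orchestration: acquire frames, segment the slit, register
frame pairs, bundle-adjust, blend, evaluate.

The pipeline is offline by design: all pairwise registrations are collected
first and the global positions are solved in one least-squares pass.  Every
stage communicates through documented artifacts (mask PNGs, edge CSV,
position CSV, mosaic PNG, evaluation JSON), and all randomness flows from
one top-level seed split deterministically per stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import blend, evaluate, graph, register, segment, simulate
from .core import Frame

__all__ = ["PipelineConfig", "PipelineResult", "read_frames", "run"]

logger = logging.getLogger("slitmosaic")

_IMAGE_EXTS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}

#: frames whose predicted foreground covers less than this fraction of the
#: image are dropped before registration — they cannot yield 6 inliers and
#: only waste matching time
MIN_FOREGROUND_FRACTION = 0.01


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run.

    Registration and boosting defaults are the method's operating point:
    RANSAC with 100 iterations and a 3 px margin, at least 6 inlier
    correspondences per accepted pair, boosting with 200 rounds, shrinkage
    0.1, row subsample 0.5, depth-3 trees, frames downscaled 4x.
    """

    # input: a frame directory / video file, or a simulator preset
    input: str | None = None
    simulate_preset: str | None = None  # "sweep" | "loop" | "static"
    n_frames: int = 40
    step: float = 8.0
    scene: dict = field(default_factory=dict)  # SceneSpec overrides
    stride: int = 1

    # segmentation
    segmenter: str = "learned"  # "learned" | "baseline"
    model_path: str | None = None  # pre-trained model for real footage
    scenario: str = "B"
    threshold: float = 0.5
    smoothing_scale: float = 2.0
    train_frames: int = 12  # simulator-training sequence length
    boost_rounds: int = 200
    shrinkage: float = 0.1
    subsample: float = 0.5
    max_depth: int = 3
    downscale: int = 4

    # registration / adjustment
    window: int | None = None  # None = all pairs
    ransac_iters: int = 100
    ransac_margin_px: float = 3.0
    min_inliers: int = 6
    anchor: int = 0
    weight_by_inliers: bool = False

    # blending
    compositor: str = "feather"

    outdir: str = "mosaic_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def boosting_config(self, seed: int) -> segment.BoostingConfig:
        return segment.BoostingConfig(
            rounds=self.boost_rounds,
            shrinkage=self.shrinkage,
            subsample=self.subsample,
            max_depth=self.max_depth,
            downscale_factor=self.downscale,
            seed=seed,
        )


@dataclass
class PipelineResult:
    frames: list[Frame]
    masks: list
    edges: list
    pose_graph: graph.PoseGraph | None
    canvas: blend.MosaicCanvas | None
    report: dict
    truth: simulate.SyntheticSequence | None = None


def read_frames(source: str | Path, stride: int = 1) -> list[Frame]:
    """Load an ordered frame sequence from a directory of numbered images
    or a video container; RGB only, normalized to [0, 1]."""
    import imageio.v3 as iio

    source = Path(source)
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if source.is_dir():
        paths = sorted(
            p for p in source.iterdir() if p.suffix.lower() in _IMAGE_EXTS
        )
        if not paths:
            raise ValueError(f"no image files found in {source}")
        arrays = [iio.imread(p) for p in paths[::stride]]
        names = [p.name for p in paths[::stride]]
    elif source.is_file():
        try:
            arrays = list(iio.imiter(source))
        except Exception as exc:  # pragma: no cover - codec availability
            raise ValueError(f"cannot read video container {source}: {exc}") from exc
        arrays = arrays[::stride]
        names = [f"{source.name}[{k}]" for k in range(len(arrays))]
    else:
        raise ValueError(f"input {source} does not exist")

    frames = []
    for k, (arr, name) in enumerate(zip(arrays, names)):
        if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] == 1):
            raise ValueError(
                f"{name}: grayscale input is unsupported; the segmentation "
                "features and the r - 0.7 g baseline need three color channels"
            )
        if arr.ndim == 3 and arr.shape[2] == 4:
            arr = arr[..., :3]
        frames.append(Frame(arr, index=k))
    return frames


def _stage_seed(seed: int, stage: int) -> int:
    return int(np.random.SeedSequence([seed, stage]).generate_state(1)[0] % (2**31))


def _segment_frames(cfg: PipelineConfig, frames, truth, outdir: Path):
    """Predict a foreground mask per frame, training on simulator ground
    truth when running from the simulator."""
    if cfg.segmenter == "baseline":
        return [segment.richa_baseline_mask(f) for f in frames]
    if cfg.segmenter != "learned":
        raise ValueError(f"unknown segmenter {cfg.segmenter!r}")
    if cfg.model_path:
        seg = segment.load_model(cfg.model_path)
    elif truth is not None:
        # train on a separately seeded sweep over the same scene statistics
        spec = dataclasses.replace(
            truth.spec, seed=_stage_seed(cfg.seed, 10)
        )
        traj = simulate.preset_trajectory("sweep", cfg.train_frames, spec, step=cfg.step)
        train_seq = simulate.render_sequence(spec, traj)
        seg = segment.train_classifier(
            train_seq.frames,
            train_seq.true_masks,
            cfg.scenario,
            cfg.boosting_config(_stage_seed(cfg.seed, 11)),
        )
        segment.save_model(seg, outdir / "segmenter.joblib")
    else:
        raise ValueError(
            "learned segmentation of real footage needs model_path "
            "(train one with `slitmosaic segment train`)"
        )
    return [
        segment.predict_mask(seg, f, cfg.threshold, cfg.smoothing_scale)
        for f in frames
    ]


def run(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and write all artifacts to ``cfg.outdir``."""
    import imageio.v3 as iio

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("config: %s", dataclasses.asdict(cfg))

    truth = None
    try:
        if cfg.simulate_preset:
            scene = simulate.SceneSpec(**{"seed": _stage_seed(cfg.seed, 0), **cfg.scene})
            traj = simulate.preset_trajectory(
                cfg.simulate_preset, cfg.n_frames, scene, step=cfg.step
            )
            truth = simulate.render_sequence(scene, traj)
            frames = truth.frames[:: cfg.stride]
            if cfg.stride > 1:
                truth = None  # planted trajectory no longer aligned 1:1
        elif cfg.input:
            frames = read_frames(cfg.input, cfg.stride)
        else:
            raise ValueError("config needs either `input` or `simulate_preset`")
        logger.info("loaded %d frames", len(frames))

        masks = _segment_frames(cfg, frames, truth, outdir)
        (outdir / "masks").mkdir(exist_ok=True)
        for f, m in zip(frames, masks):
            iio.imwrite(
                outdir / "masks" / f"mask_{f.index:04d}.png",
                np.where(m.binary, 255, 0).astype(np.uint8),
            )

        keep = [
            k for k, m in enumerate(masks)
            if m.binary.mean() >= MIN_FOREGROUND_FRACTION
        ]
        if len(keep) < len(masks):
            logger.warning(
                "skipping %d frames with <%.0f%% foreground",
                len(masks) - len(keep), 100 * MIN_FOREGROUND_FRACTION,
            )

        edges_local = register.register_sequence(
            [frames[k] for k in keep],
            [masks[k] for k in keep],
            window=cfg.window,
            iterations=cfg.ransac_iters,
            margin_px=cfg.ransac_margin_px,
            min_inliers=cfg.min_inliers,
            seed=_stage_seed(cfg.seed, 20),
        )
        # restore original frame indices after the low-content guard
        edges = [
            register.PairwiseTranslation(
                keep[e.i], keep[e.j], e.delta, e.inliers, e.accepted
            )
            for e in edges_local
        ]
        register.write_edges_csv(edges, outdir / "edges.csv")
        n_acc = sum(e.accepted for e in edges)
        logger.info("registration: %d/%d pairs accepted", n_acc, len(edges))
        if n_acc == 0:
            raise RuntimeError("graph empty: no frame pair was accepted")

        pg = graph.build_system(
            edges, n_nodes=len(frames), weight_by_inliers=cfg.weight_by_inliers
        )
        pg = graph.solve_positions(pg, anchor=cfg.anchor)
        graph.write_positions_csv(pg, outdir / "positions.csv")
        n_placed = int(pg.placed.sum())
        if n_placed == 1:
            logger.warning("anchor component has a single frame; mosaic is one frame")
        drift = graph.drift_report(pg)
        logger.info(
            "bundle adjustment: %d frames placed, max residual %.3f px",
            n_placed, drift.max_residual,
        )

        placed_idx = np.flatnonzero(pg.placed)
        canvas = blend.composite(
            [frames[k] for k in placed_idx],
            [masks[k] for k in placed_idx],
            pg.positions[placed_idx],
            compositor=cfg.compositor,
        )
        iio.imwrite(outdir / "mosaic.png", canvas.rgba)

        report = {
            "n_frames": len(frames),
            "n_registered_pairs": len(edges),
            "n_accepted_pairs": n_acc,
            "n_placed_frames": n_placed,
            "max_edge_residual_px": drift.max_residual,
            "rms_edge_residual_px": drift.rms_residual,
            "seam_gradient": blend.seam_gradient_metric(
                canvas,
                [masks[k] for k in placed_idx],
                pg.positions[placed_idx],
            ),
            "coverage_px": int(canvas.coverage.sum()),
            "fov_gain_vs_single_frame_pct": evaluate.fov_gain(
                canvas.coverage,
                masks[placed_idx[0]].binary,
            ),
        }
        if truth is not None and pg.placed.all():
            rmse, endpoint = evaluate.trajectory_error(
                pg.positions, truth.trajectory.positions
            )
            report["trajectory_rmse_px"] = rmse
            report["endpoint_drift_px"] = endpoint
        with open(outdir / "evaluation.json", "w") as fh:
            json.dump(report, fh, indent=2)
        logger.info("report: %s", report)
        return PipelineResult(frames, masks, edges, pg, canvas, report, truth)
    finally:
        logger.removeHandler(handler)
        handler.close()
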