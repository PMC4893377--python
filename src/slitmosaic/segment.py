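"""Per-pixel foreground (illuminated slit) segmentation.

Two segmenters are provided:

* :func:`richa_baseline_mask` — the fixed color threshold used by earlier
  slit-lamp mosaicking work: a pixel is foreground iff ``r - 0.7 g > 0``.
* :class:`SlitSegmenter` — gradient-boosted regression trees over cheap
  per-pixel features (color spaces, optional normalized image coordinates,
  optional Gabor texture responses), trained on binarized annotation masks.

Frames are downscaled by a factor of 4 before feature extraction, which
suppresses sensor noise and keeps training tractable; votes are smoothed,
thresholded and upscaled back to full resolution to form the binary mask.

Feature scenarios
-----------------
``A``  RGB + Lab + HSV                       (9 planes)
``B``  RGB + Lab + HSV + x + y               (11 planes)
``C``  RGB + Lab + HSV + Gabor bank          (21 planes; 3 scales x 4 directions)
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
from scipy import ndimage
from skimage import color
from skimage.filters import gabor_kernel
from skimage.transform import downscale_local_mean
from sklearn.ensemble import GradientBoostingRegressor

from .core import Frame, ForegroundMask, as_float_image

__all__ = [
    "BoostingConfig",
    "SCENARIO_PLANES",
    "richa_baseline_mask",
    "extract_features",
    "SlitSegmenter",
    "train_classifier",
    "predict_mask",
    "save_model",
    "load_model",
]

SCENARIO_PLANES = {"A": 9, "B": 11, "C": 21}

#: Gabor bank geometry: 4 orientations, 3 octave-spaced wavelengths on the
#: downscaled grid.
GABOR_THETAS = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
GABOR_WAVELENGTHS = (4.0, 8.0, 16.0)


@dataclass(frozen=True)
class BoostingConfig:
    """Gradient-boosting hyperparameters: 200 rounds, shrinkage 0.1, row
    subsampling 0.5, tree depth 3, squared loss, on frames downscaled 4x."""

    rounds: int = 200
    shrinkage: float = 0.1
    subsample: float = 0.5
    max_depth: int = 3
    downscale_factor: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.rounds, self.max_depth, self.downscale_factor) < 1:
            raise ValueError("rounds, max_depth and downscale_factor must be >= 1")
        if not (0 < self.shrinkage and 0 < self.subsample <= 1):
            raise ValueError("shrinkage must be > 0 and subsample in (0, 1]")


def _image_of(frame) -> np.ndarray:
    if isinstance(frame, Frame):
        return frame.image
    return as_float_image(frame)


def richa_baseline_mask(frame) -> ForegroundMask:
    """Fixed-threshold baseline: foreground iff ``r - 0.7 g > 0`` (strict),
    evaluated per pixel at full resolution."""
    img = _image_of(frame)
    binary = img[..., 0] - 0.7 * img[..., 1] > 0
    return ForegroundMask(votes=binary.astype(float), binary=binary)


def _gabor_bank() -> list[tuple[np.ndarray, float]]:
    """Real Gabor kernels with their L1 norms (for bounded responses)."""
    bank = []
    for lam in GABOR_WAVELENGTHS:
        for theta in GABOR_THETAS:
            k = np.real(gabor_kernel(frequency=1.0 / lam, theta=theta))
            bank.append((k, np.abs(k).sum()))
    return bank


_BANK_CACHE: list[tuple[np.ndarray, float]] | None = None


def extract_features(frame, scenario: str = "B", downscale_factor: int = 4) -> np.ndarray:
    """Per-pixel feature stack at the downscaled resolution, ``(h, w, k)``.

    All planes are rescaled to [0, 1] so tree splits see comparable ranges:
    Lab is mapped from its nominal gamut, coordinate planes are normalized
    column/row indices, and Gabor magnitudes are divided by each kernel's L1
    norm (the response's attainable bound on a [0, 1] image).
    """
    global _BANK_CACHE
    if scenario not in SCENARIO_PLANES:
        raise ValueError(f"unknown feature scenario {scenario!r}; expected A, B or C")
    img = _image_of(frame)
    small = downscale_local_mean(img, (downscale_factor, downscale_factor, 1))
    h, w = small.shape[:2]

    hsv = color.rgb2hsv(small)
    lab = color.rgb2lab(small)
    lab_01 = np.stack(
        [lab[..., 0] / 100.0, (lab[..., 1] + 128) / 255.0, (lab[..., 2] + 128) / 255.0],
        axis=-1,
    )
    planes = [small, lab_01, hsv]

    if scenario == "B":
        xg, yg = np.meshgrid(
            np.linspace(0.0, 1.0, w) if w > 1 else np.zeros(1),
            np.linspace(0.0, 1.0, h) if h > 1 else np.zeros(1),
        )
        planes.append(np.stack([xg, yg], axis=-1))
    elif scenario == "C":
        if _BANK_CACHE is None:
            _BANK_CACHE = _gabor_bank()
        value = hsv[..., 2]
        gab = [
            np.abs(ndimage.convolve(value, k, mode="reflect")) / norm
            for k, norm in _BANK_CACHE
        ]
        planes.append(np.stack(gab, axis=-1))

    stack = np.concatenate(planes, axis=-1)
    assert stack.shape[-1] == SCENARIO_PLANES[scenario]
    return np.clip(stack, 0.0, 1.0)


def _downscale_mask(mask: np.ndarray, factor: int) -> np.ndarray:
    return downscale_local_mean(mask.astype(float), (factor, factor)) > 0.5


class SlitSegmenter:
    """Gradient-boosted per-pixel slit classifier.

    A least-squares :class:`~sklearn.ensemble.GradientBoostingRegressor` is
    fit on 0/1 pixel labels; raw predictions are clipped to [0, 1] and read
    as foreground votes.
    """

    def __init__(self, scenario: str = "B", config: BoostingConfig | None = None):
        if scenario not in SCENARIO_PLANES:
            raise ValueError(f"unknown feature scenario {scenario!r}")
        self.scenario = scenario
        self.config = config or BoostingConfig()
        self.model: GradientBoostingRegressor | None = None

    def fit(self, frames, masks) -> "SlitSegmenter":
        frames = list(frames)
        masks = list(masks)
        if len(frames) != len(masks):
            raise ValueError("frames and masks differ in length")
        if len(frames) < 2:
            raise ValueError("need at least 2 annotated frames")
        cfg = self.config
        X = []
        y = []
        for fr, m in zip(frames, masks):
            feats = extract_features(fr, self.scenario, cfg.downscale_factor)
            X.append(feats.reshape(-1, feats.shape[-1]))
            y.append(_downscale_mask(np.asarray(m), cfg.downscale_factor).ravel())
        Xa = np.vstack(X)
        ya = np.concatenate(y).astype(float)
        if ya.min() == ya.max():
            raise ValueError("training data contains a single class")
        self.model = GradientBoostingRegressor(
            loss="squared_error",
            n_estimators=cfg.rounds,
            learning_rate=cfg.shrinkage,
            subsample=cfg.subsample,
            max_depth=cfg.max_depth,
            random_state=cfg.seed,
        )
        self.model.fit(Xa, ya)
        return self

    def predict_votes(self, frame) -> np.ndarray:
        """Foreground votes in [0, 1] at the downscaled resolution."""
        if self.model is None:
            raise RuntimeError("segmenter has not been trained")
        feats = extract_features(frame, self.scenario, self.config.downscale_factor)
        raw = self.model.predict(feats.reshape(-1, feats.shape[-1]))
        return np.clip(raw.reshape(feats.shape[:2]), 0.0, 1.0)


def train_classifier(frames, masks, scenario: str = "B",
                     config: BoostingConfig | None = None) -> SlitSegmenter:
    """Fit a :class:`SlitSegmenter` on annotated frames (binary masks)."""
    return SlitSegmenter(scenario, config).fit(frames, masks)


def predict_mask(
    segmenter: SlitSegmenter,
    frame,
    threshold: float = 0.5,
    smoothing_scale: float = 2.0,
) -> ForegroundMask:
    """Votes -> smooth -> threshold -> upscale chain.

    Votes are computed at 1/downscale resolution, Gaussian-smoothed with
    ``smoothing_scale`` (pixels on the downscaled grid, suppressing narrow
    vote spikes such as glare borders), thresholded, then upscaled to full
    resolution by nearest-neighbor replication.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    img = _image_of(frame)
    votes = segmenter.predict_votes(frame)
    smoothed = ndimage.gaussian_filter(votes, smoothing_scale) if smoothing_scale > 0 else votes
    binary_small = smoothed >= threshold
    f = segmenter.config.downscale_factor
    # nearest-neighbor upscale; downscale_local_mean padded partial blocks,
    # so the replicated mask is cropped back to the frame size
    binary = np.kron(binary_small, np.ones((f, f), dtype=bool))
    binary = binary[: img.shape[0], : img.shape[1]]
    return ForegroundMask(votes=votes, binary=binary)


def save_model(segmenter: SlitSegmenter, path) -> None:
    joblib.dump(
        {"scenario": segmenter.scenario, "config": segmenter.config,
         "model": segmenter.model},
        path,
    )


def load_model(path) -> SlitSegmenter:
    blob = joblib.load(path)
    seg = SlitSegmenter(blob["scenario"], blob["config"])
    seg.model = blob["model"]
    return seg
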