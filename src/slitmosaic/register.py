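"""Pairwise translation estimation between frames.

Frame-to-frame motion of the slit over the retina is modeled as a pure 2-D
translation (rotation about the optical axis is negligible at slit-lamp
magnification).  Each candidate frame pair is registered by

1. detecting scale-space blob keypoints restricted to the foreground mask
   and describing them with an upright binary descriptor (no orientation
   normalization — the motion model has no rotation),
2. nearest-neighbor descriptor matching with a Lowe-style ratio test, and
3. RANSAC over single-match translation hypotheses (100 iterations, 3 px
   inlier margin), with the winning hypothesis refined as the mean
   displacement over its inliers.

A pair is accepted only when the consensus holds at least 6 inlier
correspondences; pairs below the floor are either non-overlapping or of
too poor quality to constrain the mosaic.

Because the slit illumination falls off toward its borders, the grayscale
frame is divided by a heavily smoothed copy of itself before detection
(local illumination normalization); detection thresholds are set low so a
large number of interest points is retained.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.color import rgb2gray
from skimage.feature import BRIEF, blob_dog, match_descriptors

from .core import Frame, ForegroundMask, as_float_image

__all__ = [
    "FrameFeatures",
    "MatchSet",
    "PairwiseTranslation",
    "detect_and_describe",
    "match_features",
    "estimate_translation",
    "propose_pairs",
    "register_sequence",
    "write_edges_csv",
    "read_edges_csv",
]

#: RANSAC defaults: iteration count and inlier margin (px), and the minimum
#: number of inlier correspondences for a pair to be accepted
RANSAC_ITERATIONS = 100
RANSAC_MARGIN_PX = 3.0
MIN_INLIERS = 6

_DESCRIPTOR_BITS = 512
_PATCH_SIZE = 25
_BRIEF_SEED = 42  # fixed sampling pattern => deterministic descriptors
_ILLUM_SIGMA = 15.0  # scale of the illumination-normalization low-pass
# regularizer in the normalization denominator: keeps sensor noise in dim,
# barely-lit regions from being amplified into spurious frame-fixed features
_ILLUM_OFFSET = 0.1


@dataclass
class FrameFeatures:
    """Keypoints (row, col) and binary descriptors of one frame."""

    keypoints: np.ndarray  # (N, 2) float, (row, col)
    descriptors: np.ndarray  # (N, bits) bool

    def __len__(self) -> int:
        return len(self.keypoints)


@dataclass
class MatchSet:
    """Matched keypoint coordinates between frames i and j.

    ``displacements`` are ``kp_j - kp_i`` in (x, y) order: for content that
    physically moved, this equals ``x_i - x_j`` of the frames' global
    positions, i.e. the right-hand side of the pose-graph constraint.
    """

    i: int
    j: int
    coords_i: np.ndarray  # (M, 2) (row, col) in frame i
    coords_j: np.ndarray  # (M, 2) (row, col) in frame j

    def __len__(self) -> int:
        return len(self.coords_i)

    @property
    def displacements(self) -> np.ndarray:
        d_rc = self.coords_j - self.coords_i
        return d_rc[:, ::-1]  # (x, y)


@dataclass
class PairwiseTranslation:
    """A verified (or rejected) registration edge between frames i and j.

    ``delta`` is the estimated global-position difference
    ``(x_i - x_j, y_i - y_j)`` in pixels.
    """

    i: int
    j: int
    delta: tuple[float, float]
    inliers: int
    accepted: bool = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("a registration edge requires two distinct frames")
        if self.accepted is None:
            self.accepted = self.inliers >= MIN_INLIERS


def _normalized_gray(image: np.ndarray) -> np.ndarray:
    gray = rgb2gray(image)
    illum = ndimage.gaussian_filter(gray, _ILLUM_SIGMA)
    return gray / (illum + _ILLUM_OFFSET)


def detect_and_describe(
    frame,
    mask: ForegroundMask | np.ndarray | None = None,
    *,
    threshold: float = 0.02,
    min_sigma: float = 1.0,
    max_sigma: float = 6.0,
) -> FrameFeatures:
    """Detect upright blob keypoints inside the foreground mask.

    Difference-of-Gaussian blobs are detected on the illumination-normalized
    grayscale frame with a deliberately low ``threshold`` so many interest
    points survive; keypoints outside ``mask`` are discarded, and the
    remainder are described with fixed-pattern 512-bit BRIEF descriptors
    (upright by construction).  An empty mask yields an empty feature set.
    """
    image = frame.image if isinstance(frame, Frame) else as_float_image(frame)
    gray = _normalized_gray(image)
    blobs = blob_dog(gray, min_sigma=min_sigma, max_sigma=max_sigma,
                     threshold=threshold)
    keypoints = blobs[:, :2]

    if mask is not None:
        binary = mask.binary if isinstance(mask, ForegroundMask) else np.asarray(mask, bool)
        if binary.shape != gray.shape:
            raise ValueError("mask shape does not match the frame")
        if not binary.any():
            return FrameFeatures(np.empty((0, 2)), np.empty((0, _DESCRIPTOR_BITS), bool))
        keep = binary[keypoints[:, 0].astype(int), keypoints[:, 1].astype(int)]
        keypoints = keypoints[keep]

    if len(keypoints) == 0:
        return FrameFeatures(np.empty((0, 2)), np.empty((0, _DESCRIPTOR_BITS), bool))

    extractor = BRIEF(descriptor_size=_DESCRIPTOR_BITS, patch_size=_PATCH_SIZE,
                      sigma=1.0, rng=_BRIEF_SEED)
    extractor.extract(gray, keypoints)
    return FrameFeatures(keypoints[extractor.mask], extractor.descriptors)


def match_features(
    feats_i: FrameFeatures,
    feats_j: FrameFeatures,
    i: int = 0,
    j: int = 1,
    *,
    max_ratio: float = 0.8,
) -> MatchSet:
    """Nearest-neighbor Hamming matching with cross-check and Lowe-style
    ratio test."""
    if len(feats_i) == 0 or len(feats_j) == 0:
        return MatchSet(i, j, np.empty((0, 2)), np.empty((0, 2)))
    idx = match_descriptors(
        feats_i.descriptors, feats_j.descriptors,
        metric="hamming", cross_check=True, max_ratio=max_ratio,
    )
    return MatchSet(i, j, feats_i.keypoints[idx[:, 0]], feats_j.keypoints[idx[:, 1]])


def estimate_translation(
    matches: MatchSet,
    *,
    iterations: int = RANSAC_ITERATIONS,
    margin_px: float = RANSAC_MARGIN_PX,
    min_inliers: int = MIN_INLIERS,
    seed: int = 0,
) -> PairwiseTranslation:
    """RANSAC translation estimate from a match set.

    Each hypothesis is the displacement of a single match; inliers are
    matches whose displacement lies within ``margin_px`` (Euclidean) of the
    hypothesis.  The best hypothesis (most inliers; ties broken toward the
    smaller refined residual) is refined as the mean displacement over its
    inliers.  When the match count does not exceed the iteration budget,
    every match is tried as a hypothesis, which dominates random sampling.
    """
    if matches.i == matches.j:
        raise ValueError("cannot register a frame against itself")
    n = len(matches)
    if n == 0:
        return PairwiseTranslation(matches.i, matches.j, (0.0, 0.0), 0, False)

    disp = matches.displacements
    rng = np.random.default_rng(seed)
    if n <= iterations:
        candidate_idx = np.arange(n)
    else:
        candidate_idx = rng.choice(n, size=iterations, replace=False)

    best = None  # (inlier_count, -refined_rms, delta, inlier_mask)
    for k in candidate_idx:
        hyp = disp[k]
        err = np.linalg.norm(disp - hyp, axis=1)
        inl = err <= margin_px
        count = int(inl.sum())
        refined = disp[inl].mean(axis=0)
        rms = float(np.sqrt(((disp[inl] - refined) ** 2).sum(axis=1).mean()))
        key = (count, -rms)
        if best is None or key > best[0]:
            best = (key, refined, count)

    _, refined, count = best
    return PairwiseTranslation(
        matches.i, matches.j,
        (float(refined[0]), float(refined[1])),
        count,
        count >= min_inliers,
    )


def propose_pairs(n_frames: int, window: int | float | None = None) -> list[tuple[int, int]]:
    """Candidate frame pairs ``(i, j)`` with ``i < j`` and ``j - i <=
    window``; ``window=None`` (or ``inf``) attempts all pairs, allowing both
    minute and large motion estimates to enter the pose graph."""
    if n_frames < 2:
        raise ValueError("need at least 2 frames to propose pairs")
    if window is None or window == np.inf:
        window = n_frames - 1
    window = int(window)
    if window < 1:
        raise ValueError("window must be >= 1")
    return [
        (i, j)
        for i in range(n_frames)
        for j in range(i + 1, min(i + window + 1, n_frames))
    ]


def register_sequence(
    frames,
    masks,
    *,
    window: int | None = None,
    iterations: int = RANSAC_ITERATIONS,
    margin_px: float = RANSAC_MARGIN_PX,
    min_inliers: int = MIN_INLIERS,
    max_ratio: float = 0.8,
    seed: int = 0,
) -> list[PairwiseTranslation]:
    """Register every proposed pair of a sequence; features are computed
    once per frame.  Returns all edges, accepted or not."""
    frames = list(frames)
    masks = list(masks)
    if len(frames) != len(masks):
        raise ValueError("frames and masks differ in length")
    feats = [detect_and_describe(f, m) for f, m in zip(frames, masks)]
    edges = []
    for i, j in propose_pairs(len(frames), window):
        ms = match_features(feats[i], feats[j], i, j, max_ratio=max_ratio)
        edges.append(
            estimate_translation(
                ms, iterations=iterations, margin_px=margin_px,
                min_inliers=min_inliers, seed=seed + 31 * i + j,
            )
        )
    return edges


def write_edges_csv(edges, path: str | Path, accepted_only: bool = True) -> None:
    """Write edges as ``i,j,dx,dy,inliers`` CSV."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["i", "j", "dx", "dy", "inliers"])
        for e in edges:
            if accepted_only and not e.accepted:
                continue
            writer.writerow([e.i, e.j, e.delta[0], e.delta[1], e.inliers])


def read_edges_csv(path: str | Path) -> list[PairwiseTranslation]:
    edges = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            edges.append(
                PairwiseTranslation(
                    int(row["i"]), int(row["j"]),
                    (float(row["dx"]), float(row["dy"])),
                    int(row["inliers"]),
                )
            )
    return edges
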