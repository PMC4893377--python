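"""Shared in-memory containers for the mosaicking pipeline.

Images are float arrays in [0, 1], shape ``(H, W, 3)`` (RGB).  Binary masks
are boolean ``(H, W)`` arrays; vote maps are float ``(h, w)`` arrays at the
segmentation working resolution (the frame downscaled by the configured
factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Frame", "ForegroundMask", "as_float_image"]


def as_float_image(image: np.ndarray) -> np.ndarray:
    """Coerce an RGB image to float64 in [0, 1].

    Integer dtypes are divided by their max value; float inputs are only
    validated.  Raises ``ValueError`` for non-RGB shapes.
    """
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(
            f"expected an (H, W, 3) RGB image, got shape {arr.shape}"
        )
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image height and width must be positive")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        arr = arr.astype(np.float64) / info.max
    else:
        arr = arr.astype(np.float64, copy=False)
        if arr.size and (arr.min() < -1e-9 or arr.max() > 1 + 1e-9):
            raise ValueError("float image values must lie in [0, 1]")
    return np.clip(arr, 0.0, 1.0)


@dataclass
class Frame:
    """One RGB video frame and its temporal index."""

    image: np.ndarray
    index: int = 0

    def __post_init__(self) -> None:
        self.image = as_float_image(self.image)
        if self.index < 0:
            raise ValueError("frame index must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape[:2]


@dataclass
class ForegroundMask:
    """Per-pixel slit-content estimate for one frame.

    ``votes`` holds scores in [0, 1] at the working (possibly downscaled)
    resolution; ``binary`` is the thresholded, smoothed and upscaled mask at
    full frame resolution.
    """

    votes: np.ndarray
    binary: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.votes = np.asarray(self.votes, dtype=np.float64)
        if self.votes.size and (
            self.votes.min() < -1e-9 or self.votes.max() > 1 + 1e-9
        ):
            raise ValueError("votes must lie in [0, 1]")
        self.votes = np.clip(self.votes, 0.0, 1.0)
        if self.binary is None:
            self.binary = self.votes >= 0.5
        self.binary = np.asarray(self.binary).astype(bool)

    @property
    def foreground_fraction(self) -> float:
        return float(self.binary.mean()) if self.binary.size else 0.0
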