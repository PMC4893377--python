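"""Synthetic slit-lamp retina video generator.

Real slit-lamp footage of the retina shows a narrow, vertically elongated
band of illumination over a textured orange fundus with dark branching
vessels; the illumination is non-uniform and falls off toward the slit
borders, near-saturated glare blobs occlude content, and the camera adds
sensor noise.  No public clinical recordings exist, so this module renders
sequences with those characteristics from a latent "fundus" image together
with ground-truth foreground masks and the planted frame-to-frame
translation trajectory, making every downstream stage testable.

The slit illumination profile is separable: a boxcar of ``slit_width``
columns convolved with a Gaussian of scale ``illumination_falloff``
horizontally, times a slower analogous vertical profile.  The ground-truth
foreground mask marks pixels whose illumination is at least 20 % of the
slit-center illumination and which are not saturated by glare.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage

from .core import Frame

__all__ = [
    "SceneSpec",
    "Trajectory",
    "SyntheticSequence",
    "make_fundus",
    "slit_profile",
    "render_sequence",
    "preset_trajectory",
    "write_sequence",
]

#: illumination threshold (fraction of slit-center illumination) above which
#: a non-glare pixel counts as viable foreground content
VISIBILITY_FLOOR = 0.2

#: glare blob intensity above which a pixel is considered saturated and
#: therefore excluded from the ground-truth foreground
GLARE_SATURATION = 0.5


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the virtual slit-lamp scene.

    Defaults render frames at 128x170 px, an eighth of the 1024x1360
    clinical sensor resolution, so that full sequences stay desk-sized;
    slit geometry and artifact levels are scaled accordingly.
    """

    fundus_size: tuple[int, int] = (512, 512)  # (H, W) of latent retina
    slit_width: int = 40  # px, horizontal extent of the illuminated band
    slit_height: int = 120  # px, vertical extent
    illumination_falloff: float = 6.0  # px, border decay scale
    glare_count: int = 2  # glare blobs per frame
    glare_radius_range: tuple[float, float] = (3.0, 8.0)  # px
    noise_sigma: float = 0.01  # additive Gaussian noise, intensity units
    frame_size: tuple[int, int] = (128, 170)  # (H, W) of rendered frames
    seed: int = 0

    def __post_init__(self) -> None:
        fh, fw = self.frame_size
        if fh < 1 or fw < 1 or min(self.fundus_size) < 1:
            raise ValueError("image sizes must be positive")
        if not (0 < self.slit_width <= fw and 0 < self.slit_height <= fh):
            raise ValueError("slit must fit inside the frame")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.illumination_falloff <= 0:
            raise ValueError("illumination_falloff must be > 0")
        if self.glare_count < 0:
            raise ValueError("glare_count must be >= 0")
        lo, hi = self.glare_radius_range
        if lo <= 0 or hi < lo:
            raise ValueError("glare_radius_range must be 0 < lo <= hi")
        if self.fundus_size[0] < fh or self.fundus_size[1] < fw:
            raise ValueError("frame must fit inside the fundus")


@dataclass
class Trajectory:
    """Ordered per-frame global offsets (x, y) of the frame's top-left
    corner in fundus coordinates."""

    positions: np.ndarray  # (N, 2), columns (x, y)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array of (x, y)")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class SyntheticSequence:
    """Rendered frames plus everything downstream stages may be scored
    against: ground-truth masks, the planted trajectory, and the latent
    fundus."""

    frames: list[Frame]
    true_masks: list[np.ndarray]  # boolean (H, W) per frame
    trajectory: Trajectory
    fundus: np.ndarray
    spec: SceneSpec = field(default=None)  # type: ignore[assignment]

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def images(self) -> list[np.ndarray]:
        return [f.image for f in self.frames]


def _smooth_noise(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Zero-mean low-frequency field, normalized to unit max amplitude."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    peak = np.abs(field_).max()
    return field_ / peak if peak > 0 else field_


def make_fundus(spec: SceneSpec) -> np.ndarray:
    """Render the latent retina: orange/red low-frequency background, dark
    branching vessel curves, a bright optic-disc analogue, and fine speckle
    texture (so that local-feature detectors find content inside the slit).

    Deterministic under ``spec.seed``.
    """
    h, w = spec.fundus_size
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))

    base = np.array([0.72, 0.34, 0.16])  # fundus orange
    img = np.empty((h, w, 3))
    low = _smooth_noise(rng, (h, w), sigma=max(h, w) / 16)
    for c in range(3):
        img[..., c] = base[c] * (1.0 + 0.18 * low)

    # multi-scale texture (choriocapillaris-like granularity); the mix of
    # scales makes local patches distinctive for feature matching
    tex = (
        0.09 * _smooth_noise(rng, (h, w), sigma=0.8)
        + 0.12 * _smooth_noise(rng, (h, w), sigma=1.2)
        + 0.11 * _smooth_noise(rng, (h, w), sigma=2.5)
        + 0.08 * _smooth_noise(rng, (h, w), sigma=5.0)
    )
    img += tex[..., None] * np.array([1.0, 0.85, 0.6])

    # optic disc: bright, slightly yellow disc with a soft edge
    disc_r = min(h, w) * 0.06
    cy = rng.uniform(0.3 * h, 0.7 * h)
    cx = rng.uniform(0.3 * w, 0.7 * w)
    yy, xx = np.mgrid[0:h, 0:w]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    disc = np.exp(-d2 / (2 * disc_r**2))
    img += disc[..., None] * np.array([0.25, 0.35, 0.30])

    # vessels: random walks radiating from the disc, drawn dark
    vessel_mask = np.zeros((h, w))
    n_vessels = 24
    for _ in range(n_vessels):
        y, x = cy, cx
        ang = rng.uniform(0, 2 * np.pi)
        n_steps = int(rng.integers(int(0.4 * max(h, w)), int(0.9 * max(h, w))))
        for _ in range(n_steps):
            ang += rng.normal(0, 0.15)
            y += np.sin(ang)
            x += np.cos(ang)
            if not (0 <= y < h and 0 <= x < w):
                break
            vessel_mask[int(y), int(x)] = 1.0
    vessel_mask = ndimage.gaussian_filter(vessel_mask, 0.8)
    vm = vessel_mask / vessel_mask.max() if vessel_mask.max() > 0 else vessel_mask
    # vessels darken mainly red/green (deoxygenated blood looks dark red)
    img *= 1.0 - 0.55 * vm[..., None] * np.array([0.7, 1.0, 0.6])

    return np.clip(img, 0.0, 1.0)


def _bounded_profile(n: int, extent: int, sigma: float) -> np.ndarray:
    """Boxcar of ``extent`` samples centered in ``n``, convolved with a
    Gaussian of scale ``sigma``; peak normalized to 1."""
    box = np.zeros(n)
    lo = (n - extent) // 2
    box[lo : lo + extent] = 1.0
    prof = ndimage.gaussian_filter1d(box, sigma, mode="constant")
    return prof / prof.max()


def slit_profile(spec: SceneSpec) -> np.ndarray:
    """Separable slit illumination over one frame, peak 1 at slit center.

    Horizontal: boxcar(slit_width) * Gaussian(illumination_falloff).
    Vertical: boxcar(slit_height) * Gaussian(4 x falloff) — a slower decay,
    matching the elongated, softly vignetted vertical extent of the slit.
    """
    h, w = spec.frame_size
    horiz = _bounded_profile(w, spec.slit_width, spec.illumination_falloff)
    vert = _bounded_profile(h, spec.slit_height, 4.0 * spec.illumination_falloff)
    prof = np.outer(vert, horiz)
    return prof / prof.max()


def preset_trajectory(
    name: str,
    n_frames: int,
    spec: SceneSpec,
    step: float = 8.0,
) -> Trajectory:
    """Planted scan patterns mirroring the qualitative acquisition
    scenarios: ``sweep`` (monotone horizontal scan), ``loop`` (closed
    circuit, for drift tests) and ``static`` (slit not moving).

    Offsets are integer-valued and keep the frame window inside the fundus;
    consecutive steps stay below the slit width so masks overlap.
    """
    fh, fw = spec.frame_size
    H, W = spec.fundus_size
    cy = (H - fh) // 2
    cx = (W - fw) // 2
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if name == "static":
        pos = np.tile([cx, cy], (n_frames, 1)).astype(float)
    elif name == "sweep":
        span = (W - fw) * 0.9
        total = step * (n_frames - 1)
        if total > span:
            raise ValueError(
                f"sweep of {n_frames} frames at step {step} px exceeds the "
                f"fundus width; enlarge the fundus or shrink the step"
            )
        x0 = (W - fw - total) / 2
        xs = x0 + step * np.arange(n_frames)
        pos = np.column_stack([np.round(xs), np.full(n_frames, cy)])
    elif name == "loop":
        # circle whose circumference/n stays below the slit width
        radius = min(step * n_frames / (2 * np.pi), (W - fw) / 2 - 1, (H - fh) / 2 - 1)
        t = 2 * np.pi * np.arange(n_frames) / n_frames
        xs = cx + radius * (np.cos(t) - 1.0)
        ys = cy + radius * np.sin(t)
        pos = np.column_stack([np.round(xs + radius), np.round(ys)])
    else:
        raise ValueError(f"unknown trajectory preset {name!r}")
    traj = Trajectory(pos)
    steps = np.linalg.norm(np.diff(traj.positions, axis=0), axis=1)
    if len(steps) and steps.max() >= spec.slit_width:
        raise ValueError("consecutive offsets must differ by less than the slit width")
    return traj


def _render_frame(
    spec: SceneSpec,
    fundus: np.ndarray,
    profile: np.ndarray,
    offset: tuple[int, int],
    index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one frame and its ground-truth mask at integer offset (x, y)."""
    fh, fw = spec.frame_size
    x, y = offset
    crop = fundus[y : y + fh, x : x + fw]
    img = crop * profile[..., None]

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, index]))

    glare = np.zeros((fh, fw))
    lit = profile >= VISIBILITY_FLOOR
    if spec.glare_count > 0 and lit.any():
        ys, xs = np.nonzero(lit)
        for _ in range(spec.glare_count):
            k = rng.integers(len(ys))
            r = rng.uniform(*spec.glare_radius_range)
            yy, xx = np.mgrid[0:fh, 0:fw]
            d2 = (yy - ys[k]) ** 2 + (xx - xs[k]) ** 2
            glare = np.maximum(glare, np.exp(-d2 / (2 * (r / 2.0) ** 2)))
        img = img + 0.95 * glare[..., None]

    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, img.shape)

    mask = lit & (glare < GLARE_SATURATION)
    return np.clip(img, 0.0, 1.0), mask


def render_sequence(spec: SceneSpec, trajectory: Trajectory) -> SyntheticSequence:
    """Render the full sequence along ``trajectory``.

    Each frame is the fundus crop at its (integer-rounded) offset,
    multiplied by the slit illumination profile, with glare blobs and sensor
    noise added.  Raises ``ValueError`` naming the frame index when an
    offset would push the frame window outside the fundus.
    """
    fh, fw = spec.frame_size
    H, W = spec.fundus_size
    fundus = make_fundus(spec)
    profile = slit_profile(spec)

    frames: list[Frame] = []
    masks: list[np.ndarray] = []
    for k, (x, y) in enumerate(np.round(trajectory.positions).astype(int)):
        if not (0 <= x <= W - fw and 0 <= y <= H - fh):
            raise ValueError(
                f"frame {k}: offset ({x}, {y}) places the frame outside the fundus"
            )
        img, mask = _render_frame(spec, fundus, profile, (x, y), k)
        frames.append(Frame(img, index=k))
        masks.append(mask)
    return SyntheticSequence(frames, masks, trajectory, fundus, spec)


def write_sequence(seq: SyntheticSequence, outdir: str | Path) -> Path:
    """Write frames and masks as 8-bit PNG, the trajectory as CSV
    (``frame,x,y``), and the scene spec as YAML."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    (outdir / "frames").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    for f, m in zip(seq.frames, seq.true_masks):
        iio.imwrite(
            outdir / "frames" / f"frame_{f.index:04d}.png",
            (f.image * 255).round().astype(np.uint8),
        )
        iio.imwrite(
            outdir / "masks" / f"mask_{f.index:04d}.png",
            np.where(m, 255, 0).astype(np.uint8),
        )
    with open(outdir / "trajectory.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["frame", "x", "y"])
        for k, (x, y) in enumerate(seq.trajectory.positions):
            writer.writerow([k, x, y])
    if seq.spec is not None:
        with open(outdir / "scene.yaml", "w") as fh:
            yaml.safe_dump(asdict(seq.spec), fh)
    return outdir
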