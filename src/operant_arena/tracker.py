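"""Single-fly centroid tracking from grayscale IR-style frame stacks.

Classic background-subtraction pipeline for high-contrast single-animal
imaging: a per-pixel median background over sampled frames, an absolute
difference image thresholded automatically (Otsu with a gray-level floor),
the largest connected component, and an intensity-weighted centroid.  One
animal per arena is assumed; when several components survive thresholding
the largest is kept, with no identity tracking.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

from .geometry import ArenaGeometry, Point
from .trajio import Trajectory, trajectory_from_arrays


@dataclass
class FrameStack:
    """Ordered grayscale frames of identical shape, with a frame rate."""

    frames: np.ndarray
    fps: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, H, W) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a frame stack needs at least 2 frames")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    def __len__(self) -> int:
        return int(self.frames.shape[0])

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]


def load_stack(path: str | Path, fps: float) -> FrameStack:
    """Load a multi-page TIFF, or a directory of PNG/TIFF frames in sorted order."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            f for f in path.iterdir() if f.suffix.lower() in (".png", ".tif", ".tiff")
        )
        if not files:
            raise ValueError(f"{path}: no image files found")
        frames = np.stack([np.asarray(iio.imread(f), dtype=np.float32) for f in files])
    else:
        frames = np.asarray(iio.imread(path), dtype=np.float32)
        if frames.ndim == 2:
            frames = frames[None]
    return FrameStack(frames=frames, fps=fps)


def save_stack(stack: FrameStack, path: str | Path) -> None:
    """Write a stack as multi-page TIFF (uint8)."""
    import tifffile

    tifffile.imwrite(
        str(path),
        np.clip(stack.frames, 0, 255).astype(np.uint8),
        photometric="minisblack",
    )


def estimate_background(stack: FrameStack, n_samples: int = 25) -> np.ndarray:
    """Per-pixel median over ``n_samples`` evenly spaced frames.

    The median is robust to the fly itself: as long as the animal moves, it
    darkens each pixel in fewer than half the sampled frames.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    n = len(stack)
    idx = np.unique(np.linspace(0, n - 1, min(n_samples, n)).round().astype(int))
    return np.median(stack.frames[idx].astype(np.float64), axis=0)


def detect_fly(
    frame: np.ndarray,
    background: np.ndarray,
    threshold: float | None = None,
    otsu_floor: float = 10.0,
    min_area: int = 4,
) -> Point | None:
    """Locate the fly in one frame; None when no blob is found.

    Absolute difference from background, thresholded (fixed value, or Otsu
    with a floor of ``otsu_floor`` gray levels), largest connected
    component of at least ``min_area`` pixels, intensity-weighted centroid.
    Returns the centroid in pixel coordinates (x = column, y = row).
    """
    frame = np.asarray(frame, dtype=np.float64)
    background = np.asarray(background, dtype=np.float64)
    if frame.shape != background.shape:
        raise ValueError(
            f"frame shape {frame.shape} != background shape {background.shape}"
        )
    diff = np.abs(frame - background)
    if threshold is None:
        if diff.max() <= otsu_floor:
            return None
        try:
            thr = max(float(threshold_otsu(diff)), otsu_floor)
        except ValueError:  # single-valued difference image
            return None
    else:
        thr = float(threshold)
    mask = diff > thr
    if not mask.any():
        return None
    labels = label(mask)
    props = regionprops(labels, intensity_image=diff)
    props = [p for p in props if p.area >= min_area]
    if not props:
        return None
    best = max(props, key=lambda p: p.area)
    cy, cx = best.centroid_weighted
    return Point(float(cx), float(cy))


def track(
    stack: FrameStack,
    geometry: ArenaGeometry,
    n_background_samples: int = 25,
    threshold: float | None = None,
    otsu_floor: float = 10.0,
    min_area: int = 4,
    fly_id: str = "tracked",
) -> Trajectory:
    """Track one fly through a stack; output positions in physical units.

    One position per frame, always: frames with no detectable blob become
    invalid frames (downstream gap repair applies).  Pixel centroids are
    converted to arena units via the geometry's calibration.
    """
    bg = estimate_background(stack, n_background_samples)
    n = len(stack)
    xs = np.full(n, np.nan)
    ys = np.full(n, np.nan)
    for i in range(n):
        p = detect_fly(
            stack.frames[i],
            bg,
            threshold=threshold,
            otsu_floor=otsu_floor,
            min_area=min_area,
        )
        if p is not None:
            xs[i] = p.x / geometry.px_per_unit
            ys[i] = p.y / geometry.px_per_unit
    return trajectory_from_arrays(xs, ys, fps=stack.fps, fly_id=fly_id)
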