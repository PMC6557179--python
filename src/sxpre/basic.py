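"""Reference-image statistics, mask construction and powder accumulation.

Masks mark bad detector regions: the morphology operations therefore act on
the *excluded* (0) set, so "dilate" grows the bad region around beam stops
and dead clusters. Sigma images use the population standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Frame, PixelMask

__all__ = [
    "ReferencePair",
    "PowderPattern",
    "compute_mean_sigma",
    "build_threshold_mask",
    "refine_mask_morphology",
    "compose_masks",
    "erase_region",
    "accumulate_powder",
]


@dataclass(frozen=True)
class ReferencePair:
    mean_image: np.ndarray
    sigma_image: np.ndarray
    n_frames: int


@dataclass(frozen=True)
class PowderPattern:
    """Accumulated peak positions/intensities from many hit frames."""

    image: np.ndarray
    peak_x: np.ndarray  # columns
    peak_y: np.ndarray  # rows
    peak_intensity: np.ndarray
    peak_frame: np.ndarray
    n_frames_contributing: int = 0

    @property
    def n_peaks(self) -> int:
        return len(self.peak_x)

    def save_npz(self, path) -> None:
        np.savez(path, image=self.image, peak_x=self.peak_x, peak_y=self.peak_y,
                 peak_intensity=self.peak_intensity, peak_frame=self.peak_frame,
                 n_frames_contributing=self.n_frames_contributing)

    @classmethod
    def load_npz(cls, path) -> "PowderPattern":
        with np.load(path) as z:
            return cls(z["image"], z["peak_x"], z["peak_y"], z["peak_intensity"],
                       z["peak_frame"], int(z["n_frames_contributing"]))


def _as_arrays(frames) -> list[np.ndarray]:
    return [f.data if isinstance(f, Frame) else np.asarray(f, dtype=float)
            for f in frames]


def compute_mean_sigma(frames) -> ReferencePair:
    """Per-pixel mean and population standard deviation over a frame set."""
    arrays = _as_arrays(frames)
    if len(arrays) == 0:
        raise ValueError("need at least one frame")
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all frames must share one shape")
    stack = np.stack(arrays)
    return ReferencePair(stack.mean(axis=0), stack.std(axis=0), len(arrays))


def build_threshold_mask(reference: np.ndarray, vmin: float, vmax: float) -> PixelMask:
    """Mark pixels valid iff ``vmin <= value <= vmax``."""
    if vmin > vmax:
        raise ValueError(f"vmin={vmin} exceeds vmax={vmax}")
    ref = np.asarray(reference, dtype=float)
    return PixelMask(((ref >= vmin) & (ref <= vmax)).astype(np.uint8))


_STRUCT = np.ones((3, 3), dtype=bool)  # full 3x3 block


def refine_mask_morphology(mask: PixelMask, operation: str,
                           iterations: int = 1) -> PixelMask:
    """Grow (dilate) or shrink (erode) the excluded region of a mask."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return PixelMask(mask.grid.copy())
    excluded = mask.grid == 0
    # beyond the detector edge counts as excluded (border_value=1 for
    # erosion), which also keeps dilate-then-erode extensive
    if operation == "dilate":
        excluded = ndimage.binary_dilation(excluded, _STRUCT, iterations=iterations)
    elif operation == "erode":
        excluded = ndimage.binary_erosion(excluded, _STRUCT, iterations=iterations,
                                          border_value=1)
    else:
        raise ValueError(f"unknown morphology operation {operation!r}")
    return PixelMask((~excluded).astype(np.uint8))


def compose_masks(masks: list[PixelMask]) -> PixelMask:
    """AND-compose masks: a pixel is valid iff valid in every input."""
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("mask shapes differ")
    out = np.ones(shape, dtype=np.uint8)
    for m in masks:
        out &= m.grid
    return PixelMask(out)


def erase_region(mask: PixelMask, center: tuple[float, float], radius: float,
                 action: str = "exclude") -> PixelMask:
    """Set a circular disc of the mask to excluded (0) or valid (1).

    ``center`` is (x, y) = (col, row); the disc contains pixels whose center
    lies within Euclidean distance ``radius``. Discs extending beyond the
    image are clipped.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if action not in ("exclude", "restore"):
        raise ValueError(f"unknown eraser action {action!r}")
    cx, cy = center
    rows, cols = np.ogrid[: mask.shape[0], : mask.shape[1]]
    disc = (cols - cx) ** 2 + (rows - cy) ** 2 <= radius**2
    grid = mask.grid.copy()
    grid[disc] = 0 if action == "exclude" else 1
    return PixelMask(grid)


def accumulate_powder(hit_results, shape: tuple[int, int] | None = None
                      ) -> PowderPattern:
    """Accumulate peak lists from many hit frames into a powder pattern.

    The image records, at each peak pixel, the maximum peak intensity seen
    there across frames (keeps the rings sharp for geometry calibration).
    """
    xs, ys, intens, frames_of = [], [], [], []
    n_frames = 0
    for frame, peaks in hit_results:
        arr = frame.data if isinstance(frame, Frame) else np.asarray(frame)
        if shape is None:
            shape = arr.shape
        fid = frame.frame_id if isinstance(frame, Frame) else n_frames
        for pk in peaks:
            row, col = pk.position
            if not (0 <= row < shape[0] and 0 <= col < shape[1]):
                raise ValueError(
                    f"peak at (row={row}, col={col}) outside frame bounds "
                    f"{shape} (frame {fid})"
                )
            xs.append(col)
            ys.append(row)
            intens.append(pk.total_intensity)
            frames_of.append(fid)
        n_frames += 1
    if shape is None:
        shape = (0, 0)
    image = np.zeros(shape)
    for x, y, v in zip(xs, ys, intens):
        r, c = int(round(y)), int(round(x))
        image[r, c] = max(image[r, c], v)
    return PowderPattern(image, np.asarray(xs, dtype=float),
                         np.asarray(ys, dtype=float),
                         np.asarray(intens, dtype=float),
                         np.asarray(frames_of, dtype=int), n_frames)
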