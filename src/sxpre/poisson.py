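"""Poisson-model hit finder.

The detector image is converted from ADU to integer photon counts; every
pixel's background rate ``b`` is estimated as the mean photon count of the
radial ring (around the beam center) it belongs to. A pixel is flagged as
signal when its count exceeds the smallest integer K with
``P(X <= K) >= 1 - epsilon`` for ``X ~ Poisson(b)``, so on a peak-free
frame at most a fraction ``epsilon`` of pixels is flagged per ring.
Connected signal regions, filtered by the mask and their pixel count,
become peak candidates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import poisson as poisson_dist

from .core import Frame, PixelMask
from .snr import HitRecord, PeakRecord

__all__ = [
    "PoissonParams",
    "RadialBackground",
    "to_photon_image",
    "radial_background",
    "poisson_threshold",
    "threshold_image",
    "find_hits_poisson",
]

_STRUCT_4 = ndimage.generate_binary_structure(2, 1)
_STRUCT_8 = ndimage.generate_binary_structure(2, 2)


@dataclass
class PoissonParams:
    """Tunable parameters of the Poisson hit finder."""

    adu_per_photon: float = 1.0
    epsilon: float = 1e-5
    ring_width: float = 1.0
    connectivity: int = 4
    min_signal_pixels: int = 2
    max_signal_pixels: int = 100
    min_peaks_for_hit: int = 20
    beam_center: tuple[float, float] | None = None  # (x, y); image centre if None

    def __post_init__(self):
        if self.adu_per_photon <= 0:
            raise ValueError("adu_per_photon must be positive")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")
        if self.ring_width < 1:
            raise ValueError("ring_width must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")


def to_photon_image(frame, adu_per_photon: float) -> np.ndarray:
    """ADU image -> integer photon counts: round half away from zero,
    then clip negative counts (detector noise) to zero."""
    if adu_per_photon <= 0:
        raise ValueError("adu_per_photon must be positive")
    data = frame.data if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    scaled = data / adu_per_photon
    counts = np.sign(scaled) * np.floor(np.abs(scaled) + 0.5)
    return np.clip(counts, 0, None).astype(np.int64)


@dataclass(frozen=True)
class RadialBackground:
    """Per-ring mean photon counts around a beam center."""

    b: np.ndarray            # mean count per ring index
    ring_map: np.ndarray     # ring index of every pixel
    beam_center: tuple[float, float]
    ring_width: float

    @property
    def n_rings(self) -> int:
        return len(self.b)


def _ring_map(shape: tuple[int, int], beam_center: tuple[float, float],
              ring_width: float) -> np.ndarray:
    cx, cy = beam_center
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    dist = np.hypot(rows - cy, cols - cx)
    return (dist / ring_width).astype(np.int64)


def radial_background(photon_image: np.ndarray, mask: PixelMask | None,
                      beam_center: tuple[float, float],
                      ring_width: float = 1.0) -> RadialBackground:
    """Mean photon count per radial ring, over unmasked pixels only.

    Rings with no unmasked pixel inherit the value of the nearest
    populated ring.
    """
    photon_image = np.asarray(photon_image)
    grid = mask.grid if isinstance(mask, PixelMask) else (
        np.ones(photon_image.shape, np.uint8) if mask is None else np.asarray(mask))
    if grid.shape != photon_image.shape:
        raise ValueError("mask shape does not match image shape")
    if not grid.any():
        raise ValueError("fully masked image: no background can be estimated")
    rings = _ring_map(photon_image.shape, beam_center, ring_width)
    n_rings = int(rings.max()) + 1
    valid = grid == 1
    sums = np.bincount(rings[valid], weights=photon_image[valid].astype(float),
                       minlength=n_rings)
    counts = np.bincount(rings[valid], minlength=n_rings)
    b = np.full(n_rings, np.nan)
    populated = counts > 0
    b[populated] = sums[populated] / counts[populated]
    if not populated.all():
        pop_idx = np.flatnonzero(populated)
        empty_idx = np.flatnonzero(~populated)
        nearest = pop_idx[np.abs(empty_idx[:, None] - pop_idx[None, :]).argmin(axis=1)]
        b[empty_idx] = b[nearest]
    return RadialBackground(b, rings, (float(beam_center[0]),
                                       float(beam_center[1])), ring_width)


def poisson_threshold(b, epsilon: float):
    """Smallest integer K with ``P(Poisson(b) <= K) >= 1 - epsilon``.

    A pixel counts as signal only when its photon count exceeds K.
    Accepts scalars or arrays.
    """
    if not 0 < epsilon < 1:
        raise ValueError("epsilon must lie in (0, 1)")
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("background rate must be >= 0")
    k = poisson_dist.ppf(1.0 - epsilon, b_arr)
    k = np.where(b_arr == 0, 0.0, k)
    k = np.nan_to_num(k, nan=0.0).astype(np.int64)
    return k if np.ndim(b) else int(k)


def threshold_image(photon_image: np.ndarray, radial_bg: RadialBackground,
                    epsilon: float, mask: PixelMask | None = None) -> np.ndarray:
    """Binary signal map: count > per-ring Poisson threshold, within mask."""
    photon_image = np.asarray(photon_image)
    if radial_bg.ring_map.shape != photon_image.shape:
        raise ValueError("ring map shape does not match image shape")
    k_per_ring = poisson_threshold(radial_bg.b, epsilon)
    k_map = k_per_ring[radial_bg.ring_map]
    signal = photon_image > k_map
    if mask is not None:
        grid = mask.grid if isinstance(mask, PixelMask) else np.asarray(mask)
        signal &= grid == 1
    return signal


def find_hits_poisson(frame, mask: PixelMask | None = None,
                      params: PoissonParams | None = None) -> HitRecord:
    """Run the full Poisson hit-finding chain on one frame."""
    params = params or PoissonParams()
    data = frame.data if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    frame_id = frame.frame_id if isinstance(frame, Frame) else 0
    if mask is None:
        mask = PixelMask.all_valid(data.shape)
    if mask.shape != data.shape:
        raise ValueError("mask shape does not match frame shape")
    center = params.beam_center
    if center is None:
        center = ((data.shape[1] - 1) / 2.0, (data.shape[0] - 1) / 2.0)
    photons = to_photon_image(data, params.adu_per_photon)
    bg = radial_background(photons, mask, center, params.ring_width)
    signal = threshold_image(photons, bg, params.epsilon, mask)
    structure = _STRUCT_4 if params.connectivity == 4 else _STRUCT_8
    labels, n_components = ndimage.label(signal, structure=structure)
    peaks: list[PeakRecord] = []
    if n_components:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n_components + 1))
        totals = ndimage.sum_labels(photons, labels,
                                    index=np.arange(1, n_components + 1))
        centroids = ndimage.center_of_mass(photons, labels,
                                           index=np.arange(1, n_components + 1))
        for size, total, (crow, ccol) in zip(sizes, totals, centroids):
            size = int(size)
            if not params.min_signal_pixels <= size <= params.max_signal_pixels:
                continue
            ring = bg.ring_map[int(round(crow)), int(round(ccol))]
            b_here = float(bg.b[min(ring, bg.n_rings - 1)])
            bg_std = float(np.sqrt(b_here))
            sig_mean = float(total) / size
            snr = ((sig_mean - b_here) / bg_std if bg_std > 0
                   else (np.inf if sig_mean > 0 else 0.0))
            peaks.append(PeakRecord(
                position=(float(crow), float(ccol)),
                snr=snr,
                signal_mean=sig_mean,
                background_mean=b_here,
                background_std=bg_std,
                n_signal_pixels=size,
                total_intensity=float(total),
            ))
    return HitRecord(frame_id=frame_id, n_peaks=len(peaks),
                     is_hit=len(peaks) >= params.min_peaks_for_hit,
                     peaks=tuple(peaks))
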