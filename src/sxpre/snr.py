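"""SNR-model Bragg-peak and hit finder.

Pipeline per frame: Gaussian smoothing -> gradient-magnitude image ->
local-maximum candidate search in valid regions -> 7x7 crop from the raw
image (re-centred on the raw local maximum, because a symmetric peak's
gradient vanishes at its apex) -> signal/background classification by one
of three schemes (rings, simple, adaptive) -> SNR and signal-pixel-count
screening -> per-frame hit decision.

SNR = (<I_sig> - <I_bg>) / sigma_bg with population statistics; the ratio
is invariant under any affine intensity transform a*I + b (a > 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import peak_local_max

from .core import Frame, PixelMask

__all__ = [
    "SnrParams",
    "PeakCandidate",
    "PeakRecord",
    "HitRecord",
    "smooth_image",
    "gradient_image",
    "find_raw_peaks",
    "classify_region_rings",
    "classify_region_simple",
    "classify_region_adaptive",
    "compute_snr",
    "screen_peaks",
    "find_hits_snr",
]

CROP_HALF = 3  # 7x7 crop


class DegenerateRegionError(ValueError):
    pass


@dataclass
class SnrParams:
    """Tunable parameters of the SNR hit finder (intensities in ADU)."""

    gauss_sigma: float = 1.0
    min_gradient: float = 30.0
    min_distance: int = 5
    crop_half: int = CROP_HALF
    region_mode: str = "adaptive"  # rings | simple | adaptive
    r1: float = 1.0
    r2: float = 2.0
    r3: float = 3.0
    n_signal: int = 10
    n_background: int = 35
    bg_fraction: float = 0.70
    n_sigma: float = 5.0
    min_snr: float = 5.0
    min_signal_pixels: int = 2
    max_signal_pixels: int = 40
    min_peaks_for_hit: int = 20

    def __post_init__(self):
        if not 0 < self.bg_fraction < 1:
            raise ValueError("bg_fraction must lie in (0, 1)")
        if not self.r1 < self.r2 <= self.r3:
            raise ValueError("need r1 < r2 <= r3")
        side = 2 * self.crop_half + 1
        if self.n_signal + self.n_background > side * side:
            raise ValueError("n_signal + n_background exceeds crop area")
        if self.min_signal_pixels > self.max_signal_pixels:
            raise ValueError("min_signal_pixels exceeds max_signal_pixels")
        if self.region_mode not in ("rings", "simple", "adaptive"):
            raise ValueError(f"unknown region mode {self.region_mode!r}")


@dataclass(frozen=True)
class PeakCandidate:
    position: tuple[int, int]  # (row, col)
    crop: np.ndarray           # raw-image window, (2h+1, 2h+1)
    crop_mask: np.ndarray      # validity of crop pixels


@dataclass(frozen=True)
class PeakRecord:
    position: tuple[float, float]  # (row, col)
    snr: float
    signal_mean: float
    background_mean: float
    background_std: float
    n_signal_pixels: int
    total_intensity: float


@dataclass(frozen=True)
class HitRecord:
    frame_id: int
    n_peaks: int
    is_hit: bool
    peaks: tuple[PeakRecord, ...] = field(default_factory=tuple)


def smooth_image(frame, gauss_sigma: float) -> np.ndarray:
    """Gaussian smoothing with reflective boundaries; sigma=0 is identity."""
    if gauss_sigma < 0:
        raise ValueError("gauss_sigma must be >= 0")
    data = frame.data if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    if gauss_sigma == 0:
        return data.copy()
    return ndimage.gaussian_filter(data, gauss_sigma, mode="reflect")


def gradient_image(smoothed: np.ndarray) -> np.ndarray:
    """Central-difference gradient magnitude."""
    smoothed = np.asarray(smoothed, dtype=float)
    if smoothed.ndim != 2:
        raise ValueError("expected a 2D image")
    gy, gx = np.gradient(smoothed)
    return np.hypot(gx, gy)


def find_raw_peaks(
    gradient: np.ndarray,
    mask: PixelMask | np.ndarray | None,
    min_gradient: float,
    min_distance: int,
    raw: np.ndarray | None = None,
    crop_half: int = CROP_HALF,
) -> list[PeakCandidate]:
    """Locate peak candidates from the gradient image.

    Local maxima of the gradient with value >= ``min_gradient``, mutually
    separated by >= ``min_distance`` and restricted to valid (mask = 1)
    pixels at least ``crop_half`` from every edge. When the raw image is
    given, each candidate is re-centred on the raw-image local maximum
    within +-1 px before the crop is cut; duplicates are merged.
    """
    gradient = np.asarray(gradient, dtype=float)
    grid = mask.grid if isinstance(mask, PixelMask) else (
        np.ones(gradient.shape, np.uint8) if mask is None else np.asarray(mask))
    if grid.shape != gradient.shape:
        raise ValueError("mask shape does not match image shape")
    search = np.where(grid == 1, gradient, 0.0)
    coords = peak_local_max(
        search,
        min_distance=max(int(round(min_distance)), 1),
        threshold_abs=min_gradient,
        exclude_border=crop_half,
    )
    if raw is None:
        raw = gradient
    raw = np.asarray(raw, dtype=float)
    nrows, ncols = raw.shape
    out: list[PeakCandidate] = []
    seen: set[tuple[int, int]] = set()
    for r, c in coords:
        # re-centre on the raw-image maximum within the 3x3 neighbourhood
        win = raw[r - 1 : r + 2, c - 1 : c + 2]
        dr, dc = np.unravel_index(np.argmax(win), win.shape)
        rr, cc = r + dr - 1, c + dc - 1
        if not (crop_half <= rr < nrows - crop_half
                and crop_half <= cc < ncols - crop_half):
            continue
        if grid[rr, cc] != 1 or (rr, cc) in seen:
            continue
        seen.add((rr, cc))
        sl = (slice(rr - crop_half, rr + crop_half + 1),
              slice(cc - crop_half, cc + crop_half + 1))
        out.append(PeakCandidate((int(rr), int(cc)), raw[sl].copy(),
                                 (grid[sl] == 1)))
    return out


def _crop_distances(shape: tuple[int, int]) -> np.ndarray:
    h = shape[0] // 2
    rows, cols = np.ogrid[: shape[0], : shape[1]]
    return np.hypot(rows - h, cols - h)


def classify_region_rings(crop: np.ndarray, r1: float, r2: float, r3: float,
                          crop_mask: np.ndarray | None = None):
    """Concentric-circle classification: disc r<=r1 is signal, annulus
    r2<=r<=r3 is background."""
    if not r1 < r2 <= r3:
        raise ValueError("need r1 < r2 <= r3")
    crop = np.asarray(crop, dtype=float)
    d = _crop_distances(crop.shape)
    valid = np.ones(crop.shape, bool) if crop_mask is None else np.asarray(
        crop_mask, bool)
    sig = (d <= r1) & valid
    bg = (d >= r2) & (d <= r3) & valid
    if bg.sum() < 2:
        raise DegenerateRegionError("background annulus holds fewer than 2 pixels")
    return crop[sig], crop[bg]


def _ordered_values(crop: np.ndarray, crop_mask: np.ndarray | None):
    """Valid crop values sorted ascending, ties broken row-major."""
    crop = np.asarray(crop, dtype=float)
    flat = crop.ravel()
    if crop_mask is not None:
        keep = np.asarray(crop_mask, bool).ravel()
        idx = np.flatnonzero(keep)
    else:
        idx = np.arange(flat.size)
    order = idx[np.argsort(flat[idx], kind="stable")]
    return flat, order


def classify_region_simple(crop: np.ndarray, n_signal: int = 10,
                           n_background: int = 35,
                           crop_mask: np.ndarray | None = None):
    """Order-statistic classification: top-``n_signal`` intensities are
    signal, bottom-``n_background`` are background."""
    flat, order = _ordered_values(crop, crop_mask)
    if n_signal + n_background > order.size:
        raise ValueError(
            f"n_signal + n_background = {n_signal + n_background} exceeds the "
            f"{order.size} available crop pixels")
    bg_idx = order[:n_background]
    sig_idx = order[order.size - n_signal:]
    return flat[sig_idx], flat[bg_idx]


def classify_region_adaptive(crop: np.ndarray, bg_fraction: float = 0.70,
                             n_sigma: float = 5.0,
                             crop_mask: np.ndarray | None = None):
    """Adaptive classification: the lowest ``bg_fraction`` of pixels form
    the background; signal pixels exceed mean(bg) + n_sigma*std(bg)."""
    if not 0 < bg_fraction < 1:
        raise ValueError("bg_fraction must lie in (0, 1)")
    flat, order = _ordered_values(crop, crop_mask)
    n_bg = int(bg_fraction * order.size)
    if n_bg < 2:
        raise DegenerateRegionError("background region holds fewer than 2 pixels")
    bg_idx = order[:n_bg]
    bg = flat[bg_idx]
    threshold = bg.mean() + n_sigma * bg.std()
    rest = order[n_bg:]
    sig = flat[rest][flat[rest] > threshold]
    return sig, bg, threshold


def compute_snr(signal_pixels: np.ndarray, background_pixels: np.ndarray,
                position: tuple[float, float] = (0.0, 0.0)) -> PeakRecord:
    """Peak statistics from classified signal/background pixel sets."""
    sig = np.asarray(signal_pixels, dtype=float)
    bg = np.asarray(background_pixels, dtype=float)
    if sig.size < 1:
        raise DegenerateRegionError("need at least one signal pixel")
    if bg.size < 2:
        raise DegenerateRegionError("need at least two background pixels")
    bg_std = float(bg.std())
    if bg_std == 0:
        raise DegenerateRegionError("zero background standard deviation")
    sig_mean = float(sig.mean())
    bg_mean = float(bg.mean())
    return PeakRecord(
        position=position,
        snr=(sig_mean - bg_mean) / bg_std,
        signal_mean=sig_mean,
        background_mean=bg_mean,
        background_std=bg_std,
        n_signal_pixels=int(sig.size),
        total_intensity=float(sig.sum()),
    )


def screen_peaks(records, min_snr: float, min_signal_pixels: int,
                 max_signal_pixels: int) -> list[PeakRecord]:
    """Keep peaks with snr >= min_snr and a signal-pixel count inside
    [min_signal_pixels, max_signal_pixels]; order preserved."""
    return [
        r for r in records
        if r.snr >= min_snr
        and min_signal_pixels <= r.n_signal_pixels <= max_signal_pixels
    ]


def _classify(candidate: PeakCandidate, params: SnrParams):
    if params.region_mode == "rings":
        return classify_region_rings(candidate.crop, params.r1, params.r2,
                                     params.r3, candidate.crop_mask)
    if params.region_mode == "simple":
        return classify_region_simple(candidate.crop, params.n_signal,
                                      params.n_background, candidate.crop_mask)
    sig, bg, _ = classify_region_adaptive(candidate.crop, params.bg_fraction,
                                          params.n_sigma, candidate.crop_mask)
    return sig, bg


def find_hits_snr(frame, mask: PixelMask | None = None,
                  params: SnrParams | None = None) -> HitRecord:
    """Run the full SNR hit-finding chain on one frame."""
    params = params or SnrParams()
    data = frame.data if isinstance(frame, Frame) else np.asarray(frame, dtype=float)
    frame_id = frame.frame_id if isinstance(frame, Frame) else 0
    if mask is None:
        mask = PixelMask.all_valid(data.shape)
    if mask.shape != data.shape:
        raise ValueError("mask shape does not match frame shape")
    smoothed = smooth_image(data, params.gauss_sigma)
    grad = gradient_image(smoothed)
    candidates = find_raw_peaks(grad, mask, params.min_gradient,
                                params.min_distance, raw=data,
                                crop_half=params.crop_half)
    records = []
    for cand in candidates:
        if cand.crop_mask.sum() < params.min_signal_pixels + 2:
            continue
        try:
            sig, bg = _classify(cand, params)
            if sig.size == 0:
                continue
            rec = compute_snr(sig, bg, position=(float(cand.position[0]),
                                                 float(cand.position[1])))
        except DegenerateRegionError:
            continue
        records.append(rec)
    peaks = screen_peaks(records, params.min_snr, params.min_signal_pixels,
                         params.max_signal_pixels)
    return HitRecord(frame_id=frame_id, n_peaks=len(peaks),
                     is_hit=len(peaks) >= params.min_peaks_for_hit,
                     peaks=tuple(peaks))
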