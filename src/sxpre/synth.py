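"""Deterministic synthetic-data generators for the test and acceptance
surfaces: diffraction frames with Poisson background plus injected Bragg
peaks, frame datasets with a prescribed hit fraction, and powder-ring peak
sets from a known tilted-detector geometry.

Peaks deposit photons by integrating a 2D Gaussian over pixel areas and
Poisson-sampling the summed rate per pixel, so both hit finders see
realistic count statistics. Every generator is a pure function of its spec
(seed included).

The defaults emulate a typical single-panel serial-crystallography setup:
Poisson background of 3 photons/pixel, 20 ADU per photon, hit frames
carrying 30 Bragg peaks of 150 photons each (sigma 1.2 px, i.e. peak
pixels many sigma above background), and a 10% hit fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import h5py
import numpy as np
from scipy.special import erf

from .calib import NoIntersectionError, PowderPeakSet, project_ring
from .core import CalibrantSpec, Frame, Geometry, two_theta_from_d
from .io_formats import FrameSource

__all__ = [
    "FrameSpec",
    "RingSpec",
    "DatasetTruth",
    "generate_frame",
    "generate_dataset",
    "generate_powder_peaks",
    "default_frame_spec",
    "default_ring_spec",
]


@dataclass(frozen=True)
class FrameSpec:
    """Recipe for one synthetic diffraction frame.

    ``peaks`` lists (row, col, amplitude_photons, sigma_px) per injected
    Bragg peak; ``background_b`` is the mean Poisson photon count per pixel.
    """

    shape: tuple[int, int] = (256, 256)
    background_b: float = 3.0
    adu_per_photon: float = 20.0
    peaks: tuple[tuple[float, float, float, float], ...] = ()
    seed: int = 42

    def __post_init__(self):
        if self.background_b < 0:
            raise ValueError("background_b must be >= 0")
        for row, col, amp, sigma in self.peaks:
            if not (0 <= row < self.shape[0] and 0 <= col < self.shape[1]):
                raise ValueError(f"peak at ({row}, {col}) outside {self.shape}")
            if amp < 0 or sigma <= 0:
                raise ValueError("peak amplitude must be >= 0 and sigma > 0")


@dataclass(frozen=True)
class RingSpec:
    """Recipe for a synthetic powder peak set from a known geometry."""

    geometry: Geometry
    calibrant: CalibrantSpec
    peaks_per_ring: int = 60
    position_noise_sigma: float = 0.0
    seed: int = 42


def _gaussian_rate(shape, row, col, amplitude, sigma):
    """Expected photon count per pixel from one Gaussian peak: the 2D
    Gaussian of total weight ``amplitude`` integrated over pixel areas."""
    half = max(int(math.ceil(4 * sigma)), 2)
    r0 = max(int(math.floor(row)) - half, 0)
    r1 = min(int(math.ceil(row)) + half + 1, shape[0])
    c0 = max(int(math.floor(col)) - half, 0)
    c1 = min(int(math.ceil(col)) + half + 1, shape[1])
    rows = np.arange(r0, r1)
    cols = np.arange(c0, c1)
    s = sigma * math.sqrt(2.0)
    wr = 0.5 * (erf((rows + 0.5 - row) / s) - erf((rows - 0.5 - row) / s))
    wc = 0.5 * (erf((cols + 0.5 - col) / s) - erf((cols - 0.5 - col) / s))
    rate = np.zeros(shape)
    rate[r0:r1, c0:c1] = amplitude * np.outer(wr, wc)
    return rate


def generate_frame(spec: FrameSpec) -> tuple[Frame, list[dict]]:
    """Generate one frame and its ground-truth peak list.

    Pixel values are ``adu_per_photon`` times a Poisson draw whose rate is
    the background plus all Gaussian peak deposits.
    """
    rng = np.random.default_rng(spec.seed)
    rate = np.full(spec.shape, float(spec.background_b))
    truth = []
    for row, col, amp, sigma in spec.peaks:
        deposit = _gaussian_rate(spec.shape, row, col, amp, sigma)
        rate += deposit
        truth.append({"row": row, "col": col, "amplitude_photons": amp,
                      "sigma_px": sigma,
                      "expected_photons": float(deposit.sum())})
    counts = rng.poisson(rate)
    data = counts.astype(float) * spec.adu_per_photon
    return Frame(data, frame_id=0, source=f"synthetic(seed={spec.seed})"), truth


def _random_peak_positions(rng, shape, n_peaks, margin, min_separation):
    """Rejection-sample peak positions with a minimum mutual separation."""
    positions: list[tuple[float, float]] = []
    attempts = 0
    while len(positions) < n_peaks and attempts < 100 * n_peaks:
        attempts += 1
        row = rng.uniform(margin, shape[0] - margin)
        col = rng.uniform(margin, shape[1] - margin)
        if all(math.hypot(row - r, col - c) >= min_separation
               for r, c in positions):
            positions.append((row, col))
    if len(positions) < n_peaks:
        raise RuntimeError("could not place all peaks with the requested "
                           "separation")
    return positions


def default_frame_spec(seed: int = 42, hit: bool = True,
                       shape: tuple[int, int] = (256, 256),
                       n_peaks: int = 30, amplitude: float = 150.0,
                       sigma: float = 1.2, background_b: float = 3.0,
                       adu_per_photon: float = 20.0) -> FrameSpec:
    """Standard study conditions: blank frame or a hit with ``n_peaks``
    well-separated Bragg peaks of ``amplitude`` photons each."""
    peaks: tuple = ()
    if hit:
        rng = np.random.default_rng(seed)
        positions = _random_peak_positions(rng, shape, n_peaks, margin=10,
                                           min_separation=12.0)
        peaks = tuple((row, col, amplitude, sigma) for row, col in positions)
    return FrameSpec(shape=shape, background_b=background_b,
                     adu_per_photon=adu_per_photon, peaks=peaks, seed=seed)


@dataclass(frozen=True)
class DatasetTruth:
    """Which frames of a generated dataset are hits, and their peaks."""

    is_hit: np.ndarray
    peaks_per_frame: tuple[tuple, ...]

    @property
    def n_hits(self) -> int:
        return int(self.is_hit.sum())


def generate_dataset(n_frames: int, hit_fraction: float, out_path,
                     seed: int = 42, shape: tuple[int, int] = (256, 256),
                     n_peaks: int = 30, amplitude: float = 150.0,
                     sigma: float = 1.2, background_b: float = 3.0,
                     adu_per_photon: float = 20.0
                     ) -> tuple[FrameSource, DatasetTruth]:
    """Write an HDF5 frame stack with exactly ``round(n_frames *
    hit_fraction)`` hit frames and return its source plus the truth table."""
    if not 0 <= hit_fraction <= 1:
        raise ValueError("hit_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_hits = int(round(n_frames * hit_fraction))
    hit_ids = rng.choice(n_frames, size=n_hits, replace=False)
    is_hit = np.zeros(n_frames, dtype=bool)
    is_hit[hit_ids] = True
    stack = np.empty((n_frames,) + shape)
    truths = []
    for i in range(n_frames):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        spec = default_frame_spec(seed=sub_seed, hit=bool(is_hit[i]),
                                  shape=shape, n_peaks=n_peaks,
                                  amplitude=amplitude, sigma=sigma,
                                  background_b=background_b,
                                  adu_per_photon=adu_per_photon)
        frame, truth = generate_frame(spec)
        stack[i] = frame.data
        truths.append(tuple(truth))
    with h5py.File(out_path, "w") as f:
        f.create_dataset("data", data=stack, chunks=(1,) + shape,
                         compression="gzip", compression_opts=4,
                         shuffle=True, track_times=False)
    source = FrameSource(str(out_path), "hdf5", "data", n_frames)
    return source, DatasetTruth(is_hit, tuple(truths))


def generate_powder_peaks(spec: RingSpec) -> tuple[PowderPeakSet, dict]:
    """Generate powder peaks for every reachable calibrant ring.

    Peaks sit at uniform cone azimuths on the exact cone-plane
    intersection, with optional Gaussian position jitter. The returned
    truth records the generating geometry and each peak's ring index.
    """
    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry
    wavelength = geom.wavelength
    xs, ys, ring_of = [], [], []
    skipped = []
    psi = np.linspace(0.0, 2.0 * math.pi, spec.peaks_per_ring, endpoint=False)
    for i, d in enumerate(spec.calibrant.d_spacings):
        if wavelength > 2 * d:
            skipped.append(i)
            continue
        tth = two_theta_from_d(wavelength, d)
        try:
            x, y = project_ring(geom, tth, psi)
        except NoIntersectionError:
            skipped.append(i)
            continue
        x = np.atleast_1d(x).astype(float)
        y = np.atleast_1d(y).astype(float)
        if spec.position_noise_sigma > 0:
            x = x + rng.normal(0, spec.position_noise_sigma, size=len(x))
            y = y + rng.normal(0, spec.position_noise_sigma, size=len(y))
        xs.append(x)
        ys.append(y)
        ring_of.append(np.full(len(x), i))
    if xs:
        x_all = np.concatenate(xs)
        y_all = np.concatenate(ys)
        rings = np.concatenate(ring_of)
    else:
        x_all = y_all = rings = np.array([])
    peaks = PowderPeakSet(x_all, y_all, np.ones(len(x_all)))
    truth = {"geometry": geom, "ring_index": rings, "skipped_rings": skipped}
    return peaks, truth


def default_ring_spec(seed: int = 42, position_noise_sigma: float = 0.0,
                      peaks_per_ring: int = 60) -> RingSpec:
    """Standard calibration study conditions: a 1440x1440-pixel detector at
    100 mm with a small tilt, and a cubic calibrant with five reachable
    rings at 12 keV."""
    geometry = Geometry(
        beam_center=(726.0, 715.0),
        distance_mm=100.0,
        pixel_size_mm=0.1,
        photon_energy_ev=12000.0,
        tilt_polar=0.02,
        tilt_azimuth=math.radians(30.0),
    )
    # d spacings of a LaB6-like cubic calibrant (a = 4.157 Å), first five rings
    a = 4.157
    hkl2 = [1, 2, 3, 4, 5]
    calibrant = CalibrantSpec("cubic-calibrant",
                              tuple(a / math.sqrt(m) for m in hkl2))
    return RingSpec(geometry=geometry, calibrant=calibrant,
                    peaks_per_ring=peaks_per_ring,
                    position_noise_sigma=position_noise_sigma, seed=seed)
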