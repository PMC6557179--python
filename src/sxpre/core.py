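"""Shared domain types and physical conversions.

Conventions used throughout the package:

* images are indexed ``(row, col)``, 0-based;
* the beam center is stored as ``(x, y)`` = ``(col, row)`` in fractional
  pixels;
* the lab frame has the sample at the origin and the beam along +Z; the
  detector plane passes through the beam-piercing point at distance ``D``
  along the beam and its normal is given by a polar tilt angle ``theta_t``
  (angle to the beam axis) and an azimuthal angle ``phi_t`` (direction of
  the normal's in-plane projection).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HC_EV_ANGSTROM",
    "Frame",
    "PixelMask",
    "Geometry",
    "CalibrantSpec",
    "energy_to_wavelength",
    "wavelength_to_energy",
    "two_theta_from_d",
]

#: hc in eV·Å (CODATA); lambda[Å] = HC_EV_ANGSTROM / E[eV]
HC_EV_ANGSTROM = 12398.42


class InvalidParameterError(ValueError):
    """A physical parameter is outside its valid domain."""


class UnreachableReflectionError(ValueError):
    """Bragg condition cannot be satisfied (lambda > 2d)."""


def energy_to_wavelength(photon_energy: float) -> float:
    """Convert photon energy in eV to wavelength in Å."""
    if photon_energy <= 0:
        raise InvalidParameterError(
            f"photon energy must be positive, got {photon_energy}"
        )
    return HC_EV_ANGSTROM / photon_energy


def wavelength_to_energy(wavelength: float) -> float:
    """Convert wavelength in Å to photon energy in eV."""
    if wavelength <= 0:
        raise InvalidParameterError(f"wavelength must be positive, got {wavelength}")
    return HC_EV_ANGSTROM / wavelength


def two_theta_from_d(wavelength: float, d: float) -> float:
    """Scattering angle 2θ (rad) for lattice spacing ``d`` via Bragg's law.

    2θ = 2·arcsin(λ / 2d); strictly decreasing in ``d``.
    """
    if wavelength <= 0 or d <= 0:
        raise InvalidParameterError("wavelength and d must be positive")
    ratio = wavelength / (2.0 * d)
    if ratio > 1.0:
        raise UnreachableReflectionError(
            f"lambda={wavelength} Å exceeds 2d={2 * d} Å: reflection unreachable"
        )
    return 2.0 * math.asin(ratio)


@dataclass(frozen=True)
class Frame:
    """One 2D detector image in ADU with its identity."""

    data: np.ndarray
    frame_id: int = 0
    source: str = ""

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError(f"frame data must be 2D, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("frame contains non-finite values")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class PixelMask:
    """Binary pixel validity map: 1 = valid, 0 = excluded."""

    grid: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid)
        if grid.ndim != 2:
            raise ValueError(f"mask must be 2D, got shape {grid.shape}")
        if not np.isin(grid, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")
        object.__setattr__(self, "grid", grid.astype(np.uint8))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @classmethod
    def all_valid(cls, shape: tuple[int, int]) -> "PixelMask":
        return cls(np.ones(shape, dtype=np.uint8))


def _tilt_basis(theta_t: float, phi_t: float):
    """Detector normal and in-plane orthonormal basis in lab coordinates.

    The basis is obtained by the minimal rotation carrying the beam axis
    +Z onto the normal, so for theta_t = 0 the detector axes coincide with
    the lab X/Y axes.
    """
    n = np.array(
        [
            math.sin(theta_t) * math.cos(phi_t),
            math.sin(theta_t) * math.sin(phi_t),
            math.cos(theta_t),
        ]
    )
    if abs(theta_t) < 1e-14:
        return n, np.array([1.0, 0.0, 0.0]), np.array([0.0, 1.0, 0.0])
    axis = np.array([-math.sin(phi_t), math.cos(phi_t), 0.0])
    c, s = math.cos(theta_t), math.sin(theta_t)

    def rotate(v):
        return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)

    return n, rotate(np.array([1.0, 0.0, 0.0])), rotate(np.array([0.0, 1.0, 0.0]))


@dataclass
class Geometry:
    """Single-panel detector geometry.

    Parameters
    ----------
    beam_center : (x, y) in pixels (x = column, y = row)
    distance_mm : sample-to-detector distance along the beam, mm
    pixel_size_mm : pixel pitch, mm
    photon_energy_ev : photon energy, eV
    tilt_polar : polar tilt angle theta_t, rad (normal vs beam axis)
    tilt_azimuth : azimuthal tilt angle phi_t, rad
    """

    beam_center: tuple[float, float]
    distance_mm: float
    pixel_size_mm: float
    photon_energy_ev: float
    tilt_polar: float = 0.0
    tilt_azimuth: float = 0.0

    def __post_init__(self):
        if self.distance_mm <= 0:
            raise InvalidParameterError("distance must be positive")
        if self.pixel_size_mm <= 0:
            raise InvalidParameterError("pixel size must be positive")
        if self.photon_energy_ev <= 0:
            raise InvalidParameterError("photon energy must be positive")
        if not (0 <= self.tilt_polar < math.pi / 2):
            raise InvalidParameterError("tilt_polar must lie in [0, pi/2)")
        self.beam_center = (float(self.beam_center[0]), float(self.beam_center[1]))
        self.distance_mm = float(self.distance_mm)
        self.pixel_size_mm = float(self.pixel_size_mm)
        self.photon_energy_ev = float(self.photon_energy_ev)
        self.tilt_polar = float(self.tilt_polar)
        self.tilt_azimuth = float(self.tilt_azimuth)

    @property
    def wavelength(self) -> float:
        """Wavelength in Å derived from the photon energy."""
        return energy_to_wavelength(self.photon_energy_ev)

    @property
    def normal(self) -> np.ndarray:
        return _tilt_basis(self.tilt_polar, self.tilt_azimuth)[0]

    @property
    def basis(self) -> tuple[np.ndarray, np.ndarray]:
        """In-plane detector axes (e_x, e_y) in lab coordinates."""
        _, ex, ey = _tilt_basis(self.tilt_polar, self.tilt_azimuth)
        return ex, ey

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "beam_center_x": self.beam_center[0],
            "beam_center_y": self.beam_center[1],
            "distance_mm": self.distance_mm,
            "pixel_size_mm": self.pixel_size_mm,
            "photon_energy_ev": self.photon_energy_ev,
            "tilt_polar_deg": math.degrees(self.tilt_polar),
            "tilt_azimuth_deg": math.degrees(self.tilt_azimuth),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Geometry":
        return cls(
            beam_center=(float(d["beam_center_x"]), float(d["beam_center_y"])),
            distance_mm=float(d["distance_mm"]),
            pixel_size_mm=float(d["pixel_size_mm"]),
            photon_energy_ev=float(d["photon_energy_ev"]),
            tilt_polar=math.radians(float(d.get("tilt_polar_deg", 0.0))),
            tilt_azimuth=math.radians(float(d.get("tilt_azimuth_deg", 0.0))),
        )

    def replace(self, **kwargs) -> "Geometry":
        d = dict(
            beam_center=self.beam_center,
            distance_mm=self.distance_mm,
            pixel_size_mm=self.pixel_size_mm,
            photon_energy_ev=self.photon_energy_ev,
            tilt_polar=self.tilt_polar,
            tilt_azimuth=self.tilt_azimuth,
        )
        d.update(kwargs)
        return Geometry(**d)


@dataclass(frozen=True)
class CalibrantSpec:
    """Calibrant with known lattice-plane spacings (Å), sorted descending.

    The largest d spacing gives the smallest scattering angle, i.e. the
    innermost powder ring.
    """

    name: str
    d_spacings: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self):
        ds = tuple(float(d) for d in self.d_spacings)
        if any(d <= 0 for d in ds):
            raise InvalidParameterError("all d spacings must be positive")
        if any(a <= b for a, b in zip(ds, ds[1:])):
            raise InvalidParameterError("d spacings must be strictly decreasing")
        object.__setattr__(self, "d_spacings", ds)

    def two_thetas(self, wavelength: float) -> list[float]:
        """Scattering angles for every reachable ring, innermost first."""
        return [two_theta_from_d(wavelength, d) for d in self.d_spacings
                if wavelength <= 2 * d]
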