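"""Detector geometry calibration from powder rings.

The forward model is the exact cone-plane intersection: the diffracted rays
of one calibrant ring form a cone of half-angle 2θ around the beam; a
detector tilted by (θ_t, φ_t) cuts that cone in an ellipse. Calibration
runs in two steps:

1. a closed-form seed — DBSCAN clustering of peak radii into rings, a
   total-least-squares line through the ring centers giving the tilt
   azimuth, a linear regression of center offsets against tan²(2θ) giving
   the polar tilt, and a beam-center estimate;
2. Nelder-Mead refinement of (beam center, distance, both tilt angles —
   optionally the wavelength) minimizing the summed squared difference
   between each peak's scattering angle under the candidate geometry and
   the ring's model angle from the calibrant d spacings.

Step 1 uses ring centers computed as the mean of member peak positions.
For near-uniform azimuthal coverage that centroid sits at half the true
ellipse-center offset D·tanθ_t·tan²2θ (the mean of cos²ψ is 1/2), which
the regressions account for; any residual bias only perturbs the seed,
which refinement corrects against the exact model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from sklearn.cluster import DBSCAN

from .core import CalibrantSpec, Geometry, two_theta_from_d

__all__ = [
    "PowderPeakSet",
    "RingCluster",
    "LineFit",
    "CalibResult",
    "project_ring",
    "two_theta_of_pixel",
    "cluster_rings",
    "fit_center_line",
    "fit_polar_tilt",
    "estimate_beam_center",
    "residual",
    "calibrate_step1",
    "refine_geometry",
    "calibrate",
]

CENTER_COINCIDENCE_TOL = 0.05  # px: below this the tilt is undetectable


class InsufficientRingsError(ValueError):
    pass


class NoIntersectionError(ValueError):
    pass


@dataclass(frozen=True)
class PowderPeakSet:
    """Powder peaks on the detector: x (col), y (row), intensity."""

    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if not (len(x) == len(y) == len(inten)):
            raise ValueError("peak coordinate arrays must share one length")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return len(self.x)

    @classmethod
    def from_text(cls, path) -> "PowderPeakSet":
        arr = np.loadtxt(path, ndmin=2)
        inten = arr[:, 2] if arr.shape[1] > 2 else np.ones(len(arr))
        return cls(arr[:, 0], arr[:, 1], inten)


@dataclass
class RingCluster:
    """Peaks sharing one d spacing, with centroid and angle estimates."""

    members: np.ndarray      # indices into the PowderPeakSet
    center: tuple[float, float]   # (x, y) mean of member positions
    mean_radius: float
    two_theta: float
    positions: np.ndarray    # (N_i, 2) member (x, y)

    @property
    def n_peaks(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    residual: float
    direction: tuple[float, float]  # unit vector, inner ring -> outer ring


@dataclass
class CalibResult:
    """Outcome of the two-step calibration."""

    geometry: Geometry
    residual_R: float
    step1_geometry: Geometry
    step1_residual: float
    clusters: list[RingCluster] = field(default_factory=list)
    n_evaluations: int = 0

    def summary(self) -> str:
        g, s = self.geometry, self.step1_geometry
        lines = [
            "Geometry calibration",
            f"  rings fitted        : {len(self.clusters)}",
            f"  peaks used          : {sum(c.n_peaks for c in self.clusters)}",
            "                          step 1        refined",
            f"  beam center x [px]  : {s.beam_center[0]:12.3f}  {g.beam_center[0]:12.3f}",
            f"  beam center y [px]  : {s.beam_center[1]:12.3f}  {g.beam_center[1]:12.3f}",
            f"  distance [mm]       : {s.distance_mm:12.4f}  {g.distance_mm:12.4f}",
            f"  polar tilt [deg]    : {math.degrees(s.tilt_polar):12.5f}  {math.degrees(g.tilt_polar):12.5f}",
            f"  azimuth tilt [deg]  : {math.degrees(s.tilt_azimuth):12.4f}  {math.degrees(g.tilt_azimuth):12.4f}",
            f"  residual R [rad^2]  : {self.step1_residual:12.5e}  {self.residual_R:12.5e}",
        ]
        return "\n".join(lines)


# -- forward model ---------------------------------------------------------


def project_ring(geometry: Geometry, two_theta, psi):
    """Exact cone-plane intersection: detector pixel hit by the ray at
    scattering angle ``two_theta`` and cone azimuth ``psi``.

    Vectorized over ``psi`` (and ``two_theta`` of matching shape).
    Raises :class:`NoIntersectionError` for grazing/receding rays.
    """
    tth = np.asarray(two_theta, dtype=float)
    psi = np.asarray(psi, dtype=float)
    s = np.stack(np.broadcast_arrays(
        np.sin(tth) * np.cos(psi),
        np.sin(tth) * np.sin(psi),
        np.cos(tth) * np.ones_like(psi)), axis=-1)
    n = geometry.normal
    ex, ey = geometry.basis
    denom = s @ n
    if np.any(denom <= 1e-12):
        raise NoIntersectionError("ray parallel to or receding from detector")
    D = geometry.distance_mm
    t = D * math.cos(geometry.tilt_polar) / denom
    p = s * t[..., None]
    p0 = np.array([0.0, 0.0, D])
    rel = p - p0
    u = (rel @ ex) / geometry.pixel_size_mm
    v = (rel @ ey) / geometry.pixel_size_mm
    x = geometry.beam_center[0] + u
    y = geometry.beam_center[1] + v
    if x.ndim == 0:
        return float(x), float(y)
    return x, y


def two_theta_of_pixel(geometry: Geometry, x, y):
    """Scattering angle of detector pixel(s) — exact inverse of
    :func:`project_ring` in the angle coordinate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ex, ey = geometry.basis
    u = (x - geometry.beam_center[0]) * geometry.pixel_size_mm
    v = (y - geometry.beam_center[1]) * geometry.pixel_size_mm
    p0 = np.array([0.0, 0.0, geometry.distance_mm])
    p = p0 + u[..., None] * ex + v[..., None] * ey
    norm = np.linalg.norm(p, axis=-1)
    tth = np.arccos(np.clip(p[..., 2] / norm, -1.0, 1.0))
    return float(tth) if tth.ndim == 0 else tth


# -- step 1 ----------------------------------------------------------------


def cluster_rings(peaks: PowderPeakSet, geometry: Geometry,
                  eps: float = 10.0, min_samples: int = 4) -> list[RingCluster]:
    """Group powder peaks into rings by DBSCAN on their radii.

    Radii are measured from the current beam-center estimate; DBSCAN noise
    points are discarded. Clusters are returned sorted by mean radius
    (ring 1 = innermost), each with its centroid, mean radius and the
    scattering angle arctan(r·pixel_size/D) under the current geometry.
    """
    if len(peaks) < min_samples:
        raise InsufficientRingsError(
            f"{len(peaks)} peaks but min_samples={min_samples}")
    cx, cy = geometry.beam_center
    radii = np.hypot(peaks.x - cx, peaks.y - cy)
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(
        radii.reshape(-1, 1))
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        idx = np.flatnonzero(labels == lab)
        pos = np.column_stack([peaks.x[idx], peaks.y[idx]])
        r = float(radii[idx].mean())
        clusters.append(RingCluster(
            members=idx,
            center=(float(pos[:, 0].mean()), float(pos[:, 1].mean())),
            mean_radius=r,
            two_theta=math.atan(r * geometry.pixel_size_mm / geometry.distance_mm),
            positions=pos,
        ))
    clusters.sort(key=lambda c: c.mean_radius)
    return clusters


def _g(two_theta: float) -> float:
    """Regressor of the small-tilt center-offset law: g(x) = tan²x."""
    return math.tan(two_theta) ** 2


def fit_center_line(clusters: list[RingCluster]):
    """Total-least-squares line through the ring centers.

    Returns ``(LineFit, phi_t, tilt_detected)``. The line direction is
    oriented from the innermost to the outermost ring center; because ring
    centers drift *away from* the tilt azimuth as 2θ grows, the azimuthal
    tilt angle is the direction opposite to the fitted line:
    φ_t = angle(-û). Coincident centers (max pairwise distance below
    0.05 px) mean the tilt is undetectable and φ_t = 0 is reported.
    """
    if len(clusters) < 2:
        raise InsufficientRingsError("need at least 2 rings to fit the tilt")
    centers = np.array([c.center for c in clusters])
    span = np.linalg.norm(
        centers[:, None, :] - centers[None, :, :], axis=-1).max()
    if span < CENTER_COINCIDENCE_TOL:
        fit = LineFit(0.0, float(centers[:, 1].mean()), 0.0, (1.0, 0.0))
        return fit, 0.0, False
    mean = centers.mean(axis=0)
    u_mat, s_vals, vt = np.linalg.svd(centers - mean, full_matrices=False)
    direction = vt[0]
    # orient inner -> outer
    if np.dot(centers[-1] - centers[0], direction) < 0:
        direction = -direction
    resid = float(s_vals[1] ** 2) if len(s_vals) > 1 else 0.0
    dx, dy = direction
    if abs(dx) > 1e-12:
        slope = dy / dx
        intercept = mean[1] - slope * mean[0]
    else:
        slope = math.inf
        intercept = math.nan
    phi_t = math.atan2(-dy, -dx)
    return LineFit(slope, intercept, resid, (float(dx), float(dy))), phi_t, True


def fit_polar_tilt(clusters: list[RingCluster], geometry: Geometry,
                   line: LineFit) -> float:
    """Polar tilt from the drift of ring centers along the fitted line.

    The signed center offsets Δ_i1 = (O_i − O_1)·û are regressed against
    g(2θ_i) − g(2θ_1) with g(x) = tan²x. For centroid-based centers the
    slope is k = D·tanθ_t/(2·pixel_size), hence
    θ_t = arctan(2k·pixel_size/D).
    """
    if len(clusters) < 2:
        raise InsufficientRingsError("need at least 2 rings to fit the tilt")
    u = np.asarray(line.direction)
    o1 = np.asarray(clusters[0].center)
    g1 = _g(clusters[0].two_theta)
    delta = np.array([(np.asarray(c.center) - o1) @ u for c in clusters])
    greg = np.array([_g(c.two_theta) - g1 for c in clusters])
    spread = greg.max() - greg.min()
    if spread < 1e-12:
        raise InsufficientRingsError("degenerate regressor spread: rings share "
                                     "one scattering angle")
    k = np.polyfit(greg, delta, 1)[0]
    return math.atan(2.0 * k * geometry.pixel_size_mm / geometry.distance_mm)


def estimate_beam_center(clusters: list[RingCluster], line: LineFit,
                         tilt_polar: float, tilt_detected: bool,
                         geometry: Geometry) -> tuple[float, float]:
    """Beam center from the innermost ring center.

    Untilted case: the mean of all ring centers. Tilted: the innermost
    centroid is displaced from the beam center by
    δ_1 = D·tanθ_t·tan²(2θ_1)/(2·pixel_size) along the line direction, so
    the beam center is O_1 − δ_1·û.
    """
    centers = np.array([c.center for c in clusters])
    if not tilt_detected or tilt_polar == 0.0:
        return float(centers[:, 0].mean()), float(centers[:, 1].mean())
    delta1 = (geometry.distance_mm / (2.0 * geometry.pixel_size_mm)
              * math.tan(tilt_polar) * _g(clusters[0].two_theta))
    u = np.asarray(line.direction)
    bc = np.asarray(clusters[0].center) - delta1 * u
    return float(bc[0]), float(bc[1])


# -- residual and refinement ----------------------------------------------


def residual(geometry: Geometry, clusters: list[RingCluster],
             model_angles: list[float] | None = None) -> float:
    """Sum of squared scattering-angle residuals over all peaks.

    ``model_angles`` gives the reference 2θ per ring; when omitted, each
    ring's model value is the mean of its peaks' calculated angles (the
    step-1 convention).
    """
    total = 0.0
    for i, cluster in enumerate(clusters):
        tth = two_theta_of_pixel(geometry, cluster.positions[:, 0],
                                 cluster.positions[:, 1])
        model = float(np.mean(tth)) if model_angles is None else model_angles[i]
        total += float(np.sum((tth - model) ** 2))
    return total


def calibrate_step1(peaks: PowderPeakSet, initial: Geometry,
                    eps: float = 10.0, min_samples: int = 4
                    ) -> tuple[Geometry, list[RingCluster]]:
    """Closed-form first calibration step: clustering, tilt-azimuth line
    fit, polar-tilt regression and beam-center estimation."""
    clusters = cluster_rings(peaks, initial, eps=eps, min_samples=min_samples)
    if len(clusters) < 2:
        raise InsufficientRingsError(
            f"only {len(clusters)} ring cluster(s) found; need >= 2")
    line, phi_t, detected = fit_center_line(clusters)
    theta_t = fit_polar_tilt(clusters, initial, line) if detected else 0.0
    if theta_t < 0:  # fold a negative polar angle into the azimuth
        theta_t, phi_t = -theta_t, math.atan2(-math.sin(phi_t),
                                              -math.cos(phi_t))
    bc = estimate_beam_center(clusters, line, theta_t, detected, initial)
    geom1 = initial.replace(beam_center=bc, tilt_polar=theta_t,
                            tilt_azimuth=phi_t if detected else 0.0)
    return geom1, clusters


def refine_geometry(step1_geometry: Geometry, clusters: list[RingCluster],
                    calibrant: CalibrantSpec, free_wavelength: bool = False,
                    max_evaluations: int = 2000) -> CalibResult:
    """Nelder-Mead refinement of the geometry against the calibrant.

    Rings are matched to d spacings by rank order (innermost ring = largest
    d); the model angle of ring i is 2·arcsin(λ/2d_i). The refined residual
    never exceeds the step-1 residual.
    """
    if len(clusters) != len(calibrant.d_spacings):
        raise ValueError(
            f"{len(clusters)} ring clusters but calibrant "
            f"{calibrant.name!r} lists {len(calibrant.d_spacings)} d spacings")
    g0 = step1_geometry

    def model_angles(wavelength: float) -> list[float]:
        return [two_theta_from_d(wavelength, d) for d in calibrant.d_spacings]

    def unpack(vec) -> Geometry:
        xc, yc, dist, tx, ty = vec[:5]
        theta = math.hypot(tx, ty)
        phi = math.atan2(ty, tx) if theta > 0 else 0.0
        energy = g0.photon_energy_ev
        if free_wavelength:
            energy = g0.photon_energy_ev * g0.wavelength / vec[5]
        return Geometry(beam_center=(xc, yc), distance_mm=dist,
                        pixel_size_mm=g0.pixel_size_mm,
                        photon_energy_ev=energy,
                        tilt_polar=theta, tilt_azimuth=phi)

    def objective(vec) -> float:
        try:
            g = unpack(vec)
        except ValueError:
            return np.inf
        return residual(g, clusters, model_angles(g.wavelength))

    x0 = [g0.beam_center[0], g0.beam_center[1], g0.distance_mm,
          g0.tilt_polar * math.cos(g0.tilt_azimuth),
          g0.tilt_polar * math.sin(g0.tilt_azimuth)]
    if free_wavelength:
        x0.append(g0.wavelength)
    step1_res = objective(np.asarray(x0))
    opt = minimize(objective, np.asarray(x0), method="Nelder-Mead",
                   options={"maxfev": max_evaluations, "xatol": 1e-9,
                            "fatol": 1e-15})
    best = opt.x if opt.fun <= step1_res else np.asarray(x0)
    refined = unpack(best)
    return CalibResult(
        geometry=refined,
        residual_R=float(min(opt.fun, step1_res)),
        step1_geometry=g0,
        step1_residual=float(step1_res),
        clusters=clusters,
        n_evaluations=int(opt.nfev),
    )


def calibrate(peaks: PowderPeakSet, initial: Geometry,
              calibrant: CalibrantSpec, eps: float = 10.0,
              min_samples: int = 4, free_wavelength: bool = False,
              max_evaluations: int = 2000) -> CalibResult:
    """Run both calibration steps on a powder peak set."""
    geom1, clusters = calibrate_step1(peaks, initial, eps=eps,
                                      min_samples=min_samples)
    return refine_geometry(geom1, clusters, calibrant,
                           free_wavelength=free_wavelength,
                           max_evaluations=max_evaluations)
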