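"""Per-lumen shape descriptors and their cohort aggregation statistics.

This block contributes 96 of the 242 catalog features: 24 per-lumen
descriptors x 4 cohort statistics {mean, sd, median, p5/p95 ratio}.

The 24 descriptors
------------------
* ``fd1..fd10`` — Fourier descriptors of the centroid-distance signal
  r(t): the boundary is resampled to N = 128 equal-arclength points, the
  distances from the area centroid are Fourier transformed, and
  FD_k = |F_k| / |F_0| for k = 1..10.  Using the centroid-distance (not
  complex-coordinate) signal and magnitudes normalized by the DC term
  makes the descriptors invariant to translation, rotation, boundary
  starting point and uniform scale.
* ``hu1..hu7`` — the seven Hu invariant moments of the filled polygon,
  computed from exact polygon moments (Green's theorem) and signed-log
  compressed m -> sign(m) * log10(1 + |m| * 1e6) / 6 for numeric
  stability (compression can be switched off to obtain raw values).
* ``distance_ratio`` — mean(radii)/max(radii), in (0, 1]; 1 for a circle,
  smaller for elongated or irregular shapes.
* ``radius_sd_ratio`` — SD(radii)/mean(radii) (boundary roughness /
  eccentricity).
* ``area_ratio`` — polygon area / convex-hull area (solidity).
* ``perimeter_ratio`` — convex-hull perimeter / polygon perimeter.
* ``smoothness`` — mean |r(t) - (r(t-1)+r(t+1))/2| / mean radius.
* ``fractal_dim`` — box-counting dimension of the boundary in [1, 2],
  measured in a canonical (centroid + principal-axis) frame so the value
  is invariant to rigid motion.
* ``circularity`` — 4*pi*A / P^2, the classical isoperimetric roundness.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from shapely.geometry import Polygon

from .io_core import SENTINEL, LumenSet, ValidationError

N_BOUNDARY_SAMPLES = 128
N_FOURIER = 10

DESCRIPTOR_NAMES: tuple[str, ...] = tuple(
    [f"fd{k}" for k in range(1, N_FOURIER + 1)]
    + [f"hu{k}" for k in range(1, 8)]
    + [
        "distance_ratio",
        "radius_sd_ratio",
        "area_ratio",
        "perimeter_ratio",
        "smoothness",
        "fractal_dim",
        "circularity",
    ]
)

STAT_NAMES: tuple[str, ...] = ("mean", "sd", "median", "p5_p95")

SHAPE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"shape:{stat}:{desc}" for desc in DESCRIPTOR_NAMES for stat in STAT_NAMES
)


# ---------------------------------------------------------------------------
# Boundary resampling
# ---------------------------------------------------------------------------

@dataclass
class BoundarySignal:
    """Equal-arclength boundary samples of a simple polygon.

    points are ordered counterclockwise; radii are the centroid-to-boundary
    distances (the signal the Fourier descriptors are computed on).
    """

    points: np.ndarray  # (N, 2) um
    centroid: np.ndarray  # (2,)
    radii: np.ndarray  # (N,)


def _signed_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def resample_boundary(polygon: Polygon | np.ndarray, n: int = N_BOUNDARY_SAMPLES) -> BoundarySignal:
    """Resample a polygon boundary to ``n`` equal-arclength points (CCW)."""
    if isinstance(polygon, Polygon):
        poly = polygon
    else:
        poly = Polygon(np.asarray(polygon, dtype=float))
    if not poly.is_valid:
        raise ValidationError("polygon is self-intersecting or degenerate")
    if poly.length <= 0 or poly.area <= 0:
        raise ValidationError("polygon has zero perimeter or area")
    verts = np.asarray(poly.exterior.coords, dtype=float)[:-1]
    if _signed_area(verts) < 0:  # shapely exteriors may be CW; normalize CCW
        verts = verts[::-1]
    closed = np.vstack([verts, verts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    targets = np.arange(n) * total / n
    idx = np.searchsorted(cum, targets, side="right") - 1
    idx = np.clip(idx, 0, len(seg) - 1)
    frac = (targets - cum[idx]) / np.where(seg[idx] > 0, seg[idx], 1.0)
    pts = closed[idx] + frac[:, None] * (closed[idx + 1] - closed[idx])
    centroid = np.array([poly.centroid.x, poly.centroid.y])
    radii = np.linalg.norm(pts - centroid, axis=1)
    if np.any(radii <= 0):
        raise ValidationError("boundary passes through the centroid")
    return BoundarySignal(points=pts, centroid=centroid, radii=radii)


# ---------------------------------------------------------------------------
# Fourier descriptors
# ---------------------------------------------------------------------------

def fourier_descriptors(b: BoundarySignal, n_fd: int = N_FOURIER) -> np.ndarray:
    """FD_k = |F_k| / |F_0| of the centroid-distance signal, k = 1..n_fd."""
    r = np.asarray(b.radii, dtype=float)
    if np.mean(r) <= 0:
        raise ValidationError("zero mean radius")
    F = np.fft.fft(r)
    dc = np.abs(F[0])
    return np.abs(F[1 : n_fd + 1]) / dc


# ---------------------------------------------------------------------------
# Hu invariant moments (exact polygon moments via Green's theorem)
# ---------------------------------------------------------------------------

def _polygon_raw_moment(verts: np.ndarray, p: int, q: int) -> float:
    """Exact raw moment m_pq = iint x^p y^q dA over a simple polygon."""
    x, y = verts[:, 0], verts[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    inner = np.zeros_like(cross)
    for k in range(p + 1):
        for l in range(q + 1):
            inner += (
                comb(k + l, l)
                * comb(p + q - k - l, q - l)
                * x**k
                * x1 ** (p - k)
                * y**l
                * y1 ** (q - l)
            )
    denom = (p + q + 2) * (p + q + 1) * comb(p + q, p)
    return float(np.sum(cross * inner) / denom)


def polygon_central_moments(polygon: Polygon | np.ndarray) -> dict[tuple[int, int], float]:
    """Central moments mu_pq (p+q <= 3) of the filled polygon, exact."""
    if isinstance(polygon, Polygon):
        verts = np.asarray(polygon.exterior.coords, dtype=float)[:-1]
    else:
        verts = np.asarray(polygon, dtype=float)
    if _signed_area(verts) < 0:
        verts = verts[::-1]
    m00 = _polygon_raw_moment(verts, 0, 0)
    if m00 <= 0:
        raise ValidationError("zero-area polygon")
    cx = _polygon_raw_moment(verts, 1, 0) / m00
    cy = _polygon_raw_moment(verts, 0, 1) / m00
    centered = verts - np.array([cx, cy])
    mu = {}
    for p in range(4):
        for q in range(4 - p):
            mu[(p, q)] = _polygon_raw_moment(centered, p, q)
    return mu


def hu_log_compress(m: np.ndarray) -> np.ndarray:
    """Signed-log compression m -> sign(m) * log10(1 + |m| * 1e6) / 6."""
    m = np.asarray(m, dtype=float)
    return np.sign(m) * np.log10(1.0 + np.abs(m) * 1e6) / 6.0


def invariant_moments(polygon: Polygon | np.ndarray, log_compress: bool = True) -> np.ndarray:
    """The seven Hu moments phi1..phi7 of the filled polygon.

    Computed from exact normalized central moments; translation, rotation
    and scale invariant.  phi7 flips sign under mirroring.
    """
    mu = polygon_central_moments(polygon)
    mu00 = mu[(0, 0)]

    def eta(p: int, q: int) -> float:
        return mu[(p, q)] / mu00 ** (1 + (p + q) / 2)

    n20, n02, n11 = eta(2, 0), eta(0, 2), eta(1, 1)
    n30, n03, n21, n12 = eta(3, 0), eta(0, 3), eta(2, 1), eta(1, 2)
    phi = np.empty(7)
    phi[0] = n20 + n02
    phi[1] = (n20 - n02) ** 2 + 4 * n11**2
    phi[2] = (n30 - 3 * n12) ** 2 + (3 * n21 - n03) ** 2
    phi[3] = (n30 + n12) ** 2 + (n21 + n03) ** 2
    phi[4] = (n30 - 3 * n12) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) + (3 * n21 - n03) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    phi[5] = (n20 - n02) * ((n30 + n12) ** 2 - (n21 + n03) ** 2) + 4 * n11 * (
        n30 + n12
    ) * (n21 + n03)
    phi[6] = (3 * n21 - n03) * (n30 + n12) * (
        (n30 + n12) ** 2 - 3 * (n21 + n03) ** 2
    ) - (n30 - 3 * n12) * (n21 + n03) * (3 * (n30 + n12) ** 2 - (n21 + n03) ** 2)
    if log_compress:
        phi = hu_log_compress(phi)
    return phi


# ---------------------------------------------------------------------------
# Radius / contour ratios
# ---------------------------------------------------------------------------

def distance_ratio(b: BoundarySignal) -> float:
    """mean(radii)/max(radii) in (0, 1] — 1 for a circle."""
    return float(np.mean(b.radii) / np.max(b.radii))


def radius_sd_ratio(b: BoundarySignal) -> float:
    return float(np.std(b.radii, ddof=1) / np.mean(b.radii))


def smoothness(b: BoundarySignal) -> float:
    r = b.radii
    interp = 0.5 * (np.roll(r, 1) + np.roll(r, -1))
    return float(np.mean(np.abs(r - interp)) / np.mean(r))


def fractal_dimension(b: BoundarySignal) -> float:
    """Box-counting dimension of the boundary, clipped to [1, 2].

    The boundary is moved to a canonical frame (centroid at origin,
    principal axis along x, max radius scaled to 1) before counting so
    the value does not depend on the pose of the shape in the image.
    """
    pts = b.points - b.centroid
    # principal axis from second moments of the boundary samples; skip the
    # rotation for (near-)isotropic shapes, where the angle is pure noise
    cov = pts.T @ pts
    aniso = np.hypot(cov[0, 0] - cov[1, 1], 2 * cov[0, 1])
    if aniso > 1e-6 * np.trace(cov):
        theta = 0.5 * np.arctan2(2 * cov[0, 1], cov[0, 0] - cov[1, 1])
        c, s = np.cos(-theta), np.sin(-theta)
        pts = pts @ np.array([[c, -s], [s, c]]).T
    scale = np.max(np.linalg.norm(pts, axis=1))
    pts = pts / scale
    # densify: boxes must be smaller than the sampling interval
    dense = []
    closed = np.vstack([pts, pts[:1]])
    for a, bb in zip(closed[:-1], closed[1:]):
        dense.append(np.linspace(a, bb, 8, endpoint=False))
    dense = np.concatenate(dense)
    sizes = 2.0 ** -np.arange(2, 6)  # 1/4 .. 1/32 of max radius
    counts = []
    for size in sizes:
        boxes = np.unique(np.floor((dense + 1.0) / size).astype(int), axis=0)
        counts.append(len(boxes))
    slope = np.polyfit(np.log(1.0 / sizes), np.log(counts), 1)[0]
    return float(np.clip(slope, 1.0, 2.0))


def circularity(polygon: Polygon) -> float:
    """4*pi*A / P^2 — 1 for a circle, < 1 otherwise."""
    return float(4.0 * np.pi * polygon.area / polygon.length**2)


# ---------------------------------------------------------------------------
# Per-lumen descriptor vector
# ---------------------------------------------------------------------------

def lumen_descriptors(polygon: Polygon, n_samples: int = N_BOUNDARY_SAMPLES,
                      hu_compress: bool = True) -> np.ndarray:
    """All 24 per-lumen shape descriptors, in DESCRIPTOR_NAMES order."""
    b = resample_boundary(polygon, n_samples)
    hull = polygon.convex_hull
    fd = fourier_descriptors(b)
    hu = invariant_moments(polygon, log_compress=hu_compress)
    rest = np.array(
        [
            distance_ratio(b),
            radius_sd_ratio(b),
            polygon.area / hull.area,
            hull.length / polygon.length,
            smoothness(b),
            fractal_dimension(b),
            circularity(polygon),
        ]
    )
    return np.concatenate([fd, hu, rest])


# ---------------------------------------------------------------------------
# Cohort aggregation
# ---------------------------------------------------------------------------

def aggregate(values: np.ndarray, p5_p95_as_ratio: bool = True) -> dict[str, float]:
    """{mean, sd, median, p5_p95} of the finite entries of ``values``.

    SD uses denominator n-1 (0 when n = 1); percentiles use linear
    interpolation between order statistics; the fourth statistic is
    p5/p95 (sentinel when p95 = 0), or p95 - p5 when configured as a
    range.  Empty input -> all sentinel.
    """
    vals = np.asarray(values, dtype=float)
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return {s: SENTINEL for s in STAT_NAMES}
    p5, p95 = np.percentile(vals, [5, 95])
    if p5_p95_as_ratio:
        tail = p5 / p95 if p95 != 0 else SENTINEL
    else:
        tail = p95 - p5
    return {
        "mean": float(np.mean(vals)),
        "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0,
        "median": float(np.median(vals)),
        "p5_p95": float(tail) if np.isfinite(tail) else SENTINEL,
    }


def shape_block(ls: LumenSet, n_samples: int = N_BOUNDARY_SAMPLES,
                hu_compress: bool = True,
                p5_p95_as_ratio: bool = True) -> dict[str, float]:
    """The 96 shape features of a region: 24 descriptors x 4 statistics."""
    if len(ls) < 1:
        return {name: SENTINEL for name in SHAPE_FEATURE_NAMES}
    per_lumen = np.array(
        [lumen_descriptors(p, n_samples, hu_compress) for p in ls.lumens]
    )  # (K, 24)
    out: dict[str, float] = {}
    for d, desc in enumerate(DESCRIPTOR_NAMES):
        stats = aggregate(per_lumen[:, d], p5_p95_as_ratio)
        for stat in STAT_NAMES:
            out[f"shape:{stat}:{desc}"] = stats[stat]
    return out
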