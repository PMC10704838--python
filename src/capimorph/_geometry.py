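"""Small computational-geometry helpers shared across modules.

Everything here operates on plain (n, 2) float arrays of vertex
coordinates; shapely objects are constructed by callers where spatial
predicates are needed.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as (n, 2) vertices.

    The polygon is implicitly closed (last vertex connects to first).
    Returns the absolute area.
    """
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_perimeter(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    d = np.diff(np.vstack([v, v[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    """Area centroid of a simple closed polygon."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    if abs(a) < 1e-300:
        return v.mean(axis=0)
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def feret_diameters(vertices: np.ndarray, n_directions: int = 180) -> tuple[float, float]:
    """(max, min) caliper (Feret) diameters of a point set.

    Projects the convex hull onto ``n_directions`` evenly spaced
    directions over a half-turn; the width in each direction is the
    projection range. Adequate for smooth contours; the angular
    discretisation error is O(theta^2) ~ 1e-4 relative at the default.
    """
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 vertices for caliper diameters")
    try:
        hull = v[ConvexHull(v).vertices]
    except Exception as exc:  # degenerate (collinear) input
        raise ValueError(f"degenerate contour: {exc}") from exc
    theta = np.linspace(0.0, np.pi, n_directions, endpoint=False)
    dirs = np.column_stack([np.cos(theta), np.sin(theta)])
    proj = hull @ dirs.T  # (n_hull, n_directions)
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.max()), float(widths.min())


def min_feret_diameter(vertices: np.ndarray, n_directions: int = 180) -> float:
    """Minimal caliper diameter -- the standard 'lesser fiber diameter'."""
    return feret_diameters(vertices, n_directions)[1]


def scale_about_centroid(vertices: np.ndarray, linear_factor: float) -> np.ndarray:
    """Shrink/grow a polygon about its area centroid by a linear factor."""
    v = np.asarray(vertices, dtype=float)
    c = polygon_centroid(v)
    return c + (v - c) * linear_factor


def ray_segment_intersections(
    origin: np.ndarray, direction: np.ndarray, ring: np.ndarray
) -> np.ndarray:
    """Distances t > 0 along origin + t*direction at which the ray crosses
    the closed polyline ``ring`` ((n, 2), implicitly closed).

    Vectorised ray/segment test; returns a sorted array of distances
    (empty if no crossing). ``direction`` need not be normalised; the
    returned t values are in units of |direction|.
    """
    o = np.asarray(origin, dtype=float)
    d = np.asarray(direction, dtype=float)
    p = np.asarray(ring, dtype=float)
    q = np.roll(p, -1, axis=0)
    e = q - p  # segment vectors
    # Solve o + t d = p + u e  for each segment, 0 <= u <= 1, t > 0
    denom = d[0] * (-e[:, 1]) - d[1] * (-e[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        rhs = p - o
        t = (rhs[:, 0] * (-e[:, 1]) - rhs[:, 1] * (-e[:, 0])) / denom
        u = (d[0] * rhs[:, 1] - d[1] * rhs[:, 0]) / denom
    ok = np.isfinite(t) & (t > 1e-12) & (u >= -1e-12) & (u <= 1 + 1e-12)
    return np.sort(t[ok])
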