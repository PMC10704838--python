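"""Capillarity stereology on 2-D fields of view.

Implements the classical unbiased counting frame (two acceptance edges,
two forbidden edges with infinite extensions) for profile counting, a
test-point grid for area-fraction estimation, and the derived estimators:
capillary-to-fiber ratio (C/F), mean cross-sectional fiber area (MCSFA)
and capillary density.

Counting convention (Gundersen): the forbidden line runs down the line of
the left edge from above the frame, along the left and bottom edges, and
continues below the frame down the line of the right edge. A profile is
counted iff it intersects the closed frame and does not touch the
forbidden line. Tiling the plane with such frames counts every profile
exactly once.

MCSFA uses the point-count identity: the fraction of test points landing
on fiber profiles estimates the fiber area fraction; multiplying by the
grid area and dividing by the number of fiber profiles in the frame gives
the mean profile area. Capillary density is capillary profiles per unit
fiber area, reported per mm^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon, box
from shapely.strtree import STRtree

from .synthetic import FiberProfile, TissueScene

EDGE_TOL = 1e-9  # um; touch tolerance for edge adjudication
_EXT = 1e8  # finite stand-in for the infinite line extensions


@dataclass
class PointGrid:
    """n_rows x n_cols test points at the centres of square subcells.

    The grid's bounding square (side n * spacing) is the counting frame,
    so total_area = (n_cols * spacing) * (n_rows * spacing) and each test
    point represents one subcell of area spacing^2.
    """

    n_rows: int = 10
    n_cols: int = 10
    spacing: float = 25.0  # um
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def total_area(self) -> float:
        return (self.n_cols * self.spacing) * (self.n_rows * self.spacing)

    @property
    def n_points(self) -> int:
        return self.n_rows * self.n_cols

    def points(self) -> np.ndarray:
        ox, oy = self.origin
        xs = ox + (np.arange(self.n_cols) + 0.5) * self.spacing
        ys = oy + (np.arange(self.n_rows) + 0.5) * self.spacing
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def frame(self) -> "CountingFrame":
        ox, oy = self.origin
        return CountingFrame(
            rectangle=(ox, oy, ox + self.n_cols * self.spacing, oy + self.n_rows * self.spacing)
        )

    @classmethod
    def for_rectangle(
        cls, rect: tuple[float, float, float, float], n_rows: int = 10, n_cols: int = 10
    ) -> "PointGrid":
        """Grid whose counting frame coincides with ``rect`` (must be square-compatible)."""
        x0, y0, x1, y1 = rect
        sx = (x1 - x0) / n_cols
        sy = (y1 - y0) / n_rows
        if abs(sx - sy) > 1e-9 * max(sx, sy):
            raise ValueError("rectangle is not compatible with a uniform square grid")
        return cls(n_rows=n_rows, n_cols=n_cols, spacing=sx, origin=(x0, y0))


@dataclass
class CountingFrame:
    """Unbiased counting frame: acceptance top+right, forbidden bottom+left."""

    rectangle: tuple[float, float, float, float]  # x0, y0, x1, y1
    acceptance_edges: frozenset = frozenset({"top", "right"})
    forbidden_edges: frozenset = frozenset({"bottom", "left"})

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.rectangle
        if not (x0 < x1 and y0 < y1):
            raise ValueError("frame rectangle must satisfy x0 < x1 and y0 < y1")
        if self.acceptance_edges & self.forbidden_edges:
            raise ValueError("acceptance and forbidden edge sets must be disjoint")
        if self.acceptance_edges | self.forbidden_edges != {"top", "right", "bottom", "left"}:
            raise ValueError("edge sets must together cover all four edges")

    def forbidden_line(self) -> LineString:
        """The forbidden polyline with its infinite extensions.

        Down the left-edge line from far above, along the left edge, along
        the bottom edge, then down the right-edge line to far below.
        """
        x0, y0, x1, y1 = self.rectangle
        return LineString([(x0, y1 + _EXT), (x0, y0), (x1, y0), (x1, y0 - _EXT)])

    def region(self) -> Polygon:
        return box(*self.rectangle)


@dataclass
class StereologyCounts:
    """Raw counted quantities for one or more pooled fields of view."""

    n_capillary_profiles: int = 0
    n_fiber_profiles: int = 0
    p_fiber: int = 0
    p_total: int = 0
    total_area: float = 0.0  # um^2, summed grid area over pooled FOVs

    def __post_init__(self) -> None:
        if min(self.n_capillary_profiles, self.n_fiber_profiles, self.p_fiber, self.p_total) < 0:
            raise ValueError("counts must be >= 0")
        if self.p_fiber > self.p_total:
            raise ValueError("p_fiber cannot exceed p_total")

    @property
    def fiber_profile_area_total(self) -> float:
        """Point-count estimate of total fiber profile area (um^2)."""
        if self.p_total == 0:
            return 0.0
        return self.p_fiber / self.p_total * self.total_area

    def __add__(self, other: "StereologyCounts") -> "StereologyCounts":
        return StereologyCounts(
            n_capillary_profiles=self.n_capillary_profiles + other.n_capillary_profiles,
            n_fiber_profiles=self.n_fiber_profiles + other.n_fiber_profiles,
            p_fiber=self.p_fiber + other.p_fiber,
            p_total=self.p_total + other.p_total,
            total_area=self.total_area + other.total_area,
        )


@dataclass
class CapillarityEstimate:
    """Derived capillarity measures plus the counts they came from."""

    cf_ratio: float
    mcsfa: float  # um^2
    capillary_density: float  # per mm^2
    counts: StereologyCounts = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


def _as_geometry(profile) -> shapely.Geometry:
    arr = np.asarray(profile, dtype=float)
    if arr.ndim == 1:
        return Point(arr)
    if arr.ndim == 2 and arr.shape[0] < 3:
        return Point(arr[0])
    poly = Polygon(arr)
    if poly.area <= 0:  # degenerate polygon treated as a point
        return Point(arr[0])
    return poly


def count_with_forbidden_line(frame: CountingFrame, profiles) -> int:
    """Count profiles under the forbidden-line rule.

    A profile (polygon vertex array or point) is counted iff it
    intersects the closed frame and stays clear (> EDGE_TOL) of the
    forbidden line and its infinite extensions.
    """
    if len(profiles) == 0:
        return 0
    region = frame.region()
    forbidden = frame.forbidden_line()
    n = 0
    for profile in profiles:
        geom = _as_geometry(profile)
        if geom.distance(region) <= EDGE_TOL and geom.distance(forbidden) > EDGE_TOL:
            n += 1
    return n


def count_points_with_forbidden_line(frame: CountingFrame, points: np.ndarray) -> int:
    """Vectorised forbidden-line counting for point profiles (n, 2)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return 0
    x0, y0, x1, y1 = frame.rectangle
    x, y = pts[:, 0], pts[:, 1]
    in_frame = (x >= x0 - EDGE_TOL) & (x <= x1 + EDGE_TOL) & (y >= y0 - EDGE_TOL) & (y <= y1 + EDGE_TOL)
    on_left_line = (np.abs(x - x0) <= EDGE_TOL) & (y >= y0 - EDGE_TOL)
    on_bottom = (np.abs(y - y0) <= EDGE_TOL) & (x >= x0 - EDGE_TOL) & (x <= x1 + EDGE_TOL)
    on_right_ext = (np.abs(x - x1) <= EDGE_TOL) & (y <= y0 + EDGE_TOL)
    return int((in_frame & ~(on_left_line | on_bottom | on_right_ext)).sum())


def point_hits(grid: PointGrid, fibers: list[FiberProfile]) -> tuple[int, int]:
    """(p_fiber, p_total): test points landing on (inside or on) fiber profiles."""
    pts = grid.points()
    p_total = len(pts)
    if not fibers:
        return 0, p_total
    tree = STRtree([Polygon(f.polygon) for f in fibers])
    point_geoms = shapely.points(pts)
    pairs = tree.query(point_geoms, predicate="intersects")
    p_fiber = len(np.unique(pairs[0]))
    return int(p_fiber), int(p_total)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------


def estimate_mcsfa(counts: StereologyCounts) -> float:
    """Mean cross-sectional fiber area (um^2) by point counting.

    (p_fiber / p_total) * grid area = total fiber profile area, divided
    by the number of fiber profiles counted in the frame.
    """
    if counts.p_total == 0:
        raise ValueError("p_total must be > 0")
    if counts.n_fiber_profiles == 0:
        raise ValueError("MCSFA undefined: no fiber profiles counted")
    return counts.fiber_profile_area_total / counts.n_fiber_profiles


def estimate_capillary_density(counts: StereologyCounts) -> float:
    """Capillary profiles per mm^2 of muscle-fiber profile area."""
    fa = counts.fiber_profile_area_total
    if fa <= 0:
        raise ValueError("capillary density undefined: zero fiber profile area")
    return counts.n_capillary_profiles / fa * 1e6  # um^-2 -> mm^-2


def estimate_cf_ratio(counts: StereologyCounts) -> float:
    """Capillary-to-fiber ratio from frame counts."""
    if counts.n_fiber_profiles == 0:
        raise ValueError("C/F undefined: no fiber profiles counted")
    return counts.n_capillary_profiles / counts.n_fiber_profiles


def estimate_all(counts: StereologyCounts) -> CapillarityEstimate:
    """All three estimators from one pooled count set.

    The identity density(mm^-2) * MCSFA(mm^2) == C/F holds exactly by
    construction and is asserted here.
    """
    cf = estimate_cf_ratio(counts)
    mcsfa = estimate_mcsfa(counts)
    density = estimate_capillary_density(counts)
    assert abs(density * (mcsfa / 1e6) - cf) <= 1e-9 * max(1.0, cf)
    return CapillarityEstimate(cf_ratio=cf, mcsfa=mcsfa, capillary_density=density, counts=counts)


def aggregate_sample(per_fov: list[CapillarityEstimate]) -> CapillarityEstimate:
    """Pool raw counts across fields of view, then form ratios.

    Ratio-of-sums rather than mean-of-ratios: unbiased for ratio
    estimators and robust to fields with zero fiber profiles.
    """
    if not per_fov:
        raise ValueError("need at least one field-of-view estimate")
    pooled = per_fov[0].counts
    for est in per_fov[1:]:
        pooled = pooled + est.counts
    return estimate_all(pooled)


# ---------------------------------------------------------------------------
# Field-of-view measurement on synthetic scenes
# ---------------------------------------------------------------------------


class _SceneIndex:
    """Prebuilt shapely polygons and spatial index for one scene."""

    def __init__(self, scene: TissueScene):
        self.scene = scene
        self.polygons = [Polygon(f.polygon) for f in scene.fibers]
        self.tree = STRtree(self.polygons) if self.polygons else None


def _measure_fov_indexed(
    index: _SceneIndex,
    fov: tuple[float, float, float, float],
    n_rows: int,
    n_cols: int,
) -> CapillarityEstimate:
    grid = PointGrid.for_rectangle(fov, n_rows=n_rows, n_cols=n_cols)
    frame = grid.frame()
    region = frame.region()
    forbidden = frame.forbidden_line()
    n_fib = 0
    p_fiber = 0
    if index.tree is not None:
        # only profiles intersecting the (tolerance-buffered) frame can count
        candidates = index.tree.query(region.buffer(2 * EDGE_TOL), predicate="intersects")
        for i in candidates:
            poly = index.polygons[int(i)]
            if poly.distance(region) <= EDGE_TOL and poly.distance(forbidden) > EDGE_TOL:
                n_fib += 1
        pairs = index.tree.query(shapely.points(grid.points()), predicate="intersects")
        p_fiber = len(np.unique(pairs[0]))
    n_cap = count_points_with_forbidden_line(frame, index.scene.capillaries)
    counts = StereologyCounts(
        n_capillary_profiles=n_cap,
        n_fiber_profiles=n_fib,
        p_fiber=int(p_fiber),
        p_total=grid.n_points,
        total_area=grid.total_area,
    )
    return estimate_all(counts)


def measure_fov(
    scene: TissueScene,
    fov: tuple[float, float, float, float],
    n_rows: int = 10,
    n_cols: int = 10,
) -> CapillarityEstimate:
    """Count one field of view of a scene with the grid-aligned frame."""
    return _measure_fov_indexed(_SceneIndex(scene), fov, n_rows, n_cols)


def measure_sample(
    scene: TissueScene,
    fovs: list[tuple[float, float, float, float]],
    n_rows: int = 10,
    n_cols: int = 10,
) -> CapillarityEstimate:
    """Measure every field of view and pool counts to a sample estimate."""
    index = _SceneIndex(scene)
    return aggregate_sample(
        [_measure_fov_indexed(index, fov, n_rows, n_cols) for fov in fovs]
    )
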