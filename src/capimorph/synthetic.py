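"""Synthetic tissue scenes and TEM capillary profiles with known ground truth.

The generator emulates the data objects of a three-cohort skeletal-muscle
biopsy study: transverse semithin sections (a mosaic of muscle-fiber
cross-sections with capillaries at fiber borders, in micrometres) and
transmission-electron-microscopy capillary profiles (nested lumen /
endothelium / basement-membrane contours with pericyte arcs, in
nanometres). Every sample is produced from a per-sample substream of a
single seed, so cohorts are reproducible and per-sample ground truth
(capillary-to-fiber ratio, mean fiber area, mean basement-membrane
thickness, immune-cell counts) is returned alongside the geometry.

Units: light-microscopy geometry in um; TEM geometry in nm.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial import Voronoi

from ._geometry import (
    min_feret_diameter,
    polygon_area,
    polygon_centroid,
    scale_about_centroid,
)

MARKERS = ("CD68", "CD169", "CD206", "CD45", "CD8")
FIBER_TYPES = ("1", "2a", "2b")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class CohortSpec:
    """Study design and per-group generative parameters.

    Per-group sequences are aligned with ``group_names``. ``cf_true`` is
    the target capillary-to-fiber ratio, ``mcsfa_true`` the target mean
    cross-sectional fiber area in um^2 realised *after* type-2b atrophy
    scaling, ``cbm_mean``/``cbm_sd`` the capillary basement-membrane
    thickness distribution in nm.
    """

    group_names: tuple[str, ...] = ("HDC", "2BA", "PCS")
    group_sizes: tuple[int, ...] = (8, 8, 11)
    cf_true: tuple[float, ...] = (1.8, 1.8, 1.5)
    mcsfa_true: tuple[float, ...] = (4600.0, 5500.0, 4000.0)
    type2b_atrophy_factor: tuple[float, ...] = (1.0, 0.45, 0.55)
    type2b_atrophy_fraction: tuple[float, ...] = (0.0, 0.7, 0.4)
    fiber_type_props: tuple[float, float, float] = (0.45, 0.30, 0.25)
    cbm_mean: tuple[float, ...] = (300.0, 305.0, 340.0)
    cbm_sd: tuple[float, ...] = (60.0, 60.0, 60.0)
    cells_per_10hpf_mean: dict = field(
        default_factory=lambda: {
            "CD68": (32.0, 34.0, 58.0),
            "CD169": (17.0, 22.0, 41.0),
            "CD206": (25.0, 26.0, 28.0),
            "CD45": (30.0, 32.0, 35.0),
            "CD8": (8.0, 9.0, 10.0),
        }
    )
    capillaries_per_sample_range: tuple[int, int] = (20, 30)
    seed: int = 0
    # generator shape/nuisance options
    fibers_per_scene: int = 250
    cell_dispersion: float = 8.0
    cluster_cells_near_capillaries: bool = False
    obliqueness_sigma: float = 0.12
    lumen_radius_mean: float = 2200.0
    lumen_radius_sd: float = 300.0
    ec_thickness_mean: float = 250.0
    ec_thickness_sd: float = 50.0
    pericyte_coverage_mean: float = 0.30

    def validate(self) -> None:
        k = len(self.group_names)
        per_group = {
            "group_sizes": self.group_sizes,
            "cf_true": self.cf_true,
            "mcsfa_true": self.mcsfa_true,
            "type2b_atrophy_factor": self.type2b_atrophy_factor,
            "type2b_atrophy_fraction": self.type2b_atrophy_fraction,
            "cbm_mean": self.cbm_mean,
            "cbm_sd": self.cbm_sd,
        }
        for name, seq in per_group.items():
            if len(seq) != k:
                raise ValueError(f"{name} must have one entry per group ({k})")
        if any(n < 2 for n in self.group_sizes):
            raise ValueError("group_sizes must all be >= 2")
        if abs(sum(self.fiber_type_props) - 1.0) > 1e-9:
            raise ValueError("fiber_type_props must sum to 1")
        if any(m <= 0 for m in self.cbm_mean):
            raise ValueError("cbm_mean must be > 0")
        if any(s < 0 for s in self.cbm_sd):
            raise ValueError("cbm_sd must be >= 0")
        lo, hi = self.capillaries_per_sample_range
        if not (1 <= lo <= hi <= 100):
            raise ValueError("capillaries_per_sample_range must lie within [1, 100]")
        for f in self.type2b_atrophy_factor:
            if not (0.0 < f <= 1.0):
                raise ValueError("type2b_atrophy_factor must be in (0, 1]")
        for marker, means in self.cells_per_10hpf_mean.items():
            if len(means) != k:
                raise ValueError(f"cells_per_10hpf_mean[{marker}] must have {k} entries")


@dataclass
class FiberProfile:
    """One muscle-fiber cross-section: a simple polygon with a type label."""

    polygon: np.ndarray  # (n, 2) um, closed implicitly
    fiber_type: str  # "1" | "2a" | "2b"
    area: float  # um^2
    min_diameter: float  # minimal Feret, um
    shrunk: bool = False  # ground-truth atrophy annotation


@dataclass
class TissueScene:
    """Ground-truth geometry standing in for one semithin section."""

    sample_id: str
    fibers: list[FiberProfile]
    capillaries: np.ndarray  # (n, 2) um
    cell_markers: dict  # marker -> (n, 2) um
    scene_extent: tuple[float, float, float, float]  # x0, y0, x1, y1


@dataclass
class TEMCapillaryProfile:
    """One capillary profile: nested contours in nm plus pericyte arcs.

    ``pericyte_arcs`` are (start, end) angle intervals (radians, about the
    contour centroid, end > start) on the abluminal endothelial surface.
    ``true_cbm_field`` is the per-vertex basement-membrane thickness (nm)
    applied at generation, aligned with the contour vertex order.
    """

    capillary_id: str
    lumen_contour: np.ndarray
    ec_abluminal_contour: np.ndarray
    bm_outer_contour: np.ndarray
    pericyte_arcs: list[tuple[float, float]]
    obliqueness: float
    true_cbm_field: np.ndarray


class SampleRecord(NamedTuple):
    scene: TissueScene
    tem_profiles: list[TEMCapillaryProfile]
    truth: dict


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


def _stable_hash(text: str) -> int:
    return int.from_bytes(hashlib.sha256(text.encode()).digest()[:4], "big")


def sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    """Per-sample substream: a Generator keyed by (seed, hash(sample_id))."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), _stable_hash(sample_id)]))


# ---------------------------------------------------------------------------
# Fiber mosaic
# ---------------------------------------------------------------------------


def _hex_lattice(extent_side: float, spacing: float, margin: float) -> np.ndarray:
    xs = np.arange(-margin, extent_side + margin, spacing)
    ys = np.arange(-margin, extent_side + margin, spacing * np.sqrt(3) / 2)
    pts = []
    for j, y in enumerate(ys):
        off = 0.5 * spacing if j % 2 else 0.0
        for x in xs:
            pts.append((x + off, y))
    return np.array(pts)


def _finite_regions(vor: Voronoi) -> dict[int, np.ndarray]:
    """point index -> (n, 2) vertex array for points with finite cells."""
    out = {}
    for i, reg_idx in enumerate(vor.point_region):
        reg = vor.regions[reg_idx]
        if len(reg) >= 3 and -1 not in reg:
            out[i] = vor.vertices[reg]
    return out


def fiber_mosaic(
    rng: np.random.Generator,
    n_fibers: int,
    mean_area: float,
    lloyd_iters: int = 1,
    jitter: float = 0.28,
) -> tuple[list[np.ndarray], list[list[int]], np.ndarray, tuple[float, float, float, float]]:
    """Perturbed-hexagonal-lattice tessellation of a square scene.

    Returns (cell polygons fully inside the extent, per-Voronoi-vertex
    adjacency of kept cells, junction vertex coordinates, extent).
    Mean cell area is controlled by the lattice spacing; a Lloyd-style
    relaxation step regularises the jittered lattice into a convincing
    polygonal fiber mosaic.
    """
    side = float(np.sqrt(n_fibers * mean_area)) * 1.12  # margin for edge loss
    spacing = float(np.sqrt(2.0 * mean_area / np.sqrt(3.0)))
    pts = _hex_lattice(side, spacing, margin=2.5 * spacing)
    pts = pts + rng.uniform(-jitter * spacing, jitter * spacing, size=pts.shape)

    for _ in range(lloyd_iters):
        vor = Voronoi(pts)
        regions = _finite_regions(vor)
        new = pts.copy()
        for i, verts in regions.items():
            c = polygon_centroid(verts)
            # Qhull can report nominally finite border regions with vertices
            # at huge coordinates; accepting such a centroid flings the point
            # far away and wrecks the precision scale of the next Voronoi.
            # A valid relaxation step never moves a point more than about one
            # lattice spacing, so larger jumps are rejected.
            if np.all(np.isfinite(c)) and np.hypot(*(c - pts[i])) < spacing:
                new[i] = c
        pts = new

    vor = Voronoi(pts)
    regions = _finite_regions(vor)
    extent = (0.0, 0.0, side, side)
    polys: list[np.ndarray] = []
    kept_point_ids: list[int] = []
    for i, verts in regions.items():
        if (verts[:, 0] >= 0).all() and (verts[:, 1] >= 0).all() and (
            verts[:, 0] <= side
        ).all() and (verts[:, 1] <= side).all():
            polys.append(verts)
            kept_point_ids.append(i)

    # Junctions: Voronoi vertices adjacent to >= 2 kept cells
    kept_set = set(kept_point_ids)
    vert_adj: dict[int, list[int]] = {}
    for rank, i in enumerate(kept_point_ids):
        for vi in vor.regions[vor.point_region[i]]:
            vert_adj.setdefault(vi, []).append(rank)
    junction_ids = [vi for vi, cells in vert_adj.items() if len(cells) >= 2]
    junctions = vor.vertices[junction_ids] if junction_ids else np.empty((0, 2))
    adjacency = [vert_adj[vi] for vi in junction_ids]
    del kept_set
    return polys, adjacency, junctions, extent


def _build_scene(
    rng: np.random.Generator,
    sample_id: str,
    spec: CohortSpec,
    gi: int,
) -> tuple[TissueScene, dict]:
    p1, p2a, p2b = spec.fiber_type_props
    factor = spec.type2b_atrophy_factor[gi]
    frac = spec.type2b_atrophy_fraction[gi]
    # base cell area chosen so the post-atrophy mean hits mcsfa_true
    weight = p1 + p2a + p2b * (frac * factor + (1.0 - frac))
    base_area = spec.mcsfa_true[gi] / weight

    polys, adjacency, junctions, extent = fiber_mosaic(rng, spec.fibers_per_scene, base_area)
    n_fib = len(polys)
    if n_fib == 0:
        raise ValueError("mosaic produced no interior fibers; increase fibers_per_scene")

    types = rng.choice(FIBER_TYPES, size=n_fib, p=[p1, p2a, p2b])
    shrunk = np.zeros(n_fib, dtype=bool)
    idx_2b = np.flatnonzero(types == "2b")
    n_shrink = int(round(frac * len(idx_2b)))
    if n_shrink:
        shrunk[rng.choice(idx_2b, size=n_shrink, replace=False)] = True

    fibers: list[FiberProfile] = []
    for i, poly in enumerate(polys):
        if shrunk[i]:
            poly = scale_about_centroid(poly, np.sqrt(factor))
        fibers.append(
            FiberProfile(
                polygon=poly,
                fiber_type=str(types[i]),
                area=polygon_area(poly),
                min_diameter=min_feret_diameter(poly, n_directions=90),
                shrunk=bool(shrunk[i]),
            )
        )

    # capillaries at junction points adjacent to >= 1 unshrunk fiber,
    # so every capillary stays on a fiber boundary after atrophy scaling
    ok = np.array([any(not shrunk[c] for c in cells) for cells in adjacency], dtype=bool)
    candidates = junctions[ok]
    n_caps = int(round(spec.cf_true[gi] * n_fib))
    if n_caps > len(candidates):
        raise ValueError(
            f"cf_true={spec.cf_true[gi]} infeasible: requested {n_caps} capillaries "
            f"but only {len(candidates)} fiber-junction points are available "
            "(limiting parameter: cf_true vs fibers_per_scene)"
        )
    caps = candidates[rng.choice(len(candidates), size=n_caps, replace=False)]

    # immune-cell markers: per-field counts (10 HPF) + scene point clouds
    cell_fields: dict[str, list[int]] = {}
    cell_points: dict[str, np.ndarray] = {}
    disp = spec.cell_dispersion
    x0, y0, x1, y1 = extent
    for marker in spec.cells_per_10hpf_mean:
        mu_field = spec.cells_per_10hpf_mean[marker][gi] / 10.0
        if np.isfinite(disp) and disp > 0:
            p = disp / (disp + mu_field)
            counts = rng.negative_binomial(disp, p, size=10)
        else:
            counts = rng.poisson(mu_field, size=10)
        cell_fields[marker] = [int(c) for c in counts]
        total = int(counts.sum())
        pts = np.column_stack(
            [rng.uniform(x0, x1, size=total), rng.uniform(y0, y1, size=total)]
        )
        if spec.cluster_cells_near_capillaries and len(caps) and total:
            near = rng.random(total) < 0.5
            anchors = caps[rng.integers(0, len(caps), size=int(near.sum()))]
            pts[near] = anchors + rng.normal(0.0, 15.0, size=(int(near.sum()), 2))
            pts = np.clip(pts, [x0, y0], [x1, y1])
        cell_points[marker] = pts

    scene = TissueScene(
        sample_id=sample_id,
        fibers=fibers,
        capillaries=caps,
        cell_markers=cell_points,
        scene_extent=extent,
    )
    truth = {
        "group": spec.group_names[gi],
        "cf_target": spec.cf_true[gi],
        "cf_true": n_caps / n_fib,
        "mcsfa_target": spec.mcsfa_true[gi],
        "mcsfa_true": float(np.mean([f.area for f in fibers])),
        "n_fibers": n_fib,
        "n_capillaries": n_caps,
        "atrophic_2b_fraction": (n_shrink / len(idx_2b)) if len(idx_2b) else 0.0,
        "cell_fields": cell_fields,
    }
    return scene, truth


# ---------------------------------------------------------------------------
# Fields of view
# ---------------------------------------------------------------------------


def sample_fovs(
    scene: TissueScene,
    fov_size: tuple[float, float],
    n_fov: int,
    seed: int | np.random.Generator,
    margin: float = 0.0,
) -> list[tuple[float, float, float, float]]:
    """Uniform-random field-of-view rectangles fully inside the scene.

    ``margin`` keeps frames away from the scene border. Counting-frame
    estimators are exactly unbiased only when every frame sees a fully
    populated neighbourhood; the mosaic has a depopulated band of about
    one fiber at the border (boundary-clipped cells are dropped), so a
    guard margin of roughly two fiber diameters plus the band width
    restores unbiasedness for frame counts of extended profiles.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w, h = fov_size
    x0, y0, x1, y1 = scene.scene_extent
    x0, y0, x1, y1 = x0 + margin, y0 + margin, x1 - margin, y1 - margin
    if w > (x1 - x0) or h > (y1 - y0):
        raise ValueError(
            f"fov_size {fov_size} (with margin {margin}) exceeds scene extent "
            f"{(x1 - x0, y1 - y0)}"
        )
    out = []
    for _ in range(int(n_fov)):
        fx = rng.uniform(x0, x1 - w)
        fy = rng.uniform(y0, y1 - h)
        out.append((fx, fy, fx + w, fy + h))
    return out


def guard_margin(scene: TissueScene, factor: float = 2.5) -> float:
    """Default field-of-view guard margin: ``factor`` equivalent-circle
    fiber diameters, covering the border band plus one fiber extent."""
    mean_area = float(np.mean([f.area for f in scene.fibers]))
    return factor * float(np.sqrt(4.0 * mean_area / np.pi))


# ---------------------------------------------------------------------------
# TEM capillary profiles
# ---------------------------------------------------------------------------


def _smooth_periodic_field(rng: np.random.Generator, theta: np.ndarray, n_harmonics: int = 6) -> np.ndarray:
    """Zero-mean, unit-SD smooth periodic field on the angle grid."""
    f = np.zeros_like(theta)
    for k in range(1, n_harmonics + 1):
        a, b = rng.normal(0.0, 1.0 / k, size=2)
        f += a * np.cos(k * theta) + b * np.sin(k * theta)
    sd = f.std()
    if sd < 1e-12:
        return np.zeros_like(theta)
    return (f - f.mean()) / sd


def _draw_pericyte_arcs(
    rng: np.random.Generator, coverage: float
) -> list[tuple[float, float]]:
    """Disjoint angular arcs with total length ~ coverage * 2*pi.

    One arc per equal sector keeps arcs disjoint by construction; arc
    lengths are Dirichlet-distributed and capped at 95% of a sector.
    """
    if coverage <= 0:
        return []
    coverage = min(coverage, 0.95)
    n_arcs = int(rng.integers(2, 6))
    sector = 2 * np.pi / n_arcs
    lengths = rng.dirichlet(np.full(n_arcs, 4.0)) * coverage * 2 * np.pi
    lengths = np.minimum(lengths, 0.95 * sector)
    arcs = []
    for i, ln in enumerate(lengths):
        if ln <= 0:
            continue
        start = i * sector + rng.uniform(0.0, sector - ln)
        arcs.append((float(start), float(start + ln)))
    return arcs


def _transform_angle(theta: float, transform: np.ndarray) -> float:
    v = transform @ np.array([np.cos(theta), np.sin(theta)])
    return float(np.arctan2(v[1], v[0]))


def _transform_arcs(
    arcs: list[tuple[float, float]], transform: np.ndarray
) -> list[tuple[float, float]]:
    """Map angle intervals through a linear map (monotone with winding 1)."""
    out = []
    for a0, a1 in arcs:
        b0 = _transform_angle(a0, transform)
        b1 = _transform_angle(a1, transform)
        if b1 <= b0:
            b1 += 2 * np.pi
        out.append((b0, b1))
    return out


def make_tem_profile(
    lumen_radius: float,
    ec_thickness: float,
    cbm_mean: float,
    cbm_sd: float,
    pericyte_coverage: float,
    obliqueness: float = 1.0,
    n_vertices: int = 180,
    seed: int | np.random.Generator = 0,
    capillary_id: str = "cap",
) -> TEMCapillaryProfile:
    """Build one nested-contour capillary profile (nm).

    The basement-membrane thickness varies smoothly around the profile
    with mean ``cbm_mean`` and SD ``cbm_sd``; ``obliqueness`` >= 1 is
    applied as an area-preserving affine stretch (plus a random rotation)
    emulating oblique sectioning, so a caliper aspect-ratio measurement
    on the outer contour recovers it.
    """
    if lumen_radius <= 0 or ec_thickness <= 0 or cbm_mean <= 0:
        raise ValueError("all lengths must be > 0")
    if cbm_sd < 0:
        raise ValueError("cbm_sd must be >= 0")
    if obliqueness < 1:
        raise ValueError("obliqueness must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    theta = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    if cbm_sd > 0:
        cbm = cbm_mean + cbm_sd * _smooth_periodic_field(rng, theta)
        cbm = np.clip(cbm, 0.1 * cbm_mean, None)
    else:
        cbm = np.full_like(theta, cbm_mean)

    r_lumen = np.full_like(theta, lumen_radius)
    r_ec = r_lumen + ec_thickness
    r_bm = r_ec + cbm
    unit = np.column_stack([np.cos(theta), np.sin(theta)])

    s = np.sqrt(obliqueness)
    phi = rng.uniform(0.0, np.pi)
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    transform = rot @ np.diag([s, 1.0 / s])

    lumen = (r_lumen[:, None] * unit) @ transform.T
    ec = (r_ec[:, None] * unit) @ transform.T
    bm = (r_bm[:, None] * unit) @ transform.T

    arcs = _draw_pericyte_arcs(rng, pericyte_coverage)
    arcs = _transform_arcs(arcs, transform)

    return TEMCapillaryProfile(
        capillary_id=capillary_id,
        lumen_contour=lumen,
        ec_abluminal_contour=ec,
        bm_outer_contour=bm,
        pericyte_arcs=arcs,
        obliqueness=float(obliqueness),
        true_cbm_field=cbm,
    )


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------


def generate_cohort(spec: CohortSpec) -> dict[str, SampleRecord]:
    """Generate all samples of the cohort design.

    Returns a mapping sample_id -> (TissueScene, TEM profiles, ground
    truth). Deterministic for a fixed ``spec.seed``: each sample draws
    from its own substream keyed by the sample id, so samples are
    reproducible in isolation.
    """
    spec.validate()
    out: dict[str, SampleRecord] = {}
    lo, hi = spec.capillaries_per_sample_range
    for gi, (group, size) in enumerate(zip(spec.group_names, spec.group_sizes)):
        for si in range(1, size + 1):
            sample_id = f"{group}-{si}"
            rng = sample_rng(spec.seed, sample_id)
            scene, truth = _build_scene(rng, sample_id, spec, gi)

            n_tem = int(rng.integers(lo, hi + 1))
            profiles = []
            baselines = []
            for ci in range(n_tem):
                base = max(50.0, rng.normal(spec.cbm_mean[gi], 0.8 * spec.cbm_sd[gi]))
                baselines.append(base)
                obliq = 1.0 + abs(rng.normal(0.0, spec.obliqueness_sigma))
                profiles.append(
                    make_tem_profile(
                        lumen_radius=max(800.0, rng.normal(spec.lumen_radius_mean, spec.lumen_radius_sd)),
                        ec_thickness=max(80.0, rng.normal(spec.ec_thickness_mean, spec.ec_thickness_sd)),
                        cbm_mean=base,
                        cbm_sd=0.6 * spec.cbm_sd[gi],
                        pericyte_coverage=float(
                            np.clip(rng.beta(3.0, 7.0) + (spec.pericyte_coverage_mean - 0.3), 0.0, 0.9)
                        ),
                        obliqueness=obliq,
                        seed=rng,
                        capillary_id=f"{sample_id}-c{ci + 1}",
                    )
                )
            truth["cbm_mean_target"] = spec.cbm_mean[gi]
            truth["cbm_mean_true"] = float(
                np.mean([p.true_cbm_field.mean() for p in profiles])
            )
            truth["n_tem_profiles"] = n_tem
            truth["cells_per_10hpf_mean"] = {
                m: spec.cells_per_10hpf_mean[m][gi] for m in spec.cells_per_10hpf_mean
            }
            out[sample_id] = SampleRecord(scene=scene, tem_profiles=profiles, truth=truth)
    return out
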