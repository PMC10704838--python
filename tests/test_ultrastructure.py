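"""Tests for TEM ultrastructure morphometry.

Analytic oracles: concentric-circle profiles have known radius and
thicknesses; a dense ray-casting oracle provides an independent mean
thickness for non-circular annuli.
"""

import numpy as np
import pytest

from capimorph._geometry import polygon_centroid, ray_segment_intersections
from capimorph.synthetic import TEMCapillaryProfile, make_tem_profile
from capimorph.ultrastructure import (
    CBMMeasurementSet,
    Ensheathment,
    FeatureFlags,
    PathologyScore,
    UltrastructureConfig,
    VesicleMitoGrade,
    _allowed_domain,
    _angle_in_arcs,
    aggregate_cbm,
    aspect_ratio,
    filter_profiles,
    flags_from_profile,
    measure_cbm,
    score_capillary_pathology,
    tbia_morphometry,
)

TWO_PI = 2 * np.pi


def circle(r: float, n: int = 180) -> np.ndarray:
    t = np.linspace(0, TWO_PI, n, endpoint=False)
    return np.column_stack([r * np.cos(t), r * np.sin(t)])


def concentric_profile(r_lum=2000.0, r_ec=2200.0, r_bm=2500.0, arcs=()) -> TEMCapillaryProfile:
    return TEMCapillaryProfile(
        capillary_id="cc",
        lumen_contour=circle(r_lum),
        ec_abluminal_contour=circle(r_ec),
        bm_outer_contour=circle(r_bm),
        pericyte_arcs=list(arcs),
        obliqueness=1.0,
        true_cbm_field=np.full(180, r_bm - r_ec),
    )


def raycast_mean_thickness(inner: np.ndarray, outer: np.ndarray, n_rays: int = 1440) -> float:
    """Independent thickness oracle: mean outward-normal distance from the
    inner to the outer contour over dense, evenly spaced boundary points."""
    centroid = polygon_centroid(inner)
    nxt = np.roll(inner, -1, axis=0)
    prv = np.roll(inner, 1, axis=0)
    samples = []
    # sample along the inner polyline proportionally to arc length
    seg_len = np.hypot(*(nxt - inner).T)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    targets = np.linspace(0, cum[-1], n_rays, endpoint=False)
    for s in targets:
        j = int(np.searchsorted(cum, s, side="right")) - 1
        frac = (s - cum[j]) / seg_len[j]
        p = inner[j] + frac * (nxt[j] - inner[j])
        tangent = nxt[j] - prv[j] if frac < 0.5 else inner[(j + 2) % len(inner)] - inner[j]
        normal = np.array([tangent[1], -tangent[0]])
        normal /= np.hypot(*normal)
        if np.dot(normal, p - centroid) < 0:
            normal = -normal
        ts = ray_segment_intersections(p, normal, outer)
        if len(ts):
            samples.append(ts[0])
    return float(np.mean(samples))


class TestAspectRatio:
    def test_circle_is_one(self):
        assert aspect_ratio(circle(2500.0)) == pytest.approx(1.0, abs=1e-3)

    def test_two_to_one_ellipse(self):
        t = np.linspace(0, TWO_PI, 360, endpoint=False)
        ell = np.column_stack([4000 * np.cos(t), 2000 * np.sin(t)])
        assert aspect_ratio(ell) == pytest.approx(2.0, rel=2e-3)

    def test_generated_obliqueness_recovered(self):
        for o in (1.1, 1.2, 1.5):
            p = make_tem_profile(2000.0, 200.0, 300.0, 0.0, 0.0, obliqueness=o, seed=3)
            assert aspect_ratio(p.bm_outer_contour) == pytest.approx(o, abs=0.01)

    def test_too_few_vertices(self):
        with pytest.raises(ValueError, match=">= 8"):
            aspect_ratio(circle(1000.0, n=5))


class TestFilterProfiles:
    def _profile(self, obliq=1.0, lumen=2000.0, coverage=0.0, cid="c", seed=0):
        return make_tem_profile(
            lumen, 200.0, 300.0, 0.0, coverage, obliqueness=obliq, seed=seed, capillary_id=cid
        )

    def test_threshold_is_strict(self):
        # a profile whose measured ratio EQUALS the threshold is included
        # ("more than 1.2" is strict); infinitesimally under, excluded
        p = self._profile(obliq=1.3, cid="at")
        measured = aspect_ratio(p.bm_outer_contour)
        inc, exc = filter_profiles([p], UltrastructureConfig(max_aspect=measured))
        assert [q.capillary_id for q in inc] == ["at"]
        inc, exc = filter_profiles([p], UltrastructureConfig(max_aspect=measured - 1e-9))
        assert inc == [] and exc[0].reason == "oblique"
        assert exc[0].value == pytest.approx(measured)

    def test_exclusion_reasons(self):
        oblique = self._profile(obliq=1.5, cid="o")
        large = self._profile(lumen=6000.0, cid="l")
        covered = self._profile(coverage=0.8, cid="p", seed=4)
        ok = self._profile(cid="ok")
        cfg = UltrastructureConfig(max_pericyte_coverage_pct=40.0)
        inc, exc = filter_profiles([oblique, large, covered, ok], cfg)
        assert [p.capillary_id for p in inc] == ["ok"]
        assert {e.capillary_id: e.reason for e in exc} == {
            "o": "oblique",
            "l": "large_vessel",
            "p": "high_pericyte_coverage",
        }

    def test_known_oblique_subset_excluded(self):
        profiles = [
            self._profile(obliq=1.4 if i % 3 == 0 else 1.0, cid=f"c{i}", seed=i) for i in range(30)
        ]
        inc, exc = filter_profiles(profiles)
        assert {e.capillary_id for e in exc} == {f"c{i}" for i in range(0, 30, 3)}
        assert len(inc) == 20

    def test_relaxing_threshold_is_monotone(self):
        profiles = [self._profile(obliq=1.0 + 0.05 * i, cid=f"c{i}", seed=i) for i in range(12)]
        previous: set[str] = set()
        for max_aspect in (1.05, 1.15, 1.25, 1.45, 2.0):
            inc, _ = filter_profiles(profiles, UltrastructureConfig(max_aspect=max_aspect))
            ids = {p.capillary_id for p in inc}
            assert previous <= ids
            previous = ids

    def test_morphometry_cache_matches_direct(self):
        p = self._profile(cid="x")
        inc, exc, morphs = filter_profiles([p], return_morphometry=True)
        ar, morph = morphs["x"]
        assert ar == pytest.approx(aspect_ratio(p.bm_outer_contour))
        assert morph.bm_thickness == pytest.approx(tbia_morphometry(p).bm_thickness)


class TestTbiaMorphometry:
    def test_concentric_circle_analytic_values(self):
        m = tbia_morphometry(concentric_profile())
        assert m.lumen_radius == pytest.approx(2000.0, rel=1e-3)
        assert m.ec_thickness == pytest.approx(200.0, rel=1e-3)
        assert m.bm_thickness == pytest.approx(300.0, rel=1e-3)
        assert m.pericyte_coverage == 0.0
        assert m.area_lumen == pytest.approx(np.pi * 2000.0**2, rel=1e-3)
        assert m.circ_bm == pytest.approx(TWO_PI * 2500.0, rel=1e-3)

    def test_pericyte_coverage_quarter_arc(self):
        m = tbia_morphometry(concentric_profile(arcs=[(0.0, np.pi / 2)]))
        assert m.pericyte_coverage == pytest.approx(25.0, abs=0.5)

    def test_wraparound_arc_coverage(self):
        m = tbia_morphometry(concentric_profile(arcs=[(-0.5, 0.5)]))
        assert m.pericyte_coverage == pytest.approx(100.0 / TWO_PI, abs=0.5)

    def test_nesting_violations_named(self):
        bad = concentric_profile()
        bad.lumen_contour, bad.ec_abluminal_contour = bad.ec_abluminal_contour, bad.lumen_contour
        with pytest.raises(ValueError, match="lumen vs ec_abluminal"):
            tbia_morphometry(bad)
        shifted = concentric_profile()
        shifted.lumen_contour = circle(2000.0) + np.array([1500.0, 0.0])  # pokes outside ec
        with pytest.raises(ValueError, match="containment"):
            tbia_morphometry(shifted)

    def test_annulus_estimator_matches_raycast_oracle_on_ellipse(self):
        t = np.linspace(0, TWO_PI, 360, endpoint=False)
        inner = np.column_stack([2400 * np.cos(t), 2000 * np.sin(t)])
        outer = np.column_stack([2700 * np.cos(t), 2300 * np.sin(t)])
        p = TEMCapillaryProfile("e", circle(1500.0, 360), inner, outer, [], 1.2, np.zeros(360))
        m = tbia_morphometry(p)
        oracle = raycast_mean_thickness(inner, outer)
        assert m.bm_thickness == pytest.approx(oracle, rel=0.05)

    def test_annulus_estimator_matches_oracle_on_generated_profiles(self):
        rng = np.random.default_rng(21)
        for i in range(10):
            p = make_tem_profile(
                lumen_radius=rng.uniform(1500, 3000),
                ec_thickness=rng.uniform(150, 350),
                cbm_mean=rng.uniform(250, 400),
                cbm_sd=rng.uniform(0, 60),
                pericyte_coverage=0.0,
                obliqueness=rng.uniform(1.0, 1.2),
                seed=rng,
                capillary_id=f"g{i}",
            )
            m = tbia_morphometry(p)
            oracle = raycast_mean_thickness(p.ec_abluminal_contour, p.bm_outer_contour)
            assert m.bm_thickness == pytest.approx(oracle, rel=0.05)


class TestAllowedDomain:
    def test_no_arcs_full_circle(self):
        assert _allowed_domain([], 0.1) == [(0.0, TWO_PI)]

    def test_total_length_complements_arcs(self):
        margin = np.deg2rad(5.0)
        arcs = [(0.0, 1.0), (2.0, 2.5), (4.0, 5.5)]
        domain = _allowed_domain(arcs, margin)
        free = sum(b - a for a, b in domain)
        blocked = sum((a1 - a0) + 2 * margin for a0, a1 in arcs)
        assert free == pytest.approx(TWO_PI - blocked, abs=0.01)

    def test_domain_angles_clear_of_arcs(self):
        margin = np.deg2rad(5.0)
        arcs = [(0.5, 1.5), (3.0, 4.0)]
        for a, b in _allowed_domain(arcs, margin):
            for theta in np.linspace(a + 1e-3, b - 1e-3, 25):
                assert not _angle_in_arcs(float(np.mod(theta, TWO_PI)), arcs, margin - 2e-3)


class TestMeasureCbm:
    def test_constant_profile_recovers_thickness(self):
        p = make_tem_profile(2000.0, 200.0, 300.0, 0.0, 0.0, seed=0)
        m = measure_cbm(p, seed=1)
        assert len(m.site_thicknesses) == 6
        assert m.site_thicknesses == pytest.approx(np.full(6, 300.0), rel=0.01)
        assert m.capillary_mean == pytest.approx(300.0, rel=0.01)

    def test_sites_avoid_pericyte_arcs(self):
        cfg = UltrastructureConfig()
        margin = np.deg2rad(cfg.pericyte_margin_deg)
        rng = np.random.default_rng(3)
        for i in range(20):
            p = make_tem_profile(2000.0, 200.0, 300.0, 0.0, 0.5, seed=rng, capillary_id=f"p{i}")
            m = measure_cbm(p, cfg, seed=rng)
            for theta in m.site_angles:
                assert not _angle_in_arcs(theta, p.pericyte_arcs, margin - 1e-6)

    def test_rotation_offset_mean_stable(self):
        """Random site rotation: capillary means over many offsets agree
        with the generated thickness field mean within 2%."""
        p = make_tem_profile(2200.0, 220.0, 320.0, 55.0, 0.0, seed=9)
        means = [measure_cbm(p, seed=k).capillary_mean for k in range(120)]
        assert np.mean(means) == pytest.approx(p.true_cbm_field.mean(), rel=0.02)

    def test_near_full_coverage_raises(self):
        p = concentric_profile(arcs=[(0.0, TWO_PI * 0.99)])
        with pytest.raises(ValueError, match="<5%"):
            measure_cbm(p, seed=0)

    def test_round_trip_many_profiles(self):
        """Generate-and-measure round trip: across many constant-thickness
        profiles the measured grand mean matches the generator mean within 1%."""
        rng = np.random.default_rng(14)
        diffs = []
        for i in range(300):
            truth = rng.uniform(200.0, 450.0)
            p = make_tem_profile(
                rng.uniform(1500, 3000), rng.uniform(150, 350), truth, 0.0,
                rng.uniform(0.0, 0.4), seed=rng, capillary_id=f"r{i}",
            )
            m = measure_cbm(p, seed=rng)
            diffs.append(m.capillary_mean / truth)
        assert np.mean(diffs) == pytest.approx(1.0, abs=0.01)

    def test_measurement_set_validation(self):
        with pytest.raises(ValueError, match="> 0"):
            CBMMeasurementSet("x", np.zeros(6), np.array([1.0, 2, 3, 4, 5, -1]), np.array([]), 0.0)
        with pytest.raises(ValueError, match="align"):
            CBMMeasurementSet("x", np.zeros(5), np.ones(6), np.array([]), 1.0)


class TestAggregateCbm:
    def _mset(self, cid, values):
        values = np.asarray(values, dtype=float)
        return CBMMeasurementSet(cid, np.zeros(len(values)), values, np.array([]), float(values.mean()))

    def test_single_capillary(self):
        s = aggregate_cbm([self._mset("a", [300.0] * 6)])
        assert s.mean_single == 300.0
        assert s.mean_of_capillary_means == 300.0
        assert s.n_measurements == 6
        assert s.n_outliers_flagged == 0

    def test_outliers_flagged_but_retained(self):
        s = aggregate_cbm([self._mset("a", [340.0, 360.0, 340.0, 360.0, 340.0, 360.0])])
        assert s.n_outliers_flagged == 3
        assert s.mean_single == pytest.approx(350.0)  # outliers stay in the mean

    def test_mean_of_capillary_means_vs_mean_single(self):
        s = aggregate_cbm([self._mset("a", [100.0] * 6), self._mset("b", [200.0] * 6)])
        assert s.mean_of_capillary_means == pytest.approx(150.0)
        assert s.mean_single == pytest.approx(150.0)
        assert s.n_capillaries == 2

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            aggregate_cbm([])


class TestPathologyRubric:
    def test_normal_is_zero(self):
        assert score_capillary_pathology(FeatureFlags()) == 0

    @pytest.mark.parametrize(
        "flags,expected",
        [
            (FeatureFlags(n_pericyte_processes=3), 0),
            (FeatureFlags(n_pericyte_processes=4), 1),
            (FeatureFlags(reduplication=True), 1),
            (FeatureFlags(ensheathment=Ensheathment.SINGLE), 1),
            (FeatureFlags(vesicle_mito_grade=VesicleMitoGrade.SLIGHT), 1),
            (FeatureFlags(pericyte_irregular=True), 2),
            (FeatureFlags(ensheathment=Ensheathment.PRESENT), 2),
            (FeatureFlags(vesicle_mito_grade=VesicleMitoGrade.PROMINENT), 2),
            (FeatureFlags(pericyte_irregular=True, severe=True), 3),
            (FeatureFlags(ec_necrosis_or_debris=True), 4),
            # priority: necrosis trumps everything below it
            (FeatureFlags(ec_necrosis_or_debris=True, pericyte_irregular=True, severe=True), 4),
            # severe without any grade-2 finding does not reach 3
            (FeatureFlags(severe=True, reduplication=True), 1),
        ],
    )
    def test_rubric_cases(self, flags, expected):
        assert score_capillary_pathology(flags) == expected

    def test_score4_requires_necrosis(self):
        with pytest.raises(ValueError, match="necrosis"):
            PathologyScore("c", 4, FeatureFlags())
        PathologyScore("c", 4, FeatureFlags(ec_necrosis_or_debris=True))
        with pytest.raises(ValueError, match="0..4"):
            PathologyScore("c", 5, FeatureFlags(ec_necrosis_or_debris=True))

    def test_flags_from_profile_grades_coverage(self):
        p = concentric_profile(arcs=[(0.0, 0.5)])
        m = tbia_morphometry(p)
        flags = flags_from_profile(p, m)
        assert flags.ensheathment == Ensheathment.NONE
        high = concentric_profile(arcs=[(0.0, 2.0), (2.2, 4.2)])
        flags_high = flags_from_profile(high, tbia_morphometry(high))
        assert flags_high.ensheathment == Ensheathment.PRESENT
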