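"""Contour descriptors against closed forms and brute-force oracles, and
round-trip recovery of generator parameters."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from skimage import measure

import guvkit as g
from tests.conftest import circle_contour


def convex_polygon(rng, n=12, r_mean=40.0):
    """Random convex n-gon: convex hull of noisy points on a circle."""
    from scipy.spatial import ConvexHull
    th = np.sort(rng.uniform(0, 2 * np.pi, n))
    r = r_mean * rng.uniform(0.5, 1.5, n)
    pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
    return pts[ConvexHull(pts).vertices]


def brute_force_feret_and_perp(vertices, n_scan=4000):
    """Independent oracle: max pairwise distance over vertices; longest
    perpendicular chord by manual edge interpolation along the Feret axis."""
    best = (0.0, None)
    n = len(vertices)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.hypot(*(vertices[i] - vertices[j])))
            if d > best[0]:
                best = (d, vertices[j] - vertices[i])
    feret, direction = best
    u = direction / np.linalg.norm(direction)
    rot = vertices @ np.array([[u[0], -u[1]], [u[1], u[0]]])
    xs = rot[:, 0]
    edges = [(rot[k], rot[(k + 1) % n]) for k in range(n)]
    best_chord = 0.0
    for x in np.linspace(xs.min(), xs.max(), n_scan):
        ys = []
        for (p, q) in edges:
            if (p[0] - x) * (q[0] - x) <= 0 and p[0] != q[0]:
                t = (x - p[0]) / (q[0] - p[0])
                ys.append(p[1] + t * (q[1] - p[1]))
        if len(ys) >= 2:
            best_chord = max(best_chord, max(ys) - min(ys))
    return feret, best_chord


class TestDiameter:
    def test_closed_form_circle(self, px):
        # Area 100*pi um^2 -> d = 20 um
        c = circle_contour(10.0 / px, n=2000)
        assert g.guv_diameter(c) == pytest.approx(20.0, rel=1e-3)

    def test_rasterized_disk_vs_pixel_count(self, px):
        y, x = np.mgrid[0:128, 0:128]
        disk = (np.hypot(x - 64, y - 64) <= 50).astype(float)
        cont = max(measure.find_contours(disk, 0.5), key=len)
        c = g.GuvContour(np.column_stack([cont[:, 1], cont[:, 0]]), px)
        d_pixelcount = 2 * np.sqrt(disk.sum() / np.pi) * px
        assert g.guv_diameter(c) == pytest.approx(20.0, rel=0.02)
        assert g.guv_diameter(c) == pytest.approx(d_pixelcount, rel=0.02)

    def test_degenerate_contour_rejected(self, px):
        with pytest.raises(ValueError):
            g.GuvContour(np.array([[0, 0], [1, 1], [2, 2]]), px)


class TestEllipticity:
    def test_circle_is_100_percent(self, px):
        c = circle_contour(50.0, n=1440)
        feret, perp, ell = g.ellipticity(c)
        assert ell == pytest.approx(100.0, abs=0.5)

    def test_two_to_one_ellipse(self, px):
        th = np.linspace(0, 2 * np.pi, 2000, endpoint=False)
        pts = np.column_stack([(10.0 / px) * np.cos(th), (5.0 / px) * np.sin(th)])
        feret, perp, ell = g.ellipticity(g.GuvContour(pts, px))
        assert feret == pytest.approx(20.0, rel=1e-3)
        assert perp == pytest.approx(10.0, rel=5e-3)
        assert ell == pytest.approx(50.0, abs=0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_polygon_matches_brute_force(self, seed, px):
        rng = np.random.default_rng(seed)
        poly = convex_polygon(rng)
        feret_o, perp_o = brute_force_feret_and_perp(poly)
        feret, perp, ell = g.ellipticity(g.GuvContour(poly, px))
        assert feret == pytest.approx(feret_o * px, rel=1e-9)
        assert perp == pytest.approx(perp_o * px, rel=5e-3)

    @settings(max_examples=20, deadline=None)
    @given(angle=st.floats(0, 360), dx=st.floats(-30, 30), dy=st.floats(-30, 30),
           seed=st.integers(0, 100))
    def test_invariant_to_rotation_and_translation(self, angle, dx, dy, seed):
        px = 0.2
        rng = np.random.default_rng(seed)
        poly = convex_polygon(rng)
        a = np.radians(angle)
        R = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        moved = poly @ R.T + [dx, dy]
        _, _, e0 = g.ellipticity(g.GuvContour(poly, px))
        _, _, e1 = g.ellipticity(g.GuvContour(moved, px))
        assert e1 == pytest.approx(e0, rel=0.01)


class TestSegmentation:
    def test_contour_area_round_trip(self, plain_guv_frame, px):
        c = g.segment_guv_contour(plain_guv_frame.frames[0], pixel_size_um=px)
        assert c.area_um2 == pytest.approx(np.pi * 100.0, rel=0.03)

    def test_blank_frame_fails(self, px):
        frame = np.full((2, 64, 64), 7.0)
        with pytest.raises(g.SegmentationError):
            g.segment_guv_contour(frame, pixel_size_um=px)

    def test_seed_point_selects_one_of_two_guvs(self, px):
        spec = g.SynthSpec(guv_diameter_um=10.0, image_shape=(80, 80), pixel_size_um=px)
        tile = g.render_guv_frame(spec).frames[0]
        frame = np.full((2, 80, 160), 10.0)
        frame[:, :, :80] = tile
        frame[:, :, 80:] = tile
        left = g.segment_guv_contour(frame, seed_point=(40, 40), pixel_size_um=px)
        right = g.segment_guv_contour(frame, seed_point=(120, 40), pixel_size_um=px)
        assert left.vertices[:, 0].max() < 80
        assert right.vertices[:, 0].min() > 80


class TestActinThickness:
    def test_symmetric_shell_round_trip(self, shell_frame, px):
        c = g.segment_guv_contour(shell_frame.frames[0], pixel_size_um=px)
        prof = g.actin_thickness(shell_frame.frames[0], c)
        assert prof.max_thickness_um == pytest.approx(5.0, abs=2 * px)

    def test_no_actin_flagged_zero(self, plain_guv_frame, px):
        c = g.segment_guv_contour(plain_guv_frame.frames[0], pixel_size_um=px)
        prof = g.actin_thickness(plain_guv_frame.frames[0], c)
        assert prof.flagged
        assert prof.max_thickness_um == 0.0

    def test_asymmetric_break_orientation(self, px):
        spec = g.SynthSpec(actin_structure="asymmetric_shell", actin_thickness_um=8.0,
                           break_angle_deg=90.0, image_shape=(300, 300), pixel_size_um=px)
        frame = g.render_guv_frame(spec).frames[0]
        c = g.segment_guv_contour(frame, pixel_size_um=px)
        prof = g.actin_thickness(frame, c)
        assert prof.max_thickness_um == pytest.approx(8.0, abs=2 * px)
        assert prof.break_angle_deg == pytest.approx(90.0, abs=3.0)


class TestStructureClass:
    def test_round_trips(self, shell_frame, px):
        cases = [
            (g.SynthSpec(actin_structure="symmetric_shell", actin_thickness_um=3.0),
             "symmetric_shell"),
            (g.SynthSpec(actin_structure="asymmetric_shell", actin_thickness_um=6.0,
                         break_angle_deg=200.0, image_shape=(300, 300)),
             "asymmetric_shell"),
            (g.SynthSpec(actin_structure="comet", actin_thickness_um=1.0,
                         break_angle_deg=10.0, image_shape=(320, 320)),
             "comet"),
        ]
        for spec, expected in cases:
            rec, _, _ = g.measure_frame(g.render_guv_frame(spec).frames[0], px)
            assert rec.structure_class == expected

    def test_zero_thickness_is_none(self, plain_guv_frame, px):
        rec, _, _ = g.measure_frame(plain_guv_frame.frames[0], px)
        assert rec.structure_class == "none"

    def test_a_sym_moves_boundary_monotonically(self, px):
        spec = g.SynthSpec(actin_structure="asymmetric_shell", actin_thickness_um=6.0,
                           image_shape=(300, 300))
        frame = g.render_guv_frame(spec).frames[0]
        c = g.segment_guv_contour(frame, pixel_size_um=px)
        prof = g.actin_thickness(frame, c)
        classes = [g.classify_actin_structure(prof, 10.0, a_sym=a)
                   for a in (0.1, 0.5, 0.9, 0.99)]
        # once symmetric at some a_sym, symmetric for all larger a_sym
        syms = [cl == "symmetric_shell" for cl in classes]
        assert syms == sorted(syms)


class TestGrowthRate:
    def test_exact_line(self):
        t = np.arange(0, 60, 5.0)
        assert g.fit_growth_rate(t, 0.15 * t + 1.0) == pytest.approx(0.15)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            g.fit_growth_rate([0, 10], [0, 1])

    @pytest.mark.parametrize("rate", [0.1, 0.3])
    def test_recovered_from_noisy_lapse(self, rate, px):
        spec = g.SynthSpec(guv_diameter_um=16.0, pixel_size_um=px,
                           actin_structure="symmetric_shell", actin_thickness_um=0.5,
                           image_shape=(420, 420), shot_noise=True, seed=21)
        times = np.linspace(0, 60, 13)
        lapse = g.render_time_lapse(spec, times, rate)
        th = []
        for frame in lapse.frames:
            c = g.segment_guv_contour(frame, pixel_size_um=px)
            th.append(g.actin_thickness(frame, c).max_thickness_um)
        assert g.fit_growth_rate(times, th) == pytest.approx(rate, rel=0.1)
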