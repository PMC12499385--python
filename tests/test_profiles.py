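"""Radial profiling: peak extraction against the Gaussian-ridge closed form,
normalization invariances, Ld-domain calling, and the actin-on-Ld score."""

import numpy as np
import pytest
from scipy import integrate

import guvkit as g
from guvkit.profiles import RadialProfileSet, segment_ld_domains, actin_on_ld
from tests.conftest import circle_contour


def manual_profile_set(lipid_norm, actin_norm=None):
    n = len(lipid_norm)
    ones = np.asarray(lipid_norm, dtype=float)
    actin = np.zeros(n) if actin_norm is None else np.asarray(actin_norm, dtype=float)
    return RadialProfileSet(
        center_px=(0.0, 0.0), angles_deg=np.arange(n) * (360.0 / n),
        lipid_peak_mean=ones.copy(), actin_peak_mean=actin.copy(),
        background=np.zeros(2), lipid_norm=ones, actin_norm=actin,
    )


class TestCenterAndBackground:
    def test_circle_centroid(self, plain_guv_frame, px):
        c = g.segment_guv_contour(plain_guv_frame.frames[0], pixel_size_um=px)
        cx, cy = g.estimate_center(c)
        assert cx == pytest.approx(127.5, abs=1.0)
        assert cy == pytest.approx(127.5, abs=1.0)

    def test_polygon_matches_shoelace_oracle(self, px):
        rng = np.random.default_rng(3)
        th = np.sort(rng.uniform(0, 2 * np.pi, 9))
        r = 30 * rng.uniform(0.6, 1.4, 9)
        pts = np.column_stack([50 + r * np.cos(th), 50 + r * np.sin(th)])
        # shoelace centroid, written out independently
        x, y = pts[:, 0], pts[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cross = x * yn - xn * y
        A = cross.sum() / 2.0
        cx = ((x + xn) * cross).sum() / (6 * A)
        cy = ((y + yn) * cross).sum() / (6 * A)
        got = g.estimate_center(g.GuvContour(pts, px))
        assert got[0] == pytest.approx(cx, abs=1e-6)
        assert got[1] == pytest.approx(cy, abs=1e-6)

    def test_background_exact_noise_free(self, plain_guv_frame, px):
        c = g.segment_guv_contour(plain_guv_frame.frames[0], pixel_size_um=px)
        bg, sig = g.estimate_background(plain_guv_frame.frames[0], c)
        assert bg[0] == pytest.approx(10.0, abs=1e-6)
        assert bg[1] == pytest.approx(10.0, abs=1e-6)

    def test_background_under_gaussian_noise(self, px):
        spec = g.SynthSpec(gaussian_noise_sigma=2.0, seed=4, image_shape=(256, 256))
        frame = g.render_guv_frame(spec).frames[0]
        c = g.segment_guv_contour(frame, pixel_size_um=px)
        bg, sig = g.estimate_background(frame, c)
        assert bg[0] == pytest.approx(10.0, abs=0.5)
        assert sig[0] == pytest.approx(2.0, rel=0.2)

    def test_tight_frame_rejected(self, px):
        spec = g.SynthSpec(guv_diameter_um=20.0, image_shape=(120, 120), pixel_size_um=px)
        frame = g.render_guv_frame(spec).frames[0]
        c = g.segment_guv_contour(frame, pixel_size_um=px)
        with pytest.raises(ValueError, match="tight"):
            g.estimate_background(frame, c, factor=2.0)


class TestRadialProfiles:
    def test_ring_peak_matches_gaussian_half_max_integral(self, plain_guv_frame, px):
        """Mean of a Gaussian ridge over its half-max run has the closed form
        A * integral(exp(-d^2/2s^2), |d| < s*sqrt(2 ln 2)) / (2 s sqrt(2 ln 2))."""
        frame = plain_guv_frame.frames[0]
        c = g.segment_guv_contour(frame, pixel_size_um=px)
        bg, _ = g.estimate_background(frame, c)
        ps = g.radial_profiles(frame, g.estimate_center(c),
                               guv_radius_px=10.0 / px, background=bg)
        d0 = np.sqrt(2 * np.log(2))
        val, _ = integrate.quad(lambda d: np.exp(-d * d / 2.0), -d0, d0)
        expected = 100.0 * val / (2 * d0)        # amplitude 100, any sigma
        assert np.mean(ps.lipid_peak_mean) == pytest.approx(expected, rel=0.05)
        assert np.std(ps.lipid_peak_mean) < 0.05 * expected

    def test_blank_channel_all_zero(self, plain_guv_frame, px):
        frame = plain_guv_frame.frames[0]
        c = g.segment_guv_contour(frame, pixel_size_um=px)
        bg, _ = g.estimate_background(frame, c)
        ps = g.radial_profiles(frame, g.estimate_center(c),
                               guv_radius_px=10.0 / px, background=bg)
        assert np.all(ps.actin_peak_mean == 0.0)

    def test_ld_arc_angles_carry_the_gain(self, px):
        spec = g.SynthSpec(domain_arc_bounds_deg=[(30, 60)], n_domains=1,
                           ld_lipid_gain=3.0)
        frame = g.render_guv_frame(spec).frames[0]
        c = g.segment_guv_contour(frame, pixel_size_um=px)
        bg, _ = g.estimate_background(frame, c)
        ps = g.radial_profiles(frame, g.estimate_center(c),
                               guv_radius_px=10.0 / px, background=bg)
        on = (ps.angles_deg >= 33) & (ps.angles_deg < 57)
        off = (ps.angles_deg >= 63) | (ps.angles_deg < 27)
        assert (ps.lipid_peak_mean[on].mean()
                / ps.lipid_peak_mean[off].mean()) == pytest.approx(3.0, rel=0.05)


class TestNormalization:
    def test_max_is_one_and_scale_invariant(self, plain_guv_frame, px):
        frame = plain_guv_frame.frames[0].copy()
        c = g.segment_guv_contour(frame, pixel_size_um=px)
        bg, _ = g.estimate_background(frame, c)
        center = g.estimate_center(c)
        ps1 = g.normalize_profiles(g.radial_profiles(
            frame, center, guv_radius_px=10.0 / px, background=bg))
        assert float(ps1.lipid_norm.max()) == 1.0
        scaled = frame.copy()
        scaled[0] = 7.0 * (scaled[0] - 10.0) + 10.0    # scale signal above background
        ps7 = g.normalize_profiles(g.radial_profiles(
            scaled, center, guv_radius_px=10.0 / px, background=bg))
        assert np.allclose(ps1.lipid_norm, ps7.lipid_norm, atol=1e-9)

    def test_all_zero_channel_stays_zero_flagged(self):
        ps = manual_profile_set(np.zeros(360))
        ps.lipid_norm = None
        out = g.normalize_profiles(ps)
        assert np.all(out.lipid_norm == 0.0)
        assert "lipid_all_zero" in out.flags

    def test_negative_input_rejected(self):
        ps = manual_profile_set(np.zeros(360))
        ps.lipid_peak_mean[0] = -1.0
        with pytest.raises(ValueError):
            g.normalize_profiles(ps)


class TestDomainCalling:
    def test_all_below_threshold_gives_none(self):
        doms = segment_ld_domains(manual_profile_set(np.full(360, 0.2)))
        assert doms.n_d == 0        # strict inequality at the 0.2 threshold

    def test_wrap_interval_counted_once(self):
        lipid = np.zeros(360)
        lipid[10:40] = 1.0
        lipid[350:] = 1.0
        lipid[:5] = 1.0
        doms = segment_ld_domains(manual_profile_set(lipid))
        assert doms.n_d == 2
        widths = sorted(b - a for a, b in doms.intervals_deg)
        assert widths == [15.0, 30.0]

    def test_min_width_filter_drops_narrow_runs(self):
        lipid = np.zeros(360)
        lipid[100:103] = 1.0
        lipid[200:230] = 1.0
        doms = segment_ld_domains(manual_profile_set(lipid), min_width_deg=5.0)
        assert doms.n_d == 1

    @pytest.mark.parametrize("n_d", [2, 5, 12, 23, 36])
    def test_round_trip_domain_count(self, n_d, px):
        spec = g.SynthSpec(guv_diameter_um=30.0, image_shape=(200, 200),
                           pixel_size_um=px, n_domains=n_d)
        frame = g.render_guv_frame(spec).frames[0]
        c = g.segment_guv_contour(frame, pixel_size_um=px)
        _, doms, _ = g.profile_guv(frame, c)
        assert doms.n_d == n_d


class TestActinOnLd:
    def test_constant_actin_scores_one(self):
        lipid = np.zeros(360); lipid[0:90] = 1.0
        actin = np.zeros(360); actin[0:90] = 0.6
        ps = manual_profile_set(lipid, actin)
        doms = segment_ld_domains(ps)
        assert actin_on_ld(ps, doms) == pytest.approx(1.0)

    def test_no_domains_scores_zero(self):
        ps = manual_profile_set(np.zeros(360), np.ones(360))
        assert actin_on_ld(ps, segment_ld_domains(ps)) == 0.0

    def test_half_covered_scores_half(self):
        lipid = np.zeros(360); lipid[0:90] = 1.0
        actin = np.zeros(360); actin[0:45] = 1.0
        ps = manual_profile_set(lipid, actin)
        assert actin_on_ld(ps, segment_ld_domains(ps)) == pytest.approx(0.5)

    def test_colocalized_actin_scores_above_spread_actin(self, px):
        """With realistic shot noise, actin concentrated on the Ld arcs scores
        higher than the same total actin spread uniformly around the ring."""
        scores = {}
        for label, on_ld, intensity in [("coloc", True, 160.0), ("uniform", False, 53.3)]:
            vals = []
            for seed in range(4):
                spec = g.SynthSpec(guv_diameter_um=24.0, image_shape=(180, 180),
                                   pixel_size_um=px, n_domains=4,
                                   actin_structure="symmetric_shell",
                                   actin_thickness_um=1.5, actin_intensity=intensity,
                                   actin_on_ld_only=on_ld, shot_noise=True, seed=seed)
                frame = g.render_guv_frame(spec).frames[0]
                c = g.segment_guv_contour(frame, pixel_size_um=px)
                _, doms, score = g.profile_guv(frame, c)
                vals.append(score)
            scores[label] = np.mean(vals)
        assert scores["coloc"] > scores["uniform"]
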