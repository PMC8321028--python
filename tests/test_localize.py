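import math

import numpy as np
import pytest

from zernloc.localize import (
    LocalizerConfig,
    disk_width,
    edge_offset,
    localize_features,
    orientation,
    rotated_a11,
    streak_offset,
    subpixel_update,
)
from zernloc.models import (
    RampEdgeModel,
    WedgeStreakModel,
    edge_ratio,
    streak_ratio,
)
from zernloc.moments import compute_moments
from zernloc.synth import LineGeometry, SyntheticScene, render_scene

# Round-trip inversion error bounds per disk-width band, measured from the
# exact-ratio oracle on a 0.01-spaced (ell, w) grid with 10% headroom.
EDGE_ROUNDTRIP_BOUNDS = {0.1: 0.019, 0.2: 0.039, 0.3: 0.051, 0.5: 0.055, 0.7: 0.052}
STREAK_ROUNDTRIP_BOUNDS = {0.1: 0.0033, 0.2: 0.0075, 0.3: 0.010, 0.5: 0.011, 0.7: 0.0068}


class TestOrientation:
    def test_cardinal_directions(self):
        assert orientation(1.0, 0.0) == pytest.approx(0.0)
        assert orientation(0.0, 1.0) == pytest.approx(math.pi / 2)
        assert orientation(-1.0, 0.0) == pytest.approx(math.pi)

    def test_flat_patch_rejected(self):
        with pytest.raises(ValueError, match="flat"):
            orientation(0.0, 0.0)

    def test_rendered_edge_orientation(self, masks5):
        psi_true = math.radians(30.0)
        scene = SyntheticScene(
            geometry=LineGeometry(psi_true, 10.0, 10.0),
            feature_kind="edge", psf_sigma=0.5, image_shape=(21, 21),
        )
        img, _ = render_scene(scene)
        (s,) = compute_moments(img, [(10, 10)], masks5)
        assert orientation(s.re_a11, s.im_a11) == pytest.approx(
            psi_true, abs=math.radians(1.0)
        )


class TestRotatedA11:
    def test_modulus_at_own_angle(self):
        assert rotated_a11(3.0, 4.0, math.atan2(4, 3)) == pytest.approx(5.0)

    def test_zero_angle(self):
        assert rotated_a11(3.0, 4.0, 0.0) == pytest.approx(3.0)

    def test_imag_component_vanishes_at_estimated_angle(self):
        re, im = 2.7, -1.3
        psi = orientation(re, im)
        assert im * math.cos(psi) - re * math.sin(psi) == pytest.approx(0.0, abs=1e-12)

    def test_phase_rotation_on_analytic_signal(self, masks5):
        # A11 rotates by exp(-j psi) between frames: rendering the same edge
        # at psi and 0 gives |A11| fixed and components rotated
        from conftest import render_disk_patch
        from zernloc.models import ramp_edge_intensity

        model = RampEdgeModel(h=0, k=100, ell=0.15, w=0.25)
        prof = lambda u: ramp_edge_intensity(u, model)
        (s0,) = compute_moments(render_disk_patch(prof, 5, 0.0), [(2, 2)], masks5)
        psi = math.radians(40.0)
        (s1,) = compute_moments(render_disk_patch(prof, 5, psi), [(2, 2)], masks5)
        mag0 = math.hypot(s0.re_a11, s0.im_a11)
        mag1 = math.hypot(s1.re_a11, s1.im_a11)
        assert mag1 == pytest.approx(mag0, rel=0.01)
        assert math.atan2(s1.im_a11, s1.re_a11) == pytest.approx(psi, abs=0.01)


class TestEdgeOffset:
    def test_zero_ratio(self):
        for w in (0.0, 0.2, 0.5):
            ell, clamped = edge_offset(0.0, w)
            assert ell == pytest.approx(0.0, abs=1e-12)
            assert not clamped

    def test_step_model_limit(self):
        ell, _ = edge_offset(0.3, 0.0)
        assert ell == 0.3

    def test_small_w_continuity(self):
        ell, _ = edge_offset(0.3, 1e-8)
        assert ell == pytest.approx(0.3, abs=1e-6)

    def test_round_trip_exact_ratio(self):
        q = edge_ratio(RampEdgeModel(h=0, k=1, ell=0.2, w=0.3))
        ell, clamped = edge_offset(q, 0.3)
        assert abs(ell - 0.2) <= 0.01
        assert not clamped

    def test_negative_offsets_allowed(self):
        q = edge_ratio(RampEdgeModel(h=0, k=1, ell=-0.25, w=0.2))
        ell, _ = edge_offset(q, 0.2)
        assert ell == pytest.approx(-0.25, abs=0.04)

    def test_discriminant_clamp(self):
        ell, clamped = edge_offset(100.0, 0.3)
        assert clamped
        assert math.isfinite(ell)

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            edge_offset(0.1, 1.0)

    def test_round_trip_bounded_by_oracle_table(self):
        prev = 0.0
        for w_hi, bound in sorted(EDGE_ROUNDTRIP_BOUNDS.items()):
            for w in np.arange(prev + 0.02, w_hi + 1e-9, 0.02):
                for ell in np.arange(-0.85, 0.86, 0.05):
                    if abs(ell) + w > 0.9:
                        continue
                    q = edge_ratio(RampEdgeModel(h=0, k=1, ell=ell, w=w))
                    est, _ = edge_offset(q, w)
                    assert abs(est - ell) <= bound
            prev = w_hi


class TestStreakOffset:
    def test_zero_ratio_zero_width(self):
        ell, clamped = streak_offset(0.0, 0.0)
        assert ell == pytest.approx(0.5)
        assert not clamped

    def test_large_negative_ratio(self):
        ell, _ = streak_offset(-100.0, 0.0)
        assert ell == pytest.approx(0.003333, abs=5e-6)

    def test_round_trip_exact_ratio(self):
        q = streak_ratio(WedgeStreakModel(h=0, k=1, ell=0.3, w=0.2))
        ell, clamped = streak_offset(q, 0.2)
        assert abs(ell - 0.3) <= 0.02
        assert not clamped

    def test_nonnegative_for_model_ratios(self):
        for ell_true in np.arange(0.02, 0.5, 0.04):
            q = streak_ratio(WedgeStreakModel(h=0, k=1, ell=ell_true, w=0.15))
            est, _ = streak_offset(q, 0.15)
            assert est >= 0

    def test_matches_closed_form_at_w_zero(self):
        for q in (-5.0, -1.0, 0.0, 0.4):
            t = 3.0 * q / 8.0
            expected = t + math.sqrt(t * t + 0.25)
            assert streak_offset(q, 0.0)[0] == expected

    def test_round_trip_bounded_by_oracle_table(self):
        prev = 0.0
        for w_hi, bound in sorted(STREAK_ROUNDTRIP_BOUNDS.items()):
            for w in np.arange(prev + 0.02, w_hi + 1e-9, 0.02):
                for ell in np.arange(0.02, 0.86, 0.05):
                    if ell + w > 0.9:
                        continue
                    q = streak_ratio(WedgeStreakModel(h=0, k=1, ell=ell, w=w))
                    est, _ = streak_offset(q, w)
                    assert abs(est - ell) <= bound
            prev = w_hi


class TestSubpixelUpdate:
    def test_zero_offset(self):
        assert subpixel_update(10, 20, 5, 0.0, 1.0) == (10.0, 20.0)

    def test_axis_aligned(self):
        assert subpixel_update(10, 20, 5, 0.2, 0.0) == pytest.approx((10.5, 20.0))
        assert subpixel_update(10, 20, 5, 0.2, math.pi / 2) == pytest.approx((10.0, 20.5))


class TestLocalizerConfig:
    def test_width_conversions(self):
        assert disk_width("edge", 1.80, 0.5, 5) == pytest.approx(0.36)
        assert disk_width("streak", 0.90, 0.5, 5) == pytest.approx(0.45)

    def test_invalid_width_rejected(self):
        with pytest.raises(ValueError, match="width"):
            LocalizerConfig(mode="edge", patch_size=5, psf_sigma=2.0, k_edge=2.0)

    def test_default_max_update_is_one_pixel(self):
        cfg = LocalizerConfig(mode="edge", patch_size=5, psf_sigma=0.5)
        assert cfg.max_update_value == pytest.approx(0.4)

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            LocalizerConfig(mode="ridge")


def _mean_error(kind, polarity="bright", negate=False, n=200, seed=5):
    rng = np.random.default_rng(seed)
    cfg = LocalizerConfig(mode=kind, patch_size=5, psf_sigma=0.5, polarity=polarity)
    errs = []
    for _ in range(n):
        phi = rng.uniform(0, 2 * math.pi)
        delta = rng.uniform(-0.5, 0.5)
        geom = LineGeometry(phi, 7 + delta * math.cos(phi), 7 + delta * math.sin(phi))
        scene = SyntheticScene(geometry=geom, feature_kind=kind,
                               psf_sigma=0.5, image_shape=(15, 15))
        img, truth = render_scene(scene)
        if negate:
            img = 2 * scene.h - img  # dark feature on bright background
        (f,) = localize_features(img, [(7, 7)], cfg)
        assert f.status in ("ok", "clamped")
        errs.append(float(truth.distance(f.sub_u, f.sub_v)))
    return float(np.mean(errs))


class TestLocalizeFeatures:
    def test_noiseless_edges_mean_error(self):
        assert _mean_error("edge") <= 0.05

    def test_noiseless_streaks_mean_error(self):
        assert _mean_error("streak") <= 0.05

    def test_dark_streak_polarity(self):
        err = _mean_error("streak", polarity="dark", negate=True, n=60)
        assert err <= 0.05

    def test_flat_region_degenerate(self, masks5):
        img = np.full((11, 11), 42.0)
        feats = localize_features(
            img, [(5, 5), (4, 6)],
            LocalizerConfig(mode="edge", psf_sigma=0.5), masks5,
        )
        assert all(f.status == "degenerate" for f in feats)

    def test_border_guesses_flagged(self, masks5):
        img = np.zeros((9, 9))
        feats = localize_features(
            img, [(0, 0)], LocalizerConfig(mode="edge", psf_sigma=0.5), masks5
        )
        assert feats[0].status == "border"

    def test_update_geometry_consistency(self):
        scene = SyntheticScene(
            geometry=LineGeometry(0.3, 10.2, 10.1), feature_kind="edge",
            psf_sigma=0.5, image_shape=(21, 21),
        )
        img, _ = render_scene(scene)
        cfg = LocalizerConfig(mode="edge", psf_sigma=0.5)
        (f,) = localize_features(img, [(10, 10)], cfg)
        assert f.status == "ok"
        exp_u = f.guess_u + 5 * f.ell_hat / 2 * math.cos(f.psi)
        exp_v = f.guess_v + 5 * f.ell_hat / 2 * math.sin(f.psi)
        assert (f.sub_u, f.sub_v) == pytest.approx((exp_u, exp_v))
        assert abs(f.ell_hat) <= cfg.max_update_value


class TestRotationInvariance:
    @pytest.mark.parametrize("kind", ["edge", "streak"])
    def test_q_and_ell_stable_under_rotation(self, kind):
        delta = 0.3
        cfg = LocalizerConfig(mode=kind, psf_sigma=0.5)
        qs, ells = [], []
        for deg in range(0, 360, 30):
            phi = math.radians(deg)
            geom = LineGeometry(phi, 8 + delta * math.cos(phi),
                                8 + delta * math.sin(phi))
            scene = SyntheticScene(geometry=geom, feature_kind=kind,
                                   psf_sigma=0.5, image_shape=(17, 17))
            img, _ = render_scene(scene)
            (f,) = localize_features(img, [(8, 8)], cfg)
            assert f.status == "ok"
            qs.append(f.q_ratio)
            ells.append(f.ell_hat)
        assert np.ptp(qs) <= 0.05 * max(1.0, abs(np.mean(qs))) + 0.02
        assert np.ptp(ells) <= 0.03
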