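"""Curvature: circumcircle exactness, kymograph registration, 2D waves."""

import numpy as np
import pytest
from skimage.draw import disk

import pecowaco as pw
from pecowaco.curvature import (Contour, _anchor_arclength, contour_from_points,
                                total_turning)
from pecowaco.errors import (GeometryError, NoWaveError, SegmentationError,
                             StandingWaveError, StripError)


def ellipse_vertex_circumcircle_oracle(a, b, half_arc):
    """Independent dense-sampling oracle: curvature of the circumcircle
    through the major-axis vertex and the two exact ellipse points at
    arclength +/- half_arc from it (symmetric, so the circumcenter lies
    on the major axis)."""
    t = np.linspace(0.0, np.pi / 2, 2_000_001)
    ds = np.sqrt((a * np.sin(t)) ** 2 + (b * np.cos(t)) ** 2)
    s = np.concatenate(([0.0], np.cumsum(
        0.5 * (ds[1:] + ds[:-1]) * np.diff(t))))
    t_half = np.interp(half_arc, s, t)
    px, py = a * np.cos(t_half), b * np.sin(t_half)
    # circumcenter (x0, 0): equidistant from (a, 0) and (px, +/-py)
    x0 = (a**2 - px**2 - py**2) / (2 * (a - px))
    return 1.0 / (a - x0)


def circle_contour(radius, n=720, center=(0.0, 0.0)):
    """Points exactly on a circle, uniform arclength by construction."""
    th = np.arange(n) * (2 * np.pi / n)
    pts = np.column_stack([center[0] + radius * np.cos(th),
                           center[1] + radius * np.sin(th)])
    return Contour(points=pts, arclength_step=2 * np.pi * radius / n)


class TestMaskToContour:
    def test_disk_perimeter(self):
        mask = np.zeros((160, 160), bool)
        rr, cc = disk((80, 80), 50)
        mask[rr, cc] = True
        c = pw.mask_to_contour(mask, pixel_size=0.5)
        assert c.perimeter == pytest.approx(2 * np.pi * 25.0, rel=0.02)

    def test_border_contact_rejected(self):
        mask = np.zeros((60, 60), bool)
        mask[0:30, 10:50] = True
        with pytest.raises(GeometryError):
            pw.mask_to_contour(mask, pixel_size=0.5)

    def test_multiple_components_rejected(self):
        mask = np.zeros((80, 80), bool)
        mask[10:20, 10:20] = True
        mask[50:60, 50:60] = True
        with pytest.raises(SegmentationError):
            pw.mask_to_contour(mask, pixel_size=0.5)

    def test_orientation_enforced(self):
        mask = np.zeros((120, 120), bool)
        rr, cc = disk((60, 60), 40)
        mask[rr, cc] = True
        c = pw.mask_to_contour(mask, pixel_size=0.5)
        from pecowaco._geometry import signed_area
        assert signed_area(c.points) > 0
        # explicitly clockwise raw points are reversed on construction
        cw = circle_contour(10.0).points[::-1]
        c2 = contour_from_points(cw, 0.2)
        assert signed_area(c2.points) > 0


class TestLocalCurvature:
    def test_circle_exact(self):
        c = circle_contour(20.0)
        prof = pw.local_curvature(c, strip_length=10.0)
        assert np.allclose(prof.kappa, 0.05, atol=1e-6)

    def test_collinear_gives_zero(self):
        # a long thin rectangle's flat sides contain collinear triples
        w, h = 40.0, 4.0
        xs = np.linspace(0, w, 200, endpoint=False)
        top = np.column_stack([xs, np.zeros_like(xs)])
        right = np.column_stack([np.full(20, w), np.linspace(0, h, 20, endpoint=False)])
        bot = np.column_stack([xs[::-1], np.full_like(xs, h)])
        left = np.column_stack([np.zeros(20), np.linspace(h, 0, 20, endpoint=False)])
        rect = np.vstack([top, right, bot, left])
        c = contour_from_points(rect, 0.2)
        prof = pw.local_curvature(c, strip_length=6.0)
        mid_flat = np.argmin(np.abs(c.points[:, 0] - w / 2)
                             + np.abs(c.points[:, 1]))
        assert prof.kappa[mid_flat] == pytest.approx(0.0, abs=1e-9)

    def test_ellipse_vertex_strip_estimator(self):
        # analytic curvature at the major-axis vertex is a/b^2 = 0.30.
        # A finite strip biases the circumcircle estimate low (the chord
        # endpoints sit on flatter parts of the ellipse): the estimator
        # must match the dense-sampling circumcircle oracle at the strip
        # scale, and converge to the closed form as the strip shrinks.
        a, b = 30.0, 10.0
        th = np.linspace(0, 2 * np.pi, 4000, endpoint=False)
        pts = np.column_stack([a * np.cos(th), b * np.sin(th)])
        c = contour_from_points(pts, 0.1)
        vertex = np.argmin(np.abs(c.points[:, 0] - a) + np.abs(c.points[:, 1]))
        prof10 = pw.local_curvature(c, strip_length=10.0)
        assert prof10.kappa[vertex] == pytest.approx(
            ellipse_vertex_circumcircle_oracle(a, b, 5.0), rel=0.02)
        prof1 = pw.local_curvature(c, strip_length=1.0)
        assert prof1.kappa[vertex] == pytest.approx(a / b**2, rel=0.15)

    def test_short_perimeter_rejected(self):
        with pytest.raises(StripError):
            pw.local_curvature(circle_contour(2.0), strip_length=10.0)

    def test_total_turning_is_two_pi(self):
        contours, _ = pw.make_wave_cell(pw.WaveCellSpec(
            radius=20.0, amplitude=1.0, period=100.0, wave_number=2,
            duration=25.0, frame_interval=5.0))
        prof = pw.local_curvature(
            Contour(contours.contours[0], 0.25), strip_length=10.0)
        assert total_turning(prof) == pytest.approx(2 * np.pi, rel=0.01)

    def test_scale_coherence(self):
        coarse = pw.local_curvature(circle_contour(20.0, n=500), 10.0)
        fine = pw.local_curvature(circle_contour(20.0, n=1000), 10.0)
        assert fine.kappa.mean() == pytest.approx(coarse.kappa.mean(),
                                                  rel=1e-3)


def wave_contours(radius=20.0, period=100.0, wave_number=2, duration=600.0,
                  amplitude=1.0, seed=0):
    contours, truth = pw.make_wave_cell(pw.WaveCellSpec(
        radius=radius, amplitude=amplitude, period=period,
        wave_number=wave_number, frame_interval=5.0, duration=duration,
        seed=seed))
    return contours, truth


class TestBuildKymograph:
    def test_static_circle_constant(self):
        contours, _ = wave_contours(amplitude=0.0, duration=60.0)
        kymo = pw.build_kymograph(contours, n_bins=90)
        assert np.allclose(kymo.values, 0.05, atol=1e-4)

    def test_spatial_periodicity_matches_wave_number(self):
        contours, _ = wave_contours(wave_number=2, duration=60.0)
        kymo = pw.build_kymograph(contours, n_bins=360)
        col = kymo.values[:, 3] - kymo.values[:, 3].mean()
        rolled = np.roll(col, 180)  # half a perimeter = one wavelength
        assert np.corrcoef(col, rolled)[0, 1] > 0.99

    def test_start_index_rotation_invariance(self):
        contours, _ = wave_contours(duration=60.0)
        kymo1 = pw.build_kymograph(contours, n_bins=180)
        rolled = [np.roll(c, 57, axis=0) for c in contours.contours]
        kymo2 = pw.build_kymograph(rolled, n_bins=180, frame_interval=5.0)
        assert np.allclose(kymo1.values, kymo2.values, atol=1e-6)

    def test_anchor_is_centroid_ray_crossing(self):
        c = circle_contour(10.0, center=(3.0, -2.0))
        s0 = _anchor_arclength(c)
        # the circle starts at angle 0 from its own center, so the +x
        # crossing is at arclength 0 (mod perimeter)
        perim = 2 * np.pi * 10.0
        assert min(s0, perim - s0) < 0.2


class TestKymographPeriodAndVelocity:
    def test_period_recovery_on_grid(self):
        contours, truth = wave_contours(period=100.0, duration=600.0)
        kymo = pw.build_kymograph(contours)
        call = pw.kymograph_period(kymo)
        assert call.oscillating
        assert call.period == pytest.approx(100.0, rel=1e-9)

    def test_static_kymograph_degenerate(self):
        contours, _ = wave_contours(amplitude=0.0, duration=600.0)
        kymo = pw.build_kymograph(contours)
        call = pw.kymograph_period(kymo)
        assert not call.oscillating
        assert call.reason == "degenerate"

    def test_stronger_of_two_superposed_waves_wins(self):
        # two superposed modes with 2:1 amplitudes: the stronger one
        # (period 100 s) sets the reported period
        n = 720
        th = np.arange(n) * 2 * np.pi / n
        frames = []
        for t in np.arange(120) * 5.0:
            r = 20.0 + 1.0 * np.cos(2 * np.pi * t / 100 - 2 * th) \
                + 0.5 * np.cos(2 * np.pi * t / 150 - 2 * th)
            frames.append(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        kymo = pw.build_kymograph(frames, frame_interval=5.0)
        call = pw.kymograph_period(kymo)
        assert call.period == pytest.approx(100.0, rel=1e-9)

    def test_wave_velocity_matches_phase_velocity(self):
        contours, truth = wave_contours(radius=20.0, wave_number=2,
                                        period=100.0, duration=600.0)
        kymo = pw.build_kymograph(contours)
        est = pw.wave_velocity(kymo)
        assert est.wave_number == 2
        assert est.velocity == pytest.approx(truth.true_velocity, rel=0.05)
        assert est.direction == 1  # wave travels toward increasing theta

    def test_doubling_period_halves_velocity(self):
        _, t1 = wave_contours(period=100.0, duration=600.0)
        _, t2 = wave_contours(period=200.0, duration=600.0)
        assert t2.true_velocity == pytest.approx(t1.true_velocity / 2)
        c2, _ = wave_contours(period=200.0, duration=1200.0)
        est = pw.wave_velocity(pw.build_kymograph(c2))
        assert est.velocity == pytest.approx(t2.true_velocity, rel=0.05)

    def test_standing_wave_rejected(self):
        n = 720
        th = np.arange(n) * 2 * np.pi / n
        frames = []
        for t in np.arange(120) * 5.0:
            # two equal counter-propagating modes = standing wave
            r = 20.0 + 0.5 * np.cos(2 * np.pi * t / 100 - 2 * th) \
                + 0.5 * np.cos(2 * np.pi * t / 100 + 2 * th)
            frames.append(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        kymo = pw.build_kymograph(frames, frame_interval=5.0)
        with pytest.raises(StandingWaveError):
            pw.wave_velocity(kymo)

    def test_no_wave_error_when_not_oscillating(self):
        contours, _ = wave_contours(amplitude=0.0, duration=600.0)
        kymo = pw.build_kymograph(contours)
        with pytest.raises(NoWaveError):
            pw.wave_velocity(kymo)
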