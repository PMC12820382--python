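"""Piecewise edge detection, fibril statistics, alignment, curvature."""

import numpy as np
import pytest

from fibrildeg.imagesim import ImageSpec, SyntheticFibrilSpec, line_centerline, render
from fibrildeg.piecewise import (
    FibrilMeasurement,
    FibrilTrace,
    PieceMeasurement,
    curvature,
    detect_edges_piecewise,
    fibril_stats,
    image_alignment,
    measure_image,
)

PX = 4.0


def trace_of(scene, fid=0):
    return FibrilTrace(points=scene.traces[fid], pixel_size=PX, fibril_id=fid)


class TestDetectEdges:
    def test_straight_fibril_recovered(self, fixture_scenes):
        scene = fixture_scenes["straight_d100"]
        pieces = detect_edges_piecewise(scene.image, trace_of(scene))
        assert len(pieces) == 10  # 2.5 um / 250 nm
        for p in pieces:
            assert p.diameter == pytest.approx(100.0, abs=PX)
            assert p.orientation == pytest.approx(0.0, abs=0.5)

    def test_short_trace_rejected(self):
        img = np.zeros((128, 600))
        tr = FibrilTrace(points=[[10, 64], [10 + 1900 / PX, 64]], pixel_size=PX)
        with pytest.raises(ValueError):
            detect_edges_piecewise(img, tr)

    def test_rotation_leaves_diameter_unchanged(self, fixture_scenes):
        base = fixture_scenes["straight_d100"]
        rot = fixture_scenes["rotated_30"]
        d0 = fibril_stats(detect_edges_piecewise(base.image, trace_of(base)))
        d30 = fibril_stats(detect_edges_piecewise(rot.image, trace_of(rot)))
        assert d30.mean_orientation == pytest.approx(30.0, abs=1.0)
        assert d30.mean_diameter == pytest.approx(d0.mean_diameter, abs=PX)

    def test_quarter_turn_invariance(self, fixture_scenes):
        scene = fixture_scenes["straight_d100"]
        h = scene.image.shape[0]
        img90 = np.rot90(scene.image)  # (x, y) -> (y, h-1-x)
        pts = scene.traces[0]
        pts90 = np.column_stack([pts[:, 1], h - 1 - pts[:, 0]])
        tr90 = FibrilTrace(points=pts90, pixel_size=PX)
        d0 = fibril_stats(detect_edges_piecewise(scene.image, trace_of(scene)))
        d90 = fibril_stats(detect_edges_piecewise(img90, tr90))
        assert d90.mean_diameter == pytest.approx(d0.mean_diameter, abs=PX)

    def test_intensity_rescale_invariance(self, fixture_scenes):
        scene = fixture_scenes["straight_d100"]
        d0 = fibril_stats(detect_edges_piecewise(scene.image, trace_of(scene)))
        d1 = fibril_stats(detect_edges_piecewise(scene.image * 0.4 + 10, trace_of(scene)))
        assert d1.mean_diameter == pytest.approx(d0.mean_diameter, abs=PX / 2)

    def test_tapered_fibril_mean_and_sd(self, fixture_scenes):
        scene = fixture_scenes["tapered_80_120"]
        stats = fibril_stats(detect_edges_piecewise(scene.image, trace_of(scene)))
        assert stats.mean_diameter == pytest.approx(100.0, abs=PX)
        # linear taper 80->120 over 10 pieces: piece means step by 4 nm
        true_sd = np.std(np.linspace(82, 118, 10), ddof=1)
        assert stats.sd_diameter == pytest.approx(true_sd, abs=PX)

    def test_noise_tolerance(self, fixture_scenes):
        scene = fixture_scenes["noise_10"]
        stats = fibril_stats(detect_edges_piecewise(scene.image, trace_of(scene)))
        assert stats.mean_diameter == pytest.approx(100.0, abs=2 * PX)


class TestFibrilStats:
    def test_two_point_sd(self):
        pieces = [
            PieceMeasurement(0, 90.0, 0.0, (0, 0)),
            PieceMeasurement(1, 110.0, 0.0, (62, 0)),
        ]
        stats = fibril_stats(pieces)
        assert stats.mean_diameter == pytest.approx(100.0)
        assert stats.sd_diameter == pytest.approx(14.142, abs=0.01)

    def test_insufficient_pieces(self):
        with pytest.raises(ValueError):
            fibril_stats([PieceMeasurement(0, 100.0, 0.0, (0, 0))])

    def test_axial_mean_near_wrap(self):
        pieces = [
            PieceMeasurement(0, 100.0, 88.0, (0, 0)),
            PieceMeasurement(1, 100.0, -88.0, (62, 0)),
        ]
        stats = fibril_stats(pieces)
        assert abs(stats.mean_orientation) == pytest.approx(90.0, abs=1e-6)


class TestCurvature:
    def test_straight_is_zero(self):
        pieces = [PieceMeasurement(i, 100.0, 5.0, (i, 0)) for i in range(5)]
        assert curvature(pieces) == 0.0

    def test_five_degrees_per_piece(self):
        pieces = [PieceMeasurement(i, 100.0, 5.0 * i, (i, 0)) for i in range(10)]
        assert curvature(pieces) == pytest.approx(20.0)

    def test_reversal_invariance(self):
        rng = np.random.default_rng(3)
        ori = np.cumsum(rng.normal(0, 3, 8))
        pieces = [PieceMeasurement(i, 100.0, o, (i, 0)) for i, o in enumerate(ori)]
        rev = [PieceMeasurement(i, 100.0, o, (i, 0))
               for i, o in enumerate(ori[::-1])]
        assert curvature(rev) == pytest.approx(curvature(pieces))

    def test_measured_arc_matches_analytic(self, fixture_scenes):
        scene = fixture_scenes["arc_r5um"]
        stats = fibril_stats(detect_edges_piecewise(scene.image, trace_of(scene)))
        assert stats.curvature == pytest.approx((180 / np.pi) / 5.0, rel=0.02)


class TestImageAlignment:
    @staticmethod
    def _measurements(orientations):
        return [
            FibrilMeasurement(i, 100.0, 1.0, o, 0.0, 8)
            for i, o in enumerate(orientations)
        ]

    def test_identical_orientations(self):
        fibs, sd = image_alignment(self._measurements([15.0, 15.0, 15.0]))
        assert sd == 0.0
        assert all(f.normalized_orientation == pytest.approx(0.0) for f in fibs)

    def test_global_rotation_invariance(self):
        rng = np.random.default_rng(0)
        base = rng.normal(0, 8, 12)
        _, sd0 = image_alignment(self._measurements(base))
        for shift in (20.0, 85.0):  # the latter pushes angles across the wrap
            from fibrildeg.geometry import wrap_half_turn

            _, sd1 = image_alignment(self._measurements(wrap_half_turn(base + shift)))
            assert sd1 == pytest.approx(sd0, abs=1e-9)

    def test_single_fibril_rejected(self):
        with pytest.raises(ValueError):
            image_alignment(self._measurements([10.0]))

    def test_recovers_known_dispersion_from_pixels(self):
        # render 6 straight fibrils with known orientations (8 deg spread)
        rng = np.random.default_rng(6)
        angles = np.clip(rng.normal(0.0, 8.0, 6), -14, 14)
        spec = ImageSpec(width=704, height=1280, pixel_size=PX, seed=1)
        fibs, traces = [], []
        for i, a in enumerate(angles):
            cl = line_centerline((40, 160 + 170 * i), a, 2200.0, PX)
            fibs.append(SyntheticFibrilSpec(cl, diameter=90.0))
            traces.append(FibrilTrace(points=cl, pixel_size=PX, fibril_id=i))
        img, _ = render(spec, fibs)
        _, fib_table = measure_image(img, traces)
        measured_sd = fib_table["normalized_orientation_deg"].std(ddof=1)
        true_sd = np.std(angles - angles.mean(), ddof=1)
        assert measured_sd == pytest.approx(true_sd, abs=0.5)
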