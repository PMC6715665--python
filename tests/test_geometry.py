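"""Geometry: MDS embedding fidelity, closed-form areas, chord identities."""

import numpy as np
import pytest

from annulodyn import (
    CrystalLayout,
    ReconstructionError,
    annulus_area,
    annulus_circumference,
    classify_shape,
    cross_diameters,
    geometry_series,
    reconstruct_coordinates,
    ring_chords,
    sinus_lengths,
)
from annulodyn.errors import ValidationError
from annulodyn.geometry import DEFAULT_LAYOUT, pairwise_distance_matrix


def _hexagon_points(a=12.0, b=12.0, order=DEFAULT_LAYOUT.ring_order):
    """Six points on an ellipse at 60-degree parameter steps, rows = crystal label."""
    pts = np.zeros((6, 3))
    for pos, label in enumerate(order):
        th = np.pi / 3 * pos
        pts[label - 1] = [a * np.cos(th), b * np.sin(th), 0.0]
    return pts


def _frame_from_points(points):
    return pairwise_distance_matrix(points)


class TestReconstruction:
    def test_triangle_3_4_5_embedded_exactly(self):
        D = np.array([[np.nan, 3.0, 4.0], [3.0, np.nan, 5.0], [4.0, 5.0, np.nan]])
        np.fill_diagonal(D, 0.0)
        emb = reconstruct_coordinates(D)
        rec = pairwise_distance_matrix(emb.points)
        assert abs(rec[0, 1] - 3) < 1e-9 and abs(rec[0, 2] - 4) < 1e-9
        assert abs(rec[1, 2] - 5) < 1e-9

    def test_random_8_point_configuration_reproduced(self, rng):
        pts = rng.normal(scale=15, size=(8, 3))
        D = _frame_from_points(pts)
        emb = reconstruct_coordinates(D)
        rec = pairwise_distance_matrix(emb.points)
        off = ~np.eye(8, dtype=bool)
        assert np.abs(rec[off] - D[off]).max() < 1e-9
        assert emb.stress_mm < 1e-9

    def test_all_zero_matrix_degenerate(self):
        emb = reconstruct_coordinates(np.zeros((8, 8)))
        assert emb.degenerate
        assert np.allclose(emb.points, 0.0)

    def test_too_many_missing_rejected(self):
        D = _frame_from_points(np.random.default_rng(0).normal(size=(8, 3)))
        D[np.triu_indices(8, 1)[0][:8], np.triu_indices(8, 1)[1][:8]] = np.nan
        D[np.triu_indices(8, 1)[1][:8], np.triu_indices(8, 1)[0][:8]] = np.nan
        with pytest.raises(ReconstructionError, match="missing"):
            reconstruct_coordinates(D)

    def test_orientation_convention(self, clean_dataset):
        _, (sono, _, _, _) = clean_dataset
        emb = reconstruct_coordinates(sono.distances[0], DEFAULT_LAYOUT)
        assert np.allclose(emb.points[:6].mean(axis=0), 0.0, atol=1e-9)
        # first ring crystal along +x, apex below the annular plane
        assert emb.points[0, 1] == pytest.approx(0.0, abs=1e-6)
        assert emb.points[0, 0] > 0
        assert emb.points[6, 2] < 0


class TestAnnulusArea:
    def test_regular_hexagon_closed_form(self):
        pts = _hexagon_points(12.0, 12.0)
        expected = 3 * np.sqrt(3) / 2 * 12.0**2  # 374.1229...
        assert annulus_area(pts) == pytest.approx(expected, abs=1e-6)

    def test_collinear_points_zero_with_warning(self):
        pts = np.column_stack([np.arange(6.0), np.arange(6.0), np.zeros(6)])
        with pytest.warns(UserWarning, match="collinear"):
            assert annulus_area(pts) == 0.0

    def test_ellipse_hexagon_matches_2d_shoelace(self):
        a, b = 13.0, 10.0
        pts = _hexagon_points(a, b)
        order = [lab - 1 for lab in DEFAULT_LAYOUT.ring_order]
        x, y = pts[order, 0], pts[order, 1]
        brute = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
        assert annulus_area(pts) == pytest.approx(brute, abs=1e-9)

    def test_rigid_motion_invariance(self, rng):
        pts = _hexagon_points(13.0, 10.0) + rng.normal(scale=0.5, size=(6, 3))
        base = annulus_area(pts)
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        ) @ np.array([[1, 0, 0], [0, np.cos(0.3), -np.sin(0.3)], [0, np.sin(0.3), np.cos(0.3)]])
        moved = pts @ R.T + np.array([5.0, -2.0, 11.0])
        assert annulus_area(moved) == pytest.approx(base, abs=1e-9)

    def test_hexagon_area_bounded_by_convex_hull(self, rng):
        from scipy.spatial import ConvexHull

        pts = _hexagon_points(13.0, 10.0)
        pts[:, :2] += rng.normal(scale=1.0, size=(6, 2))
        area = annulus_area(pts)
        hull = ConvexHull(pts[:, :2])
        assert area <= hull.volume + 1e-9


class TestChordQuantities:
    def test_regular_hexagon_circumference_six_radii(self):
        D = _frame_from_points(_hexagon_points(12.0, 12.0))
        assert annulus_circumference(D) == pytest.approx(72.0, abs=1e-9)

    def test_coincident_points_zero_circumference(self):
        D = np.zeros((8, 8))
        assert annulus_circumference(D) == 0.0

    def test_sinus_lengths_regular_hexagon(self):
        D = _frame_from_points(_hexagon_points(12.0, 12.0))
        sinus = sinus_lengths(D)
        assert all(v == pytest.approx(24.0, abs=1e-9) for v in sinus.values())

    def test_sinus_sum_equals_circumference_identity(self, rng):
        pts = _hexagon_points(13.0, 10.0) + rng.normal(scale=0.8, size=(6, 3))
        D = _frame_from_points(np.vstack([pts, rng.normal(scale=30, size=(2, 3))]))
        sinus = sinus_lengths(D)
        assert sum(sinus.values()) == pytest.approx(annulus_circumference(D), abs=1e-9)

    def test_cross_diameters_on_circle_and_ellipse(self):
        D = _frame_from_points(_hexagon_points(12.0, 12.0))
        assert all(v == pytest.approx(24.0, abs=1e-9) for v in cross_diameters(D).values())
        D = _frame_from_points(_hexagon_points(13.0, 10.0))
        diam = cross_diameters(D)
        assert diam["NC-LR"] == pytest.approx(26.0, abs=1e-9)  # pair (1,4) on long axis

    def test_chords_match_forward_distances(self, clean_dataset):
        _, (sono, _, _, truth) = clean_dataset
        i = 100
        D = sono.distances[i]
        assert annulus_circumference(D) == pytest.approx(truth.frames["aac_mm"][i], abs=1e-9)
        diam = cross_diameters(D)
        assert diam["RC-LN"] == pytest.approx(truth.frames["d25_mm"][i], abs=1e-9)


class TestClassifyShape:
    @pytest.mark.parametrize(
        "diams, label",
        [
            ((26.5, 20.1, 23.0), "oval"),     # printed mid-systole means, diff 6.4 mm
            ((22.0, 22.0, 22.0), "round"),
            ((23.0, 20.0, 21.0), "round"),    # difference exactly 3: strict inequality
            ((23.1, 20.0, 21.0), "oval"),
        ],
    )
    def test_threshold_rule(self, diams, label):
        assert classify_shape(diams) == label

    def test_permutation_invariant(self):
        assert classify_shape((20.0, 26.0, 23.0)) == classify_shape((26.0, 23.0, 20.0))


class TestLayoutValidation:
    def test_bad_ring_order_rejected(self):
        with pytest.raises(ValidationError):
            CrystalLayout(ring_order=(1, 2, 3, 4, 5, 5))

    def test_bad_diameter_pairing_rejected(self):
        with pytest.raises(ValidationError, match="diameter pair"):
            CrystalLayout(diameter_pairs={"NC-LR": (1, 6), "RC-LN": (2, 5), "LC-RN": (3, 4)})


class TestGeometrySeries:
    def test_static_dataset_constant_series(self, static_dataset):
        from annulodyn import align_streams

        _, (sono, ana, _, _) = static_dataset
        geo = geometry_series(align_streams(sono, ana))
        for col in ("aaa_mm2", "aac_mm", "nc_mm", "d14_mm"):
            assert np.ptp(geo.frames[col].to_numpy()) < 1e-6

    def test_noise_free_series_matches_truth(self, clean_dataset):
        from annulodyn import align_streams

        _, (sono, ana, _, truth) = clean_dataset
        geo = geometry_series(align_streams(sono, ana))
        # chord quantities are linear in the resampled distances, so they must
        # equal the identically-interpolated truth to machine precision
        t_rec = geo.frames["time_s"].to_numpy()
        t_tru = truth.frames["time_s"].to_numpy()
        for col in ("aac_mm", "nc_mm", "rc_mm", "lc_mm", "d14_mm", "d25_mm", "d36_mm"):
            expected = np.interp(t_rec, t_tru, truth.frames[col].to_numpy())
            assert np.abs(geo.frames[col].to_numpy() - expected).max() < 1e-6
        # the area passes through the (nonlinear) embedding; only the
        # second-order resampling error remains
        expected = np.interp(t_rec, t_tru, truth.frames["aaa_mm2"].to_numpy())
        assert np.abs(geo.frames["aaa_mm2"].to_numpy() - expected).max() < 0.05

    def test_dropout_frames_flagged_and_excluded(self, static_dataset):
        from annulodyn import align_streams

        _, (sono, ana, _, _) = static_dataset
        cond = sono.condensed.copy()
        cond[50:60, 3] = np.nan  # 10-frame gap: beyond interpolation policy
        from annulodyn import DistanceSeries

        broken = DistanceSeries.from_condensed(sono.timestamps, cond, sono.fs)
        aligned = align_streams(broken, ana)
        geo = geometry_series(aligned)
        assert len(aligned.flagged) > 0
        assert len(geo.frames) < len(aligned.sono.timestamps)
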