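import numpy as np
import pytest

import limbalign as la
from limbalign.geometry import DegenerateGeometryError, ray_angle
from limbalign.landmarks import (FragmentedMaskError, fit_circle,
                                 head_landmarks, joint_line, shaft_axis)
from limbalign.masks import MissingStructureError


def circle_points(center, radius, n, start=0.0):
    th = start + np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + radius * np.sin(th),
                            center[1] + radius * np.cos(th)])


class TestFitCircle:
    def test_exact_on_noiseless_circle(self):
        pts = circle_points((5.0, 5.0), 3.0, 8)
        c, r = fit_circle(pts)
        assert abs(c.row - 5) < 1e-9 and abs(c.col - 5) < 1e-9
        assert abs(r - 3) < 1e-9

    def test_three_points_give_circumcircle(self):
        # equilateral triangle: circumcentre at centroid, R = side / sqrt(3)
        side = 4.0
        pts = np.array([[0.0, 0.0], [0.0, side],
                        [side * np.sqrt(3) / 2, side / 2]])
        c, r = fit_circle(pts)
        centroid = pts.mean(axis=0)
        assert np.allclose([c.row, c.col], centroid, atol=1e-9)
        assert r == pytest.approx(side / np.sqrt(3), abs=1e-9)

    def test_noisy_fit_is_unbiased(self):
        rng = np.random.default_rng(99)
        centers = []
        base = circle_points((5.0, 5.0), 3.0, 8)
        for _ in range(200):
            c, _ = fit_circle(base + rng.normal(0, 0.1, base.shape))
            centers.append([c.row, c.col])
        mean_c = np.mean(centers, axis=0)
        assert np.abs(mean_c - 5.0).max() < 0.05

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), 2 * np.arange(5.0) + 1])
        with pytest.raises(DegenerateGeometryError, match="collinear"):
            fit_circle(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_circle([[0, 0], [1, 1]])


class TestShaftAxis:
    def test_axis_aligned_rectangle_is_vertical(self):
        mask = np.zeros((120, 40), bool)
        mask[10:110, 12:28] = True
        axis = shaft_axis(mask)
        assert abs(axis.direction[0] - 1.0) < 1e-6
        assert abs(axis.direction[1]) < 1e-6
        assert axis.anchor.col == pytest.approx(19.5, abs=1e-6)

    def test_rotated_rectangle_recovers_tilt(self):
        # rasterise a 10-degree rotated rectangle analytically
        theta = np.deg2rad(10.0)
        d = np.array([np.cos(theta), np.sin(theta)])
        p0 = np.array([10.0, 30.0])
        R, C = np.mgrid[:160, :90].astype(float)
        rel_r, rel_c = R - p0[0], C - p0[1]
        t = rel_r * d[0] + rel_c * d[1]
        s = -rel_r * d[1] + rel_c * d[0]
        mask = (t >= 0) & (t <= 140) & (np.abs(s) <= 9)
        axis = shaft_axis(mask)
        ang = np.degrees(np.arctan2(axis.direction[1], axis.direction[0]))
        assert ang == pytest.approx(10.0, abs=0.2)

    def test_bowed_shaft_returns_central_chord(self):
        # shaft = annulus sector; the mid-boundary curve is analytic, so the
        # expected chord of the central 60% of rows is computed in closed form
        cy, cx, R0, w = 80.0, -160.0, 200.0, 10.0
        rows = np.arange(160)
        RR, CC = np.mgrid[:160, :90].astype(float)
        rad = np.hypot(RR - cy, CC - cx)
        mask = (np.abs(rad - R0) <= w)
        axis = shaft_axis(mask)

        def mid_col(r):
            dy2 = (r - cy) ** 2
            outer = cx + np.sqrt((R0 + w) ** 2 - dy2)
            inner = cx + np.sqrt((R0 - w) ** 2 - dy2)
            return (outer + inner) / 2.0

        occ = np.flatnonzero(mask.any(axis=1))
        lo = occ[0] + 0.2 * (occ[-1] - occ[0])
        hi = occ[-1] - 0.2 * (occ[-1] - occ[0])
        chord = np.array([hi - lo, mid_col(hi) - mid_col(lo)])
        expected = np.degrees(np.arctan2(chord[1], chord[0]))
        got = np.degrees(np.arctan2(axis.direction[1], axis.direction[0]))
        assert got == pytest.approx(expected, abs=0.3)

    def test_short_mask_rejected(self):
        mask = np.zeros((30, 10), bool)
        mask[5:15, 2:8] = True
        with pytest.raises(MissingStructureError, match="20"):
            shaft_axis(mask)

    def test_fragmented_mask_rejected(self):
        mask = np.zeros((100, 40), bool)
        mask[5:95, 5:12] = True
        mask[5:95, 25:32] = True  # second run in every row
        with pytest.raises(FragmentedMaskError):
            shaft_axis(mask)


def two_lobe_mask(shape, pa, pb, r, distal=True):
    """Two discs whose extremal points are exactly pa/pb plus a connecting
    block, mimicking an articular surface."""
    sgn = 1 if distal else -1
    R, C = np.mgrid[:shape[0], :shape[1]].astype(float)
    m = np.zeros(shape, bool)
    for p in (pa, pb):
        c = (p[0] - sgn * r, p[1])
        m |= (R - c[0]) ** 2 + (C - c[1]) ** 2 <= r ** 2
    lo, hi = sorted([pa[1], pb[1]])
    band_top = min(pa[0], pb[0]) - sgn * r - (r if distal else 0)
    m[int(band_top):int(band_top) + r, int(lo):int(hi) + 1] = True
    return m


class TestJointLine:
    def test_horizontal_articular_edge(self):
        mask = two_lobe_mask((80, 120), (60.0, 25.0), (60.0, 95.0), 12)
        med, lat, line, center = joint_line(mask, "tibia_distal", side="left")
        assert abs(line.direction[0]) < 0.02  # direction (0, +-1)
        # 0.5 px rasterisation bias: integer pixels sit inside the nominal disc
        assert center.row == pytest.approx(60.0, abs=0.8)
        assert center.col == pytest.approx(60.0, abs=0.5)
        assert med.col > lat.col  # left side: medial at larger col

    def test_right_side_mirrors_labels(self):
        mask = two_lobe_mask((80, 120), (62.0, 25.0), (58.0, 95.0), 12)
        med_l, lat_l, _, _ = joint_line(mask, "tibia_distal", side="left")
        med_r, lat_r, _, _ = joint_line(mask[:, ::-1], "tibia_distal", side="right")
        W = 120
        assert med_r.col == pytest.approx((W - 1) - med_l.col, abs=1e-6)
        assert lat_r.col == pytest.approx((W - 1) - lat_l.col, abs=1e-6)

    def test_single_lobe_raises_degeneracy_naming_bone(self):
        R, C = np.mgrid[:60, :60].astype(float)
        mask = (R - 20) ** 2 + (C - 30) ** 2 <= 15 ** 2
        with pytest.raises(DegenerateGeometryError, match="tibia_distal"):
            joint_line(mask, "tibia_distal", side="left")

    def test_unknown_bone_rejected(self):
        with pytest.raises(ValueError, match="unknown bone"):
            joint_line(np.ones((10, 10), bool), "patella", side="left")

    def test_phantom_knee_jlca_zero_gives_parallel_lines(self):
        spec = la.PhantomSpec(jlca_true=0.0, mMPTA_true=87.0, mLDFA_true=87.0)
        case = la.generate_phantom(spec)
        knee = case.mask_set.masks["knee"]
        _, _, fem_line, _ = joint_line(knee, "femur_distal", side="left")
        _, _, tib_line, _ = joint_line(knee, "tibia_proximal", side="left")
        ang = np.degrees(np.arccos(np.clip(abs(np.dot(fem_line.d, tib_line.d)), 0, 1)))
        assert ang < 0.3

    def test_phantom_knee_jlca_two_degrees_recovered(self):
        spec = la.PhantomSpec(jlca_true=2.0)
        case = la.generate_phantom(spec)
        knee = case.mask_set.masks["knee"]
        _, _, fem_line, _ = joint_line(knee, "femur_distal", side="left")
        _, _, tib_line, _ = joint_line(knee, "tibia_proximal", side="left")
        ang = np.degrees(np.arccos(np.clip(abs(np.dot(fem_line.d, tib_line.d)), 0, 1)))
        assert ang == pytest.approx(2.0, abs=0.3)


class TestHeadLandmarks:
    def test_phantom_head_center_within_half_pixel(self, default_case):
        ms = default_case.mask_set
        center, radius, apex, troch, neck = head_landmarks(
            ms.masks["femoral_head"], side="left")
        off = ms.offsets["femoral_head"]
        truth = default_case.truth_landmarks.head_center
        assert abs(center.row + off[0] - truth.row) < 0.5
        assert abs(center.col + off[1] - truth.col) < 0.5
        assert radius == pytest.approx(default_case.truth_landmarks.head_radius,
                                       abs=1.0)

    def test_bare_disc_reports_absent_trochanter(self):
        R, C = np.mgrid[:80, :80].astype(float)
        disc = (R - 40) ** 2 + (C - 40) ** 2 <= 30 ** 2
        center, radius, apex, troch, neck = head_landmarks(disc, side="left")
        assert troch is None and neck is None
        assert center.row == pytest.approx(40, abs=0.5)
        assert radius == pytest.approx(30, abs=0.7)

    def test_mirrored_mask_gives_mirrored_landmarks(self, default_case):
        mask = default_case.mask_set.masks["femoral_head"]
        W = mask.shape[1]
        c_l, r_l, a_l, t_l, n_l = head_landmarks(mask, side="left")
        c_r, r_r, a_r, t_r, n_r = head_landmarks(mask[:, ::-1], side="right")
        assert c_r.col == pytest.approx((W - 1) - c_l.col, abs=1e-6)
        assert t_r.col == pytest.approx((W - 1) - t_l.col, abs=1e-6)
        assert n_r.direction[0] == pytest.approx(n_l.direction[0], abs=1e-9)
        assert n_r.direction[1] == pytest.approx(-n_l.direction[1], abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(MissingStructureError):
            head_landmarks(np.zeros((10, 10), bool))


class TestAssemble:
    def test_every_landmark_within_one_pixel_of_truth(self, normal_cases):
        for case in normal_cases:
            lm = la.assemble(case.mask_set)
            truth = case.truth_landmarks
            for name, p in lm.points().items():
                tp = getattr(truth, name)
                err = p.distance_to(tp)
                assert err < 1.0, f"{name}: {err:.2f} px off"

    def test_translation_equivariance_is_exact(self, default_case):
        ms = default_case.mask_set.copy()
        dr, dc = 7, 11
        ms.offsets = {k: (v[0] + dr, v[1] + dc) for k, v in ms.offsets.items()}
        ms.canvas_shape = (ms.canvas_shape[0] + dr, ms.canvas_shape[1] + dc)
        base = la.assemble(default_case.mask_set)
        moved = la.assemble(ms)
        for name, p in base.points().items():
            q = getattr(moved, name)
            assert q.row - p.row == pytest.approx(dr, abs=1e-12)
            assert q.col - p.col == pytest.approx(dc, abs=1e-12)

    def test_missing_class_error_names_class(self, default_case):
        ms = default_case.mask_set.copy()
        del ms.masks["ankle"]
        with pytest.raises(MissingStructureError, match="ankle"):
            la.assemble(ms)

    def test_right_side_matches_mirrored_left(self):
        base = la.sample_spec(21, "normal").to_dict()
        left = la.generate_phantom(la.PhantomSpec(**{**base, "side": "left"}))
        right = la.generate_phantom(la.PhantomSpec(**{**base, "side": "right"}))
        lm_l = la.assemble(left.mask_set)
        lm_r = la.assemble(right.mask_set)
        W = left.mask_set.canvas_shape[1]
        for name, p in lm_l.points().items():
            q = getattr(lm_r, name)
            assert q.row == pytest.approx(p.row, abs=1e-9), name
            assert q.col == pytest.approx((W - 1) - p.col, abs=1e-9), name


class TestRotationRobustness:
    @pytest.mark.parametrize("theta", [2.0, 5.0])
    def test_rotating_a_shaft_rotates_its_axis(self, theta):
        d = np.array([np.cos(np.deg2rad(theta)), np.sin(np.deg2rad(theta))])
        p0 = np.array([10.0, 40.0])
        R, C = np.mgrid[:200, :110].astype(float)
        rel_r, rel_c = R - p0[0], C - p0[1]
        t = rel_r * d[0] + rel_c * d[1]
        s = -rel_r * d[1] + rel_c * d[0]
        mask = (t >= 0) & (t <= 180) & (np.abs(s) <= 12)
        axis = shaft_axis(mask)
        ang = np.degrees(np.arctan2(axis.direction[1], axis.direction[0]))
        assert ang == pytest.approx(theta, abs=0.3)
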