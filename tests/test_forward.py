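import numpy as np
import pytest
from scipy.spatial import cKDTree
from skimage import measure

from nailguide.contour import EmptyLensError
from nailguide.forward import (MILD_OBLIQUITY_BAND, SCENARIOS, beam_obliquity_deg,
                               lens_contour, make_fixture, render_radiograph,
                               sample_pose)
from nailguide.geometry import CameraModel
from nailguide.nail import NailSpec
from nailguide.pose import Pose


def aligned_pose(camera, nail, z=700.0):
    """Hole-0 axis exactly through the source."""
    R = np.array([[1.0, 0, 0], [0, 0, -1.0], [0, 1.0, 0]])
    # nail x stays x; hole axis z maps to -z (toward source) via rotation
    R = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])
    return Pose(R, np.array([0.0, 0.0, z]))


class TestSamplePose:
    @pytest.mark.parametrize("obliquity", [2.0, 10.0, 20.0])
    def test_requested_obliquity(self, camera, nail, obliquity):
        rng = np.random.default_rng(1)
        for _ in range(5):
            pose = sample_pose(camera, nail, obliquity, rng)
            assert beam_obliquity_deg(camera, nail, pose, 0) == \
                pytest.approx(obliquity, abs=1e-6)


class TestLensContour:
    def test_aligned_is_circular(self, camera, nail):
        pose = aligned_pose(camera, nail)
        lc = lens_contour(camera, nail, pose, 0)
        assert lc.is_circular
        assert lc.tips is None
        r = np.linalg.norm(lc.points - lc.points.mean(axis=0), axis=1)
        assert r.max() / r.min() - 1.0 < 1e-3

    def test_oblique_has_two_tips_inside_both(self, camera, nail):
        from nailguide.forward import hole_rim_conics
        pose = sample_pose(camera, nail, 20.0, np.random.default_rng(5))
        lc = lens_contour(camera, nail, pose, 0)
        assert not lc.is_circular
        assert lc.tips.shape == (2, 2)
        e1, e2 = hole_rim_conics(camera, nail, pose, 0)
        for conic in (e1, e2):
            vals = conic.evaluate(lc.points)
            scale = np.maximum(1.0, np.sum(lc.points ** 2, axis=1))
            assert np.max(vals / scale) < 1e-6

    def test_steep_obliquity_empty(self, camera, nail):
        pose = sample_pose(camera, nail, 80.0, np.random.default_rng(2))
        with pytest.raises(EmptyLensError):
            lens_contour(camera, nail, pose, 0)
        # ray-cast oracle: no through-hole rays -> no pixel at background level
        img = render_radiograph(camera, nail, pose, noise_sigma=0.0)
        gtc = img.ground_truth_contours[0]
        assert gtc is None

    def test_tips_are_contour_members(self, camera, nail, mild_pose):
        lc = lens_contour(camera, nail, mild_pose, 0)
        for tip in lc.tips:
            assert np.min(np.linalg.norm(lc.points - tip, axis=1)) < 0.5


class TestRenderRadiograph:
    def test_background_is_one(self, camera, nail, mild_image):
        corner = mild_image.pixels[:32, :32]
        np.testing.assert_allclose(corner, 1.0)

    def test_deterministic(self, camera, nail, mild_pose):
        a = render_radiograph(camera, nail, mild_pose, noise_sigma=0.01, seed=9)
        b = render_radiograph(camera, nail, mild_pose, noise_sigma=0.01, seed=9)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_noise_variance(self, camera, nail, mild_pose):
        img = render_radiograph(camera, nail, mild_pose, noise_sigma=0.02, seed=3)
        bg = img.pixels[:316, :316]  # ~1e5 background pixels
        assert bg.size >= 1e5 * 0.99
        assert np.var(bg) == pytest.approx(0.02 ** 2, rel=0.10)

    def test_nail_silhouette_dark(self, camera, nail, mild_pose, mild_image):
        from nailguide.geometry import project_point
        p = project_point(camera, nail.hole_center_cam(mild_pose, 0)
                          + np.array([0.0, 0.0, 0.0]))
        # a point between the holes on the nail axis projects into the
        # silhouette; sample the midpoint between hole centers
        mid = 0.5 * (nail.hole_center_cam(mild_pose, 0)
                     + nail.hole_center_cam(mild_pose, 1))
        q = project_point(camera, mid)
        assert mild_image.pixels[int(q[1]), int(q[0])] < 0.1

    def test_screw_in_hole_occludes(self, camera, nail, mild_pose):
        img = render_radiograph(camera, nail, mild_pose, noise_sigma=0.0,
                                screw_in_hole=(0,))
        lc = lens_contour(camera, nail, mild_pose, 0)
        cen = lc.points.mean(axis=0)
        assert img.pixels[int(round(cen[1])), int(round(cen[0]))] < 0.5

    def test_raycast_boundary_matches_analytic(self, camera, nail, mild_pose):
        img = render_radiograph(camera, nail, mild_pose, noise_sigma=0.0)
        lc = img.ground_truth_contours[0]
        contours = measure.find_contours(img.pixels, 0.95)
        best, bd = None, np.inf
        for c in contours:
            b = np.column_stack([c[:, 1], c[:, 0]])
            d = np.linalg.norm(b.mean(axis=0) - lc.centroid)
            if d < bd:
                best, bd = b, d
        d1 = cKDTree(lc.points).query(best)[0].max()
        d2 = cKDTree(best).query(lc.points)[0].max()
        assert max(d1, d2) < 1.5  # pixel-grid boundary; subpixel check in acceptance


class TestProperties:
    def test_inplane_rotation_equivariance(self, camera, nail):
        # rotating the pose about the principal ray rotates contours alike
        from scipy.spatial.transform import Rotation
        pose = sample_pose(CameraModel(principal_point_px=(511.5, 511.5)),
                           nail, 12.0, np.random.default_rng(8))
        ang = 0.3
        Rz = Rotation.from_rotvec([0, 0, ang]).as_matrix()
        pose2 = Pose(Rz @ pose.rotation, Rz @ pose.translation_mm)
        lc1 = lens_contour(camera, nail, pose, 0, n_points=128)
        lc2 = lens_contour(camera, nail, pose2, 0, n_points=128)
        pp = np.array(camera.principal_point_px)
        f = camera.focal_px
        # rotate contour 1 about the principal point (pure perspective:
        # in-plane rotation about the optical axis rotates pixels exactly)
        R2 = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rotated = (lc1.points - pp) @ R2.T + pp
        d = cKDTree(lc2.points).query(rotated)[0]
        assert d.max() < 1e-3

    def test_aligned_limit_area_monotone(self, camera, nail):
        # lens area grows toward the full rim-disc area as obliquity -> 0
        areas = []
        for ob in (16.0, 10.0, 5.0, 2.0):
            pose = sample_pose(camera, nail, ob, np.random.default_rng(3))
            lc = lens_contour(camera, nail, pose, 0, n_points=256)
            x, y = lc.points[:, 0], lc.points[:, 1]
            area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
            areas.append(area)
        assert all(a2 > a1 for a1, a2 in zip(areas, areas[1:]))


class TestMakeFixture:
    def test_unknown_scenario(self):
        with pytest.raises(ValueError):
            make_fixture("no-such-scenario", 0)

    def test_deterministic(self):
        a = make_fixture("aligned", 3)
        b = make_fixture("aligned", 3)
        np.testing.assert_array_equal(a.image.pixels, b.image.pixels)

    def test_aligned_band(self):
        for seed in range(3):
            fb = make_fixture("aligned", seed)
            assert fb.image.obliquities_deg[0] < 2.0

    def test_mild_band(self):
        lo, hi = MILD_OBLIQUITY_BAND
        for seed in range(3):
            fb = make_fixture("mild-oblique", seed)
            assert lo <= fb.image.obliquities_deg[0] <= hi

    def test_steep_has_no_lens(self):
        fb = make_fixture("steep-oblique", 1)
        assert fb.image.ground_truth_contours[0] is None

    def test_shifted_pair_array_roll_oracle(self):
        fb = make_fixture("shifted-frame-pair", 2)
        du, dv = fb.frame_shift_px
        rolled = np.roll(fb.frames[0], (dv, du), axis=(0, 1))
        np.testing.assert_array_equal(fb.frames[1], rolled)

    def test_one_screw_scenario(self):
        fb = make_fixture("one-screw-inserted", 4)
        assert fb.image.screw_in_hole == (0,)

    def test_catalogue_complete(self):
        assert set(SCENARIOS) == {"aligned", "mild-oblique", "steep-oblique",
                                  "one-screw-inserted", "shifted-frame-pair"}
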