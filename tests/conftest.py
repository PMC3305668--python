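import numpy as np
import pytest

from nailguide.forward import make_fixture, render_radiograph, sample_pose
from nailguide.geometry import CameraModel
from nailguide.nail import NailSpec


@pytest.fixture(scope="session")
def camera():
    return CameraModel()


@pytest.fixture(scope="session")
def nail():
    return NailSpec.default("parallel")


@pytest.fixture(scope="session")
def small_camera():
    """Legacy-style camera with round numbers for hand calculations."""
    return CameraModel(sdd_mm=1000.0, pixel_pitch_mm=0.5,
                       principal_point_px=(512.0, 512.0),
                       image_size_px=(1024, 1024))


@pytest.fixture(scope="session")
def mild_pose(camera, nail):
    return sample_pose(camera, nail, 12.0, np.random.default_rng(42))


@pytest.fixture(scope="session")
def mild_image(camera, nail, mild_pose):
    return render_radiograph(camera, nail, mild_pose, noise_sigma=0.0, seed=0)


@pytest.fixture(scope="session")
def mild_fixture():
    return make_fixture("mild-oblique", seed=7)


def match_landmarks_to_holes(contours_or_lms, ground_truth_contours):
    """Pair detected objects with hole indices via ground-truth centroids."""
    out = [None] * len(ground_truth_contours)
    for obj in contours_or_lms:
        cen = obj.centroid if hasattr(obj, "centroid") else obj
        dists = [np.linalg.norm(np.asarray(cen) - g.centroid)
                 if g is not None else np.inf
                 for g in ground_truth_contours]
        out[int(np.argmin(dists))] = obj
    return out


def hole_errors(nail, true_pose, solved_pose, hole_index=0):
    """(axis error deg, center error mm) allowing the hole-label flip of a
    symmetric parallel pair."""
    from nailguide.pose import angle_between_deg

    best = None
    for mapping in ((0, 1), (1, 0)):
        i = mapping[hole_index]
        aerr = angle_between_deg(nail.hole_axis_cam(true_pose, hole_index),
                                 nail.hole_axis_cam(solved_pose, i),
                                 directed=False)
        cerr = float(np.linalg.norm(nail.hole_center_cam(true_pose, hole_index)
                                    - nail.hole_center_cam(solved_pose, i)))
        if not nail.is_parallel_layout:
            return aerr, cerr
        if best is None or cerr < best[1]:
            best = (aerr, cerr)
    return best


def solve_image(camera, nail, image, **kw):
    """detect -> landmarks -> solve, pairing holes via the ground truth."""
    import warnings as _w

    from nailguide.detect import detect_lens_regions, extract_landmarks
    from nailguide.solver import solve_pose

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        contours = detect_lens_regions(image.pixels)
    lms = [None, None]
    for c in contours:
        dists = [np.linalg.norm(c.centroid - g.centroid)
                 if g is not None else np.inf
                 for g in image.ground_truth_contours]
        i = int(np.argmin(dists))
        lms[i] = extract_landmarks(c)
        lms[i].hole_id = i
    return solve_pose(lms, camera, nail, **kw)
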