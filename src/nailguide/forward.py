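"""Synthetic radiograph forward model.

Renders cone-beam projections of a radio-opaque nail segment (outer
cylinder minus two transverse hole cylinders) by per-pixel ray casting, and
computes the analytic lens contour of each hole from the projected rim
circles.  The renderer is the exact oracle bounding the planar-rim
approximation used by the analytic path.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .contour import EmptyLensError, LensContour, lens_from_conics
from .geometry import CameraModel, project_circle, project_points
from .nail import NailSpec, hole_rim_circles
from .pose import Pose, angle_between_deg

SCENARIOS = (
    "aligned",
    "mild-oblique",
    "steep-oblique",
    "one-screw-inserted",
    "shifted-frame-pair",
)

#: documented ground-truth obliquity band of the "mild-oblique" scenario, deg
MILD_OBLIQUITY_BAND = (5.0, 20.0)

DEFAULT_MU = 0.4  # attenuation per mm of nail material


def beam_obliquity_deg(camera: CameraModel, nail: NailSpec, pose: Pose,
                       hole_index: int) -> float:
    """Angle between the central ray to the hole center and the hole axis."""
    c = nail.hole_center_cam(pose, hole_index)
    d = nail.hole_axis_cam(pose, hole_index)
    return angle_between_deg(c, d, directed=False)


def lens_contour(camera: CameraModel, nail: NailSpec, pose: Pose,
                 hole_index: int, n_points: int = 256,
                 circular_tol_deg: float = 1.0) -> LensContour:
    """Analytic lens contour of one hole under the given pose.

    Projects the hole's two rim circles and intersects the resulting
    ellipses.  Within ``circular_tol_deg`` of exact beam/axis alignment the
    contour is reported circular with no tips (the inner rim ellipse).
    """
    rims = hole_rim_circles(nail, pose, hole_index)
    e1, e2 = (project_circle(camera, r) for r in rims)
    force = beam_obliquity_deg(camera, nail, pose, hole_index) < circular_tol_deg
    return lens_from_conics(e1, e2, n_points=n_points, force_circular=force)


def hole_rim_conics(camera: CameraModel, nail: NailSpec, pose: Pose,
                    hole_index: int) -> tuple:
    """Projected rim conics of one hole, near rim first."""
    rims = hole_rim_circles(nail, pose, hole_index)
    return tuple(project_circle(camera, r) for r in rims)


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------

def _ray_cylinder_interval(dirs: np.ndarray, axis_point: np.ndarray,
                           axis_dir: np.ndarray, radius: float):
    """Entry/exit parameters of rays (origin 0, unit ``dirs``) with an
    infinite cylinder.  Returns ``(t0, t1, hit)``."""
    w = axis_dir
    d_perp = dirs - np.outer(dirs @ w, w)
    a_perp = axis_point - (axis_point @ w) * w
    A = np.einsum("ij,ij->i", d_perp, d_perp)
    B = -2.0 * d_perp @ a_perp
    C = a_perp @ a_perp - radius * radius
    disc = B * B - 4 * A * C
    hit = (disc > 0) & (A > 1e-14)
    sq = np.sqrt(np.where(hit, disc, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t0 = np.where(hit, (-B - sq) / (2 * A), 0.0)
        t1 = np.where(hit, (-B + sq) / (2 * A), 0.0)
    return t0, t1, hit


@dataclass
class SyntheticImage:
    """Rendered radiograph plus full ground truth."""

    pixels: np.ndarray
    ground_truth: Pose
    ground_truth_contours: list
    rng_seed: int | None
    camera: CameraModel
    nail: NailSpec
    obliquities_deg: tuple = ()
    screw_in_hole: tuple = ()

    def sidecar(self) -> dict:
        return {
            "pose": self.ground_truth.to_dict(),
            "contours": [c.to_dict() if c is not None else None
                         for c in self.ground_truth_contours],
            "seed": self.rng_seed,
            "obliquities_deg": [float(x) for x in self.obliquities_deg],
            "screw_in_hole": list(self.screw_in_hole),
        }


def _nail_bbox_px(camera: CameraModel, nail: NailSpec, pose: Pose, margin: int = 6):
    s0, s1 = (h.axial_station_mm for h in nail.holes)
    mid = 0.5 * (s0 + s1)
    L, R = nail.length_mm, nail.outer_radius_mm
    xs = [mid - L / 2, mid + L / 2]
    corners = np.array([[x, y, z] for x in xs for y in (-R, R) for z in (-R, R)])
    cam_pts = pose.apply(corners)
    if np.any(cam_pts[:, 2] <= 0):
        return None  # fall back to the full image
    px = project_points(camera, cam_pts)
    w, h = camera.image_size_px
    u0 = max(0, int(np.floor(px[:, 0].min())) - margin)
    u1 = min(w, int(np.ceil(px[:, 0].max())) + margin + 1)
    v0 = max(0, int(np.floor(px[:, 1].min())) - margin)
    v1 = min(h, int(np.ceil(px[:, 1].max())) + margin + 1)
    if u0 >= u1 or v0 >= v1:
        return (0, 0, 0, 0)
    return (u0, u1, v0, v1)


def render_radiograph(camera: CameraModel, nail: NailSpec, pose: Pose,
                      noise_sigma: float = 0.0, seed: int | None = None,
                      screw_in_hole: tuple = (), mu: float = DEFAULT_MU,
                      normalize: bool = False,
                      background_gradient: float = 0.0) -> SyntheticImage:
    """Ray-cast radiograph of the nail under ``pose``.

    Per-pixel material path length through the CSG solid (outer cylinder
    minus open hole cylinders; holes listed in ``screw_in_hole`` stay
    solid, emulating an inserted screw), mapped to intensity
    ``exp(-mu * pathlength)``, plus optional additive Gaussian noise and
    min-max normalization.  Deterministic given ``seed``.
    """
    w_px, h_px = camera.image_size_px
    img = np.ones((h_px, w_px), dtype=float)

    bbox = _nail_bbox_px(camera, nail, pose)
    if bbox is None:
        bbox = (0, w_px, 0, h_px)
    u0b, u1b, v0b, v1b = bbox
    if u1b > u0b and v1b > v0b:
        uu, vv = np.meshgrid(np.arange(u0b, u1b, dtype=float),
                             np.arange(v0b, v1b, dtype=float))
        pu, pv = camera.principal_point_px
        pitch = camera.pixel_pitch_mm
        dirs = np.column_stack([
            ((uu - pu) * pitch).ravel(),
            ((vv - pv) * pitch).ravel(),
            np.full(uu.size, camera.sdd_mm),
        ])
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]

        s_holes = [h.axial_station_mm for h in nail.holes]
        mid = 0.5 * (s_holes[0] + s_holes[1])
        axis_point = pose.apply(np.array([mid, 0.0, 0.0]))
        axis_dir = pose.apply_direction(np.array([1.0, 0.0, 0.0]))

        t0, t1, hit = _ray_cylinder_interval(dirs, axis_point, axis_dir,
                                             nail.outer_radius_mm)
        # clip by the axial extent of the segment: s(t) = (t d - a) . w
        sd = dirs @ axis_dir
        sa = axis_point @ axis_dir
        half = nail.length_mm / 2.0
        with np.errstate(divide="ignore", invalid="ignore"):
            ta = np.where(np.abs(sd) > 1e-14, (sa - half) / sd, -np.inf)
            tb = np.where(np.abs(sd) > 1e-14, (sa + half) / sd, np.inf)
        lo = np.minimum(ta, tb)
        hi = np.maximum(ta, tb)
        t0 = np.maximum(t0, lo)
        t1 = np.minimum(t1, hi)
        outer_len = np.where(hit, np.maximum(t1 - t0, 0.0), 0.0)

        path = outer_len.copy()
        for i, hole in enumerate(nail.holes):
            if i in tuple(screw_in_hole):
                continue
            hc = nail.hole_center_cam(pose, i)
            hd = nail.hole_axis_cam(pose, i)
            h0, h1, hhit = _ray_cylinder_interval(dirs, hc, hd, nail.hole_radius_mm)
            overlap = np.maximum(
                np.minimum(h1, t1) - np.maximum(h0, t0), 0.0)
            path -= np.where(hhit & hit, overlap, 0.0)

        sub = np.exp(-mu * np.maximum(path, 0.0)).reshape(uu.shape)
        img[v0b:v1b, u0b:u1b] = sub

    if background_gradient != 0.0:
        gx = np.linspace(0.0, 1.0, w_px)[None, :]
        gy = np.linspace(0.0, 1.0, h_px)[:, None]
        img = img * (1.0 - background_gradient * 0.5 * (gx + gy))

    # noise is added unclipped so that background statistics stay Gaussian;
    # clipping to [0, 1] happens at quantization (image writing) time
    rng = np.random.default_rng(seed)
    if noise_sigma > 0:
        img = img + rng.normal(0.0, noise_sigma, size=img.shape)
    if normalize:
        lo, hi = img.min(), img.max()
        if hi > lo:
            img = (img - lo) / (hi - lo)

    contours = []
    obliq = []
    for i in range(2):
        obliq.append(beam_obliquity_deg(camera, nail, pose, i))
        try:
            contours.append(lens_contour(camera, nail, pose, i))
        except EmptyLensError:
            contours.append(None)
    return SyntheticImage(pixels=img, ground_truth=pose,
                          ground_truth_contours=contours, rng_seed=seed,
                          camera=camera, nail=nail,
                          obliquities_deg=tuple(obliq),
                          screw_in_hole=tuple(screw_in_hole))


# ---------------------------------------------------------------------------
# exact silhouette (CSG through-ray boundary)
# ---------------------------------------------------------------------------

def _through_metric(camera: CameraModel, nail: NailSpec, pose: Pose,
                    hole_index: int, px: np.ndarray) -> np.ndarray:
    """Signed through-hole metric for pixels ``(n, 2)``.

    A ray passes the open hole iff both of its crossing points with the
    outer cylinder lie within ``r_h`` of the hole axis (interval
    containment in a convex cylinder).  Returns ``max(d_in, d_out) - r_h``
    (negative = through); rays missing the outer cylinder get +inf.
    """
    pu, pv = camera.principal_point_px
    pitch = camera.pixel_pitch_mm
    dirs = np.column_stack([
        (px[:, 0] - pu) * pitch,
        (px[:, 1] - pv) * pitch,
        np.full(len(px), camera.sdd_mm),
    ])
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    s_holes = [h.axial_station_mm for h in nail.holes]
    mid = 0.5 * (s_holes[0] + s_holes[1])
    axis_point = pose.apply(np.array([mid, 0.0, 0.0]))
    axis_dir = pose.apply_direction(np.array([1.0, 0.0, 0.0]))
    t0, t1, hit = _ray_cylinder_interval(dirs, axis_point, axis_dir,
                                         nail.outer_radius_mm)
    hc = nail.hole_center_cam(pose, hole_index)
    hd = nail.hole_axis_cam(pose, hole_index)
    out = np.full(len(px), np.inf)
    for t in (t0, t1):
        p = dirs * t[:, None]
        rel = p - hc
        perp = rel - np.outer(rel @ hd, hd)
        d = np.linalg.norm(perp, axis=1)
        out = np.where(hit, np.maximum(np.where(np.isinf(out), -np.inf, out), d),
                       np.inf)
    return out - nail.hole_radius_mm


def exact_lens_contour(camera: CameraModel, nail: NailSpec, pose: Pose,
                       hole_index: int, n_azimuth: int = 48,
                       tol_px: float = 1e-9) -> np.ndarray:
    """Exact through-ray silhouette of one hole as a closed polyline.

    Boundary points are found by radial bisection from the projected hole
    center along ``n_azimuth`` directions against the CSG through-ray
    test; this is the renderer's geometry without pixel discretization.
    Raises :class:`EmptyLensError` when no rays pass.
    """
    c_px = project_points(camera, nail.hole_center_cam(pose, hole_index)[None, :])[0]
    center = np.asarray(c_px, dtype=float)
    if _through_metric(camera, nail, pose, hole_index, center[None, :])[0] >= 0:
        # fall back: search a small neighbourhood for an interior point
        g = np.linspace(-6, 6, 13)
        cand = np.column_stack([center[0] + np.repeat(g, 13),
                                center[1] + np.tile(g, 13)])
        m = _through_metric(camera, nail, pose, hole_index, cand)
        if m.min() >= 0:
            raise EmptyLensError("no through-hole rays (obliquity beyond grazing)")
        center = cand[int(np.argmin(m))]
    ang = np.linspace(0.0, 2 * np.pi, n_azimuth, endpoint=False)
    dirs = np.column_stack([np.cos(ang), np.sin(ang)])
    lo = np.zeros(n_azimuth)
    hi = np.full(n_azimuth, 3.0)
    # expand brackets until outside
    for _ in range(10):
        pts = center[None, :] + dirs * hi[:, None]
        inside = _through_metric(camera, nail, pose, hole_index, pts) < 0
        if not inside.any():
            break
        lo = np.where(inside, hi, lo)
        hi = np.where(inside, hi * 2.0, hi)
    for _ in range(50):
        if np.max(hi - lo) < tol_px:
            break
        mid = 0.5 * (lo + hi)
        pts = center[None, :] + dirs * mid[:, None]
        inside = _through_metric(camera, nail, pose, hole_index, pts) < 0
        lo = np.where(inside, mid, lo)
        hi = np.where(inside, mid, hi)
    r = 0.5 * (lo + hi)
    return center[None, :] + dirs * r[:, None]


# ---------------------------------------------------------------------------
# pose sampling and the fixture catalogue
# ---------------------------------------------------------------------------

def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    from scipy.spatial.transform import Rotation
    axis = axis / np.linalg.norm(axis)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def sample_pose(camera: CameraModel, nail: NailSpec, obliquity_deg: float,
                rng: np.random.Generator, roll_deg_range: float = 15.0) -> Pose:
    """Random pose with the requested beam obliquity at hole 0.

    The hole-0 center is sampled in a box in front of the source; the hole
    axis is tilted off the central ray by ``obliquity_deg`` about a random
    transverse direction; the nail axis is rolled randomly about the hole
    axis while staying roughly transverse to the beam.
    """
    c0 = np.array([
        rng.uniform(-35.0, 35.0),
        rng.uniform(-35.0, 35.0),
        rng.uniform(650.0, 780.0),
    ])
    b = c0 / np.linalg.norm(c0)
    # transverse tilt axis
    from .geometry import plane_basis
    q1, q2 = plane_basis(b)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    tilt_axis = np.cos(phi) * q1 + np.sin(phi) * q2
    d = _rotation_about(tilt_axis, np.radians(obliquity_deg)) @ (-b)
    # nail axis: perpendicular to d, near-transverse to the beam
    a0 = np.cross(d, b)
    if np.linalg.norm(a0) < 1e-6:
        a0 = plane_basis(d)[0]
    a0 /= np.linalg.norm(a0)
    psi = np.radians(rng.uniform(-roll_deg_range, roll_deg_range))
    a = _rotation_about(d, psi) @ a0
    R = np.column_stack([a, np.cross(d, a), d])
    t = c0 - R @ nail.hole_center_nail(0)
    return Pose(R, t)


@dataclass
class FixtureBundle:
    """Reproducible synthetic scenario with full ground truth."""

    scenario: str
    seed: int
    image: SyntheticImage
    camera: CameraModel
    nail: NailSpec
    frames: list = field(default_factory=list)
    frame_shift_px: tuple | None = None

    def configs(self) -> dict:
        d = {
            "scenario": self.scenario,
            "seed": self.seed,
            "camera": self.camera.to_dict(),
            "nail": self.nail.to_dict(),
        }
        if self.frame_shift_px is not None:
            d["frame_shift_px"] = list(self.frame_shift_px)
        return d


def make_fixture(scenario_id: str, seed: int, camera: CameraModel | None = None,
                 nail: NailSpec | None = None,
                 noise_sigma: float | None = None) -> FixtureBundle:
    """Generate a catalogue scenario; bit-identical for equal arguments.

    Scenarios: ``aligned`` (obliquity < 2 deg), ``mild-oblique`` (band
    ``MILD_OBLIQUITY_BAND``), ``steep-oblique`` (beyond grazing; no lens),
    ``one-screw-inserted`` (mild obliquity, hole 0 occluded),
    ``shifted-frame-pair`` (noise-free frame plus an integer-shifted copy).
    """
    if scenario_id not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_id!r}; known: {SCENARIOS}")
    camera = camera or CameraModel()
    nail = nail or NailSpec.default("parallel")
    scen_key = zlib.crc32(scenario_id.encode()) & 0xFFFF
    rng = np.random.default_rng(np.random.SeedSequence([scen_key, seed]))

    if scenario_id == "aligned":
        obliquity = rng.uniform(0.3, 1.5)
    elif scenario_id == "steep-oblique":
        obliquity = rng.uniform(45.0, 60.0)
    else:
        obliquity = rng.uniform(*MILD_OBLIQUITY_BAND)
    pose = sample_pose(camera, nail, obliquity, rng)

    screws = (0,) if scenario_id == "one-screw-inserted" else ()
    if noise_sigma is None:
        noise_sigma = 0.0 if scenario_id == "shifted-frame-pair" else 0.01
    image = render_radiograph(camera, nail, pose, noise_sigma=noise_sigma,
                              seed=seed, screw_in_hole=screws)

    frames = [image.pixels]
    shift = None
    if scenario_id == "shifted-frame-pair":
        du, dv = int(rng.integers(-12, 13)), int(rng.integers(-12, 13))
        shift = (du, dv)
        frames.append(np.roll(image.pixels, (dv, du), axis=(0, 1)))
    return FixtureBundle(scenario=scenario_id, seed=seed, image=image,
                         camera=camera, nail=nail, frames=frames,
                         frame_shift_px=shift)
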