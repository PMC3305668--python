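"""Single-view 6-DOF pose recovery from the landmark sets of both holes.

The solver minimizes squared pixel distances between detected landmarks
and virtual landmarks (generated by projecting the rim circles of a trial
pose and applying the same extraction rules) over the six pose parameters,
starting from closed-form candidates and polishing every mirror-ambiguity
combination with damped least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contour import (EmptyLensError, LandmarkSet, landmarks_from_conic_pair,
                      landmarks_from_polyline, lens_from_conics)
from .geometry import CameraModel, Circle3D, Conic2D, project_circle
from .nail import NailSpec, hole_rim_circles
from .pose import Pose, angle_between_deg


class NonConvergenceError(RuntimeError):
    """No candidate pose converged; diagnostics attached."""

    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics or {}


class UnderConstrainedError(ValueError):
    """A single hole cannot pin all 6 DOF; the free direction is reported."""

    def __init__(self, msg, free_axis=None):
        super().__init__(msg)
        self.free_axis = free_axis


# ---------------------------------------------------------------------------
# closed-form circle pose (single-view, known radius)
# ---------------------------------------------------------------------------

def circle_pose_from_conic(conic: Conic2D, camera: CameraModel,
                           radius_mm: float) -> list:
    """Both 3D interpretations of an ellipse as the image of a circle of
    known radius.

    The cone of rays through the conic, ``Q = K^T C K``, is diagonalized;
    the classical two-fold ambiguity yields two (center, normal) pairs.
    Sign conventions are resolved by requiring positive depth and a normal
    facing the source; candidates are verified by reprojection.
    """
    K = camera.intrinsic_matrix()
    Q = K.T @ conic.matrix() @ K
    w, V = np.linalg.eigh(Q)
    if np.sum(w > 0) == 1:
        Q = -Q
        w, V = np.linalg.eigh(Q)
    order = np.argsort(w)[::-1]
    w = w[order]
    V = V[:, order]
    l1, l2, l3 = w
    if not (l1 >= l2 > 0 > l3):
        return []
    g = np.sqrt((l1 - l2) / (l1 - l3))
    h = np.sqrt((l2 - l3) / (l1 - l3))
    e1, e3 = V[:, 0], V[:, 2]
    z0 = l2 * radius_mm / np.sqrt(-l1 * l3)
    out = []
    for s1 in (1.0, -1.0):
        for s2 in (1.0, -1.0):
            for s3 in (1.0, -1.0):
                c = s3 * z0 * (s1 * (l3 / l2) * g * e1 + s2 * (l1 / l2) * h * e3)
                if c[2] <= 0:
                    continue
                n = s1 * g * e1 + s2 * h * e3
                n = n / np.linalg.norm(n)
                if n @ c > 0:
                    n = -n
                try:
                    rep = project_circle(camera, Circle3D(c, n, radius_mm))
                except Exception:
                    continue
                d = min(np.linalg.norm(rep.coefficients - conic.coefficients),
                        np.linalg.norm(rep.coefficients + conic.coefficients))
                if d < 1e-6:
                    if not any(np.linalg.norm(c - cc) < 1e-6 for cc, _ in out):
                        out.append((c, n))
    return out


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

@dataclass
class HolePoseCandidate:
    """Per-hole (center, axis) hypothesis; ``branch`` tags the mirror sign."""

    center_mm: np.ndarray
    axis: np.ndarray
    branch: int
    hole_index: int

    def as_pose(self, nail: NailSpec, roll_reference: np.ndarray | None = None) -> Pose:
        """Full pose with the nail axis chosen perpendicular to the hole
        axis (roll about the hole axis is unobservable from one hole)."""
        d = nail.holes[self.hole_index].axis_dir_nail_frame
        from .geometry import plane_basis
        a_img = roll_reference if roll_reference is not None else plane_basis(self.axis)[0]
        a_img = a_img - (a_img @ self.axis) * self.axis
        a_img /= np.linalg.norm(a_img)
        # build rotation mapping the nail frame onto (a_img, axis)
        a_nail = np.array([1.0, 0.0, 0.0])
        y_nail = np.cross(d, a_nail)
        R = np.column_stack([a_img, np.cross(self.axis, a_img), self.axis]) @ \
            np.column_stack([a_nail, y_nail, d]).T
        t = self.center_mm - R @ nail.hole_center_nail(self.hole_index)
        return Pose(R, t)


def _ray_direction(camera: CameraModel, p_px: np.ndarray) -> np.ndarray:
    u0, v0 = camera.principal_point_px
    d = np.array([(p_px[0] - u0), (p_px[1] - v0), camera.focal_px])
    return d / np.linalg.norm(d)


def initial_pose_candidates(landmarks: LandmarkSet, camera: CameraModel,
                            nail: NailSpec, hole_index: int) -> list:
    """Closed-form hole pose hypotheses from one landmark set.

    Oblique case: depth from the tip-to-tip chord length (the projected
    rim diameter), the center ray from the chord midpoint, and the
    obliquity from the lens half-width via
    ``cos(t) - (h/r) sin(t) = width/rim_radius``; the tilt sign is the
    two-fold mirror ambiguity.  Aligned (circular) case: axis along the
    ray through the circle center, depth from the apparent radius.
    """
    r_h = nail.hole_radius_mm
    f = camera.focal_px
    if landmarks.is_circular:
        ray = _ray_direction(camera, landmarks.circle_center)
        z = r_h * f / landmarks.circle_radius_px
        center = ray * z / ray[2]
        return [HolePoseCandidate(center, -ray, 0, hole_index)]

    tips = landmarks.tips
    chord = tips[1] - tips[0]
    L = float(np.linalg.norm(chord))
    if L < 1e-9:
        raise ValueError("degenerate landmark chord")
    mid = 0.5 * (tips[0] + tips[1])
    ray = _ray_direction(camera, mid)

    # joint magnification/obliquity solve (weak-perspective lens model):
    #   half-chord   L/2 = m * sqrt(r^2 - h^2 sin^2 t)   (tips of the lune)
    #   half-width   w   = m * (r cos t - h sin t)       (apex offset)
    u = chord / L
    nvec = np.array([-u[1], u[0]])
    w_px = float(np.mean(np.abs((landmarks.apexes - tips[0]) @ nvec)))
    h_off = nail.rim_offset_mm

    def width_mismatch(t):
        core = r_h * r_h - h_off * h_off * np.sin(t) ** 2
        if core <= 0:
            return -w_px
        m = (L / 2.0) / np.sqrt(core)
        return m * (r_h * np.cos(t) - h_off * np.sin(t)) - w_px

    from scipy.optimize import brentq
    t_max = np.arctan(r_h / h_off)  # grazing limit: lens width -> 0
    f_lo = width_mismatch(1e-6)
    f_hi = width_mismatch(t_max - 1e-6)
    if f_lo * f_hi > 0:
        theta = 1e-3 if abs(f_lo) < abs(f_hi) else t_max - 1e-3
    else:
        theta = brentq(width_mismatch, 1e-6, t_max - 1e-6, xtol=1e-12)
    m = (L / 2.0) / np.sqrt(r_h * r_h - h_off * h_off * np.sin(theta) ** 2)
    z = f / m
    center = ray * z / ray[2]

    # chord direction in 3D (transverse to the beam), tilt about it
    chord3 = np.array([u[0], u[1], 0.0])
    chord3 -= (chord3 @ ray) * ray
    chord3 /= np.linalg.norm(chord3)
    from scipy.spatial.transform import Rotation
    out = []
    for branch, sgn in enumerate((+1.0, -1.0)):
        Rt = Rotation.from_rotvec(sgn * theta * chord3).as_matrix()
        axis = Rt @ (-ray)
        out.append(HolePoseCandidate(center, axis, branch, hole_index))

    # supplementary hypotheses: closed-form circle pose of the fitted arc
    # conics (exact when the landmarks come from the analytic model); each
    # rim center maps to the hole center at +/- h_off along the axis
    if landmarks.arc_conics is not None:
        branch = 2
        h = nail.rim_offset_mm
        for conic in landmarks.arc_conics:
            if conic is None or not conic.is_ellipse:
                continue
            for c_mm, n in circle_pose_from_conic(conic, camera, r_h):
                for s in (+1.0, -1.0):
                    out.append(HolePoseCandidate(c_mm - s * h * n, n,
                                                 branch, hole_index))
                    branch += 1
    return out


# ---------------------------------------------------------------------------
# virtual landmarks and residuals
# ---------------------------------------------------------------------------

def virtual_landmarks(camera: CameraModel, nail: NailSpec, pose: Pose,
                      hole_index: int, circular: bool = False,
                      mode: str = "conic") -> LandmarkSet:
    """Landmark set of the forward model for a trial pose.

    ``mode="conic"`` (default) applies the extraction rules to the
    planar-rim conic pair; it tracks the *detectable* lens boundary well,
    because the intensity ramp outside the geometric silhouette is too
    shallow near the tips for any detector to follow.  ``mode="exact"``
    extracts landmarks from the exact CSG through-ray silhouette with the
    same polyline rules the detector uses.
    """
    if mode == "exact":
        from .forward import exact_lens_contour
        pts = exact_lens_contour(camera, nail, pose, hole_index)
        if circular:
            center = pts.mean(axis=0)
            radius = float(np.mean(np.linalg.norm(pts - center, axis=1)))
            return LandmarkSet(is_circular=True, circle_center=center,
                               circle_radius_px=radius, hole_id=hole_index)
        return landmarks_from_polyline(pts, hole_id=hole_index)
    rims = hole_rim_circles(nail, pose, hole_index)
    e1, e2 = (project_circle(camera, r) for r in rims)
    if circular:
        lens = lens_from_conics(e1, e2, n_points=64, force_circular=True)
        pts = lens.points
        center = pts.mean(axis=0)
        radius = float(np.mean(np.linalg.norm(pts - center, axis=1)))
        return LandmarkSet(is_circular=True, circle_center=center,
                           circle_radius_px=radius, hole_id=hole_index)
    return landmarks_from_conic_pair(e1, e2, hole_id=hole_index)


def _match_vectors(detected: LandmarkSet, virtual: LandmarkSet) -> np.ndarray:
    """Residual contribution of one hole (virtual matched onto detected).

    Tips are matched by proximity; arc roles follow the chord-side
    convention, which both canonical forms share once tip order agrees.
    """
    if detected.is_circular != virtual.is_circular:
        # model/detection disagreement about degeneracy: compare centers
        dc = detected.circle_center if detected.is_circular else detected.all_points().mean(axis=0)
        vc = virtual.circle_center if virtual.is_circular else virtual.all_points().mean(axis=0)
        gap = np.linalg.norm(dc - vc) + 25.0  # constant penalty
        return np.full(3 if detected.is_circular else 16, gap / 4.0)
    if detected.is_circular:
        return detected.as_vector() - virtual.as_vector()
    v = virtual
    if (np.linalg.norm(detected.tips[0] - v.tips[0])
            > np.linalg.norm(detected.tips[0] - v.tips[1])):
        v = v.with_swapped_tips()
    return detected.as_vector() - v.as_vector()


def make_residual_fn(landmarks_both, camera: CameraModel, nail: NailSpec,
                     mode: str = "exact"):
    """Residual function mapping a trial pose to the stacked landmark
    mismatch of both holes."""
    sizes = [3 if (lm is not None and lm.is_circular) else 16
             for lm in landmarks_both]
    n_res = sum(s for lm, s in zip(landmarks_both, sizes) if lm is not None)

    def overlap_penalty(pose: Pose, i: int) -> float:
        """Differentiable stand-in when the trial pose shows no lens:
        grows with the separation of the projected rim ellipses relative
        to their size, pulling the optimizer back toward lens-producing
        poses."""
        try:
            e1, e2 = (project_circle(camera, c)
                      for c in hole_rim_circles(nail, pose, i))
            # smallest algebraic value of e2 over e1's points: positive
            # and growing as the ellipses separate
            pts = e1.ellipse_points(48)
            v = np.atleast_1d(e2.evaluate(pts))
            scale = np.maximum(1.0, np.sum(pts * pts, axis=1))
            gap = float(np.min(v / scale))
            return 50.0 + 1e4 * max(gap, 0.0)
        except Exception:
            return 200.0

    def residuals(pose: Pose) -> np.ndarray:
        out = []
        for i, lm in enumerate(landmarks_both):
            if lm is None:
                continue
            try:
                v = virtual_landmarks(camera, nail, pose, i,
                                      circular=lm.is_circular, mode=mode)
                out.append(_match_vectors(lm, v))
            except (EmptyLensError, ValueError, np.linalg.LinAlgError):
                out.append(np.full(sizes[i], overlap_penalty(pose, i)))
        return np.concatenate(out) if out else np.zeros(n_res)

    return residuals


# ---------------------------------------------------------------------------
# damped least squares
# ---------------------------------------------------------------------------

def _numeric_jacobian(fun, pose: Pose, r0: np.ndarray,
                      eps_rot: float = 1e-6, eps_t: float = 1e-4) -> np.ndarray:
    J = np.empty((len(r0), 6))
    for j in range(6):
        dx = np.zeros(6)
        eps = eps_rot if j < 3 else eps_t
        dx[j] = eps
        p = pose.perturbed(dx[:3], dx[3:])
        J[:, j] = (fun(p) - r0) / eps
    return J


@dataclass
class LMResult:
    pose: Pose
    residuals: np.ndarray
    rms: float
    converged: bool
    iterations: int
    gradient_norm: float
    rms_history: list = field(default_factory=list)
    cov_diag: np.ndarray | None = None


def _levenberg_marquardt(fun, pose0: Pose, max_iter: int = 200,
                         gtol: float = 1e-10, xtol: float = 1e-12) -> LMResult:
    """Damped least squares on the pose manifold.

    Steps are axis-angle/translation increments composed onto the current
    pose; only cost-decreasing steps are accepted, so the recorded RMS
    history is non-increasing.
    """
    pose = pose0
    r = fun(pose)
    cost = 0.5 * float(r @ r)
    rms = float(np.sqrt(np.mean(r * r)))
    history = [rms]
    lam = 1e-3
    converged = False
    gnorm = np.inf
    it = 0
    J = None
    for it in range(1, max_iter + 1):
        J = _numeric_jacobian(fun, pose, r)
        g = J.T @ r
        gnorm = float(np.abs(g).max())
        if gnorm < gtol:
            converged = True
            break
        H = J.T @ J
        accepted = False
        for _ in range(25):
            try:
                step = np.linalg.solve(H + lam * np.diag(np.maximum(np.diag(H), 1e-12)),
                                       -g)
            except np.linalg.LinAlgError:
                lam *= 10.0
                continue
            if np.linalg.norm(step) < xtol:
                converged = True
                accepted = True
                break
            p_new = pose.perturbed(step[:3], step[3:])
            r_new = fun(p_new)
            cost_new = 0.5 * float(r_new @ r_new)
            if cost_new < cost:
                pose, r, cost = p_new, r_new, cost_new
                rms = float(np.sqrt(np.mean(r * r)))
                history.append(rms)
                lam = max(lam / 3.0, 1e-12)
                accepted = True
                break
            lam *= 4.0
            if lam > 1e14:
                break
        if converged:
            break
        if not accepted:
            break  # stuck: no decreasing step found
    cov = None
    if J is not None:
        H = J.T @ J
        try:
            cov = np.diag(np.linalg.inv(H + 1e-12 * np.eye(6)))
        except np.linalg.LinAlgError:
            cov = None
    return LMResult(pose=pose, residuals=r, rms=rms, converged=converged,
                    iterations=it, gradient_norm=gnorm, rms_history=history,
                    cov_diag=cov)


# ---------------------------------------------------------------------------
# full solve
# ---------------------------------------------------------------------------

@dataclass
class PoseSolution:
    """Solved pose with residual diagnostics and ambiguity bookkeeping."""

    pose: Pose
    rms_residual_px: float
    per_landmark_residuals_px: np.ndarray
    candidate_branch_id: int
    converged: bool
    iterations: int
    covariance_diag: np.ndarray | None
    rms_history: list = field(default_factory=list)
    entry_sides: tuple = (1.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "pose": self.pose.to_dict(),
            "rms_residual_px": float(self.rms_residual_px),
            "per_landmark_residuals_px": [float(x) for x in self.per_landmark_residuals_px],
            "branch": int(self.candidate_branch_id),
            "converged": bool(self.converged),
            "iterations": int(self.iterations),
            "covariance_diag": (None if self.covariance_diag is None
                                else [float(x) for x in self.covariance_diag]),
        }


def _dedupe_candidates(cands, angle_deg: float = 2.0, dist_mm: float = 2.0) -> list:
    out = []
    for c in cands:
        if any(angle_between_deg(c.axis, o.axis) < angle_deg
               and np.linalg.norm(c.center_mm - o.center_mm) < dist_mm
               for o in out):
            continue
        out.append(c)
    return out


def _combine_candidates(cands0, cands1, nail: NailSpec) -> list:
    """Assemble full-pose initializations from per-hole hypotheses.

    Per-hole depth estimates are far noisier than transverse positions,
    and the holes sit only one station spacing apart, so the raw center
    difference is a poor nail-axis direction.  Because the hole axis
    points roughly along the beam, projecting the center difference
    perpendicular to the (accurately estimated) hole axis suppresses the
    depth-noise component.
    """
    s0 = nail.holes[0].axial_station_mm
    s1 = nail.holes[1].axial_station_mm
    d0_nail = nail.holes[0].axis_dir_nail_frame
    out = []
    branch_id = 0
    for cA in _dedupe_candidates(cands0):
        for cB in _dedupe_candidates(cands1):
            c0 = cA.center_mm
            c1 = cB.center_mm
            d = 0.5 * (cA.axis + cB.axis) if nail.is_parallel_layout else cA.axis
            nd = np.linalg.norm(d)
            if nd < 1e-6:
                branch_id += 1
                continue
            d = d / nd
            delta = c1 - c0
            a = delta - (delta @ d) * d
            norm = np.linalg.norm(a)
            if norm < 1e-6:
                branch_id += 1
                continue
            a = a / norm * np.sign(s1 - s0)
            a_nail = np.array([1.0, 0.0, 0.0])
            y_nail = np.cross(d0_nail, a_nail)
            R = np.column_stack([a, np.cross(d, a), d]) @ \
                np.column_stack([a_nail, y_nail, d0_nail]).T
            try:
                pose = Pose(R, np.zeros(3))
            except ValueError:
                branch_id += 1
                continue
            t = 0.5 * ((c0 - R @ nail.hole_center_nail(0))
                       + (c1 - R @ nail.hole_center_nail(1)))
            out.append((branch_id, Pose(R, t)))
            branch_id += 1
    return out


def solve_pose(landmarks_both, camera: CameraModel, nail: NailSpec,
               init_candidates: list | None = None,
               prepass_iterations: int = 8, refine_top: int = 2,
               virtual_mode: str = "conic") -> PoseSolution:
    """Recover the nail pose from the landmark sets of both holes.

    All mirror-ambiguity combinations are polished with a short damped
    least-squares pre-pass; the best few are fully refined and the
    lowest-residual converged solution wins.  With only one landmark set
    and a parallel hole layout an :class:`UnderConstrainedError` is raised
    naming the free rotation direction.
    """
    lms = list(landmarks_both)
    if len(lms) != 2:
        raise ValueError("landmark sets for both holes are required")
    present = [lm is not None for lm in lms]
    if sum(present) == 0:
        raise ValueError("no landmarks provided")
    if sum(present) == 1:
        i = present.index(True)
        cands = initial_pose_candidates(lms[i], camera, nail, i)
        raise UnderConstrainedError(
            "only one hole visible: rotation about its axis is unobservable",
            free_axis=cands[0].axis if cands else None)

    cands0 = initial_pose_candidates(lms[0], camera, nail, 0)
    cands1 = initial_pose_candidates(lms[1], camera, nail, 1)
    if init_candidates is None:
        init_list = _combine_candidates(cands0, cands1, nail)
    else:
        init_list = list(enumerate(init_candidates))
    if not init_list:
        raise NonConvergenceError("no valid initial candidates")

    fun_fast = make_residual_fn(lms, camera, nail, mode="conic")
    fun = make_residual_fn(lms, camera, nail, mode=virtual_mode)

    # cheap screen: one residual evaluation per combination, dropping
    # near-duplicate poses, then a short pre-pass on the most promising
    screened = []
    for bid, pose in init_list:
        dup = False
        for _, p2, _ in screened:
            if (angle_between_deg(pose.rotation[:, 2], p2.rotation[:, 2]) < 1.0
                    and np.linalg.norm(pose.translation_mm - p2.translation_mm) < 1.0):
                dup = True
                break
        if dup:
            continue
        r = fun_fast(pose)
        screened.append((bid, pose, float(np.sqrt(np.mean(r * r)))))
    screened.sort(key=lambda t: t[2])

    pre = []
    for bid, pose, _ in screened[:6]:
        res = _levenberg_marquardt(fun_fast, pose, max_iter=prepass_iterations)
        pre.append((bid, res))
    pre.sort(key=lambda t: t[1].rms)

    best = None
    n_refined = 0
    for k, (bid, warm) in enumerate(pre):
        have_good = best is not None and best[1].converged and best[1].rms < 45.0
        limit = max(1, refine_top)
        if have_good and best[1].rms > 0.25:
            limit = max(limit, 4)  # ambiguous fit: examine more branches
        if n_refined >= limit and have_good:
            break
        res = _levenberg_marquardt(fun, warm.pose, max_iter=80)
        n_refined += 1
        valid = res.rms < 45.0  # the no-lens penalty floor is 50
        best_valid = best is not None and best[1].rms < 45.0
        if best is None or (valid and not best_valid) or \
                (valid == best_valid and
                 ((res.converged and not best[1].converged)
                  or (res.converged == best[1].converged and res.rms < best[1].rms))):
            best = (bid, res)
        if res.converged and res.rms < 1e-6:
            break  # exact fit found; no other branch can do better
        # a clearly separated winner: remaining branches start much worse
        if res.converged and res.rms < 0.25 and k + 1 < len(pre) \
                and pre[k + 1][1].rms > 3.0 * res.rms:
            break
    bid, res = best
    if res.rms >= 45.0:
        raise NonConvergenceError(
            "all candidates stranded outside the lens-producing pose region",
            diagnostics={"rms": res.rms, "iterations": res.iterations})
    bid, res = best
    if not res.converged:
        raise NonConvergenceError(
            f"no converged candidate (best rms {res.rms:.3g} px)",
            diagnostics={"rms": res.rms, "iterations": res.iterations,
                         "gradient_norm": res.gradient_norm})

    r = res.residuals.reshape(-1)
    # per-landmark euclidean residuals (pairs of u, v; circular fits give
    # center + radius and are reported per component)
    per_lm = []
    idx = 0
    for lm in lms:
        if lm is None:
            continue
        if lm.is_circular:
            per_lm.extend(np.abs(r[idx:idx + 3]))
            idx += 3
        else:
            block = r[idx:idx + 16].reshape(8, 2)
            per_lm.extend(np.linalg.norm(block, axis=1))
            idx += 16
    # drill entry side per hole: the axis end nearer the source
    sides = []
    for i in range(2):
        c = nail.hole_center_cam(res.pose, i)
        d = nail.hole_axis_cam(res.pose, i)
        sides.append(1.0 if d @ c < 0 else -1.0)
    return PoseSolution(pose=res.pose, rms_residual_px=res.rms,
                        per_landmark_residuals_px=np.asarray(per_lm),
                        candidate_branch_id=bid, converged=res.converged,
                        iterations=res.iterations,
                        covariance_diag=res.cov_diag,
                        rms_history=res.rms_history,
                        entry_sides=tuple(sides))


def simulate_second_hole(prior: PoseSolution, camera: CameraModel,
                         nail: NailSpec, hole_index: int,
                         frame_shift_px: tuple = (0.0, 0.0)) -> LandmarkSet:
    """Virtual landmarks of a not-yet-drilled hole from a prior solution,
    optionally translated by an estimated inter-frame shift."""
    if not prior.converged:
        raise ValueError("prior solution did not converge")
    lm = virtual_landmarks(camera, nail, prior.pose, hole_index)
    du, dv = frame_shift_px
    if du == 0.0 and dv == 0.0:
        return lm
    d = np.array([du, dv])
    if lm.is_circular:
        return LandmarkSet(is_circular=True, circle_center=lm.circle_center + d,
                           circle_radius_px=lm.circle_radius_px,
                           hole_id=lm.hole_id)
    return LandmarkSet(
        is_circular=False,
        tips=lm.tips + d,
        apexes=lm.apexes + d,
        quarters=lm.quarters + d,
        arc_conics=tuple(c.translated(d) if c is not None else None
                         for c in lm.arc_conics),
        hole_id=lm.hole_id,
    )
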