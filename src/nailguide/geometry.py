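"""Cone-beam projective geometry primitives.

Conventions
-----------
Right-handed camera frame with the X-ray point source at the origin and the
detector plane at ``z = SDD`` (source-to-detector distance).  Pixel
coordinates are 0-based with the origin in the top-left corner, ``u``
pointing right and ``v`` pointing down.  Lengths are in millimetres, angles
in radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateProjectionError(ValueError):
    """A point or circle cannot be projected (non-positive depth)."""


class CoincidentConicsError(ValueError):
    """Two conics are numerically identical (the aligned case)."""


class NotAnEllipseError(ValueError):
    """A conic was expected to be a real ellipse but is not."""


@dataclass(frozen=True)
class CameraModel:
    """Ideal pinhole cone-beam camera (no distortion).

    Parameters
    ----------
    sdd_mm : float
        Source-to-detector distance.
    pixel_pitch_mm : float
        Detector pixel size.
    principal_point_px : tuple of float
        Intersection of the principal ray with the detector, ``(u, v)``.
    image_size_px : tuple of int
        Detector size ``(width, height)``.
    """

    sdd_mm: float = 1000.0
    pixel_pitch_mm: float = 0.3
    principal_point_px: tuple = (511.5, 511.5)
    image_size_px: tuple = (1024, 1024)

    def __post_init__(self):
        if not self.sdd_mm > 0:
            raise ValueError("sdd_mm must be positive")
        if not self.pixel_pitch_mm > 0:
            raise ValueError("pixel_pitch_mm must be positive")
        u0, v0 = self.principal_point_px
        w, h = self.image_size_px
        if not (0 <= u0 < w and 0 <= v0 < h):
            raise ValueError("principal point must lie inside the image")

    @property
    def focal_px(self) -> float:
        """Focal length expressed in pixels, ``SDD / pitch``."""
        return self.sdd_mm / self.pixel_pitch_mm

    def intrinsic_matrix(self) -> np.ndarray:
        """3x3 matrix mapping camera-frame directions to homogeneous pixels."""
        f = self.focal_px
        u0, v0 = self.principal_point_px
        return np.array([[f, 0.0, u0], [0.0, f, v0], [0.0, 0.0, 1.0]])

    def to_dict(self) -> dict:
        return {
            "sdd_mm": self.sdd_mm,
            "pixel_pitch_mm": self.pixel_pitch_mm,
            "principal_point_px": list(self.principal_point_px),
            "image_size_px": list(self.image_size_px),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CameraModel":
        return cls(
            sdd_mm=float(d["sdd_mm"]),
            pixel_pitch_mm=float(d["pixel_pitch_mm"]),
            principal_point_px=tuple(float(x) for x in d["principal_point_px"]),
            image_size_px=tuple(int(x) for x in d["image_size_px"]),
        )


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length vector")
    return v / n


def plane_basis(normal: np.ndarray) -> tuple:
    """Return two orthonormal vectors spanning the plane with this normal."""
    n = _unit(normal)
    seed = np.array([1.0, 0.0, 0.0]) if abs(n[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(n, seed))
    v = np.cross(n, u)
    return u, v


@dataclass(frozen=True)
class Circle3D:
    """A circle in the camera frame: center, unit normal and radius."""

    center_mm: np.ndarray
    normal: np.ndarray
    radius_mm: float

    def __post_init__(self):
        c = np.asarray(self.center_mm, dtype=float).reshape(3)
        n = np.asarray(self.normal, dtype=float).reshape(3)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("normal must be a unit vector (|n| = 1 within 1e-9)")
        if self.radius_mm < 0:
            raise ValueError("radius must be non-negative")
        object.__setattr__(self, "center_mm", c)
        object.__setattr__(self, "normal", n)

    def points(self, n_points: int = 64, thetas: np.ndarray | None = None) -> np.ndarray:
        """Sample 3D points on the circle; shape ``(n, 3)``."""
        if thetas is None:
            thetas = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
        u, v = plane_basis(self.normal)
        return (
            self.center_mm[None, :]
            + self.radius_mm * np.cos(thetas)[:, None] * u[None, :]
            + self.radius_mm * np.sin(thetas)[:, None] * v[None, :]
        )


@dataclass(frozen=True)
class Conic2D:
    """Conic ``A x^2 + B x y + C y^2 + D x + E y + F = 0`` in pixel coords.

    The coefficient vector is normalized to unit Euclidean norm with the
    sign convention ``A + C >= 0`` so that, for a real ellipse, interior
    points evaluate negative.
    """

    coefficients: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float).reshape(6)
        n = np.linalg.norm(c)
        if n == 0:
            raise ValueError("zero conic")
        c = c / n
        if c[0] + c[2] < 0:
            c = -c
        object.__setattr__(self, "coefficients", c)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_matrix(cls, M: np.ndarray) -> "Conic2D":
        M = 0.5 * (M + M.T)
        return cls(np.array([M[0, 0], 2 * M[0, 1], M[1, 1], 2 * M[0, 2], 2 * M[1, 2], M[2, 2]]))

    @classmethod
    def from_ellipse(cls, center, semi_axes, orientation_rad: float) -> "Conic2D":
        """Build the conic of an ellipse given center, ``(a, b)`` and tilt."""
        a, b = semi_axes
        if not (a > 0 and b > 0):
            raise ValueError("semi-axes must be positive")
        ca, sa = np.cos(orientation_rad), np.sin(orientation_rad)
        Rm = np.array([[ca, -sa], [sa, ca]])
        Q = Rm @ np.diag([1.0 / a**2, 1.0 / b**2]) @ Rm.T
        c = np.asarray(center, dtype=float)
        M = np.zeros((3, 3))
        M[:2, :2] = Q
        M[:2, 2] = -Q @ c
        M[2, :2] = -Q @ c
        M[2, 2] = c @ Q @ c - 1.0
        return cls.from_matrix(M)

    @classmethod
    def point_conic(cls, p) -> "Conic2D":
        """Degenerate conic ``(x-u)^2 + (y-v)^2 = 0`` (a single point)."""
        u, v = p
        return cls(np.array([1.0, 0.0, 1.0, -2 * u, -2 * v, u * u + v * v]))

    # -- basic queries -----------------------------------------------------

    def matrix(self) -> np.ndarray:
        A, B, C, D, E, F = self.coefficients
        return np.array(
            [[A, B / 2, D / 2], [B / 2, C, E / 2], [D / 2, E / 2, F]]
        )

    def evaluate(self, points: np.ndarray) -> np.ndarray:
        """Algebraic residual at ``(n, 2)`` points (negative inside an ellipse)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        x, y = p[:, 0], p[:, 1]
        A, B, C, D, E, F = self.coefficients
        out = A * x * x + B * x * y + C * y * y + D * x + E * y + F
        return out if out.size > 1 else float(out[0])

    @property
    def is_ellipse(self) -> bool:
        A, B, C, D, E, F = self.coefficients
        if B * B - 4 * A * C >= 0:
            return False
        # real (non-imaginary) ellipse: det(M) and A+C have opposite signs
        return np.linalg.det(self.matrix()) * (A + C) < 0

    @property
    def is_point(self) -> bool:
        A, B, C, D, E, F = self.coefficients
        if B * B - 4 * A * C >= 0:
            return False
        try:
            _, axes, _ = self._ellipse_form(allow_point=True)
        except NotAnEllipseError:
            return False
        return axes == (0.0, 0.0)

    def _ellipse_form(self, allow_point: bool = True):
        cached = getattr(self, "_ef_cache", None)
        if cached is not None:
            center, axes, theta = cached
            if axes == (0.0, 0.0) and not allow_point:
                raise NotAnEllipseError("conic is a degenerate point")
            return cached
        out = self._ellipse_form_uncached(allow_point=allow_point)
        object.__setattr__(self, "_ef_cache", out)
        return out

    def _ellipse_form_uncached(self, allow_point: bool = True):
        A, B, C, D, E, F = self.coefficients
        M2 = np.array([[A, B / 2], [B / 2, C]])
        b = np.array([D, E])
        try:
            center = np.linalg.solve(2 * M2, -b)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise NotAnEllipseError("degenerate conic") from exc
        k = center @ M2 @ center + b @ center + F
        w, V = np.linalg.eigh(M2)
        with np.errstate(invalid="ignore", divide="ignore"):
            axes2 = -k / w
        # degenerate point: squared axes vanish relative to the center scale
        if allow_point and np.all(axes2 < 1e-18 * (1.0 + center @ center) ** 2):
            return center, (0.0, 0.0), 0.0
        axes = np.sqrt(axes2)
        if not np.all(np.isfinite(axes)) or not np.all(axes > 0):
            raise NotAnEllipseError("conic is not a real ellipse")
        # major axis first
        order = np.argsort(-axes)
        axes = axes[order]
        major = V[:, order[0]]
        theta = np.arctan2(major[1], major[0])
        if theta < 0:
            theta += np.pi
        if theta >= np.pi:
            theta -= np.pi
        return center, (float(axes[0]), float(axes[1])), float(theta)

    @property
    def center_px(self) -> np.ndarray:
        return self._ellipse_form()[0]

    @property
    def semi_axes_px(self) -> tuple:
        """``(a, b)`` with ``a >= b``."""
        return self._ellipse_form()[1]

    @property
    def orientation_rad(self) -> float:
        """Angle of the major axis with +u, in ``[0, pi)``."""
        return self._ellipse_form()[2]

    def ellipse_points(self, n_points: int = 128, t: np.ndarray | None = None) -> np.ndarray:
        """Sample points on the ellipse by eccentric anomaly ``t``."""
        center, (a, b), theta = self._ellipse_form()
        if t is None:
            t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
        ca, sa = np.cos(theta), np.sin(theta)
        x = a * np.cos(t)
        y = b * np.sin(t)
        return np.column_stack(
            [center[0] + ca * x - sa * y, center[1] + sa * x + ca * y]
        )

    def translated(self, d) -> "Conic2D":
        """Conic translated by ``d = (du, dv)`` pixels."""
        du, dv = d
        T = np.array([[1.0, 0.0, -du], [0.0, 1.0, -dv], [0.0, 0.0, 1.0]])
        return Conic2D.from_matrix(T.T @ self.matrix() @ T)

    def to_dict(self) -> dict:
        d = {"coefficients": [float(x) for x in self.coefficients]}
        if self.is_ellipse:
            c, ax, th = self._ellipse_form()
            d["center_px"] = [float(c[0]), float(c[1])]
            d["semi_axes_px"] = [float(ax[0]), float(ax[1])]
            d["orientation_rad"] = th
        return d


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------

def project_point(camera: CameraModel, p) -> np.ndarray:
    """Project a 3D camera-frame point (mm) to pixel coordinates.

    Pure perspective: ``u = u0 + (x / z) * SDD / pitch``; raises
    :class:`DegenerateProjectionError` for non-positive depth.
    """
    p = np.asarray(p, dtype=float).reshape(3)
    if p[2] <= 0:
        raise DegenerateProjectionError(f"point has non-positive depth z={p[2]}")
    f = camera.focal_px
    u0, v0 = camera.principal_point_px
    return np.array([u0 + p[0] / p[2] * f, v0 + p[1] / p[2] * f])


def project_points(camera: CameraModel, pts: np.ndarray) -> np.ndarray:
    """Vectorized :func:`project_point` for an ``(n, 3)`` array."""
    pts = np.asarray(pts, dtype=float)
    if np.any(pts[:, 2] <= 0):
        raise DegenerateProjectionError("points with non-positive depth")
    f = camera.focal_px
    u0, v0 = camera.principal_point_px
    return np.column_stack(
        [u0 + pts[:, 0] / pts[:, 2] * f, v0 + pts[:, 1] / pts[:, 2] * f]
    )


def project_circle(camera: CameraModel, circle: Circle3D) -> Conic2D:
    """Exact conic image of a 3D circle under the cone-beam map.

    Computed through the homography from the circle's supporting plane to
    the detector: with plane basis ``(e1, e2)`` at the center ``c``, a plane
    point ``(x, y)`` maps to homogeneous pixel ``K [e1 e2 c] (x, y, 1)``;
    the unit circle conic ``diag(1, 1, -r^2)`` pulls back accordingly.
    """
    c, n, r = circle.center_mm, circle.normal, circle.radius_mm
    # depth extent of the circle along z
    sin_t = np.sqrt(max(0.0, 1.0 - n[2] ** 2))
    zmin = c[2] - r * sin_t
    if zmin <= 0:
        raise DegenerateProjectionError("circle crosses or touches the z=0 plane")
    if r == 0:
        return Conic2D.point_conic(project_point(camera, c))
    e1, e2 = plane_basis(n)
    H = camera.intrinsic_matrix() @ np.column_stack([e1, e2, c])
    Hinv = np.linalg.inv(H)
    C0 = np.diag([1.0, 1.0, -r * r])
    return Conic2D.from_matrix(Hinv.T @ C0 @ Hinv)


# ---------------------------------------------------------------------------
# conic intersection
# ---------------------------------------------------------------------------

# inverse Vandermonde for nodes 0,1,2,3 (row order: cubic..constant)
_VANDER_INV = np.linalg.inv(np.vander(np.array([0.0, 1.0, 2.0, 3.0]), 4))

def _split_degenerate_conic(M: np.ndarray):
    """Split a rank<=2 symmetric conic matrix into two lines (homogeneous)."""
    B = np.array(
        [
            [
                M[1, 1] * M[2, 2] - M[1, 2] * M[2, 1],
                M[0, 2] * M[2, 1] - M[0, 1] * M[2, 2],
                M[0, 1] * M[1, 2] - M[0, 2] * M[1, 1],
            ],
            [
                M[1, 2] * M[2, 0] - M[1, 0] * M[2, 2],
                M[0, 0] * M[2, 2] - M[0, 2] * M[2, 0],
                M[0, 2] * M[1, 0] - M[0, 0] * M[1, 2],
            ],
            [
                M[1, 0] * M[2, 1] - M[1, 1] * M[2, 0],
                M[0, 1] * M[2, 0] - M[0, 0] * M[2, 1],
                M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0],
            ],
        ]
    ).T
    diag = np.diag(B)
    i = int(np.argmax(np.abs(diag)))
    if diag[i] > 0:
        # adjugate diagonal should be <= 0 for a real line pair; allow tiny noise
        if diag[i] > 1e-9 * max(1.0, np.abs(M).max() ** 2):
            return None
        beta = 0.0
    else:
        beta = np.sqrt(-diag[i])
    if beta == 0:
        Cm = M
    else:
        p = B[:, i] / beta
        Px = np.array([[0, p[2], -p[1]], [-p[2], 0, p[0]], [p[1], -p[0], 0]])
        Cm = M + Px
    idx = np.unravel_index(np.argmax(np.abs(Cm)), Cm.shape)
    if np.abs(Cm[idx]) < 1e-14:
        return None
    g = Cm[idx[0], :]
    h = Cm[:, idx[1]]
    return g, h


def _line_conic_intersection(line: np.ndarray, conic: Conic2D) -> list:
    """Real intersections of a homogeneous line with a conic."""
    a, b, c = line
    M = conic.matrix()
    pts = []
    # parametrize the line by two points
    if abs(b) >= abs(a):
        # y = -(a x + c)/b
        p0 = np.array([0.0, -c / b, 1.0])
        d = np.array([1.0, -a / b, 0.0])
    else:
        p0 = np.array([-c / a, 0.0, 1.0])
        d = np.array([-b / a, 1.0, 0.0])
    A2 = d @ M @ d
    B2 = 2 * (p0 @ M @ d)
    C2 = p0 @ M @ p0
    if abs(A2) < 1e-15:
        if abs(B2) < 1e-15:
            return pts
        ts = [-C2 / B2]
    else:
        disc = B2 * B2 - 4 * A2 * C2
        scale = max(abs(B2 * B2), abs(4 * A2 * C2), 1e-300)
        if disc < -1e-9 * scale:
            return pts
        disc = max(disc, 0.0)
        ts = [(-B2 + np.sqrt(disc)) / (2 * A2), (-B2 - np.sqrt(disc)) / (2 * A2)]
    for t in ts:
        h = p0 + t * d
        if abs(h[2]) > 1e-12:
            pts.append(h[:2] / h[2])
    return pts


def _refine_intersection(p: np.ndarray, c1: Conic2D, c2: Conic2D, iters: int = 8) -> np.ndarray:
    """Newton polish of a joint root of two conic equations."""
    A1, B1, C1, D1, E1, F1 = c1.coefficients
    A2, B2, C2, D2, E2, F2 = c2.coefficients
    x, y = p
    for _ in range(iters):
        f1 = A1 * x * x + B1 * x * y + C1 * y * y + D1 * x + E1 * y + F1
        f2 = A2 * x * x + B2 * x * y + C2 * y * y + D2 * x + E2 * y + F2
        j11 = 2 * A1 * x + B1 * y + D1
        j12 = B1 * x + 2 * C1 * y + E1
        j21 = 2 * A2 * x + B2 * y + D2
        j22 = B2 * x + 2 * C2 * y + E2
        det = j11 * j22 - j12 * j21
        if abs(det) < 1e-14:
            break
        dx0 = (-f1 * j22 + f2 * j12) / det
        dx1 = (-j11 * f2 + j21 * f1) / det
        x, y = x + dx0, y + dx1
        if np.hypot(dx0, dx1) < 1e-13:
            break
    return np.array([x, y])


def intersect_conics(c1: Conic2D, c2: Conic2D, tol: float = 1e-6) -> np.ndarray:
    """Real intersection points of two conics (up to 4), shape ``(k, 2)``.

    Uses the pencil method: a degenerate member ``C1 + lam * C2`` is split
    into two lines, each intersected with ``c1``; candidates are Newton
    polished and filtered by residual.  Raises
    :class:`CoincidentConicsError` when the conics are numerically equal.
    """
    v1, v2 = c1.coefficients, c2.coefficients
    if min(np.linalg.norm(v1 - v2), np.linalg.norm(v1 + v2)) < 1e-9:
        raise CoincidentConicsError("conics are numerically coincident")
    M1, M2 = c1.matrix(), c2.matrix()
    # det(M1 + lam M2) = 0 : cubic in lam, coefficients from 4 exact samples
    vals = np.array([np.linalg.det(M1 + t * M2) for t in (0.0, 1.0, 2.0, 3.0)])
    coeffs = _VANDER_INV @ vals  # [lam^3, lam^2, lam, 1]
    roots = np.roots(coeffs)
    candidates = []
    for r in roots:
        if abs(r.imag) > 1e-8 * (1 + abs(r.real)):
            continue
        Md = M1 + r.real * M2
        split = _split_degenerate_conic(Md)
        if split is None:
            continue
        for line in split:
            if np.linalg.norm(line[:2]) < 1e-12:
                continue
            candidates.extend(_line_conic_intersection(line, c1))
    out = []
    for p in candidates:
        p = _refine_intersection(p, c1, c2)
        if not np.all(np.isfinite(p)):
            continue
        r1 = abs(float(np.atleast_1d(c1.evaluate(p))[0]))
        r2 = abs(float(np.atleast_1d(c2.evaluate(p))[0]))
        # residual scale: coefficients are unit norm, points are O(10^3) px
        scale = max(1.0, np.linalg.norm(p) ** 2)
        if r1 / scale < tol and r2 / scale < tol:
            if not any(np.linalg.norm(p - q) < 1e-5 for q in out):
                out.append(p)
    return np.array(out).reshape(-1, 2)
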