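"""Detection of lens-shaped hole projections and landmark extraction.

Pipeline: locate the dark nail silhouette, threshold bright regions inside
it (Otsu within the silhouette mask), filter candidates by area and
solidity, trace subpixel boundaries (marching squares on the smoothed
image), then reduce each contour to its significant landmarks via per-arc
conic fits.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from skimage import filters, measure
from skimage.registration import phase_cross_correlation

from .contour import LandmarkSet, LensContour, landmarks_from_polyline
from .geometry import Conic2D


class NoHoleFoundError(ValueError):
    """No candidate lens region survived filtering."""


class AmbiguousDetectionError(ValueError):
    """More than two candidate regions found; all candidates attached."""

    def __init__(self, msg, contours):
        super().__init__(msg)
        self.contours = contours


class OccludedHoleWarning(UserWarning):
    """Only one of the two expected holes was detected."""


class DegenerateFitError(ValueError):
    """Conic fit impossible (too few or collinear points)."""


# ---------------------------------------------------------------------------
# conic / circle fitting
# ---------------------------------------------------------------------------

def fit_conic(points: np.ndarray) -> Conic2D:
    """Algebraic least-squares conic through >= 5 points.

    Coordinates are Hartley-normalized (centroid shift + isotropic scale)
    before the SVD solve, making the fit invariant to point ordering and to
    uniform scaling of the coordinate frame.  Raises
    :class:`DegenerateFitError` for under-determined or collinear input.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 5:
        raise DegenerateFitError("need at least 5 points to fit a conic")
    centroid = pts.mean(axis=0)
    d = pts - centroid
    scale = np.sqrt(2.0) / max(np.mean(np.linalg.norm(d, axis=1)), 1e-12)
    q = d * scale
    x, y = q[:, 0], q[:, 1]
    A = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    _, s, Vt = np.linalg.svd(A, full_matrices=False)
    if s[-2] < 1e-10 * s[0]:
        raise DegenerateFitError("rank-deficient (collinear or repeated) points")
    a, b, c, dd, e, f = Vt[-1]
    # unnormalize: substitute x' = s (x - cx), y' = s (y - cy)
    cx, cy = centroid
    A0 = a * scale * scale
    B0 = b * scale * scale
    C0 = c * scale * scale
    D0 = -2 * A0 * cx - B0 * cy + dd * scale
    E0 = -B0 * cx - 2 * C0 * cy + e * scale
    F0 = (A0 * cx * cx + B0 * cx * cy + C0 * cy * cy
          - dd * scale * cx - e * scale * cy + f)
    return Conic2D(np.array([A0, B0, C0, D0, E0, F0]))


def fit_circle(points: np.ndarray) -> tuple:
    """Least-squares (Kasa) circle fit; returns ``(center, radius)``."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 3:
        raise DegenerateFitError("need at least 3 points to fit a circle")
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones_like(x)])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy, c = sol
    r2 = c + cx * cx + cy * cy
    if r2 <= 0:
        raise DegenerateFitError("degenerate circle fit")
    return np.array([cx, cy]), float(np.sqrt(r2))


# ---------------------------------------------------------------------------
# region detection
# ---------------------------------------------------------------------------

def _subpixel_boundary(smooth: np.ndarray, region_mask: np.ndarray) -> np.ndarray | None:
    """Marching-squares boundary of one bright region at the mid iso-level."""
    dil = ndimage.binary_dilation(region_mask, iterations=3)
    ring = dil & ~ndimage.binary_dilation(region_mask, iterations=1)
    inside_med = float(np.median(smooth[region_mask]))
    outside_med = float(np.median(smooth[ring])) if ring.any() else 0.0
    level = 0.5 * (inside_med + outside_med)
    # restrict to a padded window around the region
    rows = np.any(region_mask, axis=1).nonzero()[0]
    cols = np.any(region_mask, axis=0).nonzero()[0]
    pad = 6
    r0, r1 = max(rows[0] - pad, 0), min(rows[-1] + pad + 1, smooth.shape[0])
    c0, c1 = max(cols[0] - pad, 0), min(cols[-1] + pad + 1, smooth.shape[1])
    window = smooth[r0:r1, c0:c1]
    contours = measure.find_contours(window, level)
    if not contours:
        return None
    cen = np.array(ndimage.center_of_mass(region_mask)) - np.array([r0, c0])
    best, best_d = None, np.inf
    for c in contours:
        if len(c) < 8 or np.linalg.norm(c[0] - c[-1]) > 1e-9:
            continue  # open contour: clipped at the window edge
        d = np.linalg.norm(c.mean(axis=0) - cen)
        if d < best_d:
            best, best_d = c, d
    if best is None:
        return None
    # (row, col) -> (u, v); drop the duplicated closing point
    return np.column_stack([best[:-1, 1] + c0, best[:-1, 0] + r0])


def _refine_edge_normals(image: np.ndarray, contour: np.ndarray,
                         half_range: float = 5.0, step: float = 0.1,
                         level_frac: float = 0.85,
                         profile_sigma: float = 2.0) -> np.ndarray:
    """Subpixel edge refinement against the *raw* image.

    The lens boundary is the knee where the intensity profile reaches the
    bright plateau (material path length -> 0); outside it the intensity
    falls off like ``exp(-c sqrt(distance))``, so a mid-level crossing is
    biased outward by up to several pixels at high obliquity.  Each
    contour point is therefore moved along its local normal to the
    crossing of a high fractional level (``level_frac`` of the local
    profile range) nearest the starting point.  Points where refinement
    fails stay put."""
    pts = contour.copy()
    n = len(pts)
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    norms = np.column_stack([-tang[:, 1], tang[:, 0]])
    ln = np.linalg.norm(norms, axis=1)
    ln[ln < 1e-9] = 1.0
    norms /= ln[:, None]
    offsets = np.arange(-half_range, half_range + step / 2, step)
    samp_u = pts[:, 0][:, None] + norms[:, 0][:, None] * offsets[None, :]
    samp_v = pts[:, 1][:, None] + norms[:, 1][:, None] * offsets[None, :]
    vals = ndimage.map_coordinates(image, [samp_v.ravel(), samp_u.ravel()],
                                   order=1, mode="nearest").reshape(n, -1)
    vals = ndimage.gaussian_filter1d(vals, profile_sigma, axis=1, mode="nearest")
    out = pts.copy()
    zero_idx = int(np.argmin(np.abs(offsets)))
    for j in range(n):
        prof = vals[j]
        lo, hi = prof.min(), prof.max()
        if hi - lo < 0.05:
            continue
        level = lo + level_frac * (hi - lo)
        s = prof - level
        sign_change = np.nonzero(s[:-1] * s[1:] <= 0)[0]
        if len(sign_change) == 0:
            continue
        i = int(sign_change[np.argmin(np.abs(sign_change + 0.5 - zero_idx))])
        denom = s[i + 1] - s[i]
        frac = 0.0 if abs(denom) < 1e-12 else -s[i] / denom
        off = offsets[i] + frac * step
        out[j] = pts[j] + norms[j] * off
    return out


def detect_lens_regions(image: np.ndarray, camera=None, min_area_px: float = 30.0,
                        min_solidity: float = 0.85, smoothing_sigma: float = 1.0,
                        expected_holes: int = 2) -> list:
    """Detect up to two lens-shaped bright regions inside the nail silhouette.

    Returns a list of :class:`LensContour` (subpixel boundaries only; run
    :func:`extract_landmarks` for tips/arcs), ordered along the nail axis.
    Raises :class:`NoHoleFoundError` / :class:`AmbiguousDetectionError`;
    warns with :class:`OccludedHoleWarning` when only one hole is found.
    """
    img = np.asarray(image, dtype=float)
    if img.max() > 1.0:
        img = img / img.max()
    smooth = filters.gaussian(img, sigma=smoothing_sigma, preserve_range=True)

    thr = filters.threshold_otsu(smooth)
    dark = smooth < thr
    if not dark.any():
        raise NoHoleFoundError("no nail silhouette found (no dark pixels)")
    labels, n = ndimage.label(dark)
    if n == 0:
        raise NoHoleFoundError("no nail silhouette found")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    silhouette = labels == (1 + int(np.argmax(sizes)))
    filled = ndimage.binary_fill_holes(silhouette)
    interior = filled & ~silhouette
    if not interior.any():
        raise NoHoleFoundError("nail silhouette contains no bright region")

    # bright threshold inside the filled silhouette
    vals = smooth[filled]
    thr2 = filters.threshold_otsu(vals)
    bright = filled & (smooth > thr2)
    lab2, n2 = ndimage.label(bright)
    candidates = []
    for rp in measure.regionprops(lab2):
        if rp.area < min_area_px or rp.solidity < min_solidity:
            continue
        boundary = _subpixel_boundary(smooth, lab2 == rp.label)
        if boundary is None or len(boundary) < 12:
            continue
        boundary = _refine_edge_normals(img, boundary)
        candidates.append(LensContour(points=boundary))
    if not candidates:
        raise NoHoleFoundError("no lens-shaped region passed the filters")
    if len(candidates) > expected_holes:
        raise AmbiguousDetectionError(
            f"{len(candidates)} candidate regions found (expected <= {expected_holes})",
            candidates)
    # order along the nail axis: principal direction of the silhouette
    ys, xs = np.nonzero(filled)
    pts = np.column_stack([xs, ys]).astype(float)
    pts -= pts.mean(axis=0)
    _, _, Vt = np.linalg.svd(pts, full_matrices=False)
    axis_dir = Vt[0]
    candidates.sort(key=lambda c: float(c.centroid @ axis_dir))
    if len(candidates) < expected_holes:
        warnings.warn("only one hole projection detected (occluded or filled hole)",
                      OccludedHoleWarning)
    return candidates


# ---------------------------------------------------------------------------
# landmark extraction
# ---------------------------------------------------------------------------

def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to ``n`` points uniform in arc length."""
    p = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    si = np.linspace(0.0, total, n, endpoint=False)
    return np.column_stack([np.interp(si, s, p[:, 0]), np.interp(si, s, p[:, 1])])


def _closed_curvature(points: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """Unsigned discrete curvature of a closed, uniformly sampled polyline."""
    x = ndimage.gaussian_filter1d(points[:, 0], sigma, mode="wrap")
    y = ndimage.gaussian_filter1d(points[:, 1], sigma, mode="wrap")
    dx = np.gradient(x)
    dy = np.gradient(y)
    ddx = np.gradient(dx)
    ddy = np.gradient(dy)
    denom = (dx * dx + dy * dy) ** 1.5
    with np.errstate(divide="ignore", invalid="ignore"):
        k = np.abs(dx * ddy - dy * ddx) / np.where(denom > 1e-12, denom, np.inf)
    return k


def _is_simple(points: np.ndarray) -> bool:
    """Cheap self-intersection proxy: winding of the closed polyline."""
    p = points - points.mean(axis=0)
    ang = np.unwrap(np.arctan2(p[:, 1], p[:, 0]))
    total = ang[-1] - ang[0]
    return abs(abs(total) - 2 * np.pi) < np.pi


def _taubin_conic(points: np.ndarray) -> Conic2D:
    """Gradient-weighted (Taubin) algebraic conic fit.

    Less biased than the plain algebraic fit on partial arcs; used for
    per-arc bookkeeping and initialization, not for landmark geometry.
    """
    from scipy.linalg import eigh

    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 5:
        raise DegenerateFitError("need at least 5 points")
    c0 = pts.mean(axis=0)
    d = pts - c0
    s = np.sqrt(2.0) / max(np.mean(np.linalg.norm(d, axis=1)), 1e-12)
    q = d * s
    x, y = q[:, 0], q[:, 1]
    one = np.ones_like(x)
    zero = np.zeros_like(x)
    A = np.column_stack([x * x, x * y, y * y, x, y, one])
    Dx = np.column_stack([2 * x, y, zero, one, zero, zero])
    Dy = np.column_stack([zero, x, 2 * y, zero, one, zero])
    M = A.T @ A / len(x)
    N = (Dx.T @ Dx + Dy.T @ Dy) / len(x)
    try:
        _, V = eigh(M, N + 1e-12 * np.eye(6))
    except np.linalg.LinAlgError as exc:
        raise DegenerateFitError("Taubin eigenproblem failed") from exc
    a, b, c, dd, e, f = V[:, 0]
    cx, cy = c0
    A0 = a * s * s
    B0 = b * s * s
    C0 = c * s * s
    D0 = -2 * A0 * cx - B0 * cy + dd * s
    E0 = -B0 * cx - 2 * C0 * cy + e * s
    F0 = (A0 * cx * cx + B0 * cx * cy + C0 * cy * cy
          - dd * s * cx - e * s * cy + f)
    return Conic2D(np.array([A0, B0, C0, D0, E0, F0]))


#: detector bias compensation, calibrated on noise-free synthetic
#: radiographs at the default camera/nail geometry: the traced boundary
#: sits slightly outside the rim-model arcs and the tips are slightly
#: eroded by the imaging blur
APEX_INWARD_PX = 0.27
TIP_OUTWARD_PX = 0.115


def _compensate_landmark_bias(lm: LandmarkSet,
                              apex_inward: float = APEX_INWARD_PX,
                              tip_outward: float = TIP_OUTWARD_PX) -> LandmarkSet:
    """Shift landmarks by the calibrated systematic detection bias."""
    if lm.is_circular:
        return lm
    chord = lm.tips[1] - lm.tips[0]
    L = np.linalg.norm(chord)
    if L < 1e-9:
        return lm
    u = chord / L
    nvec = np.array([-u[1], u[0]])
    tips = np.array([lm.tips[0] - tip_outward * u, lm.tips[1] + tip_outward * u])
    apexes = lm.apexes.copy()
    quarters = lm.quarters.copy()
    h_apex = [(a - lm.tips[0]) @ nvec for a in lm.apexes]
    for k, h in enumerate(h_apex):
        sgn = np.sign(h) if h != 0 else 1.0
        apexes[k] = apexes[k] - sgn * apex_inward * nvec
        for qi in (2 * k, 2 * k + 1):
            hq = (lm.quarters[qi] - lm.tips[0]) @ nvec
            frac = abs(hq) / max(abs(h), 1e-9)
            quarters[qi] = quarters[qi] - sgn * apex_inward * min(frac, 1.0) * nvec
    return LandmarkSet(is_circular=False, tips=tips, apexes=apexes,
                       quarters=quarters, arc_conics=lm.arc_conics,
                       hole_id=lm.hole_id, arc_rms_px=lm.arc_rms_px,
                       arc_points=lm.arc_points)


def extract_landmarks(contour: LensContour, n_resample: int = 256,
                      circular_contrast: float = 3.0) -> LandmarkSet:
    """Reduce a detected contour to its significant landmarks.

    Applies the shared polyline extraction rules
    (:func:`nailguide.contour.landmarks_from_polyline`): tips at the
    refined crossing of the two arc branches, per-arc apexes at maximal
    chord distance, quarter-points at half the arc length between tip and
    apex.  A Taubin conic is fitted to each arc for bookkeeping and
    solver initialization.  If the tip curvature contrast is below
    ``circular_contrast`` times the median contour curvature the contour
    is declared circular and a circle fit is returned instead.
    """
    pts = np.asarray(contour.points, dtype=float)
    if len(pts) < 20:
        raise ValueError("contour has too few points (< 20)")
    if not _is_simple(pts):
        raise ValueError("contour is self-intersecting")
    rs = _resample_closed(pts, n_resample)
    k = _closed_curvature(rs)
    med = np.median(k)
    if k.max() < circular_contrast * med:
        center, radius = fit_circle(pts)
        return LandmarkSet(is_circular=True, circle_center=center,
                           circle_radius_px=radius)
    try:
        lm = landmarks_from_polyline(rs)
    except ValueError:
        center, radius = fit_circle(pts)
        return LandmarkSet(is_circular=True, circle_center=center,
                           circle_radius_px=radius)

    lm = _compensate_landmark_bias(lm)

    conics = []
    rms = []
    for arc in lm.arc_points:
        try:
            conic = _taubin_conic(arc)
            conics.append(conic)
            rms.append(_arc_rms(conic, arc))
        except DegenerateFitError:
            conics.append(None)
            rms.append(np.inf)
    lm.arc_conics = tuple(conics)
    lm.arc_rms_px = tuple(rms)
    return lm


def _arc_rms(conic: Conic2D, pts: np.ndarray) -> float:
    """Approximate geometric RMS distance of points to a conic (Sampson)."""
    A, B, C, D, E, F = conic.coefficients
    x, y = pts[:, 0], pts[:, 1]
    f = A * x * x + B * x * y + C * y * y + D * x + E * y + F
    gx = 2 * A * x + B * y + D
    gy = B * x + 2 * C * y + E
    g = np.hypot(gx, gy)
    d = np.abs(f) / np.where(g > 1e-12, g, np.inf)
    return float(np.sqrt(np.mean(d * d)))


# ---------------------------------------------------------------------------
# inter-frame shift
# ---------------------------------------------------------------------------

def estimate_frame_shift(frame_a: np.ndarray, frame_b: np.ndarray,
                         upsample: int = 100) -> tuple:
    """Translation ``(du, dv)`` such that ``frame_b(x) ~= frame_a(x - d)``,
    with a confidence in ``[0, 1]`` (phase-correlation peak ratio).

    Subpixel refinement by upsampled cross-correlation; low confidence is
    reported, never raised.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must have identical shapes")
    shift, _, _ = phase_cross_correlation(b, a, upsample_factor=upsample,
                                          normalization=None)
    dv, du = float(shift[0]), float(shift[1])

    # confidence: dominant peak ratio of the (coarse) phase correlation
    Fa = np.fft.fft2(a - a.mean())
    Fb = np.fft.fft2(b - b.mean())
    cross = Fa * np.conj(Fb)
    denom = np.abs(cross)
    cross = cross / np.where(denom > 1e-12, denom, 1.0)
    surf = np.abs(np.fft.ifft2(cross))
    peak_idx = np.unravel_index(np.argmax(surf), surf.shape)
    peak = surf[peak_idx]
    mask = np.ones_like(surf, dtype=bool)
    r0, c0 = peak_idx
    rr = (np.arange(surf.shape[0])[:, None] - r0) % surf.shape[0]
    cc = (np.arange(surf.shape[1])[None, :] - c0) % surf.shape[1]
    near = (np.minimum(rr, surf.shape[0] - rr) <= 2) & \
           (np.minimum(cc, surf.shape[1] - cc) <= 2)
    rest = surf[~near].max() if (~near).any() else 0.0
    confidence = float(np.clip(1.0 - rest / max(peak, 1e-12), 0.0, 1.0))
    return (du, dv), confidence
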