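"""Lens contours and landmark extraction rules shared by the forward model
and the detector.

The lens is the overlap of the two projected rim ellipses of a hole.  Its
boundary decomposes into two elliptical arcs meeting at the *tips* (the
conic intersection points).  The landmark rules below are applied both to
analytically projected conics (virtual landmarks) and to conics fitted to a
detected contour, guaranteeing like-with-like correspondence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Conic2D, CoincidentConicsError, intersect_conics


class EmptyLensError(ValueError):
    """The two rim projections do not overlap (obliquity beyond grazing)."""


def _ellipse_param_of_point(conic: Conic2D, p: np.ndarray) -> float:
    """Eccentric-anomaly parameter of a point (assumed on the ellipse)."""
    c, (a, b), theta = conic._ellipse_form(allow_point=False)
    ca, sa = np.cos(theta), np.sin(theta)
    d = np.asarray(p, dtype=float) - c
    x = ca * d[0] + sa * d[1]
    y = -sa * d[0] + ca * d[1]
    return float(np.arctan2(y / b, x / a))


def _arc_t_values(t1: float, t2: float, forward: bool, n: int) -> np.ndarray:
    """Parameter samples from ``t1`` to ``t2``, increasing (forward) or not."""
    if forward:
        span = (t2 - t1) % (2 * np.pi)
    else:
        span = -((t1 - t2) % (2 * np.pi))
    return t1 + np.linspace(0.0, span, n)


def _lens_arc(conic: Conic2D, other: Conic2D, tip1, tip2, n: int):
    """Sampled arc of ``conic`` between the tips lying inside ``other``.

    Returns ``(points, t_values)`` ordered from ``tip1`` to ``tip2``.
    """
    t1 = _ellipse_param_of_point(conic, tip1)
    t2 = _ellipse_param_of_point(conic, tip2)
    for forward in (True, False):
        ts = _arc_t_values(t1, t2, forward, n)
        pts = conic.ellipse_points(t=ts)
        mid = pts[n // 2]
        # scale-aware interiority of the arc midpoint w.r.t. the other conic
        scale = max(1.0, float(mid @ mid))
        if float(np.atleast_1d(other.evaluate(mid))[0]) / scale < 1e-12:
            return pts, ts
    raise EmptyLensError("no arc of the conic lies inside the other conic")


@dataclass
class LensContour:
    """Closed lens (or circle) boundary with optional tip/arc annotation.

    ``points`` is an ordered closed polyline (first point not repeated).
    When not circular, ``tips`` holds the two conic intersection points and
    ``arcs`` the two tip-to-tip sub-polylines that partition the contour.
    """

    points: np.ndarray
    is_circular: bool = False
    tips: np.ndarray | None = None
    arcs: tuple | None = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if self.tips is not None:
            self.tips = np.asarray(self.tips, dtype=float).reshape(-1, 2)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def to_dict(self) -> dict:
        d = {"is_circular": bool(self.is_circular),
             "points": self.points.tolist()}
        if self.tips is not None:
            d["tips"] = self.tips.tolist()
        return d


def _containment(inner: Conic2D, outer: Conic2D, n: int = 32) -> bool:
    pts = inner.ellipse_points(n_points=n)
    vals = np.atleast_1d(outer.evaluate(pts))
    scale = np.maximum(1.0, np.sum(pts * pts, axis=1))
    return bool(np.all(vals / scale < 1e-12))


def lens_from_conics(e1: Conic2D, e2: Conic2D, n_points: int = 256,
                     force_circular: bool = False) -> LensContour:
    """Lens contour of the overlap of two ellipses.

    Aligned/degenerate handling: numerically coincident conics, a conic
    contained in the other, or ``force_circular`` yield a circular contour
    (the inner ellipse) with no tips.  Disjoint ellipses raise
    :class:`EmptyLensError`.
    """
    try:
        tips = intersect_conics(e1, e2)
    except CoincidentConicsError:
        return LensContour(e1.ellipse_points(n_points), is_circular=True)

    if force_circular or len(tips) < 2:
        if _containment(e1, e2):
            inner = e1
        elif _containment(e2, e1):
            inner = e2
        elif len(tips) >= 2:
            inner = None  # grazing overlap; fall through to the tip path
        else:
            raise EmptyLensError("rim projections do not overlap")
        if inner is not None:
            return LensContour(inner.ellipse_points(n_points), is_circular=True)

    if len(tips) > 2:
        # near-tangent configurations can yield 4 crossings; the lens tips
        # are the most separated pair
        best = max(
            ((i, j) for i in range(len(tips)) for j in range(i + 1, len(tips))),
            key=lambda ij: np.linalg.norm(tips[ij[0]] - tips[ij[1]]),
        )
        tips = tips[list(best)]

    tipA, tipB = tips[0], tips[1]
    n_half = max(8, n_points // 2)
    arc1, _ = _lens_arc(e1, e2, tipA, tipB, n_half)
    arc2, _ = _lens_arc(e2, e1, tipB, tipA, n_half)
    pts = np.vstack([arc1[:-1], arc2[:-1]])
    return LensContour(pts, is_circular=False, tips=np.array([tipA, tipB]),
                       arcs=(arc1, arc2))


# ---------------------------------------------------------------------------
# landmarks
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Significant landmarks of one hole projection.

    Non-circular: 2 tips, 2 arc apexes (farthest point of each arc from the
    tip-tip chord), 4 quarter-points (half arc-length between tip and apex,
    two per arc) and the per-arc conics.  Canonical order: tips sorted
    lexicographically by ``(u, v)``; arc 0 is the arc whose apex lies on the
    positive side of the directed chord tip0 -> tip1 (positive cross
    product); quarters are ``[arc0 tip0-side, arc0 tip1-side, arc1
    tip0-side, arc1 tip1-side]``.

    Circular (aligned) case: a circle fit ``(center, radius)`` replaces the
    landmarks.
    """

    is_circular: bool
    tips: np.ndarray | None = None
    apexes: np.ndarray | None = None
    quarters: np.ndarray | None = None
    arc_conics: tuple | None = None
    circle_center: np.ndarray | None = None
    circle_radius_px: float | None = None
    hole_id: int | None = None
    arc_rms_px: tuple | None = None
    arc_points: tuple | None = None

    def as_vector(self) -> np.ndarray:
        """Flatten to the residual vector used by the solver."""
        if self.is_circular:
            return np.concatenate([self.circle_center, [self.circle_radius_px]])
        return np.concatenate(
            [self.tips.ravel(), self.apexes.ravel(), self.quarters.ravel()]
        )

    @property
    def n_landmarks(self) -> int:
        return 1 if self.is_circular else len(self.tips) + len(self.apexes) + len(self.quarters)

    def all_points(self) -> np.ndarray:
        if self.is_circular:
            return self.circle_center[None, :]
        return np.vstack([self.tips, self.apexes, self.quarters])

    def with_swapped_tips(self) -> "LandmarkSet":
        """Relabel tip0 <-> tip1 (reverses chord direction and arc roles)."""
        if self.is_circular:
            return self
        return LandmarkSet(
            is_circular=False,
            tips=self.tips[::-1].copy(),
            apexes=self.apexes[::-1].copy(),
            quarters=self.quarters[[3, 2, 1, 0]].copy(),
            arc_conics=(None if self.arc_conics is None
                        else (self.arc_conics[1], self.arc_conics[0])),
            hole_id=self.hole_id,
            arc_rms_px=(None if self.arc_rms_px is None
                        else (self.arc_rms_px[1], self.arc_rms_px[0])),
            arc_points=(None if self.arc_points is None
                        else (self.arc_points[1], self.arc_points[0])),
        )

    def to_dict(self) -> dict:
        d = {"hole_id": self.hole_id, "is_circular": bool(self.is_circular)}
        if self.is_circular:
            d["circle_center_px"] = [float(x) for x in self.circle_center]
            d["circle_radius_px"] = float(self.circle_radius_px)
        else:
            d["tips"] = self.tips.tolist()
            d["apexes"] = self.apexes.tolist()
            d["quarter_points"] = self.quarters.tolist()
            d["arc_conics"] = [c.to_dict() for c in self.arc_conics]
        return d


# ---------------------------------------------------------------------------
# polyline landmark rules (shared by the detector and the exact-silhouette
# virtual landmark generator)
# ---------------------------------------------------------------------------

def _refine_corner(rel_pts: np.ndarray, L: float, at_start: bool,
                   window_frac: float = 0.3) -> np.ndarray | None:
    """Subpixel lens tip as the crossing of the two arc branches.

    ``rel_pts`` are contour points in the chord frame (columns: along,
    side).  Near a tip each arc branch is a smooth function side(along);
    both branches are fitted with quadratics over a window and
    extrapolated to their crossing.
    """
    along, side = rel_pts[:, 0], rel_pts[:, 1]
    x0 = 0.0 if at_start else L
    w = window_frac * L
    sel = np.abs(along - x0) < w
    pos = sel & (side > 0)
    neg = sel & (side < 0)
    if pos.sum() < 4 or neg.sum() < 4:
        return None
    try:
        cpos = np.polyfit(along[pos], side[pos], 2)
        cneg = np.polyfit(along[neg], side[neg], 2)
    except np.linalg.LinAlgError:
        return None
    roots = np.roots(np.polysub(cpos, cneg))
    roots = roots[np.abs(roots.imag) < 1e-9].real
    if len(roots) == 0:
        return None
    r = roots[np.argmin(np.abs(roots - x0))]
    if abs(r - x0) > 0.6 * w:
        return None
    return np.array([r, np.polyval(cpos, r)])


def _polyline_halfway(poly: np.ndarray) -> np.ndarray:
    """Point at half the arc length of an open polyline."""
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    half = 0.5 * s[-1]
    i = int(np.searchsorted(s, half))
    i = min(max(i, 1), len(poly) - 1)
    f = (half - s[i - 1]) / max(s[i] - s[i - 1], 1e-12)
    return poly[i - 1] + f * (poly[i] - poly[i - 1])


def landmarks_from_polyline(rs: np.ndarray, apex_window_frac: float = 0.2,
                            hole_id: int | None = None) -> LandmarkSet:
    """Apply the landmark extraction rules to a closed lens polyline.

    Tips are seeded at the extremes along the principal direction (the
    lune's long axis joins the tips) and refined to the crossing of the
    two arc branches; each arc's apex maximizes the distance from the
    tip-tip chord (quadratic refinement over a window); quarter-points sit
    at half the arc length between tip and apex.  Canonical ordering as in
    :class:`LandmarkSet`.
    """
    rs = np.asarray(rs, dtype=float).reshape(-1, 2)
    if len(rs) < 16:
        raise ValueError("polyline has too few points")
    centered = rs - rs.mean(axis=0)
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ Vt[0]
    tips = np.array([rs[int(np.argmin(proj))], rs[int(np.argmax(proj))]])

    for _ in range(2):  # refine tips, then re-derive the chord frame once
        chord = tips[1] - tips[0]
        L = float(np.linalg.norm(chord))
        if L < 1e-6:
            raise ValueError("degenerate tip configuration")
        u = chord / L
        nvec = np.array([-u[1], u[0]])
        rel = np.column_stack([(rs - tips[0]) @ u, (rs - tips[0]) @ nvec])
        new_tips = []
        for at_start in (True, False):
            corner = _refine_corner(rel, L, at_start)
            if corner is None:
                new_tips.append(tips[0 if at_start else 1])
            else:
                new_tips.append(tips[0] + corner[0] * u + corner[1] * nvec)
        tips = np.array(new_tips)

    chord = tips[1] - tips[0]
    L = float(np.linalg.norm(chord))
    u = chord / L
    nvec = np.array([-u[1], u[0]])
    along = (rs - tips[0]) @ u
    side = (rs - tips[0]) @ nvec
    core = (along > 0.02 * L) & (along < 0.98 * L)

    apexes = []
    quarters = []
    arcs = []
    for sgn in (+1.0, -1.0):
        sel = core & (sgn * side > 0)
        arc = rs[sel]
        if len(arc) < 6:
            raise ValueError("degenerate arc split")
        arc = arc[np.argsort(arc @ u)]
        arcs.append(arc)
        dist = sgn * ((arc - tips[0]) @ nvec)
        x_all = (arc - tips[0]) @ u
        i = int(np.argmax(dist))
        win = np.abs(x_all - x_all[i]) < apex_window_frac * L
        if win.sum() >= 3:
            coef = np.polyfit(x_all[win], dist[win], 2)
            if abs(coef[0]) > 1e-12:
                xa = -coef[1] / (2 * coef[0])
                if abs(xa - x_all[i]) < apex_window_frac * L:
                    apex = tips[0] + xa * u + sgn * np.polyval(coef, xa) * nvec
                else:
                    apex = arc[i]
            else:
                apex = arc[i]
        else:
            apex = arc[i]
        apexes.append(apex)
        full = np.vstack([tips[0], arc, tips[1]])
        s_apex = (apex - tips[0]) @ u
        first = np.vstack([full[((full - tips[0]) @ u) < s_apex], apex])
        second = np.vstack([apex, full[((full - tips[0]) @ u) > s_apex]])
        quarters.append(_polyline_halfway(first))
        quarters.append(_polyline_halfway(second))

    lm = LandmarkSet(is_circular=False, tips=tips, apexes=np.array(apexes),
                     quarters=np.array(quarters), arc_conics=None,
                     hole_id=hole_id, arc_points=tuple(arcs))
    if (tips[0][0], tips[0][1]) > (tips[1][0], tips[1][1]):
        lm = lm.with_swapped_tips()
    return lm


def _chord_side(tips: np.ndarray, p: np.ndarray) -> float:
    """Signed side of ``p`` w.r.t. the directed chord tips[0] -> tips[1]."""
    chord = tips[1] - tips[0]
    d = np.asarray(p, dtype=float) - tips[0]
    return float(chord[0] * d[1] - chord[1] * d[0])


def _arc_apex(conic: Conic2D, ts: np.ndarray, tips: np.ndarray):
    """Apex of an arc: point of extremal distance from the tip-tip chord.

    On an ellipse the distance to a line is extremal where the tangent is
    parallel to the chord; of the two closed-form candidates the one inside
    the arc's parameter interval is returned, with its parameter.
    """
    c, (a, b), theta = conic._ellipse_form(allow_point=False)
    chord = tips[1] - tips[0]
    n = np.array([-chord[1], chord[0]])  # chord normal
    ca, sa = np.cos(theta), np.sin(theta)
    u = np.array([ca, sa])
    v = np.array([-sa, ca])
    t0 = float(np.arctan2(b * (n @ v), a * (n @ u)))
    lo, hi = (ts[0], ts[-1]) if ts[0] <= ts[-1] else (ts[-1], ts[0])
    for cand in (t0, t0 + np.pi, t0 - np.pi, t0 + 2 * np.pi, t0 - 2 * np.pi):
        if lo - 1e-9 <= cand <= hi + 1e-9:
            return conic.ellipse_points(t=np.array([cand]))[0], float(cand)
    # numerical fallback: densely scan the arc
    pts = conic.ellipse_points(t=ts)
    dist = np.abs((pts - tips[0]) @ n)
    i = int(np.argmax(dist))
    return pts[i], float(ts[i])


def _arc_quarters(conic: Conic2D, ts_full: np.ndarray, t_apex: float) -> np.ndarray:
    """Points at half the arc length between each tip and the apex."""
    n_dense = 129
    out = []
    for t_end, t_start in ((t_apex, ts_full[0]), (ts_full[-1], t_apex)):
        ts = np.linspace(t_start, t_end, n_dense)
        pts = conic.ellipse_points(t=ts)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        t_half = float(np.interp(0.5 * s[-1], s, ts))
        out.append(conic.ellipse_points(t=np.array([t_half]))[0])
    return np.array(out)


def landmarks_from_conic_pair(eA: Conic2D, eB: Conic2D,
                              tips: np.ndarray | None = None,
                              hole_id: int | None = None) -> LandmarkSet:
    """Apply the landmark extraction rules to a pair of rim conics."""
    if tips is None:
        try:
            pts = intersect_conics(eA, eB)
        except CoincidentConicsError:
            pts = np.zeros((0, 2))
        if len(pts) < 2:
            if len(pts) == 0 and not (_containment(eA, eB) or _containment(eB, eA)):
                raise EmptyLensError("rim projections do not overlap")
            c, (a, b), _ = eA._ellipse_form(allow_point=False)
            return LandmarkSet(is_circular=True, circle_center=c,
                               circle_radius_px=0.5 * (a + b), hole_id=hole_id)
        if len(pts) > 2:
            best = max(((i, j) for i in range(len(pts)) for j in range(i + 1, len(pts))),
                       key=lambda ij: np.linalg.norm(pts[ij[0]] - pts[ij[1]]))
            pts = pts[list(best)]
        tips = pts
    tips = np.asarray(tips, dtype=float).reshape(2, 2)
    # canonical tip order: lexicographic by (u, v)
    if (tips[0][0], tips[0][1]) > (tips[1][0], tips[1][1]):
        tips = tips[::-1]

    arcs = []
    for conic, other in ((eA, eB), (eB, eA)):
        pts, ts = _lens_arc(conic, other, tips[0], tips[1], 33)
        apex, t_apex = _arc_apex(conic, ts, tips)
        quarters = _arc_quarters(conic, ts, t_apex)
        arcs.append({"conic": conic, "apex": apex, "quarters": quarters,
                     "side": _chord_side(tips, apex)})
    # arc 0 = positive side of the directed chord
    if arcs[0]["side"] < 0:
        arcs = arcs[::-1]
    if not (arcs[0]["side"] > 0 > arcs[1]["side"]):
        raise ValueError("arc apexes do not lie on opposite sides of the chord")
    return LandmarkSet(
        is_circular=False,
        tips=tips,
        apexes=np.array([arcs[0]["apex"], arcs[1]["apex"]]),
        quarters=np.vstack([arcs[0]["quarters"], arcs[1]["quarters"]]),
        arc_conics=(arcs[0]["conic"], arcs[1]["conic"]),
        hole_id=hole_id,
    )
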