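"""Parametric nail geometry: a cylinder pierced by two transverse holes.

Nail frame convention: the nail axis is local ``+x``; hole axes are unit
vectors perpendicular to it.  The mediolateral (ML) hole axis defaults to
local ``+z`` and the anteroposterior (AP) axis to local ``+y``, so that under
a pose looking roughly down ``+z`` an ML hole faces the source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Circle3D
from .pose import Pose

NAIL_AXIS = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class HoleSpec:
    """One transverse interlocking hole.

    ``axial_station_mm`` locates the hole center along the nail axis;
    ``axis_dir_nail_frame`` is the bore direction (unit, perpendicular to
    the nail axis); ``label`` is ``"ML"`` or ``"AP"``.
    """

    axial_station_mm: float
    axis_dir_nail_frame: np.ndarray
    label: str = "ML"

    def __post_init__(self):
        d = np.asarray(self.axis_dir_nail_frame, dtype=float).reshape(3)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("hole axis must be a unit vector")
        if abs(d @ NAIL_AXIS) > 1e-9:
            raise ValueError("hole axis must be perpendicular to the nail axis")
        if self.label not in ("ML", "AP"):
            raise ValueError("label must be 'ML' or 'AP'")
        object.__setattr__(self, "axis_dir_nail_frame", d)

    def to_dict(self) -> dict:
        return {
            "axial_station_mm": float(self.axial_station_mm),
            "axis_dir_nail_frame": [float(x) for x in self.axis_dir_nail_frame],
            "label": self.label,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HoleSpec":
        return cls(float(d["axial_station_mm"]),
                   np.asarray(d["axis_dir_nail_frame"], dtype=float),
                   d.get("label", "ML"))


@dataclass(frozen=True)
class NailSpec:
    """Distal nail segment: outer cylinder plus exactly two hole cylinders."""

    outer_radius_mm: float = 5.0
    hole_radius_mm: float = 2.0
    length_mm: float = 60.0
    holes: tuple = (
        HoleSpec(0.0, (0.0, 0.0, 1.0), "ML"),
        HoleSpec(12.0, (0.0, 0.0, 1.0), "ML"),
    )

    def __post_init__(self):
        holes = tuple(self.holes)
        if len(holes) != 2:
            raise ValueError("exactly two holes are required")
        if not self.hole_radius_mm < self.outer_radius_mm:
            raise ValueError("hole diameter must be smaller than nail diameter")
        if abs(holes[0].axial_station_mm - holes[1].axial_station_mm) < 1e-9:
            raise ValueError("hole axial stations must be distinct")
        object.__setattr__(self, "holes", holes)

    @property
    def rim_offset_mm(self) -> float:
        """Distance from the nail axis to each rim plane, ``sqrt(R^2 - r_h^2)``."""
        return float(np.sqrt(self.outer_radius_mm ** 2 - self.hole_radius_mm ** 2))

    @property
    def is_parallel_layout(self) -> bool:
        d0, d1 = (h.axis_dir_nail_frame for h in self.holes)
        return abs(abs(d0 @ d1) - 1.0) < 1e-9

    def hole_center_nail(self, hole_index: int) -> np.ndarray:
        s = self.holes[hole_index].axial_station_mm
        return np.array([s, 0.0, 0.0])

    def hole_center_cam(self, pose: Pose, hole_index: int) -> np.ndarray:
        return pose.apply(self.hole_center_nail(hole_index))

    def hole_axis_cam(self, pose: Pose, hole_index: int) -> np.ndarray:
        return pose.apply_direction(self.holes[hole_index].axis_dir_nail_frame)

    def to_dict(self) -> dict:
        return {
            "outer_radius_mm": float(self.outer_radius_mm),
            "hole_radius_mm": float(self.hole_radius_mm),
            "length_mm": float(self.length_mm),
            "holes": [h.to_dict() for h in self.holes],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NailSpec":
        kw = {}
        for key in ("outer_radius_mm", "hole_radius_mm", "length_mm"):
            if key in d:
                kw[key] = float(d[key])
        if "holes" in d:
            kw["holes"] = tuple(HoleSpec.from_dict(h) for h in d["holes"])
        return cls(**kw)

    @classmethod
    def default(cls, layout: str = "parallel", station_spacing_mm: float = 12.0,
                outer_radius_mm: float = 5.0, hole_radius_mm: float = 2.0) -> "NailSpec":
        """Catalogue nail: two ML holes (``parallel``) or ML + AP (``orthogonal``)."""
        if layout == "parallel":
            holes = (HoleSpec(0.0, (0.0, 0.0, 1.0), "ML"),
                     HoleSpec(station_spacing_mm, (0.0, 0.0, 1.0), "ML"))
        elif layout == "orthogonal":
            holes = (HoleSpec(0.0, (0.0, 0.0, 1.0), "ML"),
                     HoleSpec(station_spacing_mm, (0.0, 1.0, 0.0), "AP"))
        else:
            raise ValueError(f"unknown layout {layout!r}")
        return cls(outer_radius_mm=outer_radius_mm, hole_radius_mm=hole_radius_mm,
                   holes=holes)


def hole_rim_circles(nail: NailSpec, pose: Pose, hole_index: int) -> tuple:
    """Camera-frame rim circles of one hole (planar-rim approximation).

    The true rim (intersection of the outer cylinder with the hole
    cylinder) is non-planar; it is modelled as two planar circles of radius
    ``r_h`` perpendicular to the hole axis at signed offsets
    ``+/- sqrt(R^2 - r_h^2)`` from the nail axis.
    """
    hole = nail.holes[hole_index]
    p0 = nail.hole_center_nail(hole_index)
    d = hole.axis_dir_nail_frame
    h = nail.rim_offset_mm
    out = []
    for s in (+1.0, -1.0):
        center = pose.apply(p0 + s * h * d)
        normal = pose.apply_direction(d)
        out.append(Circle3D(center, normal, nail.hole_radius_mm))
    return tuple(out)
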