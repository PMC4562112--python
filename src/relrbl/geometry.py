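"""X-ray projection geometry for intraoral radiography.

Models the imaging bench of a periapical exposure: a point source (focus) at
focal distance ``f`` from the receptor, a tooth standing off the receptor
plane, and a receptor that may be tilted away from the ideal paralleling
position by an angle alpha.  Projecting a 3-D tooth model through this
geometry reproduces the three classical distortions of dental radiography:

* magnification ``f / (f - d)`` from the divergent beam (central mode),
* elongation ``1 / cos(alpha_r)`` from a tilted receptor,
* foreshortening ``cos(alpha_t)`` from a tilted tooth axis.

Coordinate convention: the receptor plane passes through the origin, the
central beam runs along -z, and the source sits at ``(0, 0, f)``.  Receptor
tilt is a rotation about the horizontal x-axis, so the receptor's in-plane
vertical unit vector is ``(0, cos a, sin a)``.  All lengths are millimetres;
pixel units exist only in :mod:`relrbl.measure`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np

__all__ = [
    "DegenerateGeometryError",
    "ProjectionGeometry",
    "ToothModel3D",
    "ProjectedLandmarks",
    "project_point",
    "project_tooth",
    "scale_factor",
    "bias_comparison",
]

#: landmark key: (label, aspect, root)
LandmarkKey = Tuple[str, str, str]


class DegenerateGeometryError(ValueError):
    """Ray parallel to the receptor plane, point behind the source, or f <= d."""


@dataclass(frozen=True)
class ProjectionGeometry:
    """Source/receptor/tooth spatial configuration.

    Parameters
    ----------
    mode
        ``"central"`` for a point source at finite focal distance,
        ``"parallel"`` for projection along the central-beam direction
        (the infinite-focal-distance limit; ``focal_distance`` is ignored).
    focal_distance
        Source-to-receptor distance f in mm (central mode only).
    receptor_tilt_deg
        Rotation alpha_r of the receptor plane about the horizontal axis,
        degrees.  This is the study angle alpha: 0 deg is the ideal
        paralleling technique, 30 deg the distorted exposure.
    tooth_tilt_deg
        Rotation alpha_t of the tooth axis away from receptor-vertical,
        degrees; produces foreshortening.
    """

    mode: str = "central"
    focal_distance: float = 300.0
    receptor_tilt_deg: float = 0.0
    tooth_tilt_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("parallel", "central"):
            raise ValueError(f"mode must be 'parallel' or 'central', got {self.mode!r}")
        for name in ("receptor_tilt_deg", "tooth_tilt_deg"):
            tilt = getattr(self, name)
            if not abs(tilt) < 90.0:
                raise ValueError(f"|{name}| must be < 90 deg, got {tilt}")
        if self.mode == "central" and not self.focal_distance > 0:
            raise ValueError("focal_distance must be > 0 in central mode")

    @property
    def _alpha_r(self) -> float:
        return math.radians(self.receptor_tilt_deg)

    @property
    def normal(self) -> np.ndarray:
        """Unit normal of the (tilted) receptor plane."""
        a = self._alpha_r
        return np.array([0.0, -math.sin(a), math.cos(a)])

    @property
    def u_hat(self) -> np.ndarray:
        """Receptor in-plane horizontal unit vector."""
        return np.array([1.0, 0.0, 0.0])

    @property
    def v_hat(self) -> np.ndarray:
        """Receptor in-plane vertical unit vector."""
        a = self._alpha_r
        return np.array([0.0, math.cos(a), math.sin(a)])


def project_point(
    point3d: Tuple[float, float, float], geometry: ProjectionGeometry
) -> Tuple[float, float]:
    """Project a 3-D point onto the receptor plane.

    Central mode intersects the source->point ray with the tilted receptor
    plane; parallel mode projects along the central-beam direction (0,0,-1).
    Returns receptor-frame coordinates ``(u, v)`` in mm.
    """
    p = np.asarray(point3d, dtype=float)
    if p.shape != (3,):
        raise ValueError("point3d must be a 3-vector")
    n = geometry.normal
    if geometry.mode == "central":
        f = geometry.focal_distance
        if p[2] >= f:
            raise DegenerateGeometryError(
                f"point z={p[2]} is at or behind the source (f={f})"
            )
        source = np.array([0.0, 0.0, f])
        direction = p - source
        denom = float(n @ direction)
        if abs(denom) < 1e-12:
            raise DegenerateGeometryError("ray is parallel to the receptor plane")
        t = -float(n @ source) / denom
        x = source + t * direction
    else:
        direction = np.array([0.0, 0.0, -1.0])
        denom = float(n @ direction)  # = -cos(alpha_r), nonzero for |alpha_r| < 90
        t = -float(n @ p) / denom
        x = p + t * direction
    return float(x @ geometry.u_hat), float(x @ geometry.v_hat)


@dataclass(frozen=True)
class ToothModel3D:
    """A tooth as collinear landmarks along one axis.

    Heights are signed positions along the tooth axis in mm, apex at 0 and
    crown reference (incisal edge / highest cusp, INC_OCL) at ``length``.
    The alveolar crest sits ``h_cej - h_ac`` below the cemento-enamel
    junction: that difference is the true marginal bone level.

    ``aspect_offsets`` displace the mesial/distal CEJ and AC landmarks
    laterally off the axis, mimicking points clicked on the two sides of the
    root; ``roots`` maps a root label to an (apex height offset, lateral
    offset) pair so multi-rooted teeth carry one apex per root.
    """

    length: float
    h_cej: float
    h_ac: float
    aspect_offsets: Mapping[str, float] = field(
        default_factory=lambda: {"mesial": 3.0, "distal": -3.0}
    )
    roots: Mapping[str, Tuple[float, float]] = field(
        default_factory=lambda: {"single": (0.0, 0.0)}
    )
    tooth_id: str = "tooth"

    def __post_init__(self) -> None:
        if not self.length > 0:
            raise ValueError("tooth length must be > 0")
        if not 0 < self.h_cej <= self.length:
            raise ValueError("h_cej must satisfy 0 < h_cej <= length")
        if not 0 <= self.h_ac <= self.length:
            raise ValueError("h_ac must satisfy 0 <= h_ac <= length")
        if not self.roots:
            raise ValueError("at least one root is required")

    @property
    def bone_level(self) -> float:
        """True marginal bone level CEJ-to-AC, mm."""
        return self.h_cej - self.h_ac

    def root_length(self, root: str) -> float:
        """True axial length from the crown reference to this root's apex."""
        dh, _ = self.roots[root]
        return self.length - dh

    def landmarks_3d(
        self,
        tooth_tilt_deg: float = 0.0,
        standoff: float = 0.0,
        position: Tuple[float, float] = (0.0, 0.0),
    ) -> Dict[LandmarkKey, np.ndarray]:
        """3-D coordinates of every landmark.

        The tooth axis starts at ``(position[0], position[1], standoff)`` and
        runs along the receptor-vertical direction, tilted by
        ``tooth_tilt_deg`` towards the source (rotation about x).
        """
        a = math.radians(tooth_tilt_deg)
        x0, y0 = position
        base = np.array([x0, y0, standoff])

        def at(height: float, lateral: float) -> np.ndarray:
            return base + np.array(
                [lateral, height * math.cos(a), height * math.sin(a)]
            )

        pts: Dict[LandmarkKey, np.ndarray] = {
            ("INC_OCL", "none", "single"): at(self.length, 0.0)
        }
        for root, (dh, dx) in self.roots.items():
            pts[("APEX", "none", root)] = at(dh, dx)
        for aspect, off in self.aspect_offsets.items():
            pts[("CEJ", aspect, "single")] = at(self.h_cej, off)
            pts[("AC", aspect, "single")] = at(self.h_ac, off)
        return pts


@dataclass(frozen=True)
class ProjectedLandmarks:
    """Receptor-frame (u, v) coordinates per landmark — the simulator's
    stand-in for a clicked radiograph."""

    points: Mapping[LandmarkKey, Tuple[float, float]]
    tooth_id: str = "tooth"

    def __getitem__(self, key: LandmarkKey) -> Tuple[float, float]:
        return self.points[key]

    def vertical_extent(self) -> float:
        vs = [v for _, v in self.points.values()]
        return max(vs) - min(vs)


def project_tooth(
    model: ToothModel3D,
    geometry: ProjectionGeometry,
    standoff: float = 0.0,
    position: Tuple[float, float] = (0.0, 0.0),
) -> ProjectedLandmarks:
    """Project every landmark of a tooth model onto the receptor.

    ``standoff`` is the tooth-axis-to-receptor distance d (mm) and
    ``position`` the in-plane placement of the apex-level base point.
    Equivalent to applying :func:`project_point` landmark-wise.
    """
    if standoff < 0:
        raise ValueError("standoff must be >= 0")
    pts3d = model.landmarks_3d(
        tooth_tilt_deg=geometry.tooth_tilt_deg, standoff=standoff, position=position
    )
    projected = {
        key: project_point(tuple(p), geometry) for key, p in pts3d.items()
    }
    return ProjectedLandmarks(points=projected, tooth_id=model.tooth_id)


def scale_factor(geometry: ProjectionGeometry, at_standoff: float = 0.0) -> float:
    """Nominal local vertical image/object length ratio at a given standoff.

    Combines divergent-beam magnification ``f/(f-d)`` (central mode),
    receptor-tilt elongation ``1/cos(alpha_r)`` and tooth-tilt
    foreshortening ``cos(alpha_t)``.  In central mode with a tilted receptor
    the true scale varies slightly along the tooth; this is the first-order
    value at the tooth axis.
    """
    if at_standoff < 0:
        raise ValueError("standoff must be >= 0")
    if geometry.mode == "central":
        f = geometry.focal_distance
        if f <= at_standoff:
            raise DegenerateGeometryError(
                f"focal distance {f} must exceed standoff {at_standoff}"
            )
        mag = f / (f - at_standoff)
    else:
        mag = 1.0
    return (
        mag
        * math.cos(math.radians(geometry.tooth_tilt_deg))
        / math.cos(math.radians(geometry.receptor_tilt_deg))
    )


def bias_comparison(
    object_length: float,
    tooth_length: float,
    geometry0: ProjectionGeometry,
    geometry1: ProjectionGeometry,
    standoff: float = 0.0,
) -> Tuple[float, float]:
    """Compare direct vs ratio measurement bias between two exposures.

    Places an object of ``object_length`` mm (a bone-level segment) on a
    tooth of ``tooth_length`` mm, images it under both geometries, and
    returns ``(direct_bias, ratio_bias)``:

    * ``direct_bias``: |projected object length under geometry1 - geometry0|
      in mm — the error a direct mm measurement commits between exams;
    * ``ratio_bias``: |relRBL1 - relRBL0| x true tooth length, the
      mm-equivalent error of the length-adjusted measurement.

    Under parallel projection the ratio bias is exactly zero for any angle
    pair; for small objects the direct bias shrinks proportionally, which is
    the trade-off governing when length adjustment is worthwhile.
    """
    if not 0 < object_length <= tooth_length:
        raise ValueError("require 0 < object_length <= tooth_length")
    # centre the segment on the tooth axis; lateral offsets zero so the
    # comparison isolates vertical-axis distortion
    h_cej = (tooth_length + object_length) / 2.0
    model = ToothModel3D(
        length=tooth_length,
        h_cej=h_cej,
        h_ac=h_cej - object_length,
        aspect_offsets={"mesial": 0.0},
    )

    def measure(geom: ProjectionGeometry) -> Tuple[float, float]:
        lm = project_tooth(model, geom, standoff=standoff)
        v_inc = lm[("INC_OCL", "none", "single")][1]
        v_apex = lm[("APEX", "none", "single")][1]
        v_cej = lm[("CEJ", "mesial", "single")][1]
        v_ac = lm[("AC", "mesial", "single")][1]
        a = abs(v_inc - v_apex)
        b = abs(v_ac - v_cej)
        return a, b

    a0, b0 = measure(geometry0)
    a1, b1 = measure(geometry1)
    direct_bias = abs(b1 - b0)
    ratio_bias = abs(b1 / a1 - b0 / a0) * tooth_length
    return direct_bias, ratio_bias
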