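"""Landmark-based tooth length, bone level and relRBL measurement.

Given clicked landmark pixel coordinates on a periapical radiograph —
crown reference (INC_OCL), root apex(es) (APEX), and per-aspect alveolar
crest (AC) and cemento-enamel junction (CEJ) — this module computes:

* ``a``  tooth length (INC_OCL to APEX) per root, mm,
* ``b``  radiographic bone level RBL (AC to CEJ) per aspect, mm,
* ``relRBL = 100 * b / a`` per aspect, percent.

Every distance is taken on an imaginary vertical axis parallel to the
vertical edge of the receptor: only the y pixel coordinate enters, the
horizontal coordinate is discarded.  Because elongation and magnification
rescale that axis uniformly, the ratio b/a is invariant to them while the
direct mm measurements are not — which is the whole point of the
length-adjusted technique.

Image coordinates have their origin at the upper-left corner with y
increasing downward; all distances are absolute values, so orientation
never flips signs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Dict, Iterable, Optional, Tuple

__all__ = [
    "LABELS",
    "ASPECTS",
    "ROOTS",
    "LandmarkPoint",
    "Calibration",
    "SiteAnnotation",
    "Measurement",
    "IncompleteSiteError",
    "ZeroLengthError",
    "ImplausibleBoneLevelWarning",
    "axis_coordinate",
    "tooth_length",
    "rbl",
    "rel_rbl",
    "measure_site",
]

LABELS = frozenset({"INC_OCL", "APEX", "AC", "CEJ", "RM"})
ASPECTS = frozenset({"mesial", "distal", "none"})
ROOTS = frozenset({"M", "D", "single"})


class IncompleteSiteError(ValueError):
    """A required landmark (AC or CEJ for the requested aspect) is missing."""


class ZeroLengthError(ValueError):
    """Crown reference and apex coincide on the vertical axis."""


class ImplausibleBoneLevelWarning(UserWarning):
    """Bone level exceeds tooth length (b > a) — anatomically implausible."""


@dataclass(frozen=True)
class LandmarkPoint:
    """One clicked point: label, aspect (for AC/CEJ/RM), root (for APEX),
    and pixel coordinates relative to the upper-left image corner."""

    label: str
    x: float
    y: float
    aspect: str = "none"
    root: str = "single"

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"unknown landmark label {self.label!r}")
        if self.aspect not in ASPECTS:
            raise ValueError(f"unknown aspect {self.aspect!r}")
        if self.root not in ROOTS:
            raise ValueError(f"unknown root designation {self.root!r}")
        for c in (self.x, self.y):
            if not (c == c and abs(c) != float("inf")):
                raise ValueError("coordinates must be finite")
        if self.x < 0 or self.y < 0:
            raise ValueError("pixel coordinates must be >= 0 (origin upper-left)")

    @property
    def key(self) -> Tuple[str, str, str]:
        return (self.label, self.aspect, self.root)


@dataclass(frozen=True)
class Calibration:
    """Image scale in mm per pixel, plus where it came from."""

    mm_per_px: float
    source: str = "sidecar"  # sidecar | tiff_tag | default

    def __post_init__(self) -> None:
        if not self.mm_per_px > 0:
            raise ValueError("mm_per_px must be > 0")


@dataclass(frozen=True)
class SiteAnnotation:
    """All landmarks of one tooth on one image, plus calibration.

    Invariants: exactly one INC_OCL, at least one APEX, no duplicate
    (label, aspect, root) triple.  An aspect is *measurable* when it carries
    both an AC and a CEJ point.
    """

    image_id: str
    tooth_id: str
    points: Tuple[LandmarkPoint, ...]
    calibration: Calibration

    def __post_init__(self) -> None:
        keys = [p.key for p in self.points]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (label, aspect, root) triple in annotation")
        n_inc = sum(p.label == "INC_OCL" for p in self.points)
        if n_inc != 1:
            raise ValueError(f"exactly one INC_OCL required, found {n_inc}")
        if not any(p.label == "APEX" for p in self.points):
            raise ValueError("at least one APEX required")

    def find(self, label: str, aspect: str = "none", root: str = "single"
             ) -> Optional[LandmarkPoint]:
        for p in self.points:
            if p.key == (label, aspect, root):
                return p
        return None

    @property
    def apex_roots(self) -> Tuple[str, ...]:
        return tuple(p.root for p in self.points if p.label == "APEX")

    @property
    def measurable_aspects(self) -> Tuple[str, ...]:
        out = []
        for aspect in ("mesial", "distal"):
            if self.find("AC", aspect) and self.find("CEJ", aspect):
                out.append(aspect)
        return tuple(out)


@dataclass(frozen=True)
class Measurement:
    """Derived quantities for one annotated site: tooth length per root,
    RBL per aspect, relRBL per aspect (paired to its root), unit and
    timestamp, plus per-aspect completeness status."""

    image_id: str
    tooth_id: str
    length_mm: Dict[str, float]
    rbl_mm: Dict[str, float]
    rel_rbl_pct: Dict[str, float]
    aspect_status: Dict[str, str] = field(default_factory=dict)
    unit: str = "mm"
    timestamp: str = ""


def axis_coordinate(point: LandmarkPoint, calibration: Calibration) -> float:
    """Position of a landmark on the receptor-vertical axis, mm.

    The horizontal pixel coordinate is deliberately discarded: distances are
    measured along the axis parallel to the receptor's vertical edge, not as
    2-D Euclidean point-to-point distances.
    """
    return point.y * calibration.mm_per_px


def tooth_length(site: SiteAnnotation) -> Dict[str, float]:
    """Tooth length ``a`` per root: |axis(INC_OCL) - axis(APEX)|, mm.

    The single registered INC_OCL is, by annotation convention, the most
    elevated cusp of the imaged crown; for multi-rooted teeth each apex
    yields its own length from that one cusp.
    """
    inc = next(p for p in site.points if p.label == "INC_OCL")
    v_inc = axis_coordinate(inc, site.calibration)
    lengths: Dict[str, float] = {}
    for p in site.points:
        if p.label != "APEX":
            continue
        a = abs(v_inc - axis_coordinate(p, site.calibration))
        if a == 0.0:
            raise ZeroLengthError(
                f"INC_OCL and APEX({p.root}) coincide on the vertical axis"
            )
        lengths[p.root] = a
    return lengths


def rbl(site: SiteAnnotation, aspect: str) -> float:
    """Radiographic bone level ``b`` for one aspect: |axis(AC) - axis(CEJ)|, mm."""
    ac = site.find("AC", aspect)
    cej = site.find("CEJ", aspect)
    if ac is None or cej is None:
        missing = "AC" if ac is None else "CEJ"
        raise IncompleteSiteError(
            f"site {site.tooth_id}: {aspect} aspect is missing {missing}"
        )
    cal = site.calibration
    return abs(axis_coordinate(ac, cal) - axis_coordinate(cej, cal))


def rel_rbl(b: float, a: float) -> float:
    """Length-adjusted bone level ``100 * b / a``, percent.

    b > a is anatomically implausible but can arise from annotation noise;
    it triggers a warning and the value is still returned (silent clamping
    would bias means).
    """
    if a == 0:
        raise ZeroDivisionError("tooth length a must be > 0")
    if b > a:
        warnings.warn(
            f"bone level b={b:.3g} exceeds tooth length a={a:.3g}",
            ImplausibleBoneLevelWarning,
            stacklevel=2,
        )
    return 100.0 * b / a


def _root_for_aspect(aspect: str, roots: Iterable[str]) -> str:
    """Aspect-to-root pairing: mesial aspect uses the mesial root's length,
    distal the distal root's; single-rooted teeth use their only root."""
    roots = tuple(roots)
    if len(roots) == 1:
        return roots[0]
    want = "M" if aspect == "mesial" else "D"
    if want in roots:
        return want
    return roots[0]


def measure_site(site: SiteAnnotation, timestamp: Optional[str] = None) -> Measurement:
    """Compose length, RBL and relRBL for every measurable aspect of a site.

    Aspects missing an AC or CEJ are flagged ``incomplete`` rather than
    failing the whole site; mesial and distal results are kept separate
    (each tooth contributes two sites to a study).
    """
    lengths = tooth_length(site)
    rbl_mm: Dict[str, float] = {}
    rel_pct: Dict[str, float] = {}
    status: Dict[str, str] = {}
    for aspect in ("mesial", "distal"):
        has_any = any(
            p.label in ("AC", "CEJ") and p.aspect == aspect for p in site.points
        )
        try:
            b = rbl(site, aspect)
        except IncompleteSiteError:
            if has_any:
                status[aspect] = "incomplete"
            continue
        root = _root_for_aspect(aspect, lengths.keys())
        rbl_mm[aspect] = b
        rel_pct[aspect] = rel_rbl(b, lengths[root])
        status[aspect] = "ok"
    if timestamp is None:
        timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
    return Measurement(
        image_id=site.image_id,
        tooth_id=site.tooth_id,
        length_mm=lengths,
        rbl_mm=rbl_mm,
        rel_rbl_pct=rel_pct,
        aspect_status=status,
        unit="mm",
        timestamp=timestamp,
    )
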