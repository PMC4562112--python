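"""Readers and writers for the package's plain-text interchange formats.

* landmark CSV — ``image_id, tooth_id, root, label, aspect, x_px, y_px``;
  one clicked point per row, UTF-8, dot decimal.  Simulated and
  hand-annotated data share this format.
* calibration sidecar JSON — ``{"image_id": ..., "mm_per_px": ...}``, a
  single object or a list of them.
* measurement CSV — one row per site/aspect with a, b, relRBL, unit and an
  ISO-8601 timestamp, mirroring the plugin's stored text file.
* long-format readings CSV — ``site, examiner, repeat, angle, metric,
  value`` for reliability analysis.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Union

import pandas as pd

from .measure import (
    Calibration,
    LandmarkPoint,
    Measurement,
    SiteAnnotation,
    _root_for_aspect,
)

__all__ = [
    "LANDMARK_COLUMNS",
    "READING_COLUMNS",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_calibrations_json",
    "write_calibrations_json",
    "calibration_from_tiff",
    "sites_from_frame",
    "measurements_to_frame",
    "write_measurements_csv",
    "read_readings_csv",
    "write_readings_csv",
]

LANDMARK_COLUMNS = ["image_id", "tooth_id", "root", "label", "aspect", "x_px", "y_px"]
READING_COLUMNS = ["site", "examiner", "repeat", "angle", "metric", "value"]

PathLike = Union[str, Path]


def read_landmarks_csv(path: PathLike) -> pd.DataFrame:
    """Read a landmark CSV, validating the header and row values."""
    try:
        df = pd.read_csv(path, dtype={"image_id": str, "tooth_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty landmark file") from exc
    missing = [c for c in LANDMARK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing landmark columns {missing}")
    if df.empty:
        raise ValueError(f"{path}: landmark file has no rows")
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            LandmarkPoint(
                label=row.label, aspect=row.aspect, root=row.root,
                x=float(row.x_px), y=float(row.y_px),
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return df


def write_landmarks_csv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False, columns=LANDMARK_COLUMNS)


def read_calibrations_json(path: PathLike) -> Dict[str, Calibration]:
    """Read a calibration sidecar: one object or a list, keyed by image_id."""
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if isinstance(data, dict):
        data = [data]
    out: Dict[str, Calibration] = {}
    for entry in data:
        out[str(entry["image_id"])] = Calibration(
            mm_per_px=float(entry["mm_per_px"]),
            source=entry.get("source", "sidecar"),
        )
    return out


def write_calibrations_json(
    calibrations: Dict[str, Calibration], path: PathLike
) -> None:
    payload = [
        {"image_id": k, "mm_per_px": c.mm_per_px, "source": c.source}
        for k, c in sorted(calibrations.items())
    ]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def calibration_from_tiff(path: PathLike) -> Calibration:
    """Read mm/px from a TIFF file's resolution tags (optional extra).

    Uses XResolution/YResolution + ResolutionUnit; requires ``tifffile``.
    """
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        tags = page.tags
        try:
            num, den = tags["YResolution"].value
            unit = tags["ResolutionUnit"].value
        except KeyError as exc:
            raise ValueError(f"{path}: no resolution tags") from exc
    px_per_unit = num / den
    unit = getattr(unit, "value", unit)
    if unit == 2:  # inch
        mm_per_px = 25.4 / px_per_unit
    elif unit == 3:  # centimetre
        mm_per_px = 10.0 / px_per_unit
    else:
        raise ValueError(f"{path}: unsupported ResolutionUnit {unit}")
    return Calibration(mm_per_px=mm_per_px, source="tiff_tag")


def sites_from_frame(
    df: pd.DataFrame, calibrations: Dict[str, Calibration]
) -> List[SiteAnnotation]:
    """Group landmark rows into per-(image, tooth) annotations.

    Raises if an image has no calibration entry — there is no silent
    default scale.
    """
    sites: List[SiteAnnotation] = []
    for (image_id, tooth_id), grp in df.groupby(["image_id", "tooth_id"], sort=True):
        if image_id not in calibrations:
            raise ValueError(f"no calibration for image {image_id!r}")
        points = tuple(
            LandmarkPoint(
                label=row.label, aspect=row.aspect, root=row.root,
                x=float(row.x_px), y=float(row.y_px),
            )
            for row in grp.itertuples(index=False)
        )
        sites.append(
            SiteAnnotation(
                image_id=str(image_id), tooth_id=str(tooth_id),
                points=points, calibration=calibrations[image_id],
            )
        )
    return sites


def measurements_to_frame(measurements: Iterable[Measurement]) -> pd.DataFrame:
    """One row per site/aspect with a, b, relRBL, unit and timestamp."""
    rows = []
    for m in measurements:
        for aspect in ("mesial", "distal"):
            status = m.aspect_status.get(aspect)
            if status is None:
                continue
            root = _root_for_aspect(aspect, m.length_mm.keys())
            rows.append(
                {
                    "image_id": m.image_id,
                    "tooth_id": m.tooth_id,
                    "aspect": aspect,
                    "root": root,
                    "length_mm": m.length_mm[root],
                    "rbl_mm": m.rbl_mm.get(aspect),
                    "rel_rbl_pct": m.rel_rbl_pct.get(aspect),
                    "status": status,
                    "unit": m.unit,
                    "timestamp": m.timestamp,
                }
            )
    return pd.DataFrame(rows)


def write_measurements_csv(measurements: Iterable[Measurement], path: PathLike) -> None:
    measurements_to_frame(measurements).to_csv(path, index=False)


def read_readings_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site": str, "examiner": str, "metric": str})
    missing = [c for c in READING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing readings columns {missing}")
    return df


def write_readings_csv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False, columns=READING_COLUMNS)
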