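"""Extraction of section-plane markers into 3D atlas point clouds.

Markers placed on a registered section image (labeled cells, injection
sites, fiber terminals...) are lifted to 3D atlas coordinates through the
section's registration: through the nonlinear warp first when warp markers
exist, then through the affine cut plane.  The resulting clouds carry the
atlas region id under each point and export to two plain-text formats:

* a viewer-style JSON object ``{"name", "color": [r,g,b],
  "points": [x,y,z, x,y,z, ...]}`` with a flat coordinate triplet list, and
* CSV with one row per point including the source section, pixel position
  and region id/name.

Coordinates are voxel units throughout.  Marker pixels are interpreted in
the registration-resolution image; callers working at full scan resolution
must scale first.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .anchoring import SectionAnchoring, map_pixel_to_atlas, nearest_voxel_labels
from .atlas import AtlasVolume, RegionNode
from .errors import ValidationError
from .warp import build_warp, warp_lookup

__all__ = [
    "AtlasPoint",
    "PointCloud",
    "extract_point",
    "extract_points",
    "export_point_cloud",
    "read_point_cloud_json",
    "read_point_cloud_csv",
    "filter_between_planes",
]


@dataclass(frozen=True)
class AtlasPoint:
    """One extracted marker: its 3D atlas coordinate, provenance (section
    and pixel) and the atlas region id at the coordinate (0 outside)."""

    coord: tuple[float, float, float]
    section_nr: int
    pixel: tuple[float, float]
    region_id: int
    inside: bool = True


@dataclass
class PointCloud:
    name: str
    color: tuple[int, int, int] = (255, 0, 0)
    points: list[AtlasPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("point cloud name must be nonempty")

    def coords(self) -> np.ndarray:
        return np.array([p.coord for p in self.points], dtype=float).reshape(-1, 3)


def extract_point(
    atlas: AtlasVolume,
    a: SectionAnchoring,
    markers: Sequence | None,
    x: float,
    y: float,
) -> AtlasPoint:
    """Lift one section pixel to an atlas point (warp first, if markers)."""
    if markers:
        fld = build_warp(markers, a.width, a.height)
        sx, sy = warp_lookup(fld, float(x), float(y))
    else:
        sx, sy = float(x), float(y)
    coord = map_pixel_to_atlas(a, sx, sy)
    region = int(nearest_voxel_labels(atlas, coord[np.newaxis, :])[0])
    idx = np.copysign(np.floor(np.abs(coord) + 0.5), coord)
    inside = bool(np.all((idx >= 0) & (idx <= np.array(atlas.shape) - 1)))
    return AtlasPoint(
        coord=tuple(float(c) for c in coord),
        section_nr=a.section_nr,
        pixel=(float(x), float(y)),
        region_id=region,
        inside=inside,
    )


def extract_points(
    atlas: AtlasVolume,
    a: SectionAnchoring,
    markers: Sequence | None,
    pixels: Sequence[tuple[float, float]],
) -> list[AtlasPoint]:
    return [extract_point(atlas, a, markers, x, y) for x, y in pixels]


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

_CSV_HEADER = [
    "section_nr",
    "pixel_x",
    "pixel_y",
    "atlas_x",
    "atlas_y",
    "atlas_z",
    "region_id",
    "region_name",
]


def export_point_cloud(
    cloud: PointCloud,
    fmt: str,
    hierarchy: Sequence[RegionNode] | None = None,
) -> str:
    """Serialize a cloud to ``meshview_json`` or ``csv`` text."""
    if fmt == "meshview_json":
        flat: list[float] = []
        for p in cloud.points:
            flat.extend(float(c) for c in p.coord)
        return json.dumps(
            {"name": cloud.name, "color": [int(c) for c in cloud.color], "points": flat}
        )
    if fmt == "csv":
        names = {n.id: n.name for n in hierarchy} if hierarchy else {}
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(_CSV_HEADER)
        for p in cloud.points:
            writer.writerow(
                [
                    int(p.section_nr),
                    repr(float(p.pixel[0])),
                    repr(float(p.pixel[1])),
                    repr(float(p.coord[0])),
                    repr(float(p.coord[1])),
                    repr(float(p.coord[2])),
                    int(p.region_id),
                    names.get(p.region_id, ""),
                ]
            )
        return buf.getvalue()
    raise ValidationError(f"unknown point cloud format {fmt!r}")


def read_point_cloud_json(text: str) -> PointCloud:
    """Parse viewer-style JSON back into a cloud (coordinates only: section,
    pixel and region provenance are not part of that format)."""
    data = json.loads(text)
    flat = data["points"]
    if len(flat) % 3:
        raise ValidationError("point list length must be a multiple of 3")
    points = [
        AtlasPoint(
            coord=(float(flat[i]), float(flat[i + 1]), float(flat[i + 2])),
            section_nr=0,
            pixel=(0.0, 0.0),
            region_id=0,
        )
        for i in range(0, len(flat), 3)
    ]
    return PointCloud(
        name=str(data["name"]),
        color=tuple(int(c) for c in data["color"]),  # type: ignore[arg-type]
        points=points,
    )


def read_point_cloud_csv(text: str, name: str = "cloud") -> PointCloud:
    reader = csv.reader(io.StringIO(text))
    header = next(reader)
    if header != _CSV_HEADER:
        raise ValidationError(f"unexpected point cloud CSV header: {header}")
    points = []
    for row in reader:
        points.append(
            AtlasPoint(
                coord=(float(row[3]), float(row[4]), float(row[5])),
                section_nr=int(row[0]),
                pixel=(float(row[1]), float(row[2])),
                region_id=int(row[6]),
            )
        )
    return PointCloud(name=name, points=points)


def filter_between_planes(
    cloud: PointCloud,
    plane_point: Sequence[float],
    normal: Sequence[float],
    thickness: float,
) -> PointCloud:
    """Keep points within ``thickness/2`` of the plane (point, normal).

    Pure geometry convenience for inspecting a slab of a dense cloud.
    """
    n = np.asarray(normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm == 0:
        raise ValidationError("plane normal must be nonzero")
    n = n / norm
    p0 = np.asarray(plane_point, dtype=float)
    kept = [
        p
        for p in cloud.points
        if abs(float(np.dot(np.asarray(p.coord) - p0, n))) <= thickness / 2
    ]
    return PointCloud(name=cloud.name, color=cloud.color, points=kept)
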