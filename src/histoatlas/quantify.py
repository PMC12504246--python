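"""Regional quantification of binary segmentations and hemisphere masking.

Given a section's atlas label map and a binary segmentation of some feature
of interest (cells, plaques, fibers...), this module tallies the feature per
reporting region: region area in pixels, segmented pixels, object count and
the *load* — the fraction of a region's pixels occupied by the feature,

    load = object_pixels / region_pixels        (0 when the region is empty).

Objects are connected components (8-connectivity) of the segmentation.  Two
counting modes exist because region boundaries split objects:

* ``split`` (default): components are formed after cutting the segmentation
  along reporting-region boundaries, so every fragment counts in the region
  that contains it.  Pixel counts are exactly conserved.
* ``centroid``: whole components are assigned to the region under their
  centroid pixel.

Hemisphere masks classify each pixel as left or right of the atlas midline
plane by mapping it to atlas space — through the nonlinear warp first, when
markers are given, so the mask respects deformations applied around the
midline.  A coordinate exactly on the plane counts as right.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

from .anchoring import SectionAnchoring, map_pixel_to_atlas
from .atlas import AtlasVolume, RegionNode, mapping_lut
from .errors import ValidationError
from .warp import build_warp, warp_lookup

__all__ = [
    "LEFT",
    "RIGHT",
    "RegionStats",
    "QuantReport",
    "load_segmentation",
    "resample_nearest",
    "quantify_section",
    "aggregate_reports",
    "hemisphere_mask",
    "write_report_tsv",
    "write_stats_tsv",
]

LEFT, RIGHT = 0, 1

# 8-connectivity structuring element for object labeling
_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class RegionStats:
    """Per-region tallies for one section or an aggregate."""

    region_id: int
    region_pixels: int = 0
    object_pixels: int = 0
    object_count: int = 0

    @property
    def load(self) -> float:
        if self.region_pixels == 0:
            return 0.0
        return self.object_pixels / self.region_pixels


@dataclass
class QuantReport:
    """Quantification of one section under one mapping and mask."""

    section_nr: int
    mask_descriptor: str  # "none" | "left" | "right" | "custom"
    stats: dict[int, RegionStats]
    background: RegionStats
    mapping_signature: frozenset = field(default_factory=frozenset)

    @property
    def total_foreground(self) -> int:
        return self.background.object_pixels + sum(
            s.object_pixels for s in self.stats.values()
        )


def load_segmentation(path: str | Path, threshold: int = 0) -> np.ndarray:
    """Read a PNG/TIFF segmentation; foreground = pixel value > threshold."""
    with Image.open(path) as img:
        arr = np.asarray(img)
    if arr.ndim == 3:  # RGB(A): any nonzero channel is foreground
        arr = arr[..., :3].max(axis=2)
    return (arr > threshold).astype(np.uint8)


def resample_nearest(seg: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Nearest-neighbor resample of a 2D image to ``shape`` (preserves binarity)."""
    if seg.shape == shape:
        return seg
    rows = (np.arange(shape[0]) * seg.shape[0]) // shape[0]
    cols = (np.arange(shape[1]) * seg.shape[1]) // shape[1]
    return seg[np.ix_(rows, cols)]


def _count_objects(mask: np.ndarray) -> int:
    _, n = ndimage.label(mask, structure=_CONN8)
    return int(n)


def quantify_section(
    seg: np.ndarray,
    label_map: np.ndarray,
    mapping: Mapping[int, int],
    hemi_mask: np.ndarray | None = None,
    side: int | None = None,
    section_nr: int = 0,
    mode: str = "split",
    resample: bool = True,
) -> QuantReport:
    """Tally a binary segmentation per reporting region of one section.

    ``mapping`` collapses atlas labels to reporting regions (see
    :func:`histoatlas.atlas.collapse_hierarchy`).  With ``hemi_mask`` and
    ``side`` the analysis is restricted to one hemisphere: pixels of the
    other side are excluded from all tallies.  ``mode`` selects the object
    counting rule described in the module docstring.
    """
    seg = np.asarray(seg)
    if seg.shape != label_map.shape:
        if not resample:
            raise ValidationError(
                f"segmentation shape {seg.shape} != label map shape {label_map.shape}"
            )
        seg = resample_nearest(seg, label_map.shape)
    seg = (seg > 0)
    if mode not in ("split", "centroid"):
        raise ValidationError(f"unknown counting mode {mode!r}")

    mask_descriptor = "none"
    valid = np.ones(label_map.shape, dtype=bool)
    if side is not None:
        if hemi_mask is None:
            raise ValidationError("side given but no hemisphere mask")
        if hemi_mask.shape != label_map.shape:
            raise ValidationError(
                f"hemisphere mask shape {hemi_mask.shape} != label map shape {label_map.shape}"
            )
        valid = hemi_mask == side
        mask_descriptor = "left" if side == LEFT else "right"
    elif hemi_mask is not None:
        raise ValidationError("hemisphere mask given but no side selected")

    max_label = int(label_map.max(initial=0))
    lut = mapping_lut(mapping, max_label)
    collapsed = lut[label_map]
    collapsed = np.where(valid, collapsed, -1)  # -1 marks excluded pixels
    seg = seg & valid

    reporting_ids = sorted(set(mapping.values()) - {0})
    stats = {rid: RegionStats(rid) for rid in reporting_ids}
    background = RegionStats(0)

    for rid in reporting_ids:
        region = collapsed == rid
        stats[rid].region_pixels = int(region.sum())
    background.region_pixels = int((collapsed == 0).sum())

    if mode == "split":
        for rid in reporting_ids:
            hit = seg & (collapsed == rid)
            stats[rid].object_pixels = int(hit.sum())
            stats[rid].object_count = _count_objects(hit)
        bg_hit = seg & (collapsed == 0)
        background.object_pixels = int(bg_hit.sum())
        background.object_count = _count_objects(bg_hit)
    else:  # centroid mode: whole objects assigned to their centroid's region
        labeled, n = ndimage.label(seg, structure=_CONN8)
        if n:
            sizes = ndimage.sum_labels(seg, labeled, index=np.arange(1, n + 1))
            centroids = ndimage.center_of_mass(seg, labeled, index=np.arange(1, n + 1))
            for size, (cy, cx) in zip(sizes, centroids):
                iy = int(np.clip(np.floor(cy + 0.5), 0, label_map.shape[0] - 1))
                ix = int(np.clip(np.floor(cx + 0.5), 0, label_map.shape[1] - 1))
                rid = int(collapsed[iy, ix])
                target = stats.get(rid, background)
                target.object_pixels += int(size)
                target.object_count += 1

    signature = frozenset(mapping.items())
    return QuantReport(
        section_nr=section_nr,
        mask_descriptor=mask_descriptor,
        stats=stats,
        background=background,
        mapping_signature=signature,
    )


def aggregate_reports(reports: Sequence[QuantReport]) -> dict[int, RegionStats]:
    """Sum per-region tallies across sections; loads recompute from summed
    pixels (never averaged)."""
    if not reports:
        raise ValidationError("no reports to aggregate")
    sig = reports[0].mapping_signature
    mask = reports[0].mask_descriptor
    for r in reports[1:]:
        if r.mapping_signature != sig:
            raise ValidationError("cannot aggregate reports with different mappings")
        if r.mask_descriptor != mask:
            raise ValidationError("cannot aggregate reports with different masks")
    out: dict[int, RegionStats] = {}
    for r in reports:
        for rid, s in r.stats.items():
            agg = out.setdefault(rid, RegionStats(rid))
            agg.region_pixels += s.region_pixels
            agg.object_pixels += s.object_pixels
            agg.object_count += s.object_count
    return out


def hemisphere_mask(
    atlas: AtlasVolume,
    a: SectionAnchoring,
    markers: Sequence | None = None,
) -> np.ndarray:
    """Classify every pixel of a section as LEFT (0) or RIGHT (1).

    The pixel's 3D atlas coordinate — through the nonlinear warp when
    markers are given — is compared against the atlas midline plane along
    the midline axis; the tie (exactly on the plane) goes right.
    """
    if atlas.midline is None:
        raise ValidationError(
            f"atlas {atlas.name!r} has no midline metadata; cannot build hemisphere masks"
        )
    axis, plane = atlas.midline
    xs = np.arange(a.width, dtype=float)
    ys = np.arange(a.height, dtype=float)
    gx, gy = np.meshgrid(xs, ys)
    if markers:
        field = build_warp(markers, a.width, a.height)
        src = warp_lookup(field, gx, gy)
        coords = map_pixel_to_atlas(a, src[..., 0], src[..., 1])
    else:
        coords = map_pixel_to_atlas(a, gx, gy)
    return np.where(coords[..., axis] < plane, LEFT, RIGHT).astype(np.uint8)


# ---------------------------------------------------------------------------
# TSV reports
# ---------------------------------------------------------------------------

_TSV_HEADER = "region_id\tregion_name\tregion_pixels\tobject_pixels\tobject_count\tload\n"


def _region_names(hierarchy: Sequence[RegionNode] | None) -> dict[int, str]:
    if not hierarchy:
        return {}
    return {n.id: n.name for n in hierarchy}


def write_stats_tsv(
    stats: Mapping[int, RegionStats],
    path: str | Path,
    hierarchy: Sequence[RegionNode] | None = None,
) -> None:
    names = _region_names(hierarchy)
    with open(path, "w") as fh:
        fh.write(_TSV_HEADER)
        for rid in sorted(stats):
            s = stats[rid]
            fh.write(
                f"{rid}\t{names.get(rid, '')}\t{s.region_pixels}\t"
                f"{s.object_pixels}\t{s.object_count}\t{s.load!r}\n"
            )


def write_report_tsv(
    report: QuantReport,
    path: str | Path,
    hierarchy: Sequence[RegionNode] | None = None,
) -> None:
    write_stats_tsv(report.stats, path, hierarchy)
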