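"""Affine section-to-atlas registration: cut planes, slicing and propagation.

A section's placement in the atlas is an affine cut plane written as three
3-vectors in atlas voxel units: ``o`` is the atlas position of image pixel
(0, 0), ``u`` spans the image's x extent and ``v`` its y extent, so pixel
(x, y) of a W×H registration image maps to

    p(x, y) = o + u * x / (W - 1) + v * y / (H - 1).

The (W-1, H-1) normalization makes the four image corners land exactly on
o, o+u, o+v and o+u+v.  Slicing samples the label volume at the nearest
voxel (labels are categorical, so no interpolation); coordinates outside the
volume read as background 0.

Registration of a serial series is sparse: a few key sections are anchored
by hand (or programmatically via :func:`estimate_anchoring`) and the rest
receive anchorings by componentwise linear interpolation of (o, u, v) in the
section number, with linear extrapolation beyond the anchored range.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .atlas import AtlasVolume
from .errors import GeometryError, ValidationError

__all__ = [
    "SectionAnchoring",
    "SeriesSection",
    "SeriesDescriptor",
    "parse_section_number",
    "map_pixel_to_atlas",
    "nearest_voxel_labels",
    "slice_atlas",
    "propagate_series",
    "estimate_anchoring",
    "load_descriptor",
    "save_descriptor",
]

_SECTION_TOKEN = re.compile(r"_s(\d+)")


@dataclass(frozen=True)
class SectionAnchoring:
    """One section's affine placement: origin ``o`` plus spanning vectors
    ``u`` (image x extent) and ``v`` (image y extent), all in voxel units."""

    section_nr: int
    width: int
    height: int
    o: np.ndarray
    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        for name in ("o", "u", "v"):
            vec = np.asarray(getattr(self, name), dtype=float)
            if vec.shape != (3,):
                raise ValidationError(f"anchoring vector {name} must be a 3-vector")
            object.__setattr__(self, name, vec)
        if self.section_nr < 0:
            raise ValidationError("section_nr must be non-negative")
        if self.width < 2 or self.height < 2:
            raise ValidationError("registration image must be at least 2x2 pixels")
        if np.linalg.norm(np.cross(self.u, self.v)) == 0.0:
            raise ValidationError(
                f"degenerate anchoring for section {self.section_nr}: u and v are collinear"
            )

    def as_vector(self) -> np.ndarray:
        """Flat [ox,oy,oz, ux,uy,uz, vx,vy,vz] form used in descriptors."""
        return np.concatenate([self.o, self.u, self.v])

    @classmethod
    def from_vector(
        cls, vec: Sequence[float], section_nr: int, width: int, height: int
    ) -> "SectionAnchoring":
        arr = np.asarray(vec, dtype=float)
        if arr.shape != (9,):
            raise ValidationError("anchoring vector must have 9 components")
        return cls(section_nr, width, height, arr[0:3], arr[3:6], arr[6:9])


@dataclass
class SeriesSection:
    """One entry of a series descriptor."""

    filename: str
    nr: int
    width: int
    height: int
    anchoring: SectionAnchoring | None = None
    markers: list[tuple[float, float, float, float]] = field(default_factory=list)


@dataclass
class SeriesDescriptor:
    """An ordered serial section series registered to one atlas."""

    atlas_name: str
    sections: list[SeriesSection]

    def __post_init__(self) -> None:
        nrs = [s.nr for s in self.sections]
        if len(set(nrs)) != len(nrs):
            raise ValidationError(f"duplicate section numbers in series: {sorted(nrs)}")
        if nrs != sorted(nrs):
            raise ValidationError("sections must be sorted by ascending section number")


def parse_section_number(filename: str) -> int:
    """Extract the section number from the ``_sXXX`` filename token.

    The last such token wins, so pathological names parse deterministically.
    """
    stem = Path(filename).name
    stem = stem[: stem.rfind(".")] if "." in stem else stem
    tokens = _SECTION_TOKEN.findall(stem)
    if not tokens:
        raise ValidationError(
            f"{filename!r} does not follow the section naming convention: filenames "
            "must contain an '_s' token followed by digits, e.g. 'brain_s017.png'"
        )
    return int(tokens[-1])


def map_pixel_to_atlas(a: SectionAnchoring, x, y) -> np.ndarray:
    """Map image pixel(s) to continuous atlas voxel coordinates.

    ``x`` and ``y`` may be scalars or broadcastable arrays; the result has
    shape ``broadcast(x, y).shape + (3,)``.  Coordinates outside the image
    extrapolate linearly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fx = x / (a.width - 1)
    fy = y / (a.height - 1)
    return (
        a.o
        + fx[..., np.newaxis] * a.u
        + fy[..., np.newaxis] * a.v
    )


def nearest_voxel_labels(atlas: AtlasVolume, coords: np.ndarray) -> np.ndarray:
    """Sample the label volume at the nearest voxel to each coordinate.

    Rounding is half-away-from-zero; coordinates outside the volume yield 0.
    ``coords`` has shape ``(..., 3)``; the result drops the last axis.
    """
    c = np.asarray(coords, dtype=float)
    idx = np.copysign(np.floor(np.abs(c) + 0.5), c).astype(np.int64)
    shape = atlas.labels.shape
    inside = (
        (idx[..., 0] >= 0) & (idx[..., 0] < shape[0])
        & (idx[..., 1] >= 0) & (idx[..., 1] < shape[1])
        & (idx[..., 2] >= 0) & (idx[..., 2] < shape[2])
    )
    out = np.zeros(c.shape[:-1], dtype=atlas.labels.dtype)
    if np.any(inside):
        ii = idx[inside]
        out[inside] = atlas.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def slice_atlas(atlas: AtlasVolume, a: SectionAnchoring) -> np.ndarray:
    """Extract the label map of a section: a height×width grid of region ids."""
    xs = np.arange(a.width, dtype=float)
    ys = np.arange(a.height, dtype=float)
    gx, gy = np.meshgrid(xs, ys)  # shape (H, W)
    coords = map_pixel_to_atlas(a, gx, gy)
    return nearest_voxel_labels(atlas, coords)


def propagate_series(series: SeriesDescriptor, clamp: bool = False) -> SeriesDescriptor:
    """Fill missing anchorings by linear interpolation in the section number.

    Sections between two anchored sections interpolate (o, u, v)
    componentwise; sections outside the anchored range extrapolate linearly
    from the two nearest anchored sections (``clamp=True`` replicates the
    nearest instead).  With a single anchored section it is replicated.
    Already-anchored sections are returned unchanged.
    """
    if not series.sections:
        raise ValidationError("cannot propagate an empty series")
    anchored = [(s.nr, s.anchoring) for s in series.sections if s.anchoring is not None]
    if not anchored:
        raise ValidationError("cannot propagate: no section is anchored")
    nrs = np.array([nr for nr, _ in anchored], dtype=float)
    vecs = np.stack([a.as_vector() for _, a in anchored])  # (k, 9)

    def interp(nr: float) -> np.ndarray:
        if len(anchored) == 1:
            return vecs[0]
        if clamp:
            nr = float(np.clip(nr, nrs[0], nrs[-1]))
        if nr <= nrs[0]:
            lo, hi = 0, 1
        elif nr >= nrs[-1]:
            lo, hi = len(nrs) - 2, len(nrs) - 1
        else:
            hi = int(np.searchsorted(nrs, nr, side="right"))
            lo = hi - 1
        t = (nr - nrs[lo]) / (nrs[hi] - nrs[lo])
        return vecs[lo] + t * (vecs[hi] - vecs[lo])

    out_sections = []
    for s in series.sections:
        if s.anchoring is not None:
            out_sections.append(s)
        else:
            anc = SectionAnchoring.from_vector(interp(s.nr), s.nr, s.width, s.height)
            out_sections.append(replace(s, anchoring=anc))
    return SeriesDescriptor(atlas_name=series.atlas_name, sections=out_sections)


def estimate_anchoring(
    correspondences: Sequence[tuple[tuple[float, float], Sequence[float]]],
    width: int,
    height: int,
    section_nr: int = 0,
) -> SectionAnchoring:
    """Least-squares fit of (o, u, v) from pixel↔atlas point correspondences.

    Each correspondence pairs an image pixel (x, y) with its 3D atlas
    coordinate.  Three exact non-collinear correspondences determine the
    anchoring with zero residual; more correspondences are fit in the
    least-squares sense.
    """
    if len(correspondences) < 3:
        raise GeometryError(
            f"need at least 3 correspondences to estimate an anchoring, got {len(correspondences)}"
        )
    pix = np.array([c[0] for c in correspondences], dtype=float)
    tgt = np.array([c[1] for c in correspondences], dtype=float)
    if tgt.shape[1] != 3:
        raise ValidationError("atlas points must be 3-vectors")
    design = np.column_stack(
        [np.ones(len(pix)), pix[:, 0] / (width - 1), pix[:, 1] / (height - 1)]
    )
    if np.linalg.matrix_rank(design, tol=1e-9) < 3:
        raise GeometryError(
            "pixel points are collinear: the anchoring fit is rank-deficient"
        )
    params, *_ = np.linalg.lstsq(design, tgt, rcond=None)  # rows: o, u, v
    return SectionAnchoring(section_nr, width, height, params[0], params[1], params[2])


# ---------------------------------------------------------------------------
# registration descriptor JSON
# ---------------------------------------------------------------------------

def save_descriptor(series: SeriesDescriptor, path: str | Path) -> None:
    """Write the registration descriptor JSON (value-level round-trip safe)."""
    sections = []
    for s in series.sections:
        rec: dict = {
            "filename": s.filename,
            "nr": s.nr,
            "width": s.width,
            "height": s.height,
        }
        if s.anchoring is not None:
            rec["anchoring"] = [float(v) for v in s.anchoring.as_vector()]
        if s.markers:
            rec["markers"] = [[float(c) for c in m] for m in s.markers]
        sections.append(rec)
    with open(path, "w") as fh:
        json.dump({"atlas": series.atlas_name, "sections": sections}, fh, indent=1)
        fh.write("\n")


def load_descriptor(path: str | Path) -> SeriesDescriptor:
    """Read a registration descriptor JSON written by :func:`save_descriptor`."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        sections = []
        for rec in data["sections"]:
            nr = int(rec["nr"])
            w, h = int(rec["width"]), int(rec["height"])
            anchoring = None
            if rec.get("anchoring") is not None:
                anchoring = SectionAnchoring.from_vector(rec["anchoring"], nr, w, h)
            markers = [tuple(float(c) for c in m) for m in rec.get("markers", [])]
            sections.append(
                SeriesSection(
                    filename=str(rec["filename"]),
                    nr=nr,
                    width=w,
                    height=h,
                    anchoring=anchoring,
                    markers=markers,  # type: ignore[arg-type]
                )
            )
        return SeriesDescriptor(atlas_name=str(data["atlas"]), sections=sections)
    except KeyError as exc:
        raise ValidationError(f"{path}: descriptor missing field {exc}") from exc
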