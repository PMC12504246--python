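"""Piecewise-linear in-plane refinement of an affine registration.

Residual anatomical variability after affine registration is corrected with
draggable anchor-point markers.  Each marker pairs a *target* position (where
the user dragged the overlay to) with a *source* position (where that point
sits in the unwarped, linear atlas slice).  A Delaunay triangulation is built
over the target points; for any target pixel, its barycentric coordinates in
the containing target triangle are reused in the corresponding source
triangle to find which linear-slice pixel to sample.  The warp is therefore
piecewise affine, exact at every marker, and continuous across triangle
edges.

Four fixed corner markers (source = target) are inserted automatically so
the triangulation always covers the whole image.  Markers that fold the
source space (negative orientation) are permitted — the lookup lives in
target space and stays well defined — but trigger a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .anchoring import SectionAnchoring, map_pixel_to_atlas, nearest_voxel_labels
from .atlas import AtlasVolume
from .errors import GeometryError, ValidationError

__all__ = ["WarpMarker", "WarpField", "build_warp", "warp_lookup", "warped_label_map"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WarpMarker:
    """A single displacement marker: ``target`` is the final (dragged)
    position, ``source`` the original position, both in registration-image
    pixels."""

    target: tuple[float, float]
    source: tuple[float, float]

    @classmethod
    def from_quad(cls, quad: Sequence[float]) -> "WarpMarker":
        """Build from the descriptor quadruple [tx, ty, sx, sy]."""
        tx, ty, sx, sy = (float(c) for c in quad)
        return cls((tx, ty), (sx, sy))

    def as_quad(self) -> tuple[float, float, float, float]:
        return (*self.target, *self.source)


@dataclass
class WarpField:
    """Markers plus the Delaunay triangulation of their target points."""

    markers: list[WarpMarker]
    triangulation: Delaunay
    width: int
    height: int

    @property
    def targets(self) -> np.ndarray:
        return np.array([m.target for m in self.markers], dtype=float)

    @property
    def sources(self) -> np.ndarray:
        return np.array([m.source for m in self.markers], dtype=float)

    @property
    def triangles(self) -> np.ndarray:
        """Index triples into the marker list, one row per triangle."""
        return self.triangulation.simplices


def _as_markers(markers: Sequence) -> list[WarpMarker]:
    out = []
    for m in markers:
        if isinstance(m, WarpMarker):
            out.append(m)
        else:
            out.append(WarpMarker.from_quad(m))
    return out


def build_warp(markers: Sequence, width: int, height: int) -> WarpField:
    """Assemble a warp field from user markers for a W×H image.

    Accepts :class:`WarpMarker` objects or [tx, ty, sx, sy] quadruples.
    Corner markers are added wherever no user marker already occupies the
    corner target.  Duplicate target points are rejected (the triangulation
    would be degenerate there).
    """
    user = _as_markers(markers)
    if not all(np.isfinite(m.as_quad()).all() for m in user):
        raise ValidationError("marker coordinates must be finite")
    corner_targets = [
        (0.0, 0.0),
        (float(width - 1), 0.0),
        (0.0, float(height - 1)),
        (float(width - 1), float(height - 1)),
    ]
    all_markers = list(user)
    occupied = {m.target for m in user}
    for c in corner_targets:
        if c not in occupied:
            all_markers.append(WarpMarker(c, c))
    targets = np.array([m.target for m in all_markers], dtype=float)
    if len(np.unique(targets, axis=0)) != len(targets):
        raise ValidationError("duplicate marker target points")
    try:
        tri = Delaunay(targets)
    except QhullError as exc:
        raise GeometryError(f"cannot triangulate marker targets: {exc}") from exc
    field = WarpField(all_markers, tri, width, height)
    _warn_on_folding(field)
    return field


def _cross2(a: np.ndarray, b: np.ndarray) -> float:
    return float(a[0] * b[1] - a[1] * b[0])


def _warn_on_folding(field: WarpField) -> None:
    tgt, src = field.targets, field.sources
    for tri in field.triangles:
        t = tgt[tri]
        s = src[tri]
        ot = _cross2(t[1] - t[0], t[2] - t[0])
        os_ = _cross2(s[1] - s[0], s[2] - s[0])
        if ot * os_ < 0:
            logger.warning(
                "warp field folds: triangle %s has inverted source orientation", tri
            )
            return


def warp_lookup(field: WarpField, x, y):
    """Map target pixel(s) to source pixel(s) through the piecewise warp.

    Scalar in, scalar pair out; array in, ``(..., 2)`` array out.  Points
    outside the triangulated hull (possible only outside the image) raise.
    """
    scalar = np.isscalar(x) and np.isscalar(y)
    pts = np.stack(
        [np.asarray(x, dtype=float).ravel(), np.asarray(y, dtype=float).ravel()], axis=1
    )
    simplex = field.triangulation.find_simplex(pts)
    if np.any(simplex < 0):
        # retry near-boundary points with a tolerance before giving up
        bad = simplex < 0
        simplex[bad] = field.triangulation.find_simplex(pts[bad], tol=1e-9)
        if np.any(simplex < 0):
            outside = pts[simplex < 0][0]
            raise GeometryError(
                f"point {tuple(outside)} lies outside the warp triangulation hull"
            )
    # barycentric coordinates via the triangulation's affine transform
    trans = field.triangulation.transform[simplex]  # (n, 3, 2)
    b2 = np.einsum("nij,nj->ni", trans[:, :2, :], pts - trans[:, 2, :])
    bary = np.column_stack([b2, 1.0 - b2.sum(axis=1)])  # (n, 3)
    verts = field.triangulation.simplices[simplex]  # (n, 3)
    src = field.sources[verts]  # (n, 3, 2)
    out = np.einsum("ni,nij->nj", bary, src)
    if scalar:
        return (float(out[0, 0]), float(out[0, 1]))
    shape = np.broadcast(np.asarray(x), np.asarray(y)).shape
    return out.reshape(shape + (2,))


def warped_label_map(
    atlas: AtlasVolume, a: SectionAnchoring, markers: Sequence
) -> np.ndarray:
    """Label map of a section after nonlinear refinement.

    Every pixel is routed through the warp into the linear atlas slice:
    label(x, y) = atlas nearest-voxel at map_pixel_to_atlas(a, warp(x, y)).
    With no markers this reduces exactly to the linear slice.
    """
    field = build_warp(markers, a.width, a.height)
    xs = np.arange(a.width, dtype=float)
    ys = np.arange(a.height, dtype=float)
    gx, gy = np.meshgrid(xs, ys)
    src = warp_lookup(field, gx, gy)  # (H, W, 2)
    coords = map_pixel_to_atlas(a, src[..., 0], src[..., 1])
    return nearest_voxel_labels(atlas, coords)
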