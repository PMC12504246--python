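"""Deterministic synthetic atlases, section series and segmentations.

Real reference atlases and registered histology series are large external
downloads; every other module in this package is instead exercised against
synthetic inputs with known ground truth, generated here as pure functions
of a seed.

The synthetic atlas is a mirror-symmetric "brain": two nested ellipsoidal
shells (an outer cortex ring around an inner subcortex) centered on the
volume, plus a configurable number of small ellipsoidal nuclei planted in
one hemisphere and mirrored into the other.  Left and right copies of each
structure carry distinct region ids under a root → hemisphere → structure
hierarchy, and the midline plane is declared in the atlas metadata, so
hemisphere masking, hierarchy collapse and symmetry properties all have
exact expected answers.

Section series are evenly spaced cut planes along the atlas y axis
(coronal-like), optionally with a fixed oblique tilt; rendered grayscale
images are a deterministic intensity per region id plus seeded noise.
Segmentations plant non-overlapping disks of known radius fully inside
chosen regions (margin one pixel from the boundary, so split- and
centroid-mode counting agree), and report the exact planted counts and
pixel totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .anchoring import SectionAnchoring, SeriesDescriptor, SeriesSection, slice_atlas
from .atlas import AtlasVolume, RegionNode
from .errors import ValidationError

__all__ = [
    "SynthSpec",
    "SegGroundTruth",
    "make_atlas",
    "mirror_label_map",
    "make_series",
    "make_segmentation",
    "disk_offsets",
]

# id scheme: root 1, left hemisphere 2, right 3; structure k (0 = cortex,
# 1 = subcortex, 2.. = nuclei) has left id 10+k and right id 110+k
ROOT_ID, LEFT_ID, RIGHT_ID = 1, 2, 3
_LEFT_BASE, _RIGHT_BASE = 10, 110


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of the synthetic atlas; generation is a pure function of
    this record."""

    seed: int = 1
    dims: tuple[int, int, int] = (64, 80, 56)
    n_nuclei: int = 3
    depth: int = 3  # 2: root -> structures; 3: root -> hemispheres -> structures

    def __post_init__(self) -> None:
        if any(d < 16 for d in self.dims):
            raise ValidationError(f"atlas dims must each be >= 16, got {self.dims}")
        if self.depth not in (2, 3):
            raise ValidationError("hierarchy depth must be 2 or 3")
        if self.n_nuclei < 0:
            raise ValidationError("n_nuclei must be non-negative")


@dataclass
class SegGroundTruth:
    """Exact planted content of a synthetic segmentation."""

    counts: dict[int, int] = field(default_factory=dict)  # region -> objects
    pixels: dict[int, int] = field(default_factory=dict)  # region -> pixel total


def _structure_names(n_nuclei: int) -> list[str]:
    return ["cortex", "subcortex"] + [f"nucleus {i + 1}" for i in range(n_nuclei)]


def _build_hierarchy(spec: SynthSpec, rng: np.random.Generator) -> list[RegionNode]:
    names = _structure_names(spec.n_nuclei)
    nodes = [RegionNode(ROOT_ID, "brain", None, (240, 240, 240))]
    if spec.depth == 3:
        nodes.append(RegionNode(LEFT_ID, "left hemisphere", ROOT_ID, (200, 120, 120)))
        nodes.append(RegionNode(RIGHT_ID, "right hemisphere", ROOT_ID, (120, 120, 200)))
        left_parent, right_parent = LEFT_ID, RIGHT_ID
    else:
        left_parent = right_parent = ROOT_ID
    for k, name in enumerate(names):
        color = tuple(int(c) for c in rng.integers(32, 224, size=3))
        nodes.append(RegionNode(_LEFT_BASE + k, f"left {name}", left_parent, color))
        nodes.append(RegionNode(_RIGHT_BASE + k, f"right {name}", right_parent, color))
    return nodes


def mirror_label_map(hierarchy: Sequence[RegionNode]) -> dict[int, int]:
    """The left↔right id swap under mirror symmetry (identity elsewhere)."""
    swap = {0: 0}
    for n in hierarchy:
        if n.id == LEFT_ID:
            swap[n.id] = RIGHT_ID
        elif n.id == RIGHT_ID:
            swap[n.id] = LEFT_ID
        elif _LEFT_BASE <= n.id < _RIGHT_BASE:
            swap[n.id] = n.id - _LEFT_BASE + _RIGHT_BASE
        elif n.id >= _RIGHT_BASE:
            swap[n.id] = n.id - _RIGHT_BASE + _LEFT_BASE
        else:
            swap[n.id] = n.id
    return swap


def _ellipsoid_mask(grid: tuple[np.ndarray, ...], center, semi) -> np.ndarray:
    gx, gy, gz = grid
    return (
        ((gx - center[0]) / semi[0]) ** 2
        + ((gy - center[1]) / semi[1]) ** 2
        + ((gz - center[2]) / semi[2]) ** 2
    ) <= 1.0


def make_atlas(spec: SynthSpec) -> tuple[AtlasVolume, list[RegionNode]]:
    """Generate the mirror-symmetric synthetic label atlas.

    The midline is axis 0 at plane (X-1)/2; structures are computed from
    |x - midline|, so flipping the volume along axis 0 and swapping left and
    right ids reproduces it exactly.
    """
    rng = np.random.default_rng(spec.seed)
    hierarchy = _build_hierarchy(spec, rng)
    X, Y, Z = spec.dims
    cx = (X - 1) / 2.0
    center = (cx, (Y - 1) / 2.0, (Z - 1) / 2.0)
    gx, gy, gz = np.meshgrid(
        np.arange(X, dtype=float),
        np.arange(Y, dtype=float),
        np.arange(Z, dtype=float),
        indexing="ij",
    )
    grid = (gx, gy, gz)
    outer = _ellipsoid_mask(grid, center, (0.46 * X, 0.42 * Y, 0.42 * Z))
    inner = _ellipsoid_mask(grid, center, (0.30 * X, 0.27 * Y, 0.27 * Z))
    right_side = gx >= cx  # midline tie goes right, consistent with masking

    labels = np.zeros(spec.dims, dtype=np.int32)
    labels[outer & ~inner & ~right_side] = _LEFT_BASE + 0
    labels[outer & ~inner & right_side] = _RIGHT_BASE + 0
    labels[inner & ~right_side] = _LEFT_BASE + 1
    labels[inner & right_side] = _RIGHT_BASE + 1

    # nuclei: sampled in the right hemisphere inside the subcortex, mirrored
    # to the left; non-overlap enforced by center distance
    placed: list[tuple[np.ndarray, np.ndarray]] = []
    for k in range(spec.n_nuclei):
        semi = rng.uniform(2.5, 4.5, size=3)
        ok = False
        for _ in range(200):
            cand = np.array(
                [
                    rng.uniform(cx + semi[0] + 2.0, cx + 0.27 * X - semi[0]),
                    rng.uniform(
                        center[1] - 0.2 * Y + semi[1], center[1] + 0.2 * Y - semi[1]
                    ),
                    rng.uniform(
                        center[2] - 0.2 * Z + semi[2], center[2] + 0.2 * Z - semi[2]
                    ),
                ]
            )
            if all(
                np.linalg.norm(cand - prev_c) > (semi.max() + prev_s.max() + 2.0)
                for prev_c, prev_s in placed
            ):
                ok = True
                break
        if not ok:
            raise ValidationError(
                f"dims {spec.dims} too small to host {spec.n_nuclei} nuclei"
            )
        placed.append((cand, semi))
        right_mask = _ellipsoid_mask(grid, cand, semi) & inner
        mirrored = np.array([2 * cx - cand[0], cand[1], cand[2]])
        left_mask = _ellipsoid_mask(grid, mirrored, semi) & inner
        labels[right_mask] = _RIGHT_BASE + 2 + k
        labels[left_mask] = _LEFT_BASE + 2 + k

    atlas = AtlasVolume(
        name=f"synth-{spec.seed}",
        labels=labels,
        voxel_size_um=(25.0, 25.0, 25.0),
        midline=(0, cx),
        hierarchy=hierarchy,
    )
    return atlas, hierarchy


def make_series(
    atlas: AtlasVolume,
    n_sections: int,
    orientation: str = "coronal",
    seed: int = 0,
    noise_sd: float = 4.0,
) -> tuple[SeriesDescriptor, dict[str, np.ndarray]]:
    """Cut an evenly spaced section series and render grayscale images.

    Sections are cut along atlas axis 1 (anterior-posterior in the synthetic
    brain); ``orientation="oblique"`` adds a fixed tilt of the cut plane.
    Returns the descriptor with true anchorings plus rendered images keyed
    by filename.  Rendering is region-id-dependent intensity plus seeded
    Gaussian noise, so slicing at the true anchorings reproduces the id maps
    underlying the images.
    """
    if n_sections < 1:
        raise ValidationError("n_sections must be >= 1")
    if orientation not in ("coronal", "oblique"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    X, Y, Z = atlas.shape
    rng = np.random.default_rng(seed)
    y_lo, y_hi = 0.18 * (Y - 1), 0.82 * (Y - 1)
    if n_sections == 1:
        positions = [0.5 * (y_lo + y_hi)]
    else:
        positions = list(np.linspace(y_lo, y_hi, n_sections))
    tilt = 0.06 * (Y - 1) if orientation == "oblique" else 0.0
    if min(positions) - tilt < 0 or max(positions) + tilt > Y - 1:
        raise ValidationError("sections would fall outside the volume")

    sections, images = [], {}
    width, height = X, Z
    for i, ypos in enumerate(positions):
        nr = i + 1
        filename = f"synth_s{nr:03d}.png"
        anchoring = SectionAnchoring(
            section_nr=nr,
            width=width,
            height=height,
            o=np.array([0.0, ypos - tilt / 2, 0.0]),
            u=np.array([float(X - 1), tilt, 0.0]),
            v=np.array([0.0, tilt, float(Z - 1)]),
        )
        lm = slice_atlas(atlas, anchoring)
        gray = np.where(lm > 0, (lm * 37) % 180 + 60, 8).astype(float)
        gray += rng.normal(0.0, noise_sd, size=gray.shape)
        images[filename] = np.clip(gray, 0, 255).astype(np.uint8)
        sections.append(
            SeriesSection(
                filename=filename, nr=nr, width=width, height=height, anchoring=anchoring
            )
        )
    return SeriesDescriptor(atlas_name=atlas.name, sections=sections), images


def disk_offsets(radius: int) -> np.ndarray:
    """Integer lattice offsets of the closed disk of the given radius."""
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = dx**2 + dy**2 <= r**2
    return np.stack([dy[keep], dx[keep]], axis=1)


def _disk_kernel(radius: int) -> np.ndarray:
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return dx**2 + dy**2 <= r**2


def make_segmentation(
    label_map: np.ndarray,
    counts: Mapping[int, int],
    radius: int = 3,
    seed: int = 0,
    max_tries: int = 30,
    reduce_on_failure: bool = False,
) -> tuple[np.ndarray, SegGroundTruth]:
    """Plant non-overlapping disks fully inside the requested regions.

    Valid centers are the region eroded by the disk radius plus a one-pixel
    margin (so disks never touch a region boundary); sequential seeded
    placement keeps a clearance of two pixels between disks so planted
    objects can never become 8-connected, even across region boundaries.
    If a sequence of picks dead-ends, placement restarts for that region (up
    to ``max_tries`` times).  Ground truth records the exact object count
    and pixel total per region; with ``reduce_on_failure`` a region that
    cannot host all requested disks keeps the best attempt instead of
    raising.
    """
    from scipy import ndimage

    lm = np.asarray(label_map)
    seg = np.zeros(lm.shape, dtype=np.uint8)
    rng = np.random.default_rng(seed)
    offsets = disk_offsets(radius)
    clear_offsets = disk_offsets(radius + 2)
    margin_kernel = _disk_kernel(radius + 1)
    truth = SegGroundTruth()
    H, W = lm.shape
    for region, n in sorted(counts.items()):
        truth.counts[region] = 0
        truth.pixels[region] = 0
        if n == 0:
            continue
        if not np.any(lm == region):
            raise ValidationError(f"region {region} absent from label map")
        valid = ndimage.binary_erosion(lm == region, structure=margin_kernel,
                                       border_value=0)
        centers = np.argwhere(valid)
        best: tuple[np.ndarray, int] | None = None
        for _ in range(max_tries):
            attempt_seg = seg.copy()
            placed = 0
            for _ in range(n):
                open_mask = np.fromiter(
                    (
                        not np.any(
                            attempt_seg[
                                np.clip(clear_offsets[:, 0] + cy, 0, H - 1),
                                np.clip(clear_offsets[:, 1] + cx, 0, W - 1),
                            ]
                        )
                        for cy, cx in centers
                    ),
                    dtype=bool,
                    count=len(centers),
                )
                open_centers = centers[open_mask]
                if len(open_centers) == 0:
                    break
                cy, cx = open_centers[rng.integers(len(open_centers))]
                fp = offsets + (cy, cx)
                attempt_seg[fp[:, 0], fp[:, 1]] = 1
                placed += 1
            if best is None or placed > best[1]:
                best = (attempt_seg, placed)
            if placed == n:
                break
        assert best is not None
        if best[1] < n and not reduce_on_failure:
            raise ValidationError(
                f"could not place {n} disks of radius {radius} in region {region} "
                f"after {max_tries} restarts (best: {best[1]})"
            )
        seg = best[0]
        truth.counts[region] = best[1]
        truth.pixels[region] = best[1] * len(offsets)
    return seg, truth
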