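# Methods

This note documents the models and numerical conventions implemented in
`histoatlas`, the parameters that matter, what the synthetic-data generator
does and does not emulate, and the design choices made where more than one
convention was defensible.

## Coordinate conventions

Atlas coordinates are continuous, 0-based voxel indices with voxel centers
at integers; all geometry is done in voxel units, and physical voxel size
(µm) is carried as metadata only. Image pixels are `(x, y)` with `x` along
image columns; 2D arrays are indexed `[y, x]`.

## Affine anchoring and slicing

A section's placement is the triple `(o, u, v)`: `o` is the atlas position
of pixel (0, 0), `u` spans the image's x extent, `v` its y extent. Pixel
`(x, y)` of a `W x H` image maps to `o + u·x/(W−1) + v·y/(H−1)`. The
`(W−1, H−1)` normalization was chosen so the four corners land exactly on
`o, o+u, o+v, o+u+v`, which makes corner exactness a machine-precision
invariant rather than an approximate one; a `W`-denominator convention
would differ by half a pixel's worth of span and has no such fixed points.

Label volumes are categorical, so slicing uses nearest-voxel sampling with
round-half-away-from-zero (a fixed, sign-symmetric tie rule; NumPy's
banker's rounding would make tie behavior depend on parity). Coordinates
outside the volume read background 0. Degenerate anchorings (`u × v = 0`)
are rejected at construction.

`estimate_anchoring` fits `(o, u, v)` to pixel↔atlas correspondences by
ordinary least squares on the design `[1, x/(W−1), y/(H−1)]` per output
coordinate; rank below 3 (collinear pixels, tolerance 1e-9) is an error
rather than a pseudo-inverse answer, because a rank-deficient fit would
silently leave one in-plane direction unconstrained.

## Series propagation

Serial sections are ordered by the `_sXXX` number embedded in filenames
(the last such token wins, so pathological double-token names parse
deterministically). Missing anchorings are filled by componentwise linear
interpolation of the 9-vector `(o, u, v)` in the section number; outside
the anchored range the two nearest anchored sections extrapolate linearly.
Extrapolation is not clamped by default — clamping would contradict the
linear model that justifies interpolating in the first place — but a
`--clamp` flag replicates the nearest anchored section for series whose
ends are unreliable. A single anchored section is replicated to all.

## Piecewise-linear warp

Markers pair a *target* (dragged) position with a *source* position in the
unwarped slice, both in registration-image pixels (one coordinate system
with slicing; no normalized coordinates). Scipy's Delaunay triangulation is
built over the target points; a queried pixel's barycentric coordinates in
its containing target triangle are reused over the corresponding source
vertices. Consequences, all tested: the warp is exact at every marker,
piecewise affine, and continuous across shared edges (adjacent triangles
agree on edge points, so which triangle claims an edge point is
irrelevant; the implementation takes whatever `find_simplex` returns and
retries near-boundary points with a small tolerance before declaring a
point outside the hull).

Four fixed corner markers (source = target) are inserted unless a user
marker already occupies a corner target, guaranteeing the triangulation's
hull covers the whole image. Folding — marker sets whose source triangles
invert orientation — is permitted, since the lookup lives in target space
and remains single-valued; a warning is logged because folded warps usually
indicate a mis-dragged marker.

## Regional quantification

Segmentations are binary (foreground = feature of interest); grayscale
inputs threshold at a user flag, and a size mismatch against the label map
is resolved by nearest-neighbor resampling (preserves binarity). Atlas
labels are collapsed to reporting regions through a mapping produced by
`collapse_hierarchy`: each label maps to its nearest selected
ancestor-or-self, unselected subtrees map to 0, and nested selections are
rejected as ambiguous.

Objects are 8-connected components. Because region boundaries cut through
objects, two counting modes exist and are labeled as such:

* `split` (default): components are formed after cutting along reporting
  boundaries; every fragment counts where it lies. Pixel tallies are then
  exactly conserved (`Σ region object_pixels + background = total
  foreground`), which the suite asserts on random segmentations.
* `centroid`: whole components are assigned to the region under their
  centroid pixel (rounded half-away, clipped to the image).

The regional load is `object_pixels / region_pixels` with 0/0 → 0; it is
bounded in [0, 1] and aggregates stably: series-level aggregation sums the
pixel tallies and recomputes the load, never averages per-section loads.

Hemisphere masks classify each pixel by the sign of its atlas coordinate
along the declared midline axis relative to the midline plane, after
routing through the warp when markers exist. A coordinate exactly on the
plane counts as right — any fixed convention works; this one is stated so
results are reproducible. The midline is declared atlas metadata (axis +
plane coordinate), never inferred from label symmetry, since real atlases
are not exactly symmetric.

## Systematic-sampling QC

Grid points are `(offset + i·spacing)` clipped to the image, enumerated
row-major. Points over background are prefilled `outside`; raters label the
rest `accurate`, `inaccurate`, `uncertain` or `damage` via CSV (no GUI in
this package). Per reporting region, accuracy is
`accurate/(accurate+inaccurate)`; `uncertain` is excluded from the
denominator because an indeterminate mark carries no evidence either way —
the convention is repeated in output headers so downstream readers cannot
misread the denominator. Damage fractions are computed per section and per
region over in-tissue points, and entities above a user threshold are
listed for exclusion. Note that halving the grid spacing quadruples the
point count exactly when both spacings divide the image extent; with other
spacings boundary clipping can leave the finer grid slightly below 4x.

## Point clouds

Markers on a registered section lift to 3D by warp-then-anchor; each point
keeps its provenance (section, pixel) and the atlas region id under it
(0 with an `inside=False` flag outside the volume). Exports are a
viewer-style JSON object with a flat `[x,y,z, x,y,z, ...]` triplet list and
an RFC-4180 CSV with full provenance; both re-import value-identically
(floats are written with `repr`, which round-trips IEEE doubles). Pixel
coordinates are registration-resolution; full-resolution callers scale
first (`--scale`). Coordinates are voxel units for internal consistency; a
micrometer export is a one-line multiplication by the voxel size and is
left to callers. A plane-slab filter (`keep points within t/2 of a plane`)
is provided as pure geometry for inspecting dense clouds.

## Synthetic data

The generator exists so that every pipeline stage can be tested against
exact ground truth without reference-atlas downloads.

* **Atlas** (default `64 x 80 x 56` voxels at 25 µm, seed-deterministic):
  two nested ellipsoidal shells ("cortex" ring around a "subcortex") plus
  `n_nuclei = 3` small ellipsoidal nuclei per hemisphere, mirror-symmetric
  about the declared midline plane `x = (X−1)/2` with distinct left/right
  region ids under a root → hemisphere → structure hierarchy. Symmetry is
  exact by construction (structures are functions of `|x − midline|`), so
  hemisphere balance and flip-equivalence are exact test oracles.
* **Series** (default 5 sections): evenly spaced cut planes along the atlas
  y axis spanning the middle 64% of the volume, coronal or with a fixed 6%
  oblique tilt; anchorings are exactly affine in the section index, making
  propagation recovery exact. Images are a deterministic per-label
  intensity plus seeded Gaussian noise (sd 4 gray levels).
* **Segmentations**: disks of radius 3 planted fully inside requested
  regions. Valid centers come from eroding the region by radius+1 (disks
  never touch a boundary, so split- and centroid-mode counts agree on
  fixtures), and a clearance of radius+2 between a candidate center and any
  planted pixel makes 8-connection between planted objects geometrically
  impossible. Sequential seeded placement restarts (up to 30 times) if a
  random sequence of picks dead-ends; small regions can still genuinely
  lack capacity, which is an error by default or a reduced planting under
  `reduce_on_failure` (ground truth always records what was planted).

What the generator does **not** emulate: histological texture, staining
variability, tears, folds, missing tissue, section-thickness effects, or
anatomically realistic region shapes. Passing tests therefore demonstrate
the correctness of the geometry and bookkeeping — slicing, warping,
counting, conservation — not robustness to real-tissue artifacts, and say
nothing about registration *quality* on real data, which remains a human
(or external-tool) judgment that this package only audits via QC sampling.

## Problem sizes and determinism

The test suite and the acceptance script run on small volumes (a 16³
two-label volume for brute-force oracle comparisons, the default synthetic
atlas elsewhere) — sizes chosen so brute-force per-pixel oracles are
feasible and the full suite runs in seconds. Every random quantity flows
from an explicit seed (`numpy.random.default_rng`); reruns are
bit-identical, and the CLI's `simulate` output is byte-stable per seed.

## Known limitations

* The registration-descriptor JSON is this package's own dialect; import
  shims for the file formats of existing GUI registration tools are future
  work (those schemas are not standardized).
* Object counting is per-section 2D; objects spanning sections are counted
  once per section (no 3D reconstruction or stereological correction).
* Quantification is binary; intensity-weighted measures are out of scope.
* The warp is in-plane only; out-of-plane (z) deformation is not modeled.
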