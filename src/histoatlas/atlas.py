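"""Volumetric label atlas, region hierarchy and hierarchy collapse.

The atlas is a 3D grid of non-negative integer region ids (0 = background)
together with a flat region hierarchy: every region is a node with a unique
positive id, a display color and an optional parent.  Analyses rarely report
at the finest atlas granularity; instead a set of "parent" (reporting)
regions is selected in the hierarchy and every leaf label is collapsed onto
its nearest selected ancestor.  This module owns those structures, their
(de)serialization and the collapse operation.

Coordinate convention: atlas coordinates are continuous 0-based voxel
indices with voxel centers at integers.  The midline is declared metadata —
an axis index and a plane coordinate in voxel units — not inferred from the
label content.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np

from .errors import ValidationError

__all__ = [
    "RegionNode",
    "AtlasVolume",
    "validate_hierarchy",
    "load_hierarchy",
    "save_hierarchy",
    "load_atlas",
    "save_atlas",
    "collapse_hierarchy",
    "ancestor_chain",
]


@dataclass(frozen=True)
class RegionNode:
    """One region of the atlas hierarchy.

    ``parent_id`` is ``None`` for a root.  ``color`` is an RGB byte triple
    used for overlay rendering and point-cloud export.
    """

    id: int
    name: str
    parent_id: int | None = None
    color: tuple[int, int, int] = (128, 128, 128)

    def __post_init__(self) -> None:
        if self.id <= 0:
            raise ValidationError(f"region id must be positive, got {self.id}")
        if len(self.color) != 3 or any(not (0 <= c <= 255) for c in self.color):
            raise ValidationError(f"region {self.id}: color must be an RGB byte triple")


@dataclass
class AtlasVolume:
    """A 3D label volume plus region hierarchy and midline metadata.

    ``labels`` holds region ids (0 = background).  ``midline`` is
    ``(axis, plane_coordinate)`` in voxel units, or ``None`` when the atlas
    carries no hemisphere information.
    """

    name: str
    labels: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    midline: tuple[int, float] | None = None
    hierarchy: list[RegionNode] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError(
                f"atlas volume must be 3D, got {self.labels.ndim} dimensions"
            )
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError(
                f"atlas volume must hold integers, got dtype {self.labels.dtype}"
            )
        if any(d < 2 for d in self.labels.shape):
            raise ValidationError(f"atlas dims must be >= 2, got {self.labels.shape}")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValidationError("voxel sizes must be positive")
        if self.midline is not None:
            axis, coord = self.midline
            if axis not in (0, 1, 2):
                raise ValidationError(f"midline axis must be 0, 1 or 2, got {axis}")
            if not (0.0 <= coord <= self.labels.shape[axis] - 1):
                raise ValidationError(
                    f"midline coordinate {coord} outside [0, {self.labels.shape[axis] - 1}]"
                )
        nodes = validate_hierarchy(self.hierarchy)
        present = set(np.unique(self.labels).tolist()) - {0}
        unknown = sorted(present - set(nodes))
        if unknown:
            raise ValidationError(
                f"labels present in volume but missing from hierarchy: {unknown}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def node(self, region_id: int) -> RegionNode:
        for n in self.hierarchy:
            if n.id == region_id:
                return n
        raise KeyError(region_id)


def validate_hierarchy(nodes: Sequence[RegionNode]) -> dict[int, RegionNode]:
    """Check uniqueness, parent resolution and acyclicity; return an id index."""
    index: dict[int, RegionNode] = {}
    for n in nodes:
        if n.id in index:
            raise ValidationError(f"duplicate region id {n.id}")
        index[n.id] = n
    for n in nodes:
        if n.parent_id is not None and n.parent_id not in index:
            raise ValidationError(
                f"unresolved parent: region {n.id} refers to missing parent {n.parent_id}"
            )
    # cycle check by walking parent links with a visited budget
    for n in nodes:
        seen = {n.id}
        cur = n
        while cur.parent_id is not None:
            if cur.parent_id in seen:
                raise ValidationError(f"cyclic hierarchy detected at region {n.id}")
            seen.add(cur.parent_id)
            cur = index[cur.parent_id]
    return index


def ancestor_chain(index: Mapping[int, RegionNode], region_id: int) -> list[int]:
    """Ids from ``region_id`` up to its root, inclusive, nearest first."""
    chain = [region_id]
    cur = index[region_id]
    while cur.parent_id is not None:
        chain.append(cur.parent_id)
        cur = index[cur.parent_id]
    return chain


# ---------------------------------------------------------------------------
# hierarchy (de)serialization: a flat JSON list of node records, optionally
# wrapped in an object that also carries the atlas metadata block
# ---------------------------------------------------------------------------

def _node_to_record(n: RegionNode) -> dict:
    rec: dict = {"id": n.id, "name": n.name, "color": list(n.color)}
    if n.parent_id is not None:
        rec["parent_id"] = n.parent_id
    return rec


def _record_to_node(rec: Mapping) -> RegionNode:
    try:
        return RegionNode(
            id=int(rec["id"]),
            name=str(rec["name"]),
            parent_id=(int(rec["parent_id"]) if rec.get("parent_id") is not None else None),
            color=tuple(int(c) for c in rec.get("color", (128, 128, 128))),  # type: ignore[arg-type]
        )
    except KeyError as exc:
        raise ValidationError(f"hierarchy record missing field {exc}") from exc


def load_hierarchy(path: str | Path) -> tuple[list[RegionNode], dict]:
    """Read a hierarchy JSON file.

    Accepts either a bare JSON list of node records or an object
    ``{"name", "voxel_size_um", "midline_axis", "midline_coord", "regions": [...]}``.
    Returns ``(nodes, metadata)`` where metadata is ``{}`` for the bare form.
    """
    with open(path) as fh:
        data = json.load(fh)
    if isinstance(data, list):
        records, meta = data, {}
    elif isinstance(data, dict) and "regions" in data:
        records = data["regions"]
        meta = {k: v for k, v in data.items() if k != "regions"}
    else:
        raise ValidationError(
            f"{path}: hierarchy JSON must be a list of nodes or an object with a 'regions' list"
        )
    nodes = [_record_to_node(r) for r in records]
    validate_hierarchy(nodes)
    return nodes, meta


def save_hierarchy(
    nodes: Sequence[RegionNode], path: str | Path, metadata: Mapping | None = None
) -> None:
    """Write hierarchy JSON; with metadata, the wrapped-object form is used."""
    records = [_node_to_record(n) for n in nodes]
    payload: object = records if not metadata else {**metadata, "regions": records}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def load_atlas(volume_path: str | Path, hierarchy_path: str | Path) -> AtlasVolume:
    """Load a NIfTI label volume and its hierarchy JSON into an AtlasVolume.

    The hierarchy file may carry the atlas metadata block (name, voxel size,
    midline); voxel size falls back to the NIfTI header zooms and the name to
    the volume filename.
    """
    img = nib.load(str(volume_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(f"{volume_path}: expected a 3D volume, got {data.ndim}D")
    if not np.issubdtype(data.dtype, np.integer):
        as_int = data.astype(np.int64)
        if not np.array_equal(as_int, data):
            raise ValidationError(f"{volume_path}: voxel data is not integer-valued")
        data = as_int
    nodes, meta = load_hierarchy(hierarchy_path)
    zooms = img.header.get_zooms()[:3]
    voxel = tuple(float(v) for v in meta.get("voxel_size_um", zooms))
    midline = None
    if "midline_axis" in meta:
        midline = (int(meta["midline_axis"]), float(meta["midline_coord"]))
    name = str(meta.get("name", Path(volume_path).stem))
    return AtlasVolume(
        name=name, labels=data, voxel_size_um=voxel, midline=midline, hierarchy=nodes
    )


def save_atlas(atlas: AtlasVolume, volume_path: str | Path, hierarchy_path: str | Path) -> None:
    """Write the label volume as NIfTI-1 and the hierarchy (with metadata) as JSON."""
    affine = np.diag(list(atlas.voxel_size_um) + [1.0])
    img = nib.Nifti1Image(atlas.labels.astype(np.int32), affine)
    img.header.set_zooms(atlas.voxel_size_um)
    nib.save(img, str(volume_path))
    meta: dict = {"name": atlas.name, "voxel_size_um": list(atlas.voxel_size_um)}
    if atlas.midline is not None:
        meta["midline_axis"] = atlas.midline[0]
        meta["midline_coord"] = atlas.midline[1]
    save_hierarchy(atlas.hierarchy, hierarchy_path, metadata=meta)


# ---------------------------------------------------------------------------
# hierarchy collapse
# ---------------------------------------------------------------------------

def collapse_hierarchy(
    hierarchy: Sequence[RegionNode], selected_ids: Iterable[int]
) -> dict[int, int]:
    """Map every hierarchy id onto its nearest selected ancestor-or-self.

    ``selected_ids`` are the chosen reporting ("parent") regions.  Ids with
    no selected ancestor map to 0 (dropped from reports).  Selecting nested
    ids is ambiguous and rejected.
    """
    index = validate_hierarchy(hierarchy)
    selected = set(int(s) for s in selected_ids)
    missing = selected - set(index)
    if missing:
        raise ValidationError(f"selected ids not in hierarchy: {sorted(missing)}")
    for s in selected:
        for anc in ancestor_chain(index, s)[1:]:
            if anc in selected:
                raise ValidationError(
                    f"nested selection: region {s} descends from selected region {anc}"
                )
    mapping: dict[int, int] = {}
    for rid in index:
        mapping[rid] = 0
        for anc in ancestor_chain(index, rid):
            if anc in selected:
                mapping[rid] = anc
                break
    return mapping


def mapping_lut(mapping: Mapping[int, int], max_label: int) -> np.ndarray:
    """Dense lookup table for applying a RegionMapping to a label array.

    Labels above ``max_label`` or absent from the mapping collapse to 0.
    """
    lut = np.zeros(max_label + 1, dtype=np.int64)
    for src, dst in mapping.items():
        if 0 <= src <= max_label:
            lut[src] = dst
    return lut
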