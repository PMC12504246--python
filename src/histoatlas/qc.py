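"""Systematic-sampling quality control of atlas registration and tissue damage.

A regular grid of sampling points is laid over each section; a rater labels
every in-tissue point as

* ``accurate`` / ``inaccurate`` — registration correct or not at the point,
* ``uncertain`` — the rater cannot decide,
* ``damage``   — the tissue at the point is missing or damaged,
* ``outside``  — the point falls outside the tissue (prefilled from the
  label map, never rated).

Per reporting region the registration accuracy is

    accuracy = accurate / (accurate + inaccurate)

with ``uncertain`` excluded from the denominator (indeterminate marks carry
no evidence either way; this convention is repeated in output headers).
Damage is tallied per section and per region as the fraction of in-tissue
points marked ``damage``; sections and regions exceeding a damage threshold
are listed for exclusion from downstream quantification.

Since this toolkit has no rating GUI, assessments travel as CSV files of
(point_index, label) pairs.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .atlas import RegionNode, mapping_lut
from .errors import ValidationError

__all__ = [
    "LABELS",
    "QCGrid",
    "RegionQC",
    "QCReport",
    "generate_grid",
    "qc_statistics",
    "read_assessment_csv",
    "write_assessment_csv",
    "write_qc_tsv",
    "write_section_summary_tsv",
]

ACCURATE, INACCURATE, UNCERTAIN, DAMAGE, OUTSIDE = (
    "accurate",
    "inaccurate",
    "uncertain",
    "damage",
    "outside",
)
LABELS = (ACCURATE, INACCURATE, UNCERTAIN, DAMAGE, OUTSIDE)


@dataclass
class QCGrid:
    """Row-major systematic sampling grid clipped to the image bounds."""

    spacing: int
    offset: tuple[int, int]
    width: int
    height: int
    points: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class RegionQC:
    region_id: int
    accurate: int = 0
    inaccurate: int = 0
    uncertain: int = 0
    damage: int = 0

    @property
    def in_tissue(self) -> int:
        return self.accurate + self.inaccurate + self.uncertain + self.damage

    @property
    def accuracy(self) -> float | None:
        denom = self.accurate + self.inaccurate
        return self.accurate / denom if denom else None

    @property
    def damage_fraction(self) -> float | None:
        return self.damage / self.in_tissue if self.in_tissue else None


@dataclass
class QCReport:
    """Registration accuracy per region and damage summary for one section."""

    section_nr: int
    regions: dict[int, RegionQC]
    in_tissue_points: int
    damage_points: int
    outside_points: int

    @property
    def damage_fraction(self) -> float | None:
        if self.in_tissue_points == 0:
            return None
        return self.damage_points / self.in_tissue_points


def generate_grid(
    width: int,
    height: int,
    spacing: int,
    offset: tuple[int, int] = (0, 0),
    label_map: np.ndarray | None = None,
) -> tuple[QCGrid, list[str | None]]:
    """Enumerate grid points row-major and prefill ``outside`` labels.

    Points are ``(offset_x + i*spacing, offset_y + j*spacing)`` clipped to
    the image.  Where a label map is given, points over background (label 0)
    are prefilled ``outside``; all other points start unlabeled (None) and
    must be supplied by the rater's assessment file.
    """
    if spacing < 1:
        raise ValidationError(f"grid spacing must be >= 1, got {spacing}")
    ox, oy = offset
    xs = [x for x in range(ox, width, spacing) if x >= 0]
    ys = [y for y in range(oy, height, spacing) if y >= 0]
    points = [(x, y) for y in ys for x in xs]
    grid = QCGrid(spacing=spacing, offset=(ox, oy), width=width, height=height, points=points)
    assessment: list[str | None] = [None] * len(points)
    if label_map is not None:
        for i, (x, y) in enumerate(points):
            if label_map[y, x] == 0:
                assessment[i] = OUTSIDE
    return grid, assessment


def qc_statistics(
    grid: QCGrid,
    assessment: Sequence[str | None],
    label_map: np.ndarray,
    mapping: Mapping[int, int],
    damage_threshold: float,
    section_nr: int = 0,
) -> tuple[QCReport, dict]:
    """Compute per-region accuracy and damage statistics for one section.

    Every in-tissue grid point is attributed to its reporting region through
    the label map and mapping.  Returns the report and an exclusion record
    ``{"section_excluded": bool, "excluded_regions": [ids]}`` listing the
    section and regions whose damage fraction exceeds the threshold.
    """
    if len(assessment) != len(grid.points):
        raise ValidationError(
            f"assessment has {len(assessment)} labels for {len(grid.points)} grid points"
        )
    unlabeled = [i for i, lab in enumerate(assessment) if lab is None]
    if unlabeled:
        raise ValidationError(
            f"{len(unlabeled)} grid points are unlabeled (first: index {unlabeled[0]})"
        )
    bad = sorted({lab for lab in assessment if lab not in LABELS})
    if bad:
        raise ValidationError(f"unknown assessment labels: {bad}; expected one of {LABELS}")

    max_label = int(label_map.max(initial=0))
    lut = mapping_lut(mapping, max_label)
    regions: dict[int, RegionQC] = {}
    in_tissue = damage_total = outside = 0
    for (x, y), lab in zip(grid.points, assessment):
        if lab == OUTSIDE:
            outside += 1
            continue
        in_tissue += 1
        rid = int(lut[label_map[y, x]])
        r = regions.setdefault(rid, RegionQC(rid))
        if lab == ACCURATE:
            r.accurate += 1
        elif lab == INACCURATE:
            r.inaccurate += 1
        elif lab == UNCERTAIN:
            r.uncertain += 1
        else:
            r.damage += 1
            damage_total += 1

    report = QCReport(
        section_nr=section_nr,
        regions=regions,
        in_tissue_points=in_tissue,
        damage_points=damage_total,
        outside_points=outside,
    )
    excluded_regions = sorted(
        rid
        for rid, r in regions.items()
        if r.damage_fraction is not None and r.damage_fraction > damage_threshold
    )
    section_excluded = (
        report.damage_fraction is not None and report.damage_fraction > damage_threshold
    )
    return report, {
        "section_excluded": section_excluded,
        "excluded_regions": excluded_regions,
    }


# ---------------------------------------------------------------------------
# assessment CSV and report TSV formats
# ---------------------------------------------------------------------------

def write_assessment_csv(
    grid: QCGrid, assessment: Sequence[str | None], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["point_index", "x", "y", "label"])
        for i, ((x, y), lab) in enumerate(zip(grid.points, assessment)):
            writer.writerow([i, x, y, lab if lab is not None else ""])


def read_assessment_csv(path: str | Path, n_points: int) -> list[str | None]:
    """Read (point_index, label) rows; missing indices stay unlabeled."""
    assessment: list[str | None] = [None] * n_points
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        try:
            idx_col = header.index("point_index")
            lab_col = header.index("label")
        except ValueError as exc:
            raise ValidationError(
                f"{path}: assessment CSV needs 'point_index' and 'label' columns"
            ) from exc
        for row in reader:
            if not row:
                continue
            i = int(row[idx_col])
            if not 0 <= i < n_points:
                raise ValidationError(f"{path}: point index {i} out of range")
            lab = row[lab_col].strip()
            assessment[i] = lab if lab else None
    return assessment


def write_qc_tsv(
    report: QCReport, path: str | Path, hierarchy: Sequence[RegionNode] | None = None
) -> None:
    names = {n.id: n.name for n in hierarchy} if hierarchy else {}
    with open(path, "w") as fh:
        fh.write("# accuracy = accurate/(accurate+inaccurate); uncertain excluded\n")
        fh.write("region_id\tregion_name\taccurate\tinaccurate\tuncertain\tdamage\taccuracy\n")
        for rid in sorted(report.regions):
            r = report.regions[rid]
            acc = "NA" if r.accuracy is None else repr(r.accuracy)
            fh.write(
                f"{rid}\t{names.get(rid, '')}\t{r.accurate}\t{r.inaccurate}\t"
                f"{r.uncertain}\t{r.damage}\t{acc}\n"
            )


def write_section_summary_tsv(
    rows: Sequence[tuple[QCReport, dict]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("section_nr\tin_tissue_points\tdamage_points\tdamage_fraction\texcluded\n")
        for report, exclusion in rows:
            frac = "NA" if report.damage_fraction is None else repr(report.damage_fraction)
            fh.write(
                f"{report.section_nr}\t{report.in_tissue_points}\t"
                f"{report.damage_points}\t{frac}\t{exclusion['section_excluded']}\n"
            )
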