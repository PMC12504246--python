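"""Regional quantification: tallies, conservation, aggregation, hemisphere masks."""

import numpy as np
import pytest

from histoatlas.anchoring import SectionAnchoring, slice_atlas
from histoatlas.atlas import collapse_hierarchy
from histoatlas.errors import ValidationError
from histoatlas.quantify import (
    LEFT,
    RIGHT,
    QuantReport,
    RegionStats,
    aggregate_reports,
    hemisphere_mask,
    quantify_section,
    resample_nearest,
)
from histoatlas.synth import make_segmentation
from histoatlas.warp import WarpMarker


def simple_label_map():
    """12x12 map: region 1 left half, region 2 right half, ring of background."""
    lm = np.zeros((12, 12), dtype=np.int64)
    lm[1:11, 1:6] = 1
    lm[1:11, 6:11] = 2
    return lm


IDENTITY = {1: 1, 2: 2}


class TestQuantifySection:
    def test_empty_segmentation_all_zero(self):
        lm = simple_label_map()
        report = quantify_section(np.zeros_like(lm), lm, IDENTITY)
        for s in report.stats.values():
            assert (s.object_pixels, s.object_count, s.load) == (0, 0, 0.0)

    def test_segmentation_equal_to_region_gives_load_one(self):
        lm = simple_label_map()
        seg = (lm == 1).astype(np.uint8)
        report = quantify_section(seg, lm, IDENTITY)
        assert report.stats[1].load == 1.0
        assert report.stats[1].object_count == 1
        assert report.stats[2].object_pixels == 0

    def test_planted_disks_recovered_exactly(self, synth_atlas, synth_series):
        atlas, hierarchy = synth_atlas
        series, _ = synth_series
        lm = slice_atlas(atlas, series.sections[2].anchoring)
        seg, truth = make_segmentation(lm, {11: 4, 111: 3}, radius=3, seed=3)
        mapping = {n.id: n.id for n in hierarchy}
        report = quantify_section(seg, lm, mapping)
        for rid in truth.counts:
            assert report.stats[rid].object_count == truth.counts[rid]
            assert report.stats[rid].object_pixels == truth.pixels[rid]

    def test_conservation_on_random_segmentations(self):
        lm = simple_label_map()
        rng = np.random.default_rng(13)
        for _ in range(100):
            seg = (rng.random(lm.shape) < 0.3).astype(np.uint8)
            report = quantify_section(seg, lm, IDENTITY)
            total = report.background.object_pixels + sum(
                s.object_pixels for s in report.stats.values()
            )
            assert total == int(seg.sum())
            # area conservation too
            assert report.background.region_pixels + sum(
                s.region_pixels for s in report.stats.values()
            ) == lm.size

    def test_monotone_in_foreground(self):
        lm = simple_label_map()
        rng = np.random.default_rng(21)
        seg = (rng.random(lm.shape) < 0.2).astype(np.uint8)
        more = seg.copy()
        more[rng.random(lm.shape) < 0.2] = 1
        r1 = quantify_section(seg, lm, IDENTITY)
        r2 = quantify_section(more, lm, IDENTITY)
        for rid in r1.stats:
            assert r2.stats[rid].object_pixels >= r1.stats[rid].object_pixels

    def test_collapse_consistency_pixels_exact_counts_ge(self, synth_atlas, synth_series):
        atlas, hierarchy = synth_atlas
        series, _ = synth_series
        lm = slice_atlas(atlas, series.sections[2].anchoring)
        rng = np.random.default_rng(5)
        seg = (rng.random(lm.shape) < 0.25).astype(np.uint8)
        leaf_mapping = {n.id: n.id for n in hierarchy}
        parent_mapping = collapse_hierarchy(hierarchy, {2, 3})  # hemispheres
        leaf_rep = quantify_section(seg, lm, leaf_mapping)
        parent_rep = quantify_section(seg, lm, parent_mapping)
        for parent in (2, 3):
            leaves = [n.id for n in hierarchy if parent_mapping[n.id] == parent]
            assert parent_rep.stats[parent].region_pixels == sum(
                leaf_rep.stats[l].region_pixels for l in leaves if l in leaf_rep.stats
            )
            assert parent_rep.stats[parent].object_pixels == sum(
                leaf_rep.stats[l].object_pixels for l in leaves if l in leaf_rep.stats
            )
            # fragments can merge across sibling leaves, never split further
            assert parent_rep.stats[parent].object_count <= sum(
                leaf_rep.stats[l].object_count for l in leaves if l in leaf_rep.stats
            )

    def test_split_mode_splits_and_centroid_mode_does_not(self):
        lm = simple_label_map()
        seg = np.zeros_like(lm, dtype=np.uint8)
        seg[5, 4:9] = 1  # one horizontal bar straddling the 1|2 boundary
        split = quantify_section(seg, lm, IDENTITY, mode="split")
        assert split.stats[1].object_count == 1 and split.stats[2].object_count == 1
        assert split.stats[1].object_pixels == 2 and split.stats[2].object_pixels == 3
        cent = quantify_section(seg, lm, IDENTITY, mode="centroid")
        # centroid at x=6 lies in region 2: the whole bar goes there
        assert cent.stats[2].object_count == 1 and cent.stats[2].object_pixels == 5
        assert cent.stats[1].object_count == 0

    def test_resampling_preserves_binarity_and_counts(self):
        lm = simple_label_map()
        seg = np.zeros((24, 24), dtype=np.uint8)
        seg[4:8, 4:8] = 1  # maps onto a 2x2 block at half resolution
        report = quantify_section(seg, lm, IDENTITY)
        assert report.total_foreground == 4
        with pytest.raises(ValidationError, match="shape"):
            quantify_section(seg, lm, IDENTITY, resample=False)

    def test_hemisphere_restriction_partitions_stats(self):
        lm = simple_label_map()
        hemi = np.zeros_like(lm, dtype=np.uint8)
        hemi[:, 6:] = RIGHT
        rng = np.random.default_rng(3)
        seg = (rng.random(lm.shape) < 0.4).astype(np.uint8)
        full = quantify_section(seg, lm, IDENTITY)
        left = quantify_section(seg, lm, IDENTITY, hemi_mask=hemi, side=LEFT)
        right = quantify_section(seg, lm, IDENTITY, hemi_mask=hemi, side=RIGHT)
        for rid in full.stats:
            assert (left.stats[rid].region_pixels + right.stats[rid].region_pixels
                    == full.stats[rid].region_pixels)
            assert (left.stats[rid].object_pixels + right.stats[rid].object_pixels
                    == full.stats[rid].object_pixels)


class TestAggregate:
    def _report(self, nr, stats):
        return QuantReport(
            section_nr=nr, mask_descriptor="none",
            stats={rid: RegionStats(rid, rp, op, oc) for rid, (rp, op, oc) in stats.items()},
            background=RegionStats(0),
            mapping_signature=frozenset({(1, 1)}),
        )

    def test_single_report_is_identity(self):
        r = self._report(1, {1: (10, 2, 1)})
        agg = aggregate_reports([r])
        assert agg[1].region_pixels == 10 and agg[1].object_pixels == 2

    def test_load_recomputed_from_summed_pixels(self):
        r1 = self._report(1, {1: (10, 2, 1)})   # load 0.2
        r2 = self._report(2, {1: (30, 24, 2)})  # load 0.8
        agg = aggregate_reports([r1, r2])
        assert agg[1].load == pytest.approx(26 / 40)  # 0.65, not mean of loads

    def test_order_invariance(self):
        r1 = self._report(1, {1: (10, 2, 1), 2: (5, 1, 1)})
        r2 = self._report(2, {1: (30, 24, 2), 2: (7, 0, 0)})
        a = aggregate_reports([r1, r2])
        b = aggregate_reports([r2, r1])
        for rid in a:
            assert (a[rid].region_pixels, a[rid].object_pixels, a[rid].object_count) == (
                b[rid].region_pixels, b[rid].object_pixels, b[rid].object_count)

    def test_mixed_mappings_rejected(self):
        r1 = self._report(1, {1: (10, 2, 1)})
        r2 = self._report(2, {1: (10, 2, 1)})
        r2.mapping_signature = frozenset({(1, 2)})
        with pytest.raises(ValidationError, match="mapping"):
            aggregate_reports([r1, r2])


class TestHemisphereMask:
    def test_partition(self, synth_atlas, synth_series):
        atlas, _ = synth_atlas
        series, _ = synth_series
        for s in series.sections:
            hm = hemisphere_mask(atlas, s.anchoring)
            assert ((hm == LEFT) | (hm == RIGHT)).all()
            assert not ((hm == LEFT) & (hm == RIGHT)).any()

    def test_midline_centered_coronal_is_balanced(self, synth_atlas, synth_series):
        atlas, _ = synth_atlas
        series, _ = synth_series
        hm = hemisphere_mask(atlas, series.sections[2].anchoring)
        left, right = int((hm == LEFT).sum()), int((hm == RIGHT).sum())
        assert abs(left - right) <= hm.shape[1]

    def test_section_entirely_left_of_midline(self, synth_atlas):
        atlas, _ = synth_atlas
        # sagittal-like plane at atlas x=5, well left of the midline at 31.5
        a = SectionAnchoring(0, 32, 32, np.array([5.0, 10, 10]),
                             np.array([0, 40.0, 0]), np.array([0, 0, 30.0]))
        assert (hemisphere_mask(atlas, a) == LEFT).all()

    def test_warp_shifts_midline_respecting_markers(self, synth_atlas, synth_series):
        atlas, _ = synth_atlas
        series, _ = synth_series
        a = series.sections[2].anchoring
        # drag the overlay 4 px to the right at the center: tissue pixels just
        # right of the old midline now sample atlas coordinates left of it
        cx = (a.width - 1) / 2
        cy = (a.height - 1) / 2
        markers = [WarpMarker((cx + 4.0, cy), (cx, cy))]
        plain = hemisphere_mask(atlas, a)
        warped = hemisphere_mask(atlas, a, markers)
        row = int(cy)
        assert int((warped[row] == LEFT).sum()) > int((plain[row] == LEFT).sum())

    def test_missing_midline_errors(self, small_atlas):
        from dataclasses import replace

        atlas = replace(small_atlas, midline=None)
        a = SectionAnchoring(0, 8, 8, np.zeros(3), np.array([15.0, 0, 0]),
                             np.array([0, 15.0, 0]))
        with pytest.raises(ValidationError, match="midline"):
            hemisphere_mask(atlas, a)


def test_resample_nearest_identity_and_halving():
    img = np.arange(16).reshape(4, 4)
    assert resample_nearest(img, (4, 4)) is img
    half = resample_nearest(img, (2, 2))
    np.testing.assert_array_equal(half, [[0, 2], [8, 10]])
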