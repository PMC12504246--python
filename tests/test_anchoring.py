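"""Cut-plane geometry, slicing oracle, propagation and anchoring recovery."""

import numpy as np
import pytest

from histoatlas.anchoring import (
    SectionAnchoring,
    SeriesDescriptor,
    SeriesSection,
    estimate_anchoring,
    load_descriptor,
    map_pixel_to_atlas,
    parse_section_number,
    propagate_series,
    save_descriptor,
    slice_atlas,
)
from histoatlas.errors import GeometryError, ValidationError

from conftest import random_anchoring


def brute_force_slice(atlas, a):
    """Per-pixel oracle: map each pixel, round half-away-from-zero, index."""
    out = np.zeros((a.height, a.width), dtype=atlas.labels.dtype)
    for y in range(a.height):
        for x in range(a.width):
            p = a.o + a.u * (x / (a.width - 1)) + a.v * (y / (a.height - 1))
            idx = tuple(
                int(np.floor(abs(c) + 0.5)) * (1 if c >= 0 else -1) for c in p
            )
            if all(0 <= i < s for i, s in zip(idx, atlas.labels.shape)):
                out[y, x] = atlas.labels[idx]
    return out


FLAT = SectionAnchoring(0, 11, 11, np.zeros(3), np.array([10.0, 0, 0]),
                        np.array([0, 10.0, 0]))


class TestSectionNumberParsing:
    @pytest.mark.parametrize(
        "filename,expected",
        [
            ("rat42_s017.png", 17),
            ("brain_s001_s002.tif", 2),  # last token wins
            ("x_s0.png", 0),
            ("deep/dir/mouse_s123.tiff", 123),
        ],
    )
    def test_parses(self, filename, expected):
        assert parse_section_number(filename) == expected

    def test_missing_token_errors_with_convention(self):
        with pytest.raises(ValidationError, match="_s"):
            parse_section_number("section7.png")


class TestPixelMapping:
    @pytest.mark.parametrize(
        "xy,expected",
        [((0, 0), (0, 0, 0)), ((10, 10), (10, 10, 0)), ((5, 2), (5, 2, 0))],
    )
    def test_flat_plane_linearity(self, xy, expected):
        np.testing.assert_allclose(map_pixel_to_atlas(FLAT, *xy), expected)

    def test_corner_exactness_random_anchorings(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a = random_anchoring(rng)
            corners = {
                (0, 0): a.o,
                (a.width - 1, 0): a.o + a.u,
                (0, a.height - 1): a.o + a.v,
                (a.width - 1, a.height - 1): a.o + a.u + a.v,
            }
            for (x, y), expected in corners.items():
                np.testing.assert_array_equal(map_pixel_to_atlas(a, x, y), expected)


class TestSliceAtlas:
    def test_constant_volume_gives_constant_map(self, small_atlas):
        from histoatlas.atlas import AtlasVolume, RegionNode

        labels = np.full((16, 16, 16), 5, dtype=np.int32)
        atlas = AtlasVolume("const", labels, hierarchy=[RegionNode(5, "all")])
        a = SectionAnchoring(0, 8, 8, np.array([4.0, 4, 4]),
                             np.array([6.0, 0, 0]), np.array([0, 6.0, 0]))
        assert (slice_atlas(atlas, a) == 5).all()

    def test_axis_aligned_plane_equals_array_extraction(self, small_atlas):
        X, Y, _ = small_atlas.labels.shape
        for k in (0, 5, 9, 15):
            a = SectionAnchoring(
                0, X, Y,
                np.array([0.0, 0.0, float(k)]),
                np.array([float(X - 1), 0, 0]),
                np.array([0, float(Y - 1), 0]),
            )
            lm = slice_atlas(small_atlas, a)
            # pixel (x, y) -> atlas (x, y, k): label map is the transposed plane
            np.testing.assert_array_equal(lm, small_atlas.labels[:, :, k].T)

    def test_fully_outside_volume_is_all_zero(self, small_atlas):
        a = SectionAnchoring(0, 8, 8, np.array([100.0, 100, 100]),
                             np.array([5.0, 0, 0]), np.array([0, 5.0, 0]))
        assert not slice_atlas(small_atlas, a).any()

    def test_matches_brute_force_oracle_on_random_anchorings(self, small_atlas):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = random_anchoring(rng)
            np.testing.assert_array_equal(
                slice_atlas(small_atlas, a), brute_force_slice(small_atlas, a)
            )

    def test_degenerate_anchoring_rejected(self):
        with pytest.raises(ValidationError, match="collinear"):
            SectionAnchoring(0, 8, 8, np.zeros(3), np.array([1.0, 0, 0]),
                             np.array([2.0, 0, 0]))


def _series(anchored: dict, nrs=(1, 2, 3, 4, 5), w=8, h=8):
    sections = []
    for nr in nrs:
        anc = None
        if nr in anchored:
            anc = SectionAnchoring.from_vector(anchored[nr], nr, w, h)
        sections.append(SeriesSection(f"x_s{nr:03d}.png", nr, w, h, anchoring=anc))
    return SeriesDescriptor("test", sections)


class TestPropagation:
    A1 = np.arange(9, dtype=float)
    A3 = np.arange(9, dtype=float) * 3 + 1

    def test_midpoint_is_componentwise_mean(self):
        out = propagate_series(_series({1: self.A1, 3: self.A3}, nrs=(1, 2, 3)))
        got = out.sections[1].anchoring.as_vector()
        np.testing.assert_allclose(got, (self.A1 + self.A3) / 2)

    def test_extrapolation_matches_closed_form(self):
        out = propagate_series(_series({1: self.A1, 3: self.A3}))
        a5 = out.sections[4].anchoring.as_vector()
        expected = self.A3 + (self.A3 - self.A1) * (5 - 3) / (3 - 1)
        np.testing.assert_allclose(a5, expected, atol=1e-12)

    def test_single_anchor_replicates(self):
        out = propagate_series(_series({3: self.A3}))
        for s in out.sections:
            np.testing.assert_array_equal(s.anchoring.as_vector(), self.A3)

    def test_anchored_sections_unchanged(self):
        out = propagate_series(_series({1: self.A1, 3: self.A3}))
        np.testing.assert_array_equal(out.sections[0].anchoring.as_vector(), self.A1)
        np.testing.assert_array_equal(out.sections[2].anchoring.as_vector(), self.A3)

    def test_shift_equivariance_in_section_nr(self):
        base = propagate_series(_series({1: self.A1, 3: self.A3}))
        shifted = propagate_series(
            _series({11: self.A1, 13: self.A3}, nrs=(11, 12, 13, 14, 15))
        )
        for s_base, s_shift in zip(base.sections, shifted.sections):
            np.testing.assert_allclose(
                s_base.anchoring.as_vector(), s_shift.anchoring.as_vector(), atol=1e-12
            )

    def test_clamped_extrapolation_replicates_edges(self):
        out = propagate_series(_series({2: self.A1, 4: self.A3}), clamp=True)
        np.testing.assert_array_equal(out.sections[0].anchoring.as_vector(), self.A1)
        np.testing.assert_array_equal(out.sections[4].anchoring.as_vector(), self.A3)

    def test_no_anchor_errors(self):
        with pytest.raises(ValidationError, match="no section is anchored"):
            propagate_series(_series({}))
        with pytest.raises(ValidationError, match="empty"):
            propagate_series(SeriesDescriptor("x", []))


class TestEstimateAnchoring:
    def test_exact_recovery_from_three_corners(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = random_anchoring(rng, width=11, height=9)
            pix = [(0.0, 0.0), (10.0, 0.0), (0.0, 8.0)]
            corr = [((x, y), map_pixel_to_atlas(a, x, y)) for x, y in pix]
            est = estimate_anchoring(corr, 11, 9)
            for name in ("o", "u", "v"):
                np.testing.assert_allclose(
                    getattr(est, name), getattr(a, name), atol=1e-9
                )

    def test_noisy_recovery_within_tolerance(self):
        rng = np.random.default_rng(7)
        a = random_anchoring(rng, width=21, height=17, scale=40.0)
        sigma = 0.5
        pix = rng.uniform([0, 0], [20, 16], size=(20, 2))
        corr = [
            ((x, y), map_pixel_to_atlas(a, x, y) + rng.normal(0, sigma, 3))
            for x, y in pix
        ]
        est = estimate_anchoring(corr, 21, 17)
        residuals = np.array(
            [map_pixel_to_atlas(est, x, y) - p for (x, y), p in corr]
        )
        assert np.sqrt((residuals**2).mean()) <= 3 * sigma
        for name in ("u", "v"):
            truth = getattr(a, name)
            err = np.linalg.norm(getattr(est, name) - truth) / np.linalg.norm(truth)
            assert err < 0.05

    def test_collinear_pixels_rejected(self):
        corr = [((float(i), float(i)), (0.0, 0.0, 0.0)) for i in range(5)]
        with pytest.raises(GeometryError, match="collinear"):
            estimate_anchoring(corr, 8, 8)

    def test_too_few_correspondences_rejected(self):
        with pytest.raises(GeometryError, match="3"):
            estimate_anchoring([((0, 0), (0, 0, 0)), ((1, 1), (1, 1, 0))], 8, 8)


class TestDescriptorRoundTrip:
    @pytest.mark.parametrize("seed", [0, 1, 7, 42, 2**31 - 1])
    def test_save_load_identity(self, seed, tmp_path_factory):
        rng = np.random.default_rng(seed)
        sections = []
        for i, nr in enumerate(sorted(rng.choice(100, size=4, replace=False))):
            anc = None
            if rng.random() < 0.7:
                anc = SectionAnchoring.from_vector(
                    rng.uniform(-50, 50, 9), int(nr), 12, 10
                )
            markers = [tuple(rng.uniform(0, 11, 4)) for _ in range(rng.integers(0, 3))]
            sections.append(
                SeriesSection(f"img_s{nr:03d}.png", int(nr), 12, 10, anc, markers)
            )
        series = SeriesDescriptor("atlas-x", sections)
        path = tmp_path_factory.mktemp("desc") / "d.json"
        save_descriptor(series, path)
        back = load_descriptor(path)
        assert back.atlas_name == series.atlas_name
        for s1, s2 in zip(series.sections, back.sections):
            assert (s1.filename, s1.nr, s1.width, s1.height) == (
                s2.filename, s2.nr, s2.width, s2.height)
            assert s1.markers == s2.markers
            if s1.anchoring is None:
                assert s2.anchoring is None
            else:
                np.testing.assert_array_equal(
                    s1.anchoring.as_vector(), s2.anchoring.as_vector()
                )
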