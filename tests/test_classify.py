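"""Recognition pipeline stages and end-to-end counting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from ctcscope import (
    CHANNELS,
    FOUR_COLOR_RULES,
    GroundTruthCell,
    PhenotypeRule,
    PipelineConfig,
    SimulationConfig,
    SnapSet,
    SyntheticScene,
    circle_area_px,
    classify_and_count,
    compose_mask,
    extract_components,
    filter_by_area,
    median_filter,
    merge_colorize,
    otsu_threshold,
    window_level,
)

from conftest import render_snapset


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------


def brute_force_median(image: np.ndarray, k: int) -> np.ndarray:
    """Sliding-window median with edge replication."""
    pad = k // 2
    padded = np.pad(image, pad, mode="edge")
    out = np.empty_like(image)
    for i in range(image.shape[0]):
        for j in range(image.shape[1]):
            out[i, j] = np.median(padded[i : i + k, j : j + k])
    return out


def brute_force_otsu(image: np.ndarray) -> int:
    """Exhaustive between-class-variance maximization, lowest tie wins."""
    flat = image.ravel().astype(np.float64)
    n = flat.size
    best_t, best_v = None, -1.0
    for t in range(int(flat.min()), int(flat.max()) + 1):
        c0 = flat[flat <= t]
        c1 = flat[flat > t]
        if c0.size == 0 or c1.size == 0:
            continue
        v = (c0.size / n) * (c1.size / n) * (c0.mean() - c1.mean()) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


def flood_fill_components(mask: np.ndarray) -> list[int]:
    """8-connected component areas via explicit flood fill."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    areas = []
    for si in range(mask.shape[0]):
        for sj in range(mask.shape[1]):
            if not mask[si, sj] or seen[si, sj]:
                continue
            stack, area = [(si, sj)], 0
            seen[si, sj] = True
            while stack:
                i, j = stack.pop()
                area += 1
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if (
                            0 <= ni < mask.shape[0]
                            and 0 <= nj < mask.shape[1]
                            and mask[ni, nj]
                            and not seen[ni, nj]
                        ):
                            seen[ni, nj] = True
                            stack.append((ni, nj))
            areas.append(area)
    return sorted(areas)


# ---------------------------------------------------------------------------
# Stage tests
# ---------------------------------------------------------------------------


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((7, 7), 42, dtype=np.uint8)
        assert np.array_equal(median_filter(img, 3), img)

    def test_hot_pixel_rejected(self):
        img = np.zeros((9, 9), dtype=np.uint16)
        img[4, 4] = 60000
        assert median_filter(img, 3).max() == 0

    def test_kernel_one_is_identity(self, rng):
        img = rng.integers(0, 256, (8, 8), dtype=np.uint8)
        assert np.array_equal(median_filter(img, 1), img)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            img = rng.integers(0, 256, (9, 9), dtype=np.uint8)
            assert np.array_equal(median_filter(img, 3), brute_force_median(img, 3))

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            median_filter(np.zeros((4, 4), dtype=np.uint8), 2)


class TestWindowLevel:
    def test_full_span_identity(self):
        img = np.linspace(0, 255, 256).astype(np.uint8).reshape(16, 16)
        out = window_level(img, 0, 100)
        assert np.abs(out.astype(int) - img.astype(int)).max() <= 1

    def test_two_valued_image_maps_to_extremes(self):
        img = np.array([[10, 200]] * 8, dtype=np.uint8)
        out = window_level(img, 0, 100)
        assert set(out.ravel().tolist()) == {0, 255}

    def test_ramp_closed_form(self):
        """25th/75th percentile anchors on a 0..255 ramp."""
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        out = window_level(img, 25, 75)
        lo, hi = np.percentile(img, [25, 75])
        assert (out[img <= int(lo)] == 0).all()
        assert (out[img >= int(np.ceil(hi))] == 255).all()
        mid = 128
        expected = (mid - lo) / (hi - lo) * 255
        assert abs(int(out[img == mid][0]) - expected) <= 1

    def test_degenerate_image_returned_unchanged(self, caplog):
        img = np.full((5, 5), 7, dtype=np.uint8)
        with caplog.at_level("WARNING", logger="ctcscope.classify"):
            out = window_level(img, 1, 99)
        assert np.array_equal(out, img)
        assert any("degenerate" in r.message for r in caplog.records)

    @settings(derandomize=True, max_examples=30)
    @given(arrays(np.uint8, (6, 6), elements=st.integers(0, 255)))
    def test_mapping_is_monotone(self, img):
        out = window_level(img, 5, 95)
        flat_in, flat_out = img.ravel(), out.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert (np.diff(flat_out[order].astype(int)) >= 0).all()


class TestComposeMask:
    def _snap(self, pixels: dict[str, int], dtype=np.uint8) -> SnapSet:
        return SnapSet(
            images={ch: np.full((4, 4), v, dtype=dtype) for ch, v in pixels.items()}
        )

    def test_required_channels_add(self):
        snap = self._snap({"blue": 100, "orange": 50})
        rule = PhenotypeRule("CTC", {"blue", "orange"}, min_diameter_um=7)
        assert compose_mask(snap, rule)[0, 0] == 150

    def test_saturates_at_dtype_max(self):
        snap = self._snap({"blue": 200, "green": 200, "orange": 200, "red": 255})
        rule = PhenotypeRule("CTC", {"blue", "green", "orange"}, {"red"}, 7)
        assert compose_mask(snap, rule)[0, 0] == 255

    @pytest.mark.parametrize(
        "pixels,expected",
        [
            ({"blue": 100, "green": 0, "orange": 0, "red": 100}, 200),
            ({"blue": 100, "green": 200, "orange": 200, "red": 100}, 0),
        ],
    )
    def test_widened_arithmetic(self, pixels, expected):
        rule = PhenotypeRule("WBC", {"blue", "red"}, {"green", "orange"}, 2.5)
        assert compose_mask(self._snap(pixels), rule)[0, 0] == expected

    def test_missing_channel_named_in_error(self):
        snap = self._snap({"blue": 1})
        rule = PhenotypeRule("WBC", {"blue", "red"}, min_diameter_um=2.5)
        with pytest.raises(KeyError, match="red"):
            compose_mask(snap, rule)


class TestOtsu:
    def test_tie_breaks_to_smallest_threshold(self):
        img = np.array([10] * 50 + [200] * 50, dtype=np.uint8).reshape(10, 10)
        t, separable = otsu_threshold(img)
        assert (t, separable) == (10, True)

    def test_constant_image_not_separable(self):
        t, separable = otsu_threshold(np.full((6, 6), 99, dtype=np.uint8))
        assert (t, separable) == (99, False)

    def test_matches_exhaustive_maximizer(self, rng):
        for _ in range(30):
            img = rng.integers(0, 256, (16, 16), dtype=np.uint8)
            t, separable = otsu_threshold(img)
            assert separable
            assert t == brute_force_otsu(img)

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError):
            otsu_threshold(np.zeros((0, 0), dtype=np.uint8))


class TestComponents:
    def test_empty_mask(self):
        assert extract_components(np.zeros((8, 8), dtype=bool)) == []

    def test_two_disjoint_squares(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        cells = extract_components(mask)
        assert sorted(c.area_px for c in cells) == [9, 9]

    def test_diagonal_touch_is_one_component(self):
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = mask[1, 1] = True
        assert len(extract_components(mask)) == 1

    def test_border_components_kept(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[0, :3] = True
        assert len(extract_components(mask)) == 1

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(5):
            mask = rng.random((20, 20)) < 0.35
            cells = extract_components(mask)
            assert sorted(c.area_px for c in cells) == flood_fill_components(mask)

    def test_centroid_is_pixel_centre_mean(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 1:4] = True
        (cell,) = extract_components(mask)
        assert cell.centroid_px == (2.0, 2.0)
        assert cell.bounding_box == (1, 2, 4, 3)


class TestFilterByArea:
    def test_strictly_greater_gate(self):
        mask = np.zeros((40, 40), dtype=bool)
        cells = extract_components(_blob_mask([(5, 5, 107), (25, 25, 108)]))
        kept = filter_by_area(cells, 107)
        assert [c.area_px for c in kept] == [108]

    def test_gate_zero_is_identity_and_conserves(self, rng):
        mask = rng.random((30, 30)) < 0.3
        cells = extract_components(mask)
        assert filter_by_area(cells, 0) == cells
        assert filter_by_area(cells, np.inf) == []


def _blob_mask(specs):
    """Rectangular blobs of requested areas at given top-left corners."""
    mask = np.zeros((60, 60), dtype=bool)
    for i, j, area in specs:
        w = int(np.ceil(np.sqrt(area)))
        h = int(np.ceil(area / w))
        flat = np.zeros(w * h, dtype=bool)
        flat[:area] = True
        mask[i : i + h, j : j + w] = flat.reshape(h, w)
    return mask


# ---------------------------------------------------------------------------
# End-to-end classification
# ---------------------------------------------------------------------------


class TestClassifyAndCount:
    def test_noise_free_counts_exact(self, small_optics, small_scene):
        cfg = SimulationConfig(optics=small_optics, noise=False)
        snap = render_snapset(small_scene, cfg)
        report, masks = classify_and_count(snap, FOUR_COLOR_RULES, small_optics)
        assert report.totals == {"CTC": 3, "WBC": 20, "NUCLEATED_OTHER": 15}
        assert set(masks) == {"CTC", "WBC", "NUCLEATED_OTHER"}

    def test_raised_gate_drops_ctcs_without_wbc_leak(self, small_optics, small_scene):
        """CTCs failing the size gate must not reappear as WBCs."""
        cfg = SimulationConfig(optics=small_optics, noise=False)
        snap = render_snapset(small_scene, cfg)
        rules = [
            PhenotypeRule("CTC", {"blue", "green", "orange"}, {"red"}, 20.0, 0),
            PhenotypeRule("WBC", {"blue", "red"}, {"green", "orange"}, 2.5, 1),
        ]
        report, _ = classify_and_count(snap, rules, small_optics)
        assert report.totals["CTC"] == 0
        assert report.totals["WBC"] == 20

    def test_counts_monotone_in_min_diameter(self, small_optics, small_scene):
        cfg = SimulationConfig(optics=small_optics, noise=False)
        snap = render_snapset(small_scene, cfg)
        previous = None
        for d in (2.5, 7.0, 9.0, 11.0, 15.0):
            rules = [PhenotypeRule("CTC", {"blue", "green", "orange"}, {"red"}, d, 0)]
            report, _ = classify_and_count(snap, rules, small_optics)
            if previous is not None:
                assert report.totals["CTC"] <= previous
            previous = report.totals["CTC"]

    def test_overlapping_ctcs_merge_into_one(self, small_optics):
        """Two tumor cells closer than one radius form a single contour."""
        cells = (
            GroundTruthCell("CTC", (70.0, 50.0), 10.0,
                            {"blue": 1e5, "green": 5e4, "orange": 3.5e3}),
            GroundTruthCell("CTC", (74.0, 50.0), 10.0,
                            {"blue": 1e5, "green": 5e4, "orange": 3.5e3}),
        )
        scene = SyntheticScene(small_optics.fov_um, cells, seed=0)
        cfg = SimulationConfig(optics=small_optics, noise=False)
        snap = render_snapset(scene, cfg)
        report, _ = classify_and_count(snap, FOUR_COLOR_RULES, small_optics)
        assert report.totals["CTC"] == 1

    def test_uniform_offset_below_window_low_leaves_counts_unchanged(
        self, small_optics, small_scene
    ):
        cfg = SimulationConfig(optics=small_optics, noise=False)
        snap = render_snapset(small_scene, cfg)
        shifted = SnapSet(
            images={ch: img + 150 for ch, img in snap.images.items()},
            snap_id=snap.snap_id,
        )
        base, _ = classify_and_count(snap, FOUR_COLOR_RULES, small_optics)
        moved, _ = classify_and_count(shifted, FOUR_COLOR_RULES, small_optics)
        assert base.totals == moved.totals

    def test_duplicate_priorities_rejected(self, small_optics, small_scene):
        cfg = SimulationConfig(optics=small_optics, noise=False)
        snap = render_snapset(small_scene, cfg)
        rules = [
            PhenotypeRule("A", {"blue"}, min_diameter_um=2.5, priority=0),
            PhenotypeRule("B", {"red"}, min_diameter_um=2.5, priority=0),
        ]
        with pytest.raises(ValueError):
            classify_and_count(snap, rules, small_optics)


class TestMergeColorize:
    def test_single_channel_blue_tint(self):
        img = np.arange(64, dtype=np.uint8).reshape(8, 8)
        snap = SnapSet(images={"blue": img})
        rgb = merge_colorize(snap, channel_colors={"blue": (0.0, 0.0, 1.0)})
        assert np.array_equal(rgb[..., 2], img)
        assert rgb[..., 0].max() == 0 and rgb[..., 1].max() == 0

    def test_all_zero_channels_black(self):
        snap = SnapSet(images={ch: np.zeros((6, 6), dtype=np.uint8) for ch in CHANNELS})
        assert merge_colorize(snap).max() == 0

    def test_channel_swap_permutes_planes(self):
        a = np.random.default_rng(0).integers(0, 255, (6, 6), dtype=np.uint8)
        colors = {"green": (0.0, 1.0, 0.0), "red": (1.0, 0.0, 0.0)}
        rgb1 = merge_colorize(SnapSet(images={"green": a}), channel_colors=colors)
        rgb2 = merge_colorize(SnapSet(images={"red": a}), channel_colors=colors)
        assert np.array_equal(rgb1[..., 1], rgb2[..., 0])


class TestRuleValidation:
    def test_overlapping_required_excluded_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeRule("X", {"blue"}, {"blue"}, 5.0)

    def test_empty_required_rejected(self):
        with pytest.raises(ValueError):
            PhenotypeRule("X", frozenset(), {"red"}, 5.0)
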