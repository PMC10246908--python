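import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ivhypoxia import (
    CellSample,
    RegionMask,
    bivariate_histogram,
    classify_gfp_levels,
    expand_roi,
    gfp_metrics,
    pearson,
    sample_cells,
    segment_tumor_roi,
    segment_vessels,
    vascular_density,
    vessel_distance_map,
)
from ivhypoxia.roi_vasculature import cells_to_frame, resolve_threshold

from conftest import brute_force_distance_map


def mask_of(arr, px=1.0, kind="tumor_roi"):
    return RegionMask(np.asarray(arr, bool), px, kind)


class TestSegmentTumor:
    def test_constant_below_threshold_gives_empty_flagged_mask(self):
        with pytest.warns(UserWarning, match="empty"):
            roi = segment_tumor_roi(np.ones((32, 32)), 5.0)
        assert roi.is_empty and "empty_mask" in roi.flags

    def test_recovers_ground_truth_exactly(self, small_scene):
        params, image, truth = small_scene
        roi = segment_tumor_roi(
            image.channel("DsRed"), 50.0, pixel_size_um=params.pixel_size_um
        )
        inter = np.logical_and(roi.mask, truth.tumor_mask.mask).sum()
        union = np.logical_or(roi.mask, truth.tumor_mask.mask).sum()
        assert inter / union == 1.0

    def test_otsu_threshold_lies_between_modes(self):
        img = np.concatenate([np.full(500, 10.0), np.full(500, 200.0)])
        img = img.reshape(25, 40)
        thr = resolve_threshold(img, "otsu")
        assert 10.0 < thr < 200.0

    def test_percentile_spec_uses_background(self):
        img = np.zeros((10, 10))
        bg = np.arange(100, dtype=float)
        assert resolve_threshold(img, ("percentile", 99), background=bg) == pytest.approx(
            np.percentile(bg, 99)
        )

    def test_small_objects_removed(self):
        img = np.zeros((64, 64))
        img[:20, :20] = 100.0  # 400 px object survives
        img[40:42, 40:42] = 100.0  # 4 px speck removed
        roi = segment_tumor_roi(img, 50.0, min_area_px=50)
        assert roi.mask[:20, :20].all()
        assert not roi.mask[40:42, 40:42].any()


class TestGfpMetrics:
    def test_all_positive_gives_fraction_one(self):
        roi = mask_of(np.ones((8, 8)))
        m = gfp_metrics(np.full((8, 8), 10.0), roi, 5.0)
        assert m.gfp_positive_fraction == 1.0

    def test_hand_computed_four_pixel_mask(self):
        gfp = np.zeros((2, 4))
        gfp[0] = [0.0, 0.0, 10.0, 10.0]
        roi = mask_of(np.array([[1, 1, 1, 1], [0, 0, 0, 0]]))
        m = gfp_metrics(gfp, roi, 5.0)
        assert m.gfp_positive_fraction == 0.5
        assert m.mean_gfp_intensity == 5.0
        assert m.n_tumor_pixels == 4

    def test_matches_brute_force_loop(self, rng):
        gfp = rng.uniform(0, 100, (20, 20))
        roi_arr = rng.uniform(size=(20, 20)) > 0.5
        m = gfp_metrics(gfp, mask_of(roi_arr), 40.0)
        n_pos = sum(
            1 for y in range(20) for x in range(20) if roi_arr[y, x] and gfp[y, x] > 40.0
        )
        total = int(roi_arr.sum())
        s = sum(gfp[y, x] for y in range(20) for x in range(20) if roi_arr[y, x])
        assert m.gfp_positive_fraction == pytest.approx(n_pos / total)
        assert m.mean_gfp_intensity == pytest.approx(s / total)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            gfp_metrics(np.ones((4, 4)), mask_of(np.zeros((4, 4))), 0.5)


class TestExpandRoi:
    def test_zero_distance_is_identity(self):
        roi = mask_of(np.eye(8))
        out = expand_roi(roi, 0.0)
        np.testing.assert_array_equal(out.mask, roi.mask)
        assert out.kind == "expanded_tumor_roi"

    def test_single_pixel_disk_pixel_count(self):
        # DERIVED oracle: brute-force disk enumeration.
        arr = np.zeros((301, 301), bool)
        arr[150, 150] = True
        out = expand_roi(mask_of(arr, px=1.0), 100.0)
        expected = sum(
            1
            for dy in range(-100, 101)
            for dx in range(-100, 101)
            if dy * dy + dx * dx <= 100 * 100
        )
        assert out.n_pixels == expected

    def test_always_superset(self, rng):
        arr = rng.uniform(size=(40, 40)) > 0.9
        roi = mask_of(arr, px=2.0)
        out = expand_roi(roi, 15.0)
        assert np.all(out.mask[arr])

    def test_sequential_dilation_vs_distance_map(self):
        # DERIVED oracle: brute-force distance map. Two 50-um dilations
        # cover everything strictly inside 100 um and nothing beyond
        # 100 um plus one discretization step.
        arr = np.zeros((260, 260), bool)
        arr[120:140, 120:140] = True
        roi = mask_of(arr)
        twice = expand_roi(expand_roi(roi, 50.0), 50.0)
        dist = brute_force_distance_map(arr, 1.0)
        assert np.all(twice.mask[dist <= 99.0])
        assert np.all(dist[twice.mask] <= 101.0)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            expand_roi(mask_of(np.ones((4, 4))), -1.0)


class TestSegmentVessels:
    def test_zero_image_gives_empty_mask(self):
        assert segment_vessels(np.zeros((64, 64))).is_empty

    def test_recovers_scene_vessels(self, small_scene):
        params, image, truth = small_scene
        out = segment_vessels(
            image.channel("APC"), pixel_size_um=params.pixel_size_um
        )
        gt = truth.vessel_mask.mask
        dice = 2 * (out.mask & gt).sum() / (out.mask.sum() + gt.sum())
        assert dice >= 0.8

    def test_mask_subset_of_foreground(self, small_scene):
        params, image, _ = small_scene
        apc = image.channel("APC")
        out = segment_vessels(apc, pixel_size_um=params.pixel_size_um)
        assert np.all(apc[out.mask] > np.percentile(apc, 50))

    def test_window_larger_than_image_errors(self):
        with pytest.raises(ValueError, match="window"):
            segment_vessels(np.random.default_rng(0).uniform(size=(32, 32)),
                            adaptive_window_px=65)


class TestVascularDensity:
    def test_full_coverage_is_one(self):
        v = mask_of(np.ones((6, 6)), kind="vessel")
        e = mask_of(np.ones((6, 6)), kind="expanded_tumor_roi")
        assert vascular_density(v, e) == 1.0

    def test_no_vessels_is_zero(self):
        v = mask_of(np.zeros((6, 6)), kind="vessel")
        e = mask_of(np.ones((6, 6)), kind="expanded_tumor_roi")
        assert vascular_density(v, e) == 0.0

    def test_matches_brute_force_ratio(self, rng):
        v_arr = rng.uniform(size=(15, 15)) > 0.7
        e_arr = rng.uniform(size=(15, 15)) > 0.3
        if not e_arr.any():
            e_arr[0, 0] = True
        got = vascular_density(mask_of(v_arr, kind="vessel"), mask_of(e_arr))
        count = sum(
            1 for y in range(15) for x in range(15) if v_arr[y, x] and e_arr[y, x]
        )
        assert got == pytest.approx(count / e_arr.sum())

    def test_empty_roi_errors(self):
        with pytest.raises(ValueError):
            vascular_density(mask_of(np.ones((4, 4))), mask_of(np.zeros((4, 4))))


class TestDistanceMap:
    def test_four_adjacent_pixel_distance(self):
        arr = np.zeros((5, 5), bool)
        arr[2, 2] = True
        d = vessel_distance_map(mask_of(arr, kind="vessel"))
        assert d[2, 3] == pytest.approx(1.0)
        assert d[3, 3] == pytest.approx(np.sqrt(2))
        assert d[2, 2] == 0.0

    def test_scales_with_pixel_size(self):
        arr = np.zeros((5, 5), bool)
        arr[2, 2] = True
        d = vessel_distance_map(mask_of(arr, px=2.5, kind="vessel"))
        assert d[2, 4] == pytest.approx(5.0)

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(5):
            arr = rng.uniform(size=(48, 48)) > 0.98
            if not arr.any():
                arr[10, 10] = True
            d = vessel_distance_map(mask_of(arr, px=1.5, kind="vessel"))
            np.testing.assert_allclose(
                d, brute_force_distance_map(arr, 1.5), atol=1e-9
            )

    def test_empty_mask_warns_and_returns_inf(self):
        with pytest.warns(UserWarning, match="empty"):
            d = vessel_distance_map(mask_of(np.zeros((4, 4)), kind="vessel"))
        assert np.all(np.isinf(d))

    def test_lipschitz_per_pixel_step(self, rng):
        arr = rng.uniform(size=(32, 32)) > 0.95
        if not arr.any():
            arr[5, 5] = True
        px = 1.186
        d = vessel_distance_map(mask_of(arr, px=px, kind="vessel"))
        step = np.sqrt(2) * px + 1e-9
        assert np.all(np.abs(np.diff(d, axis=0)) <= step)
        assert np.all(np.abs(np.diff(d, axis=1)) <= step)


class TestSampleCells:
    def test_full_mask_grid_count(self):
        # DERIVED oracle: grid enumeration (rows/cols 0,20,...,80 -> 5x5).
        roi = mask_of(np.ones((100, 100)))
        cells = sample_cells(roi, np.zeros((100, 100)), np.zeros((100, 100)), 20.0)
        assert len(cells) == 25
        assert {(c.y_px, c.x_px) for c in cells} == {
            (y, x) for y in range(0, 100, 20) for x in range(0, 100, 20)
        }

    def test_empty_mask_gives_no_cells(self):
        roi = mask_of(np.zeros((50, 50)))
        assert sample_cells(roi, np.zeros((50, 50)), np.zeros((50, 50))) == []

    def test_all_samples_inside_mask(self, rng):
        arr = rng.uniform(size=(80, 80)) > 0.6
        roi = mask_of(arr, px=2.0)
        cells = sample_cells(roi, rng.uniform(size=(80, 80)), np.zeros((80, 80)), 20.0)
        assert all(arr[c.y_px, c.x_px] for c in cells)

    def test_subpixel_spacing_rejected(self):
        roi = mask_of(np.ones((10, 10)), px=10.0)
        with pytest.raises(ValueError):
            sample_cells(roi, np.zeros((10, 10)), np.zeros((10, 10)), 2.0)

    def test_records_intensity_and_distance(self):
        roi = mask_of(np.ones((4, 4)))
        gfp = np.arange(16, dtype=float).reshape(4, 4)
        dmap = 2.0 * gfp
        cells = sample_cells(roi, gfp, dmap, 2.0)
        for c in cells:
            assert c.gfp_intensity == gfp[c.y_px, c.x_px]
            assert c.distance_um == dmap[c.y_px, c.x_px]


class TestBivariateHistogram:
    def test_single_cell_single_bin(self):
        cells = [CellSample(0, 0, 5.0, 15.0)]
        h = bivariate_histogram(cells, np.array([0, 10, 20]), np.array([0, 4, 8]))
        assert h.sum() == 1.0
        assert h[1, 1] == 1.0

    def test_normalization(self, rng):
        cells = [
            CellSample(0, 0, rng.uniform(0, 10), rng.uniform(0, 100))
            for _ in range(200)
        ]
        h = bivariate_histogram(cells, np.linspace(0, 100, 11), np.linspace(0, 10, 6))
        assert h.sum() == pytest.approx(1.0)

    def test_matches_brute_force_binning(self, rng):
        # DERIVED oracle: explicit double loop over bins.
        d_edges = np.linspace(0, 50, 6)
        i_edges = np.linspace(0, 20, 5)
        cells = [
            CellSample(0, 0, rng.uniform(0, 20), rng.uniform(0, 50))
            for _ in range(1000)
        ]
        h = bivariate_histogram(cells, d_edges, i_edges)
        brute = np.zeros((5, 4))
        for c in cells:
            for i in range(5):
                hi_d = d_edges[i + 1]
                in_d = (d_edges[i] <= c.distance_um < hi_d) or (
                    i == 4 and c.distance_um == hi_d
                )
                if not in_d:
                    continue
                for j in range(4):
                    hi_i = i_edges[j + 1]
                    if (i_edges[j] <= c.gfp_intensity < hi_i) or (
                        j == 3 and c.gfp_intensity == hi_i
                    ):
                        brute[i, j] += 1
        np.testing.assert_allclose(h, brute / brute.sum())

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            bivariate_histogram([], np.array([0, 1]), np.array([0, 1]))


class TestClassifyLevels:
    def test_boundary_is_moderate(self):
        cells = classify_gfp_levels([CellSample(0, 0, 5.0, 0.0)], 5.0, 10.0)
        assert cells[0].gfp_level == "moderate"

    def test_all_below_low_cut(self):
        cells = [CellSample(0, 0, v, 0.0) for v in (0.0, 1.0, 2.0)]
        out = classify_gfp_levels(cells, 5.0, 10.0)
        assert all(c.gfp_level == "low" for c in out)

    def test_counts_match_brute_force(self, rng):
        cells = [CellSample(0, 0, rng.uniform(0, 15), 0.0) for _ in range(500)]
        out = classify_gfp_levels(cells, 5.0, 10.0)
        counts = {
            lvl: sum(c.gfp_level == lvl for c in out)
            for lvl in ("low", "moderate", "high")
        }
        brute = {"low": 0, "moderate": 0, "high": 0}
        for c in cells:
            if c.gfp_intensity < 5.0:
                brute["low"] += 1
            elif c.gfp_intensity < 10.0:
                brute["moderate"] += 1
            else:
                brute["high"] += 1
        assert counts == brute

    def test_inverted_cuts_rejected(self):
        with pytest.raises(ValueError):
            classify_gfp_levels([], 10.0, 5.0)


class TestGradientRecovery:
    def test_gfp_distance_correlation_positive_on_gradient_scenes(self, small_scene):
        params, image, truth = small_scene
        roi = segment_tumor_roi(image.channel("DsRed"), 50.0,
                                pixel_size_um=params.pixel_size_um)
        vessels = segment_vessels(image.channel("APC"),
                                  pixel_size_um=params.pixel_size_um)
        dmap = vessel_distance_map(vessels)
        cells = sample_cells(roi, image.channel("GFP"), dmap, 20.0)
        frame = cells_to_frame(cells)
        frame = frame[np.isfinite(frame.distance_um)]
        r = pearson(frame.gfp_intensity, frame.distance_um).r
        assert r > 0.3


@given(
    low=st.floats(0, 50, allow_nan=False),
    span=st.floats(0, 50, allow_nan=False),
    value=st.floats(0, 120, allow_nan=False),
)
@settings(max_examples=200, deadline=None)
def test_classification_halfopen_property(low, span, value):
    high = low + span
    out = classify_gfp_levels([CellSample(0, 0, value, 0.0)], low, high)[0]
    if value < low:
        assert out.gfp_level == "low"
    elif value < high:
        assert out.gfp_level == "moderate"
    else:
        assert out.gfp_level == "high"
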