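import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from algacyto import (
    FluorescenceField,
    SceneSpec,
    SegmentationParams,
    assign_cells,
    binarize_and_clean,
    enhance_contrast,
    optimal_threshold,
    render_scene,
    segment_field,
    to_grayscale,
)
from algacyto.errors import ConversionError, DegenerateHistogramError

from .conftest import exhaustive_bcv_threshold


class TestGrayscale:
    def test_single_channel_mode_is_identity_on_2d(self, rng):
        img = rng.integers(0, 256, (10, 10)).astype(np.uint8)
        out = to_grayscale(img, "single-channel")
        np.testing.assert_array_equal(out, img)

    def test_gray_rgb_pixel_is_a_luminosity_fixed_point(self):
        img = np.full((2, 2, 3), 100, np.uint8)
        out = to_grayscale(img, "luminosity")
        # weights sum to 0.9999, so a gray pixel maps to ~its own value
        np.testing.assert_allclose(out, 100.0, rtol=1e-3)

    def test_max_channel_takes_per_pixel_maximum(self):
        img = np.array([[[10, 200, 30]]], np.uint8)
        assert to_grayscale(img, "max-channel")[0, 0] == 200

    def test_single_channel_mode_rejects_rgb(self):
        with pytest.raises(ConversionError):
            to_grayscale(np.zeros((4, 4, 3), np.uint8), "single-channel")


class TestEnhanceContrast:
    def test_constant_image_returned_unchanged(self):
        img = np.full((8, 8), 7.0)
        np.testing.assert_array_equal(enhance_contrast(img, 1, 99, 255), img)

    def test_full_range_stretch_is_identity(self):
        img = np.arange(256, dtype=np.uint8).reshape(16, 16)
        np.testing.assert_allclose(enhance_contrast(img, 0, 100, 255), img)

    def test_affine_map_endpoints_and_midpoint(self):
        img = np.arange(10, 61, dtype=float).reshape(1, -1)
        out = enhance_contrast(img, 0, 100, 255)
        assert out.min() == 0.0
        assert out.max() == 255.0
        mid = out[0, list(img[0]).index(35.0)]
        assert mid == pytest.approx((35 - 10) / 50 * 255)  # 127.5, unrounded


class TestOptimalThreshold:
    def test_matches_exhaustive_scan_on_random_images(self, rng):
        for _ in range(20):
            img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
            assert optimal_threshold(img) == exhaustive_bcv_threshold(img)

    def test_agrees_with_independent_otsu_implementation(self, rng):
        from skimage.filters import threshold_otsu

        for _ in range(10):
            img = rng.integers(0, 256, (48, 48)).astype(np.uint8)
            binwidth = (img.max() - img.min()) / 256
            assert abs(optimal_threshold(img) - threshold_otsu(img, nbins=256)) <= 1.5 * binwidth

    def test_two_value_tie_breaks_to_lowest_bin(self):
        img = np.tile([0, 255], 32).astype(np.uint8).reshape(8, 8)
        t = optimal_threshold(img)
        assert 0 < t < 1  # center of the 0-adjacent bin
        assert t == exhaustive_bcv_threshold(img)

    def test_separates_two_well_separated_modes(self, rng):
        vals = np.concatenate([rng.normal(30, 5, 2000), rng.normal(200, 5, 2000)])
        img = np.clip(vals, 0, 255).reshape(40, 100)
        t = optimal_threshold(img)
        assert (vals[:2000] < t).all() and (vals[2000:] > t).all()
        # the empty valley is a tie plateau; the oracle's pick also separates
        t_oracle = exhaustive_bcv_threshold(img)
        assert (vals[:2000] < t_oracle).all() and (vals[2000:] > t_oracle).all()

    def test_constant_image_raises(self):
        with pytest.raises(DegenerateHistogramError):
            optimal_threshold(np.full((4, 4), 9.0))


class TestBinarizeAndClean:
    def _blob_image(self, n_pixels):
        img = np.zeros((12, 12))
        img.ravel()[[13, 14, 15, 26, 27][:n_pixels]] = 10.0
        return img

    def test_blob_below_minimum_removed(self):
        out = binarize_and_clean(self._blob_image(3), 5.0, min_object_pixels=5)
        assert not out.any()

    def test_blob_at_exact_minimum_kept(self):
        out = binarize_and_clean(self._blob_image(5), 5.0, min_object_pixels=5)
        assert out.sum() == 5

    def test_threshold_is_strict(self):
        img = np.array([[5.0, 5.1]])
        out = binarize_and_clean(img, 5.0, min_object_pixels=1)
        assert out.tolist() == [[False, True]]

    def test_cleaning_never_adds_foreground_and_is_monotone(self, rng):
        img = rng.random((64, 64))
        t = 0.7
        before = (img > t).sum()
        counts = []
        for m in (1, 3, 6, 12):
            cleaned = binarize_and_clean(img, t, min_object_pixels=m)
            assert cleaned.sum() <= before
            counts.append(assign_cells(cleaned).n_cells)
        assert counts == sorted(counts, reverse=True)


class TestAssignCells:
    def test_all_background_gives_zero_cells(self):
        mask = assign_cells(np.zeros((5, 5), bool))
        assert mask.n_cells == 0

    def test_diagonal_pixels_split_by_connectivity(self):
        binary = np.zeros((4, 4), bool)
        binary[1, 1] = binary[2, 2] = True
        assert assign_cells(binary, connectivity=4).n_cells == 2
        assert assign_cells(binary, connectivity=8).n_cells == 1

    def test_labels_contiguous_and_in_raster_scan_order(self, rng):
        binary = rng.random((64, 64)) > 0.9
        mask = assign_cells(binary)
        labels = mask.labels
        present = np.unique(labels)
        np.testing.assert_array_equal(present, np.arange(mask.n_cells + 1))
        firsts = [np.flatnonzero(labels.ravel() == k)[0] for k in range(1, mask.n_cells + 1)]
        assert firsts == sorted(firsts)

    def test_counts_fifty_separated_disks(self):
        field, truth = render_scene(
            SceneSpec(image_shape=(512, 512), n_cells=50, noise_sd=0.0, seed=3)
        )
        binary = field.chl_raw > 20
        assert assign_cells(binary).n_cells == 50


class TestSegmentField:
    def test_lipid_channel_never_triggers_detection(self):
        chl = np.zeros((64, 64), np.uint8)
        lipid = np.full((64, 64), 200, np.uint8)
        field = FluorescenceField("f", chl, lipid)
        with pytest.warns(UserWarning):
            mask = segment_field(field)
        assert mask.n_cells == 0

    def test_segmentation_invariant_to_lipid_channel(self, small_scene, rng):
        _, field, _ = small_scene
        mask1 = segment_field(field)
        scrambled = FluorescenceField(
            field.field_id,
            field.chl_raw,
            rng.integers(0, 256, field.shape).astype(np.uint8),
            bit_depth=field.bit_depth,
        )
        mask2 = segment_field(scrambled)
        np.testing.assert_array_equal(mask1.labels, mask2.labels)

    def test_deterministic_for_identical_inputs(self, small_scene):
        _, field, _ = small_scene
        m1, m2 = segment_field(field), segment_field(field)
        np.testing.assert_array_equal(m1.labels, m2.labels)

    def test_recovers_ground_truth_cell_count(self, small_scene):
        _, field, truth = small_scene
        assert segment_field(field).n_cells == len(truth)

    def test_min_object_pixels_above_largest_cell_removes_everything(self, small_scene):
        _, field, truth = small_scene
        params = SegmentationParams(min_object_pixels=int(truth["pixel_count"].max()) + 1)
        assert segment_field(field, params).n_cells == 0

    def test_blank_noisy_field_yields_no_cells(self):
        field, _ = render_scene(SceneSpec(n_cells=0, seed=5))
        with pytest.warns(UserWarning):
            assert segment_field(field).n_cells == 0


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_threshold_optimality_property(seed):
    """The returned threshold always achieves the maximal between-class variance."""
    rng = np.random.default_rng(seed)
    img = rng.integers(0, 256, (24, 24)).astype(np.uint8)
    if img.min() == img.max():
        return
    assert optimal_threshold(img) == exhaustive_bcv_threshold(img)
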