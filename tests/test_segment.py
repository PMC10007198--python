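import numpy as np
import pytest
from scipy import ndimage as ndi

from fluokernel.segment import (
    binarize_morph,
    crop_instances,
    laplacian_sharpen,
    median_filter,
    segment_scene,
    to_gray,
    watershed_split,
)


def make_disk(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestToGray:
    def test_uniform_image(self):
        img = np.full((5, 5, 3), 0.4)
        assert np.allclose(to_gray(img), 0.4)

    def test_pure_red(self):
        img = np.zeros((4, 4, 3))
        img[..., 0] = 1.0
        assert np.allclose(to_gray(img), 0.299)

    def test_black(self):
        assert np.all(to_gray(np.zeros((3, 3, 3))) == 0.0)

    def test_wrong_shape(self):
        with pytest.raises(ValueError):
            to_gray(np.zeros((4, 4)))


class TestMedianFilter:
    def test_constant_unchanged(self):
        img = np.full((7, 7), 0.3)
        for window in (1, 3, 5):
            assert np.allclose(median_filter(img, window), 0.3)

    def test_hot_pixel_removed(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        assert median_filter(img, 3)[2, 2] == 0.0

    def test_window_one_identity(self, rng):
        img = rng.uniform(size=(6, 6))
        assert np.array_equal(median_filter(img, 1), img)

    def test_center_matches_sort_oracle(self, rng):
        img = rng.uniform(size=(5, 5))
        out = median_filter(img, 3)
        neighbourhood = np.sort(img[1:4, 1:4].ravel())
        assert out[2, 2] == neighbourhood[4]

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            median_filter(np.zeros((4, 4)), 2)


class TestLaplacianSharpen:
    def test_constant_unchanged(self):
        img = np.full((6, 6), 0.5)
        for strength in (0.0, 0.5, 2.0):
            assert np.allclose(laplacian_sharpen(img, strength), 0.5)

    def test_zero_strength_identity(self, rng):
        img = rng.uniform(size=(5, 5))
        assert np.allclose(laplacian_sharpen(img, 0.0), img)

    def test_step_edge_hand_convolution(self):
        # one row 0 0 0 1 1 1, constant vertically; 4-neighbour Laplacian:
        # at the last dark pixel  lap = 0+0+0+1-0 = 1  -> out = 0-1 -> clip 0
        # at the first bright one lap = 1+1+0+1-4 = -1 -> out = 1+1 -> clip 1
        # interior values untouched
        row = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        img = np.tile(row, (5, 1))
        out = laplacian_sharpen(img, strength=1.0)
        expected_row = np.array([0.0, 0.0, 0.0, 1.0, 1.0, 1.0])
        # before clipping: [0, 0, -1, 2, 1, 1]
        assert np.allclose(out[2], expected_row)
        # verify against a direct unclipped convolution
        kernel = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)
        lap = ndi.convolve(img, kernel, mode="reflect")
        assert np.allclose(out, np.clip(img - lap, 0, 1))
        assert lap[2, 2] == 1.0 and lap[2, 3] == -1.0

    def test_negative_strength_rejected(self):
        with pytest.raises(ValueError):
            laplacian_sharpen(np.zeros((3, 3)), -1.0)


class TestBinarizeMorph:
    def test_two_bright_squares(self):
        img = np.zeros((40, 40))
        img[5:15, 5:15] = 0.9
        img[25:35, 25:35] = 0.9
        binary = binarize_morph(img, open_radius=1, close_radius=1)
        assert binary[10, 10] and binary[30, 30]
        assert not binary[0, 0] and not binary[20, 20]

    def test_opening_removes_small_object(self):
        img = np.zeros((40, 40))
        img[5:25, 5:25] = 0.9   # 20x20 survives opening radius 3
        img[30:33, 30:33] = 0.9  # 3x3 dies
        binary = binarize_morph(img, open_radius=3, close_radius=0)
        assert binary[15, 15]
        assert not binary[31, 31]

    def test_blank_image_raises(self):
        with pytest.raises(ValueError, match="no foreground"):
            binarize_morph(np.zeros((10, 10)))

    def test_component_count_matches_truth(self, scene_batch):
        hits = 0
        for img, truths in scene_batch[:8]:
            gray = laplacian_sharpen(median_filter(to_gray(img), 3), 0.5)
            binary = binarize_morph(gray, 2, 2)
            _, n = ndi.label(binary)
            hits += n == len(truths)
        assert hits >= 7


class TestWatershedSplit:
    def test_single_disk(self):
        binary = make_disk((50, 50), (25, 25), 12)
        labels = watershed_split(binary)
        assert labels.max() == 1
        assert np.array_equal(labels > 0, binary)

    def test_dumbbell_splits_in_two(self):
        shape = (60, 90)
        binary = make_disk(shape, (30, 25), 12) | make_disk(shape, (30, 65), 12)
        binary[28:33, 25:65] = True  # thin neck
        labels = watershed_split(binary)
        assert labels.max() == 2

    def test_empty_foreground_raises(self):
        with pytest.raises(ValueError):
            watershed_split(np.zeros((10, 10), dtype=bool))

    def test_labels_contiguous_raster_order(self):
        binary = np.zeros((30, 90), dtype=bool)
        binary |= make_disk(binary.shape, (15, 70), 8)
        binary |= make_disk(binary.shape, (15, 15), 8)
        binary |= make_disk(binary.shape, (15, 42), 8)
        labels = watershed_split(binary)
        assert sorted(np.unique(labels).tolist()) == [0, 1, 2, 3]
        # first occurrences appear in increasing raster position
        firsts = [np.flatnonzero(labels.ravel() == k)[0] for k in (1, 2, 3)]
        assert firsts == sorted(firsts)


class TestCropInstances:
    def test_full_frame_label(self, rng):
        img = rng.uniform(size=(20, 20, 3))
        labels = np.ones((20, 20), dtype=int)
        crops = crop_instances(img, labels, pad_px=0)
        assert len(crops) == 1
        crop, bbox, mask = crops[0]
        assert np.array_equal(crop, img)
        assert (bbox.x_min, bbox.y_min, bbox.x_max, bbox.y_max) == (0, 0, 20, 20)
        assert mask.all()

    def test_k_labels_k_crops(self, default_scene):
        img, truths = default_scene
        labels = segment_scene(img)
        crops = crop_instances(img, labels, pad_px=2)
        assert len(crops) == labels.max()

    def test_bbox_is_tight_box_plus_padding(self):
        img = np.zeros((30, 30, 3))
        labels = np.zeros((30, 30), dtype=int)
        labels[10:15, 12:20] = 1
        (crop, bbox, mask), = crop_instances(img, labels, pad_px=3)
        assert (bbox.x_min, bbox.y_min, bbox.x_max, bbox.y_max) == (9, 7, 23, 18)
        assert crop.shape[:2] == mask.shape == (11, 14)


class TestPipeline:
    def test_determinism(self, default_scene):
        img, _ = default_scene
        assert np.array_equal(segment_scene(img), segment_scene(img))

    def test_instances_partition_foreground(self, default_scene):
        img, _ = default_scene
        gray = laplacian_sharpen(median_filter(to_gray(img), 3), 0.5)
        binary = binarize_morph(gray, 2, 2)
        labels = watershed_split(binary)
        assert np.array_equal(labels > 0, binary)

    def test_count_recovery_with_jaccard(self, scene_batch):
        """Watershed recovers the truth count with mask Jaccard > 0.7."""
        exact = 0
        for img, truths in scene_batch[:8]:
            labels = segment_scene(img)
            if labels.max() != len(truths):
                continue
            ok = True
            for t in truths:
                best = 0.0
                for k in range(1, labels.max() + 1):
                    m = labels == k
                    inter = np.count_nonzero(m & t.mask)
                    if inter == 0:
                        continue
                    union = np.count_nonzero(m | t.mask)
                    best = max(best, inter / union)
                ok = ok and best > 0.7
            exact += ok
        assert exact >= 7
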