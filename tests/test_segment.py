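import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nucshell import (
    DegenerateDataError,
    LabelMask,
    SegmentationMask,
    SegmentationParams,
    ValidationError,
    VolumeImage,
    binarize_and_refine,
    clear_lateral_border,
    gaussian_smooth,
    label_and_filter,
    otsu_threshold,
    segment_stack,
)
from nucshell.phantom import NucleusSpec, PhantomConfig, flat_profile, generate_phantom

from conftest import exhaustive_otsu

UNIT = (1.0, 1.0, 1.0)


def vol(arr, spacing=UNIT):
    return VolumeImage(np.asarray(arr, dtype=float), spacing)


class TestGaussianSmooth:
    def test_zero_sigma_is_identity(self):
        rng = np.random.default_rng(0)
        img = vol(rng.uniform(0, 100, (4, 5, 6)))
        out = gaussian_smooth(img, (0, 0, 0))
        np.testing.assert_array_equal(out.voxels, img.voxels)

    def test_constant_preserved(self):
        img = vol(np.full((6, 6, 6), 42.0))
        out = gaussian_smooth(img, (1.0, 1.0, 1.0))
        np.testing.assert_allclose(out.voxels, 42.0, rtol=1e-12)

    def test_impulse_kernel_sums_to_one_and_is_symmetric(self):
        grid = np.zeros((31, 31, 31))
        grid[15, 15, 15] = 1.0
        out = gaussian_smooth(vol(grid), (2.0, 2.0, 2.0)).voxels
        assert abs(out.sum() - 1.0) < 1e-6
        np.testing.assert_allclose(out, out[::-1, :, :], atol=1e-12)
        np.testing.assert_allclose(out, out[:, ::-1, :], atol=1e-12)
        np.testing.assert_allclose(out, out[:, :, ::-1], atol=1e-12)

    def test_sigma_is_physical(self):
        # same physical sigma on a 2x coarser axis must use half the voxel sigma
        rng = np.random.default_rng(1)
        base = rng.uniform(0, 100, (8, 8, 8))
        fine = gaussian_smooth(vol(base, (1, 1, 1)), (2, 2, 2))
        coarse = gaussian_smooth(vol(base, (2, 1, 1)), (2, 2, 2))
        assert not np.allclose(fine.voxels, coarse.voxels)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValidationError):
            gaussian_smooth(vol(np.ones((3, 3, 3))), (-1, 0, 0))


class TestOtsu:
    def test_bimodal_threshold_between_modes(self):
        data = np.concatenate([np.full(500, 10.0), np.full(500, 200.0)])
        rng = np.random.default_rng(2)
        thr = otsu_threshold(vol(rng.permutation(data).reshape(10, 10, 10)))
        assert 10 <= thr < 200

    def test_two_gaussian_modes_land_between(self):
        rng = np.random.default_rng(3)
        a = rng.normal(30, 10, 4000)
        b = rng.normal(160, 10, 4000)
        data = np.clip(np.concatenate([a, b]), 0, None).reshape(20, 20, 20)
        thr = otsu_threshold(vol(data))
        assert 80 <= thr <= 110
        assert thr == exhaustive_otsu(data)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateDataError):
            otsu_threshold(vol(np.full((4, 4, 4), 9.0)))

    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_scan(self, seed):
        """Histogram Otsu equals an exhaustive between-class-variance scan."""
        rng = np.random.default_rng(seed)
        n_distinct = rng.integers(2, 65)
        levels = rng.choice(256, size=n_distinct, replace=False)
        data = rng.choice(levels, size=(8, 8, 8)).astype(float)
        if np.unique(data).size < 2:  # tiny chance all draws coincide
            data.ravel()[0] = levels.min() if data.ravel()[0] != levels.min() else levels.max()
        assert otsu_threshold(vol(data)) == exhaustive_otsu(data)


class TestBinarizeAndRefine:
    def test_threshold_below_minimum_gives_all_foreground(self):
        img = vol(np.arange(27).reshape(3, 3, 3) + 1.0)
        mask = binarize_and_refine(img, 0.5, SegmentationParams(morph_ops=()))
        assert mask.binary.all()

    def test_strict_inequality_excludes_ties(self):
        img = vol(np.full((3, 3, 3), 5.0))
        strict = binarize_and_refine(img, 5.0, SegmentationParams(morph_ops=()))
        assert not strict.binary.any()
        incl = binarize_and_refine(
            img, 5.0, SegmentationParams(morph_ops=(), threshold_mode="inclusive")
        )
        assert incl.binary.all()

    def test_closing_fills_interior_hole(self):
        grid = np.zeros((13, 13, 13))
        grid[2:11, 2:11, 2:11] = 100.0
        grid[6, 6, 6] = 0.0
        mask = binarize_and_refine(vol(grid), 50.0, SegmentationParams(morph_ops=(("closing", 1),)))
        assert mask.binary[6, 6, 6]

    def test_erosion_then_dilation_contained_in_closing(self):
        """Opening (erode-dilate) never adds voxels beyond closing of the same mask."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            grid = (rng.uniform(size=(10, 10, 10)) < 0.4) * 100.0
            img = vol(grid)
            opened = binarize_and_refine(
                img, 50, SegmentationParams(morph_ops=(("erosion", 1), ("dilation", 1)))
            )
            closed = binarize_and_refine(img, 50, SegmentationParams(morph_ops=(("closing", 1),)))
            assert not (opened.binary & ~closed.binary).any()


class TestLabelAndFilter:
    def _mask(self, grid):
        return SegmentationMask(grid, UNIT)

    def test_two_cubes_two_labels(self):
        grid = np.zeros((12, 12, 12), dtype=bool)
        grid[1:6, 1:6, 1:6] = True
        grid[7:12, 7:12, 7:12] = True
        labels = label_and_filter(self._mask(grid), SegmentationParams(min_volume_um3=0))
        assert set(np.unique(labels.labels)) == {0, 1, 2}

    def test_small_speck_removed(self):
        grid = np.zeros((8, 8, 8), dtype=bool)
        grid[1, 1, 1:3] = True  # 2 voxels of 1 um^3 each
        labels = label_and_filter(self._mask(grid), SegmentationParams(min_volume_um3=3.0))
        assert labels.n_objects == 0

    def test_connectivity_modes_on_diagonal_cubes(self):
        grid = np.zeros((8, 8, 8), dtype=bool)
        grid[0:3, 0:3, 0:3] = True
        grid[3:6, 3:6, 3:6] = True  # touch only at a corner
        face = label_and_filter(
            self._mask(grid), SegmentationParams(min_volume_um3=0, connectivity="face")
        )
        full = label_and_filter(
            self._mask(grid), SegmentationParams(min_volume_um3=0, connectivity="full")
        )
        assert face.n_objects == 2
        assert full.n_objects == 1

    def test_labels_ordered_by_decreasing_volume(self):
        grid = np.zeros((14, 14, 14), dtype=bool)
        grid[1:3, 1:3, 1:3] = True       # 8 voxels
        grid[6:12, 6:12, 6:12] = True    # 216 voxels
        labels = label_and_filter(self._mask(grid), SegmentationParams(min_volume_um3=0))
        assert (labels.labels[6:12, 6:12, 6:12] == 1).all()
        assert (labels.labels[1:3, 1:3, 1:3] == 2).all()


class TestClearLateralBorder:
    def _labels(self, grid):
        return LabelMask(grid, UNIT)

    def test_lateral_touchers_removed_z_touchers_kept(self):
        grid = np.zeros((6, 10, 10), dtype=np.int32)
        grid[2:4, 0:3, 4:7] = 1    # touches y = 0 -> removed
        grid[0:2, 4:7, 4:7] = 2    # touches z = 0 only -> kept
        grid[2:5, 5:8, 1:4] = 3    # interior -> kept
        out = clear_lateral_border(self._labels(grid))
        assert out.n_objects == 2
        assert (out.labels[:, 0, :] == 0).all()
        assert out.labels[0:2, 4:7, 4:7].max() > 0

    @pytest.mark.parametrize("face", ["y0", "ymax", "x0", "xmax"])
    def test_each_lateral_face_triggers_removal(self, face):
        grid = np.zeros((5, 8, 8), dtype=np.int32)
        sl = {
            "y0": (slice(1, 3), slice(0, 2), slice(3, 5)),
            "ymax": (slice(1, 3), slice(6, 8), slice(3, 5)),
            "x0": (slice(1, 3), slice(3, 5), slice(0, 2)),
            "xmax": (slice(1, 3), slice(3, 5), slice(6, 8)),
        }[face]
        grid[sl] = 1
        assert clear_lateral_border(self._labels(grid)).n_objects == 0

    @given(st.integers(0, 1000))
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        from scipy import ndimage

        blob = rng.uniform(size=(6, 10, 10)) < 0.25
        grid, _ = ndimage.label(blob)
        once = clear_lateral_border(self._labels(grid.astype(np.int32)))
        twice = clear_lateral_border(once)
        np.testing.assert_array_equal(once.labels, twice.labels)


class TestSegmentStack:
    def test_noise_free_ellipsoid_recovered(self):
        """Default segmentation recovers a clean ellipsoid at Jaccard >= 0.95."""
        cfg = PhantomConfig(
            shape=(24, 160, 160),
            nuclei=(NucleusSpec((2.4, 4.0, 4.0), (1.5, 3.0, 3.2)),),
            radial_profile=flat_profile(100.0),
            seed=0,
        )
        img, truth = generate_phantom(cfg)
        labels = segment_stack(img)
        seg = labels.labels > 0
        true = truth.mask > 0
        jaccard = (seg & true).sum() / (seg | true).sum()
        assert labels.n_objects == 1
        assert jaccard >= 0.95
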