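"""RGB-like slice decomposition: slicing, composition, grouping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mriens import (
    DecompositionConfig,
    ValidationError,
    Volume,
    anchor_indices,
    compose_rgb,
    decompose_volume,
    extract_slice,
    group_by_slice,
)

from conftest import random_volume


def index_volume(shape):
    """Voxel (i, j, k) = i*10000 + j*100 + k: every voxel identifiable."""
    i, j, k = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    return Volume(voxels=(i * 10000 + j * 100 + k).astype(float))


class TestExtractSlice:
    def test_sagittal_slice_is_direct_indexing(self):
        shape = (4, 5, 6)
        j, k = np.meshgrid(np.arange(5), np.arange(6), indexing="ij")
        v = Volume(voxels=np.broadcast_to((j + k)[None], shape).copy())
        np.testing.assert_array_equal(extract_slice(v, "sagittal", 0), j + k)

    def test_available_transaxial_indices(self):
        v = random_volume((10, 10, 10))
        for idx in range(10):
            extract_slice(v, "transaxial", idx)
        with pytest.raises(IndexError):
            extract_slice(v, "transaxial", 10)

    def test_coronal_slice_matches_loop_oracle(self):
        v = random_volume((7, 9, 8), seed=11)
        got = extract_slice(v, "coronal", 5)
        expected = np.empty((7, 8))
        for i in range(7):
            for k in range(8):
                expected[i, k] = v.voxels[i, 5, k]
        np.testing.assert_array_equal(got, expected)

    def test_unknown_orientation_rejected(self):
        with pytest.raises(ValidationError):
            extract_slice(random_volume((4, 4, 4)), "axial-ish", 0)


class TestComposeRGB:
    def test_approach_a_gap1_first_anchor_is_first_three_sagittal(self):
        v = random_volume((10, 12, 10), seed=1)
        img = compose_rgb(v, DecompositionConfig("A", gap=1, scale=False), 0)
        np.testing.assert_array_equal(img.r, v.voxels[0])
        np.testing.assert_array_equal(img.g, v.voxels[1])
        np.testing.assert_array_equal(img.b, v.voxels[2])

    @pytest.mark.parametrize("approach", ["A", "B", "C"])
    def test_gap_zero_gives_identical_bands(self, approach):
        v = random_volume((8, 9, 10), seed=2)
        img = compose_rgb(v, DecompositionConfig(approach, gap=0), 3)
        np.testing.assert_array_equal(img.r, img.g)
        np.testing.assert_array_equal(img.g, img.b)

    def test_approach_b_gap2_band_indices(self):
        # anchor n=5 (1-based) i.e. 4 (0-based) -> coronal slices 4, 6, 8
        v = index_volume((10, 12, 10))
        img = compose_rgb(v, DecompositionConfig("B", gap=2, scale=False), 4)
        np.testing.assert_array_equal(img.r, v.voxels[:, 4, :])
        np.testing.assert_array_equal(img.g, v.voxels[:, 6, :])
        np.testing.assert_array_equal(img.b, v.voxels[:, 8, :])

    def test_approach_d_mixes_orientations_with_padding(self):
        v = index_volume((10, 12, 14))
        img = compose_rgb(v, DecompositionConfig("D", gap=1, scale=False), 2)
        # bands padded to element-wise max of (12,14), (10,14), (10,12)
        assert img.bands.shape == (12, 14, 3)
        np.testing.assert_array_equal(img.r, v.voxels[2, :, :])  # (12,14): no pad

    def test_out_of_range_band_rejected(self):
        v = random_volume((6, 6, 6))
        with pytest.raises(ValidationError):
            compose_rgb(v, DecompositionConfig("A", gap=2), 3)

    def test_scaling_maps_bands_to_unit_interval(self):
        v = Volume(voxels=np.random.default_rng(0).uniform(5, 9, (6, 6, 6)))
        img = compose_rgb(v, DecompositionConfig("A", gap=0), 2)
        assert img.bands.min() >= 0.0 and img.bands.max() <= 1.0

    def test_deterministic_on_equal_volumes(self):
        v1 = random_volume((8, 8, 8), seed=5, subject_id="a")
        v2 = random_volume((8, 8, 8), seed=5, subject_id="b")
        cfg = DecompositionConfig("D", gap=1)
        np.testing.assert_array_equal(
            compose_rgb(v1, cfg, 1).bands, compose_rgb(v2, cfg, 1).bands
        )


def brute_force_anchors(shape, approach, gap, stride, n_start=0):
    from mriens.decomposition import APPROACH_BANDS, ORIENTATION_AXIS

    anchors = []
    for n in range(n_start, max(shape) + 1, stride):
        ok = all(
            n + i * gap < shape[ORIENTATION_AXIS[o]]
            for i, o in enumerate(APPROACH_BANDS[approach])
        )
        if ok:
            anchors.append(n)
        else:
            break
    return anchors


class TestDecomposeVolume:
    def test_gap0_stride1_one_image_per_sagittal_slice(self):
        v = random_volume((20, 20, 20), seed=3)
        images = decompose_volume(v, DecompositionConfig("A", gap=0))
        assert len(images) == 20
        assert [img.n for img in images] == list(range(20))

    def test_default_stride_gap1_on_cubic_volume(self):
        # 100^3, gap 1, stride 3: anchors 1, 4, ..., 97 (1-based) -> 33
        anchors = anchor_indices((100, 100, 100), DecompositionConfig("A", gap=1))
        assert len(anchors) == 33
        assert anchors[0] == 0 and anchors[-1] == 96 and anchors[1] == 3

    @pytest.mark.parametrize("approach", ["A", "B", "C", "D"])
    @pytest.mark.parametrize("gap", [0, 1, 2])
    @pytest.mark.parametrize("shape", [(20, 24, 20), (15, 15, 15), (9, 30, 17)])
    def test_anchor_sets_match_enumeration(self, approach, gap, shape):
        cfg = DecompositionConfig(approach, gap=gap)
        assert anchor_indices(shape, cfg) == brute_force_anchors(
            shape, approach, gap, cfg.effective_stride
        )

    def test_lossless_reconstruction_gap0_stride1(self):
        v = random_volume((10, 12, 9), seed=4)
        images = decompose_volume(
            v, DecompositionConfig("B", gap=0, scale=False)
        )
        rebuilt = np.stack([img.r for img in images], axis=1)
        np.testing.assert_array_equal(rebuilt, v.voxels)

    def test_too_small_volume_rejected(self):
        v = random_volume((1, 1, 1))
        with pytest.raises(ValidationError):
            decompose_volume(v, DecompositionConfig("A", gap=2))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        gap=st.integers(0, 3),
        stride=st.integers(1, 5),
        n_start=st.integers(0, 3),
    )
    def test_anchors_depend_only_on_shape_not_content(self, gap, stride, n_start):
        cfg = DecompositionConfig("C", gap=gap, stride=stride, n_start=n_start)
        shape = (12, 14, 16)
        a1 = anchor_indices(shape, cfg)
        a2 = anchor_indices(shape, cfg)
        assert a1 == a2
        if a1:
            v = random_volume(shape, seed=gap + stride)
            assert [img.n for img in decompose_volume(v, cfg)] == a1


class TestGroupBySlice:
    def _cohort_images(self, n_subjects=3, seed=0):
        cfg = DecompositionConfig("A", gap=0)
        images = []
        for s in range(n_subjects):
            v = random_volume((10, 10, 10), seed=seed + s, subject_id=f"s{s}")
            images.extend(decompose_volume(v, cfg))
        return images

    def test_group_counts(self):
        images = self._cohort_images(3)
        groups = group_by_slice(images)
        assert len(groups) == 10
        assert all(len(g) == 3 for g in groups.values())

    def test_groups_partition_input(self):
        images = self._cohort_images(3)
        groups = group_by_slice(images)
        regrouped = [img for g in groups.values() for img in g.values()]
        assert len(regrouped) == len(images)
        assert {id(i) for i in regrouped} == {id(i) for i in images}

    def test_removing_a_subject_removes_one_image_per_group(self):
        images = self._cohort_images(3)
        full = group_by_slice(images)
        reduced = group_by_slice(
            [img for img in images if img.subject_id != "s1"]
        )
        assert set(full) == set(reduced)
        for key in full:
            assert len(full[key]) - len(reduced[key]) == 1

    def test_inconsistent_subject_sets_rejected(self):
        images = self._cohort_images(2)
        with pytest.raises(ValidationError):
            group_by_slice(images[:-1])  # one subject misses a slice
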