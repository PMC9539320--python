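"""Containers, file round-trips and coordinate/distance primitives."""

import numpy as np
import nibabel as nib
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from _bruteforce import bf_distance_map, bf_length

from arcore.formats import (
    BinaryMask,
    FormatError,
    TractogramMM,
    VolumeGrid,
    distance_map,
    read_mask,
    read_tractogram,
    streamline_length,
    voxel_to_world,
    world_to_voxel,
    write_mask,
    write_tractogram,
)


def _random_tractogram(rng, n=3, affine=None):
    streamlines = [
        np.cumsum(rng.normal(0, 2, size=(rng.integers(5, 30), 3)), axis=0) + 20.0
        for _ in range(n)
    ]
    return TractogramMM(
        streamlines=streamlines,
        reference_affine=np.eye(4) if affine is None else affine,
        reference_shape=(32, 32, 32),
    )


class TestMaskIO:
    def test_round_trip_preserves_voxels_and_affine(self, tmp_path):
        affine = np.diag([1.5, 1.5, 2.0, 1.0])
        affine[:3, 3] = (-10, 4, 7)
        values = np.zeros((4, 4, 4))
        values[[0, 1, 2, 3, 3], [0, 1, 2, 3, 0], [0, 1, 2, 3, 2]] = 1
        write_mask(BinaryMask(values=values, affine=affine), tmp_path / "m.nii.gz")
        back = read_mask(tmp_path / "m.nii.gz")
        assert back.n_voxels == 5
        assert np.allclose(back.affine, affine)
        assert np.array_equal(back.values, values.astype(bool))

    def test_nonzero_values_binarise_to_one(self, tmp_path):
        data = np.zeros((3, 3, 3))
        data[0, 0, 0], data[1, 1, 1], data[2, 2, 2] = 2.0, 0.5, -1.0
        nib.save(nib.Nifti1Image(data, np.eye(4)), tmp_path / "v.nii.gz")
        mask = read_mask(tmp_path / "v.nii.gz")
        assert mask.n_voxels == 3
        assert mask.values.dtype == bool

    def test_4d_file_is_a_format_error(self, tmp_path):
        nib.save(nib.Nifti1Image(np.zeros((3, 3, 3, 2)), np.eye(4)), tmp_path / "x.nii.gz")
        with pytest.raises(FormatError):
            read_mask(tmp_path / "x.nii.gz")


class TestTractogramIO:
    def test_tck_round_trip(self, tmp_path, rng):
        t = _random_tractogram(rng)
        write_tractogram(t, tmp_path / "t.tck")
        back = read_tractogram(tmp_path / "t.tck")
        assert len(back) == 3
        for a, b in zip(t.streamlines, back.streamlines):
            assert np.allclose(a, b, atol=1e-5)

    def test_trk_matches_tck_world_coordinates(self, tmp_path, rng):
        # TRK stores voxel-scaled corner-origin coordinates; after reading,
        # world coordinates must agree with the TCK route within float32.
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = (-5.0, 3.0, 1.0)
        t = _random_tractogram(rng, affine=affine)
        write_tractogram(t, tmp_path / "t.tck")
        write_tractogram(t, tmp_path / "t.trk")
        tck = read_tractogram(tmp_path / "t.tck")
        trk = read_tractogram(tmp_path / "t.trk")
        for a, b in zip(tck.streamlines, trk.streamlines):
            assert np.allclose(a, b, atol=1e-4)

    def test_empty_tractogram_round_trip(self, tmp_path):
        t = TractogramMM(streamlines=[])
        write_tractogram(t, tmp_path / "e.tck")
        assert len(read_tractogram(tmp_path / "e.tck")) == 0

    def test_unreadable_file_is_a_format_error(self, tmp_path):
        path = tmp_path / "bad.tck"
        path.write_bytes(b"not a tractogram at all")
        with pytest.raises(FormatError):
            read_tractogram(path)


class TestWorldVoxel:
    def test_nearest_voxel_under_identity_affine(self):
        grid = VolumeGrid(values=np.zeros((5, 5, 5)), affine=np.eye(4))
        idx, inside = world_to_voxel(np.array([[1.6, 2.4, 0.0]]), grid)
        assert tuple(idx[0]) == (2, 2, 0) and inside[0]

    def test_half_integer_ties_round_to_even(self):
        grid = VolumeGrid(values=np.zeros((5, 5, 5)), affine=np.diag([2.0, 2.0, 2.0, 1.0]))
        idx, _ = world_to_voxel(np.array([[3.0, 0.0, 0.0]]), grid)  # voxel coord 1.5
        assert tuple(idx[0]) == (2, 0, 0)
        idx, _ = world_to_voxel(np.array([[1.0, 0.0, 0.0]]), grid)  # voxel coord 0.5
        assert tuple(idx[0]) == (0, 0, 0)

    def test_out_of_grid_is_flagged_not_clamped(self):
        grid = VolumeGrid(values=np.zeros((4, 4, 4)), affine=np.eye(4))
        idx, inside = world_to_voxel(np.array([[10.0, 0.0, 0.0]]), grid)
        assert not inside[0] and idx[0, 0] == 10

    def test_voxel_world_round_trip_on_random_indices(self, rng):
        affine = np.array(
            [[1.2, 0, 0, -30], [0, 0.9, 0, 12], [0, 0, 2.1, -4], [0, 0, 0, 1]]
        )
        grid = VolumeGrid(values=np.zeros((20, 20, 20)), affine=affine)
        indices = rng.integers(0, 20, size=(100, 3))
        world = voxel_to_world(indices, grid)
        back, inside = world_to_voxel(world, grid)
        assert np.array_equal(back, indices) and inside.all()


class TestDistanceMap:
    def test_zero_inside_mask_and_pythagorean_outside(self):
        values = np.zeros((8, 8, 8), dtype=bool)
        values[0, 0, 0] = True
        mask = BinaryMask(values=values, affine=np.eye(4))
        dist = distance_map(mask).values
        assert dist[0, 0, 0] == 0.0
        assert dist[3, 4, 0] == pytest.approx(5.0)

    def test_empty_mask_raises(self):
        mask = BinaryMask(values=np.zeros((4, 4, 4), dtype=bool), affine=np.eye(4))
        with pytest.raises(ValueError):
            distance_map(mask)

    def test_matches_exhaustive_search_anisotropic(self, rng):
        values = rng.random((16, 16, 16)) < 0.02
        values[4, 7, 9] = True  # guarantee non-empty
        affine = np.diag([1.0, 1.5, 2.0, 1.0])
        mask = BinaryMask(values=values, affine=affine)
        assert np.allclose(distance_map(mask).values, bf_distance_map(mask), atol=1e-6)

    def test_lipschitz_between_neighbours(self, rng):
        values = rng.random((12, 12, 12)) < 0.05
        values[6, 6, 6] = True
        spacing = np.array([1.25, 1.25, 1.25])
        mask = BinaryMask(values=values, affine=np.diag([*spacing, 1.0]))
        d = distance_map(mask).values
        for axis, s in enumerate(spacing):
            diff = np.abs(np.diff(d, axis=axis))
            assert np.all(diff <= s + 1e-9)


class TestStreamlineLength:
    def test_straight_and_bent_segments(self):
        assert streamline_length([[0, 0, 0], [60, 0, 0]]) == pytest.approx(60.0)
        assert streamline_length([[0, 0, 0], [3, 4, 0], [3, 4, 12]]) == pytest.approx(17.0)

    def test_single_point_raises(self):
        with pytest.raises(ValueError):
            streamline_length(np.zeros((1, 3)))

    def test_matches_bruteforce_on_random_polyline(self, rng):
        s = rng.normal(0, 10, size=(50, 3))
        assert streamline_length(s) == pytest.approx(bf_length(s), rel=1e-12)

    def test_invariant_under_rigid_transform(self, rng):
        s = np.cumsum(rng.normal(0, 1, size=(30, 3)), axis=0)
        # random rotation via QR, plus translation
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = s @ q.T + np.array([5.0, -3.0, 11.0])
        assert streamline_length(moved) == pytest.approx(streamline_length(s))

    @given(
        points=st.lists(
            st.tuples(*[st.floats(-100, 100) for _ in range(3)]),
            min_size=3,
            max_size=25,
        ),
        split=st.integers(1, 23),
        shift=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_additive_over_splits_and_translation_invariant(self, points, split, shift):
        s = np.asarray(points, dtype=np.float64)
        split = min(split, len(s) - 2)
        whole = streamline_length(s)
        parts = streamline_length(s[: split + 1]) + streamline_length(s[split:])
        assert parts == pytest.approx(whole, abs=1e-8)
        assert streamline_length(s + np.asarray(shift)) == pytest.approx(whole, abs=1e-7)
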