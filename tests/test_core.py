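"""Volume/mask primitives: distance maps, resampling, morphology, NIfTI I/O."""

import numpy as np
import pytest

from corseg import (BinaryMask, VolumeGrid, morphology, read_mask, read_volume, resample,
                    signed_distance, write_volume)
from conftest import box, make_grid, sphere, world_axes


class TestVolumeGrid:
    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            VolumeGrid(np.zeros((4, 4, 4)), spacing=(1, 0, 1))
        with pytest.raises(ValueError, match="orthonormal"):
            VolumeGrid(np.zeros((4, 4, 4)), direction=np.eye(3) * 2)

    def test_world_coordinates_voxel_centre_convention(self):
        g = VolumeGrid(np.zeros((8, 8, 8)), spacing=(2, 2, 2.5), origin=(10, 0, -5))
        assert np.allclose(g.index_to_world([0, 0, 0]), [10, 0, -5])
        assert np.allclose(g.index_to_world([1, 2, 3]), [12, 4, 2.5])
        assert np.allclose(g.world_to_index([12, 4, 2.5]), [1, 2, 3])

    def test_mask_volume_is_count_times_voxel_volume(self):
        g = make_grid((10, 10, 10), (2, 2, 2.5))
        m = BinaryMask.from_array(np.ones((10, 10, 10)), g)
        assert m.volume_mm3 == pytest.approx(1000 * 2 * 2 * 2.5)

    def test_mask_values_strictly_binary(self):
        g = make_grid((4, 4, 4))
        with pytest.raises(ValueError, match="0 or 1"):
            BinaryMask(g.with_values(np.full((4, 4, 4), 2.0)))


class TestSignedDistance:
    def test_sphere_centre_depth_matches_radius(self, grid_1mm):
        m = sphere(grid_1mm, (32, 32, 32), 20.0)
        d = signed_distance(m)
        centre_val = d.values[32, 32, 32]
        assert centre_val == pytest.approx(-20.0, abs=grid_1mm.voxel_diagonal_mm)

    def test_normalised_deepest_point_is_minus_one(self, grid_1mm):
        m = sphere(grid_1mm, (32, 32, 32), 20.0)
        d = signed_distance(m, normalise=True)
        assert d.values.min() == pytest.approx(-1.0)
        assert d.depth_scale == pytest.approx(20.0, abs=grid_1mm.voxel_diagonal_mm)

    def test_zero_level_set_on_boundary(self, grid_1mm):
        m = sphere(grid_1mm, (32, 32, 32), 15.0)
        d = signed_distance(m)
        inner = morphology(m, "erode", 1.0)
        boundary = m.values.astype(bool) & ~inner.values.astype(bool)
        assert np.abs(d.values[boundary]).max() <= grid_1mm.voxel_diagonal_mm

    def test_eikonal_property_on_sphere(self, grid_1mm):
        m = sphere(grid_1mm, (32, 32, 32), 20.0)
        d = signed_distance(m)
        gx, gy, gz = np.gradient(d.values, *grid_1mm.spacing)
        gmag = np.sqrt(gx ** 2 + gy ** 2 + gz ** 2)
        # away from the medial axis (centre) and the image edge
        shell = (np.abs(d.values) > 3) & (np.abs(d.values) < 15)
        assert 0.9 <= gmag[shell].mean() <= 1.1

    def test_empty_mask_rejected(self, grid_1mm):
        empty = BinaryMask.from_array(np.zeros(grid_1mm.shape), grid_1mm)
        with pytest.raises(ValueError, match="empty mask"):
            signed_distance(empty)


class TestResample:
    def test_identity_resample_preserves_values(self, grid_1mm):
        m = sphere(grid_1mm, (32, 32, 32), 12.0)
        out = resample(m.grid, grid_1mm, "nearest")
        assert np.array_equal(out.values, m.values)

    def test_downsampled_mask_conserves_volume(self, grid_1mm):
        m = sphere(grid_1mm, (32, 32, 32), 20.0)
        coarse = make_grid((16, 16, 16), (4, 4, 4))
        out = resample(m.grid, coarse, "nearest")
        v_out = out.values.sum() * coarse.voxel_volume_mm3
        assert v_out == pytest.approx(m.volume_mm3, rel=0.15)

    def test_linear_round_trip_error_bounded(self):
        g = make_grid((32, 32, 32), (2, 2, 2))
        X, Y, Z = world_axes(g)
        smooth = g.with_values(np.sin(X / 20) + np.cos(Y / 15) + Z / 50)
        fine = make_grid((64, 64, 64), (1, 1, 1))
        back = resample(resample(smooth, fine, "linear"), g, "linear")
        interior = np.s_[2:-2, 2:-2, 2:-2]
        err = np.abs(back.values[interior] - smooth.values[interior]).max()
        assert err < 0.01  # second-order interpolation error on a smooth field

    def test_unknown_interpolation_rejected(self, grid_1mm):
        with pytest.raises(ValueError, match="interpolation"):
            resample(grid_1mm, grid_1mm, "cubic")


class TestMorphology:
    def test_dilated_sphere_volume_matches_analytic(self, grid_1mm):
        m = sphere(grid_1mm, (32, 32, 32), 10.0)
        out = morphology(m, "dilate", 5.0)
        assert out.volume_mm3 == pytest.approx(4 / 3 * np.pi * 15 ** 3, rel=0.10)

    def test_dilate_then_erode_recovers_convex_mask(self, grid_1mm):
        m = sphere(grid_1mm, (32, 32, 32), 12.0)
        back = morphology(morphology(m, "dilate", 4.0), "erode", 4.0)
        diff = np.logical_xor(back.values, m.values)
        # disagreement confined to a one-voxel boundary layer
        inner = morphology(m, "erode", grid_1mm.voxel_diagonal_mm)
        assert not (diff & inner.values.astype(bool)).any()

    def test_fill_holes_removes_enclosed_cavity(self, grid_1mm):
        outer = sphere(grid_1mm, (32, 32, 32), 15.0)
        cavity = sphere(grid_1mm, (32, 32, 32), 6.0)
        hollow = outer.difference(cavity)
        filled = morphology(hollow, "fill_holes")
        assert np.array_equal(filled.values, outer.values)

    def test_largest_component_keeps_biggest(self, grid_1mm):
        big = box(grid_1mm, (5, 5, 5), (15, 15, 15))
        small = box(grid_1mm, (40, 40, 40), (42, 42, 42))
        out = morphology(big.union(small), "largest_component")
        assert np.array_equal(out.values, big.values)

    def test_largest_component_of_empty_mask_is_empty(self, grid_1mm):
        empty = BinaryMask.from_array(np.zeros(grid_1mm.shape), grid_1mm)
        assert morphology(empty, "largest_component").is_empty

    def test_negative_radius_rejected(self, grid_1mm):
        m = sphere(grid_1mm, (32, 32, 32), 5.0)
        with pytest.raises(ValueError, match="radius"):
            morphology(m, "dilate", -1.0)


def test_nifti_round_trip(tmp_path, grid_1mm):
    m = sphere(grid_1mm, (30, 28, 35), 9.0)
    p = tmp_path / "mask.nii.gz"
    write_volume(m.grid, p, dtype="uint8")
    back = read_mask(p)
    assert back.grid.same_geometry(m.grid)
    assert np.array_equal(back.values, m.values)

    img = grid_1mm.with_values(np.random.default_rng(0).normal(size=grid_1mm.shape))
    p2 = tmp_path / "img.nii.gz"
    write_volume(img, p2)
    back2 = read_volume(p2)
    assert np.allclose(back2.values, img.values, atol=1e-6)
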