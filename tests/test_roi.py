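import numpy as np
import pytest

from suvhist import (
    BinaryMask,
    SphereROI,
    SUVVolume,
    extract_voxels,
    mirror_spheres,
    rasterize_sphere,
    resample_mask,
    union_masks,
)
from suvhist.errors import (
    EmptyROIError,
    GridMismatchError,
    PlacementError,
    PlacementWarning,
)


def brute_force_sphere(center, radius, grid: SUVVolume) -> np.ndarray:
    """Oracle: per-voxel world distance test over the whole grid."""
    import nibabel as nib

    idx = np.argwhere(np.ones(grid.shape, dtype=bool)).astype(float)
    world = nib.affines.apply_affine(grid.affine, idx)
    inside = np.linalg.norm(world - np.asarray(center), axis=1) <= radius
    out = np.zeros(grid.shape, dtype=bool)
    ii = idx.astype(int)
    out[ii[inside, 0], ii[inside, 1], ii[inside, 2]] = True
    return out


def grid_volume(shape, spacing, origin=(0, 0, 0)):
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return SUVVolume(data=np.zeros(shape), affine=aff)


class TestRasterizeSphere:
    def test_10mm_sphere_on_1mm_grid_matches_oracle(self):
        grid = grid_volume((24, 24, 24), (1, 1, 1), origin=(-11.5, -11.5, -11.5))
        sphere = SphereROI(center=(0.3, -0.2, 0.1), diameter=10.0)
        mask = rasterize_sphere(sphere, grid)
        oracle = brute_force_sphere(sphere.center, 5.0, grid)
        assert np.array_equal(mask.data, oracle)
        # continuum volume 523.6 mm^3; center-count discretization stays close
        assert 515 <= mask.n_voxels <= 530

    def test_oblique_affine_matches_oracle(self):
        aff = np.eye(4)
        aff[:3, :3] = np.array([[1.5, 0.2, 0.0], [0.0, 1.2, 0.3], [0.1, 0.0, 2.0]])
        aff[:3, 3] = (-10, -10, -10)
        grid = SUVVolume(data=np.zeros((16, 16, 12)), affine=aff)
        sphere = SphereROI(center=(2.0, 1.0, 3.0), diameter=9.0)
        mask = rasterize_sphere(sphere, grid)
        assert np.array_equal(mask.data, brute_force_sphere(sphere.center, 4.5, grid))

    def test_no_overlap_raises(self):
        grid = grid_volume((10, 10, 10), (1, 1, 1))
        with pytest.raises(EmptyROIError):
            rasterize_sphere(SphereROI(center=(100, 100, 100), diameter=10), grid)

    def test_resolution_scaling(self):
        # halving the spacing multiplies the voxel count by ~8
        coarse = grid_volume((30, 30, 30), (2, 2, 2), origin=(-29, -29, -29))
        fine = grid_volume((60, 60, 60), (1, 1, 1), origin=(-29.5, -29.5, -29.5))
        sphere = SphereROI(center=(0, 0, 0), diameter=20.0)
        n_coarse = rasterize_sphere(sphere, coarse).n_voxels
        n_fine = rasterize_sphere(sphere, fine).n_voxels
        assert n_fine == pytest.approx(8 * n_coarse, rel=0.05)


class TestMirrorSpheres:
    def _lesion(self, grid, center_idx):
        data = np.zeros(grid.shape, dtype=bool)
        data[center_idx] = True
        return BinaryMask(data=data, affine=grid.affine, label="lesion")

    def test_reflection_across_midplane(self):
        # grid spans world x in [-39.5, 39.5] -> x_mid = 0
        grid = grid_volume((80, 80, 80), (1, 1, 1), origin=(-39.5, -39.5, -39.5))
        lesion = self._lesion(grid, (int(39.5 + 30), int(39.5 + 10), int(39.5 + 5)))
        centroid = lesion.centroid_world()
        spheres = mirror_spheres(lesion, grid)
        assert spheres[0].center == pytest.approx((-centroid[0], centroid[1], centroid[2]))

    def test_three_distinct_centers_12mm_apart(self):
        grid = grid_volume((80, 80, 80), (1, 1, 1), origin=(-39.5, -39.5, -39.5))
        lesion = self._lesion(grid, (60, 40, 40))
        spheres = mirror_spheres(lesion, grid, n=3)
        zs = sorted(s.center[2] for s in spheres)
        assert len({s.center for s in spheres}) == 3
        assert np.allclose(np.diff(zs), 12.0)

    def test_midline_lesion_warns(self):
        grid = grid_volume((21, 21, 21), (1, 1, 1), origin=(-10, -10, -10))
        lesion = self._lesion(grid, (10, 10, 10))  # centroid exactly at x_mid = 0
        with pytest.warns(PlacementWarning):
            spheres = mirror_spheres(lesion, grid, n=1)
        assert spheres[0].center[0] == pytest.approx(0.0)

    def test_reflected_center_outside_raises(self):
        grid = grid_volume((40, 40, 40), (1, 1, 1), origin=(0, 0, 0))
        lesion = self._lesion(grid, (5, 20, 20))
        # x_mid far to the left throws the reflection out of the volume
        with pytest.raises(PlacementError):
            mirror_spheres(lesion, grid, x_mid=-30.0)

    def test_empty_lesion_raises(self):
        grid = grid_volume((10, 10, 10), (1, 1, 1))
        empty = BinaryMask(data=np.zeros(grid.shape, dtype=bool), affine=grid.affine)
        with pytest.raises(EmptyROIError):
            mirror_spheres(empty, grid)


class TestResampleMask:
    def test_identity_on_identical_grids(self, rng):
        grid = grid_volume((12, 12, 12), (2, 2, 2))
        data = rng.random((12, 12, 12)) > 0.5
        mask = BinaryMask(data=data, affine=grid.affine)
        out = resample_mask(mask, grid)
        assert np.array_equal(out.data, data)
        assert out.data is not data  # a copy, not a view

    def test_cross_resolution_agrees_at_interior(self):
        # sphere rasterized on a 1 mm grid, resampled to 2 mm: may differ
        # from direct 2 mm rasterization only within one voxel of the surface
        fine = grid_volume((40, 40, 40), (1, 1, 1), origin=(-19.5, -19.5, -19.5))
        coarse = grid_volume((20, 20, 20), (2, 2, 2), origin=(-19, -19, -19))
        sphere = SphereROI(center=(0.0, 0.0, 0.0), diameter=20.0)
        resampled = resample_mask(rasterize_sphere(sphere, fine), coarse)
        import nibabel as nib

        idx = np.argwhere(resampled.data ^ brute_force_sphere((0, 0, 0), 10.0, coarse))
        if idx.size:
            dists = np.linalg.norm(nib.affines.apply_affine(coarse.affine, idx), axis=1)
            assert np.all(np.abs(dists - 10.0) <= 2.0)  # one 2 mm voxel layer
        # volumes agree within that same surface layer
        v_fine = rasterize_sphere(sphere, fine).n_voxels * fine.voxel_volume
        v_coarse = resampled.n_voxels * coarse.voxel_volume
        assert abs(v_fine - v_coarse) < 4 * np.pi * 10.0**2 * 2.0 / 1000.0

    def test_disjoint_extents_raise(self):
        src = grid_volume((10, 10, 10), (1, 1, 1), origin=(0, 0, 0))
        mask = BinaryMask(data=np.ones(src.shape, dtype=bool), affine=src.affine)
        target = grid_volume((10, 10, 10), (1, 1, 1), origin=(500, 500, 500))
        with pytest.raises(EmptyROIError):
            resample_mask(mask, target)


class TestExtractVoxels:
    def test_all_true_constant_volume(self, make_volume):
        vol = make_volume(np.ones((2, 2, 2)))
        mask = BinaryMask(data=np.ones((2, 2, 2), dtype=bool), affine=vol.affine)
        series = extract_voxels(vol, mask)
        assert series.n_voxels == 8
        assert np.all(series.values == 1.0)
        assert series.voxel_volume == pytest.approx(0.001)

    def test_single_voxel(self, make_volume):
        data = np.arange(27.0).reshape(3, 3, 3)
        vol = make_volume(data)
        mask_data = np.zeros((3, 3, 3), dtype=bool)
        mask_data[1, 2, 0] = True
        series = extract_voxels(vol, BinaryMask(data=mask_data, affine=vol.affine))
        assert series.n_voxels == 1
        assert series.values[0] == data[1, 2, 0]

    def test_top_three_of_ramp(self, make_volume):
        data = np.arange(64.0).reshape(4, 4, 4)
        vol = make_volume(data)
        mask_data = data >= 61  # the 3 largest voxels
        series = extract_voxels(vol, BinaryMask(data=mask_data, affine=vol.affine))
        assert sorted(series.values) == [61.0, 62.0, 63.0]

    def test_empty_mask_raises(self, make_volume):
        vol = make_volume(np.ones((2, 2, 2)))
        with pytest.raises(EmptyROIError):
            extract_voxels(vol, BinaryMask(data=np.zeros((2, 2, 2), bool), affine=vol.affine))

    def test_grid_mismatch_raises(self, make_volume, spacing_affine):
        vol = make_volume(np.ones((2, 2, 2)))
        mask = BinaryMask(
            data=np.ones((2, 2, 2), bool), affine=spacing_affine((2, 2, 2))
        )
        with pytest.raises(GridMismatchError):
            extract_voxels(vol, mask)

    def test_union_is_multiset_union(self, make_volume, rng):
        vol = make_volume(rng.random((6, 6, 6)))
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[:3] = rng.random((3, 6, 6)) > 0.5
        b[3:] = rng.random((3, 6, 6)) > 0.5  # disjoint halves
        ma = BinaryMask(data=a, affine=vol.affine)
        mb = BinaryMask(data=b, affine=vol.affine)
        sa = extract_voxels(vol, ma)
        sb = extract_voxels(vol, mb)
        su = extract_voxels(vol, union_masks([ma, mb]))
        assert su.n_voxels == sa.n_voxels + sb.n_voxels
        assert np.allclose(
            np.sort(su.values), np.sort(np.concatenate([sa.values, sb.values]))
        )
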