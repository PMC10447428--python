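"""Mask loading, binarization, fusion and the volumetry baseline."""

import numpy as np
import pytest

from gaussmap.mask_io import (EmptyMaskError, GridMismatchError, VoxelMask,
                              fuse_regions, load_mask, mask_volume,
                              read_manifest, save_mask)

from conftest import voxel_sphere_mask


def _write(tmp_path, data, affine=None, name="m.nii.gz"):
    import nibabel as nib
    affine = np.eye(4) if affine is None else affine
    p = tmp_path / name
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine), p)
    return p


class TestLoadMask:
    def test_all_zero_volume_is_an_error(self, tmp_path):
        p = _write(tmp_path, np.zeros((5, 5, 5)))
        with pytest.raises(EmptyMaskError, match="sub01"):
            load_mask(p, subject_id="sub01", region_tag="hippocampus")

    def test_binary_volume_loads_unchanged(self, tmp_path):
        data = np.zeros((4, 4, 4))
        data[1:3, 1:3, 1:3] = 1
        m = load_mask(_write(tmp_path, data), threshold=0.5)
        assert np.array_equal(m.grid, data.astype(np.uint8))

    def test_probabilistic_map_thresholds_at_cut(self, tmp_path):
        data = np.full((3, 3, 3), 0.2)
        data[1, 1, 1] = 0.7
        m = load_mask(_write(tmp_path, data), threshold=0.5)
        assert m.n_foreground == 1 and m.grid[1, 1, 1] == 1

    def test_label_map_selection(self, tmp_path):
        data = np.zeros((4, 4, 4))
        data[0] = 17
        data[1] = 53
        m = load_mask(_write(tmp_path, data), label=53)
        assert m.n_foreground == 16 and m.grid[1].all()

    def test_keep_largest_component(self, tmp_path):
        data = np.zeros((10, 10, 10))
        data[1:5, 1:5, 1:5] = 1  # 64 voxels
        data[8, 8, 8] = 1        # speck
        p = _write(tmp_path, data)
        assert load_mask(p).n_foreground == 65
        assert load_mask(p, keep_largest=True).n_foreground == 64

    def test_bad_threshold_rejected(self, tmp_path):
        p = _write(tmp_path, np.ones((3, 3, 3)))
        with pytest.raises(ValueError):
            load_mask(p, threshold=0.0)

    def test_roundtrip_is_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = (rng.random((7, 6, 5)) > 0.5).astype(np.uint8)
        grid[0, 0, 0] = 1
        # float32-representable entries: the NIfTI-1 header stores the
        # affine in single precision by format
        affine = np.diag([1.25, 1.0, 1.0, 1.0])
        affine[:3, 3] = (3.5, -2.0, 11.0)
        m = VoxelMask(grid=grid, affine=affine)
        save_mask(m, tmp_path / "rt.nii.gz")
        m2 = load_mask(tmp_path / "rt.nii.gz")
        assert np.array_equal(m.grid, m2.grid)
        assert np.array_equal(m.affine, m2.affine)


class TestFuseRegions:
    def _mask(self, coords, shape=(16, 16, 16), affine=None):
        grid = np.zeros(shape, dtype=np.uint8)
        for c in coords:
            grid[c] = 1
        return VoxelMask(grid=grid, affine=np.eye(4) if affine is None
                         else affine)

    def test_disjoint_union_adds_counts(self):
        a = self._mask([(i, 0, 0) for i in range(10)])
        b = self._mask([(0, j, 1) for j in range(6)])
        fused = fuse_regions(a, b)
        assert fused.n_foreground == 16
        assert fused.region_tag == "fused"

    def test_self_fusion_is_idempotent(self):
        a = self._mask([(1, 2, 3), (4, 5, 6)])
        assert np.array_equal(fuse_regions(a, a).grid, a.grid)

    def test_overlap_follows_inclusion_exclusion(self):
        a = self._mask([(i % 16, i // 16, 0) for i in range(100)])
        b = self._mask([(i % 16, i // 16, 0) for i in range(90, 150)])
        assert fuse_regions(a, b).n_foreground == 150

    def test_commutative_and_associative(self):
        rng = np.random.default_rng(3)
        ms = [VoxelMask((rng.random((6, 6, 6)) > 0.6).astype(np.uint8) |
                        _one(), np.eye(4)) for _ in range(3)]
        a, b, c = ms
        assert np.array_equal(fuse_regions(a, b).grid, fuse_regions(b, a).grid)
        assert np.array_equal(fuse_regions(fuse_regions(a, b), c).grid,
                              fuse_regions(a, fuse_regions(b, c)).grid)

    def test_mismatched_space_rejected(self):
        a = self._mask([(0, 0, 0)])
        b = self._mask([(0, 0, 0)], affine=np.diag([2.0, 1, 1, 1]))
        with pytest.raises(GridMismatchError):
            fuse_regions(a, b)
        c = self._mask([(0, 0, 0)], shape=(5, 5, 5))
        with pytest.raises(GridMismatchError):
            fuse_regions(a, c)

    def test_fused_volume_subadditive(self):
        a = self._mask([(i % 16, i // 16, 0) for i in range(100)])
        b = self._mask([(i % 16, i // 16, 0) for i in range(90, 150)])
        assert mask_volume(fuse_regions(a, b)) < mask_volume(a) + mask_volume(b)


def _one():
    g = np.zeros((6, 6, 6), dtype=np.uint8)
    g[0, 0, 0] = 1
    return g


class TestMaskVolume:
    def test_volume_is_count_times_voxel_volume(self):
        grid = np.zeros((20, 20, 20), dtype=np.uint8)
        grid.ravel()[:1000] = 1
        m = VoxelMask(grid=grid, affine=np.diag([1.2, 1.0, 1.0, 1.0]))
        assert mask_volume(m) == pytest.approx(1200.0)

    def test_digitized_sphere_close_to_analytic(self):
        m = voxel_sphere_mask(15.0)
        assert mask_volume(m) == pytest.approx(4 / 3 * np.pi * 15 ** 3,
                                               rel=0.02)

    def test_single_voxel_unit_spacing(self):
        m = VoxelMask(grid=_one(), affine=np.eye(4))
        assert mask_volume(m) == pytest.approx(1.0)


class TestManifest:
    def test_reads_and_resolves_relative_paths(self, tmp_path):
        (tmp_path / "m.csv").write_text(
            "subject_id,label,path_hippocampus,path_amygdala\n"
            "s1,NC,a.nii.gz,b.nii.gz\n")
        df = read_manifest(tmp_path / "m.csv")
        assert df.path_hippocampus[0] == str(tmp_path / "a.nii.gz")

    def test_rejects_missing_columns_and_bad_labels(self, tmp_path):
        (tmp_path / "bad1.csv").write_text("subject_id,label\ns1,NC\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_manifest(tmp_path / "bad1.csv")
        (tmp_path / "bad2.csv").write_text(
            "subject_id,label,path_hippocampus,path_amygdala\n"
            "s1,SICK,a,b\n")
        with pytest.raises(ValueError, match="unknown labels"):
            read_manifest(tmp_path / "bad2.csv")
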