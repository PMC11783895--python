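"""Point-cloud preparation, Gaussian voxelization, Hilbert images, surfaces."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings, strategies as st

from flexfrag import featurize as fz
from conftest import make_fragment


class TestPointCloud:
    def test_pad_keeps_all_originals(self, pro_fragment):
        pc = fz.prepare_pointcloud(pro_fragment, 24, seed=3)
        assert pc.points.shape == (24, 3)
        shifted = pro_fragment.coords - pro_fragment.coords.min(axis=0)
        present = {tuple(np.round(p, 9)) for p in pc.points}
        for p in shifted:
            assert tuple(np.round(p, 9)) in present
        # 7 pad points at the origin
        n_origin = sum(np.allclose(p, 0) for p in pc.points)
        assert n_origin >= 24 - 17

    def test_exact_size_is_permutation(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(10, 3))
        pc = fz.prepare_pointcloud(pts, 10, seed=1)
        shifted = pts - pts.min(axis=0)
        assert sorted(map(tuple, np.round(pc.points, 9))) == \
            sorted(map(tuple, np.round(shifted, 9)))

    def test_subsample_is_subset(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(50, 3))
        pc = fz.prepare_pointcloud(pts, 24, seed=2)
        shifted = {tuple(np.round(p, 9))
                   for p in pts - pts.min(axis=0)}
        assert pc.points.shape == (24, 3)
        for p in pc.points:
            assert tuple(np.round(p, 9)) in shifted

    def test_min_shift_property(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(30, 3)) + 100
        pc = fz.prepare_pointcloud(pts, 30, seed=0)
        assert np.allclose(pc.points.min(axis=0), 0)

    def test_deterministic_and_empty_rejected(self):
        pts = np.random.default_rng(3).normal(size=(40, 3))
        a = fz.prepare_pointcloud(pts, 24, seed=9).points
        b = fz.prepare_pointcloud(pts, 24, seed=9).points
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            fz.prepare_pointcloud(np.zeros((0, 3)), 10)


class TestVoxels:
    def test_single_atom_matches_kernel(self):
        atom = np.array([[7.75, 7.75, 7.75]])  # a voxel center
        g = fz.voxelize(atom, center=False)
        assert g.values[15, 15, 15] == pytest.approx(1.0, abs=1e-12)
        assert g.values[17, 15, 15] == pytest.approx(np.exp(-0.5), abs=1e-12)
        # direct kernel evaluation at every voxel center
        centers = g.voxel_centers()
        d2 = ((centers - atom) ** 2).sum(axis=1)
        expected = np.where(d2 <= 144.0, np.exp(-d2 / 2.0), 0.0)
        assert np.allclose(g.values.ravel(), expected, atol=1e-12)

    def test_cutoff_strictly_enforced(self):
        atom = np.array([[0.25, 0.25, 0.25]])  # corner voxel center
        g = fz.voxelize(atom, center=False)
        centers = g.voxel_centers()
        d = np.sqrt(((centers - atom) ** 2).sum(axis=1))
        vals = g.values.ravel()
        assert (vals[d > 12.0] == 0).all()
        assert (vals[d <= 12.0] > 0).all()

    def test_translation_invariance(self, met_ensemble):
        f = met_ensemble[0]
        a = fz.voxelize(f.coords)
        b = fz.voxelize(f.coords + np.array([37.1, -11.4, 230.0]))
        # geometric centering cancels the shift up to float rounding
        assert np.allclose(a.values, b.values, atol=1e-9)

    def test_rotation_equivariance(self, met_ensemble):
        """90-degree lattice rotation about the box center permutes voxels."""
        f = met_ensemble[1]
        c = f.coords - f.coords.mean(axis=0)
        rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        a = fz.voxelize(c)
        b = fz.voxelize(c @ rot.T)
        assert np.allclose(b.values, np.rot90(a.values, axes=(0, 1)),
                           atol=1e-12)

    def test_mirror_symmetry(self):
        pts = np.array([[1.0, 0.5, -0.25], [-0.75, 0.25, 1.0]])
        a = fz.voxelize(pts)
        b = fz.voxelize(-pts)
        assert np.allclose(b.values, a.values[::-1, ::-1, ::-1], atol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fz.voxelize(np.zeros((0, 3)))


class TestHilbertImage:
    def test_constant_grid_maps_to_constant_image(self):
        g = np.full((32, 32, 32), 3.25)
        img = fz.make_hilbert_image(g)
        assert img.pixels.shape == (128, 128)
        assert np.allclose(img.pixels, 3.25)

    def test_one_hot_grid(self):
        g = np.zeros((32, 32, 32))
        g[4, 21, 9] = 7.0
        vec = fz.flatten_voxels(g)
        assert np.count_nonzero(vec) == 1
        img = fz.make_hilbert_image(g)
        assert np.count_nonzero(img.pixels) == 1
        assert img.pixels.sum() == pytest.approx(3.5)  # mean of the pair

    def test_pixel_count_is_half_voxel_count(self):
        img = fz.make_hilbert_image(np.zeros((32, 32, 32)))
        assert img.pixels.size == 16384 == 32768 // 2

    def test_linearity(self):
        rng = np.random.default_rng(8)
        g1 = rng.random((32, 32, 32))
        g2 = rng.random((32, 32, 32))
        lhs = fz.make_hilbert_image(2.0 * g1 - 0.5 * g2).pixels
        rhs = 2.0 * fz.make_hilbert_image(g1).pixels \
            - 0.5 * fz.make_hilbert_image(g2).pixels
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_intensity_conservation(self):
        rng = np.random.default_rng(9)
        g = rng.random((32, 32, 32))
        img = fz.make_hilbert_image(g)
        assert img.pixels.sum() == pytest.approx(g.sum() / 2.0, rel=1e-12)

    def test_downsample_examples(self):
        assert np.array_equal(fz.downsample_curve(np.array([0.0, 2, 4, 6])),
                              [1.0, 5.0])
        with pytest.raises(ValueError):
            fz.downsample_curve(np.arange(5.0))

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            fz.flatten_voxels(np.zeros((16, 16, 16)))


class TestSurface:
    def test_single_atom_sphere(self):
        mesh = fz.compute_surface(np.zeros((1, 3)))
        r = fz.VDW_RADII["C"] + fz.PROBE_RADIUS
        assert mesh.area() == pytest.approx(4 * np.pi * r * r, rel=0.15)
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        assert tm.is_watertight
        assert tm.euler_number == 2  # genus 0

    def test_two_far_atoms_two_components(self):
        pts = np.array([[0.0, 0, 0], [40.0, 0, 0]])
        mesh = fz.compute_surface(pts, spacing=0.7)
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        assert len(tm.split(only_watertight=False)) == 2

    def test_smoothing_shrinks_area(self):
        raw = fz.compute_surface(np.zeros((1, 3)), smoothing_steps=0)
        smoothed = fz.compute_surface(np.zeros((1, 3)), smoothing_steps=1)
        assert smoothed.area() < raw.area()

    def test_fragment_surface_and_pointcloud(self, ala_fragment):
        pc = fz.surface_pointcloud(ala_fragment, 1500, seed=0)
        assert pc.points.shape == (1500, 3)
        # shift happens before subsampling, so points stay non-negative
        assert (pc.points >= 0).all()


@settings(deadline=None, max_examples=25)
@given(st.integers(min_value=1, max_value=60),
       st.integers(min_value=1, max_value=60),
       st.integers(min_value=0, max_value=2 ** 31 - 1))
def test_pointcloud_size_contract(n_points, target, seed):
    """Output size always equals the target, whatever the input size."""
    pts = np.random.default_rng(seed).normal(size=(n_points, 3))
    pc = fz.prepare_pointcloud(pts, target, seed=seed)
    assert pc.points.shape == (target, 3)
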