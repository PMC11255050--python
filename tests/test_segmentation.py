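import numpy as np
import pytest

from eatkit.exceptions import GeometryError, InputError
from eatkit.segmentation import (
    CompartmentDefinition,
    SparseAnnotation,
    compartment_masks,
    interpolate_sparse_mask,
    pericoronary_cylinder_mask,
)
from eatkit.volume import Centerline, VoxelMask

from conftest import full_mask, make_volume


class TestCompartments:
    def test_band_membership(self):
        vol = make_volume(np.array([-100.0, -30.0, 50.0]).reshape(3, 1, 1) * np.ones((3, 2, 2)))
        low, high, total = compartment_masks(vol, full_mask(vol))
        assert low.voxels[0].all() and not low.voxels[1:].any()
        assert high.voxels[1].all() and not high.voxels[0].any() and not high.voxels[2].any()
        assert np.array_equal(total.voxels, low.voxels | high.voxels)

    def test_boundary_minus_45_belongs_to_low(self):
        vol = make_volume(np.full((2, 2, 2), -45.0))
        low, high, _ = compartment_masks(vol, full_mask(vol))
        assert low.voxels.all() and not high.voxels.any()

    def test_integer_sweep_partitions_fat_range(self):
        """Every HU in [-195, -15] lands in exactly one compartment."""
        hus = np.arange(-195, -14, dtype=float)
        vol = make_volume(np.tile(hus[:, None, None], (1, 2, 2)))
        low, high, total = compartment_masks(vol, full_mask(vol))
        assert not (low.voxels & high.voxels).any()
        assert total.voxels.all()
        # and the half-integer boundary region is classified too (no gap)
        vol2 = make_volume(np.full((2, 2, 2), -44.5))
        _, high2, total2 = compartment_masks(vol2, full_mask(vol2))
        assert high2.voxels.all() and total2.voxels.all()

    def test_empty_roi_gives_empty_masks(self):
        vol = make_volume(np.full((3, 3, 3), -100.0))
        roi = VoxelMask(np.zeros(vol.shape, dtype=bool), vol.spacing, vol.origin)
        for mask in compartment_masks(vol, roi):
            assert not mask.voxels.any()

    def test_grid_mismatch_is_a_geometry_error(self):
        vol = make_volume(np.zeros((3, 3, 3)))
        roi = VoxelMask(np.ones((3, 3, 3), dtype=bool), (2.0, 2.0, 2.0))
        with pytest.raises(GeometryError):
            compartment_masks(vol, roi)

    def test_noncontiguous_bands_rejected(self):
        with pytest.raises(InputError):
            CompartmentDefinition((-195.0, -50.0), (-45.0, -15.0))


def _disc(shape, center, radius):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


class TestSparseInterpolation:
    def test_identical_annotations_propagate_unchanged(self):
        grid = make_volume(np.zeros((32, 32, 12)))
        disc = _disc((32, 32), (16, 16), 6)
        ann = SparseAnnotation(2, {3: disc, 7: disc})
        out = interpolate_sparse_mask(ann, grid)
        for k in range(3, 8):
            assert np.array_equal(out.voxels[:, :, k], disc)
        assert not out.voxels[:, :, :3].any() and not out.voxels[:, :, 8:].any()

    def test_concentric_discs_interpolate_radius(self):
        """Discs of radius 5 and 10 at slices 0/10 give ~7.5 at slice 5."""
        grid = make_volume(np.zeros((40, 40, 11)))
        ann = SparseAnnotation(2, {0: _disc((40, 40), (20, 20), 5),
                                   10: _disc((40, 40), (20, 20), 10)})
        out = interpolate_sparse_mask(ann, grid)
        r_mid = np.sqrt(out.voxels[:, :, 5].sum() / np.pi)
        assert r_mid == pytest.approx(7.5, abs=0.5)

    def test_annotated_slices_reproduced_exactly(self, rng):
        grid = make_volume(np.zeros((20, 20, 9)))
        blobs = {k: rng.random((20, 20)) > 0.6 for k in (1, 4, 8)}
        blobs = {k: m if m.any() else m | True for k, m in blobs.items()}
        ann = SparseAnnotation(2, blobs)
        out = interpolate_sparse_mask(ann, grid)
        for k, m in blobs.items():
            assert np.array_equal(out.voxels[:, :, k], m)

    def test_inserting_own_interpolation_is_idempotent(self):
        grid = make_volume(np.zeros((40, 40, 11)))
        d0, d10 = _disc((40, 40), (20, 20), 5), _disc((40, 40), (20, 20), 10)
        base = interpolate_sparse_mask(SparseAnnotation(2, {0: d0, 10: d10}), grid)
        mid = base.voxels[:, :, 5]
        again = interpolate_sparse_mask(SparseAnnotation(2, {0: d0, 5: mid, 10: d10}), grid)
        # exact in the continuum; on the pixel grid only boundary pixels may flip
        sym_diff = (base.voxels ^ again.voxels).sum()
        assert sym_diff <= 0.05 * base.voxels.sum()

    def test_single_slice_is_a_precondition_error(self):
        with pytest.raises(InputError):
            SparseAnnotation(2, {3: np.ones((4, 4), dtype=bool)})


def _brute_force_cylinder(grid, cl, radius, start, length):
    shape, spacing, origin = grid.shape, grid.spacing, grid.origin
    out = np.zeros(shape, dtype=bool)
    P, arc = cl.points, cl.arc_length
    for i in range(shape[0]):
        for j in range(shape[1]):
            for k in range(shape[2]):
                p = np.array([origin[0] + i * spacing[0],
                              origin[1] + j * spacing[1],
                              origin[2] + k * spacing[2]])
                best_d, best_s = np.inf, 0.0
                for s in range(len(P) - 1):
                    a, b = P[s], P[s + 1]
                    ab = b - a
                    t = float(np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0))
                    d = float(np.linalg.norm(p - (a + t * ab)))
                    if d < best_d:
                        best_d, best_s = d, arc[s] + t * np.linalg.norm(ab)
                out[i, j, k] = best_d <= radius and start <= best_s <= start + length
    return out


class TestPericoronaryCylinder:
    def test_axis_voxel_included_and_strict_radius(self):
        grid = make_volume(np.zeros((9, 9, 12)))
        cl = Centerline([[4.0, 4.0, 0.0], [4.0, 4.0, 11.0]])
        mask = pericoronary_cylinder_mask(grid, cl, radius=4.0, start_offset=2.0, length=6.0)
        assert mask.voxels[4, 4, 5]          # on the axis, inside the window
        assert not mask.voxels[4, 4, 0]      # arc parameter below the window
        # a voxel center at perpendicular distance 4.1 mm is excluded
        grid2 = make_volume(np.zeros((2, 2, 4)), spacing=(4.1, 1.0, 1.0))
        cl2 = Centerline([[0.0, 0.0, 0.0], [0.0, 0.0, 3.0]])
        m2 = pericoronary_cylinder_mask(grid2, cl2, radius=4.0, start_offset=0.0, length=3.0)
        assert m2.voxels[0, 0, 1] and not m2.voxels[1, 0, 1]

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(rng.integers(6, 11, 3))
        spacing = tuple(rng.uniform(0.5, 2.0, 3))
        origin = tuple(rng.uniform(-3, 3, 3))
        grid = make_volume(np.zeros(shape), spacing=spacing, origin=origin)
        pts = np.cumsum(rng.uniform(-4, 4, (3, 3)), axis=0) + np.array(origin)
        cl = Centerline(pts)
        radius = float(rng.uniform(1.0, 5.0))
        start = float(rng.uniform(0, cl.total_length * 0.4))
        length = float(rng.uniform(0.1, cl.total_length - start))
        mask = pericoronary_cylinder_mask(grid, cl, radius, start, length)
        oracle = _brute_force_cylinder(grid, cl, radius, start, length)
        assert np.array_equal(mask.voxels, oracle)

    def test_monotone_in_radius(self, rng):
        grid = make_volume(np.zeros((12, 12, 16)))
        cl = Centerline([[5.0, 5.0, 1.0], [7.0, 6.0, 8.0], [5.0, 5.0, 15.0]])
        m_small = pericoronary_cylinder_mask(grid, cl, 2.0, 1.0, 10.0)
        m_big = pericoronary_cylinder_mask(grid, cl, 4.0, 1.0, 10.0)
        assert not (m_small.voxels & ~m_big.voxels).any()

    def test_translation_invariance(self):
        grid = make_volume(np.zeros((10, 10, 12)))
        cl = Centerline([[4.0, 4.0, 1.0], [5.0, 5.0, 10.0]])
        m1 = pericoronary_cylinder_mask(grid, cl, 3.0, 0.5, 8.0)
        shift = np.array([11.0, -7.0, 3.5])
        grid2 = make_volume(np.zeros((10, 10, 12)), origin=tuple(shift))
        m2 = pericoronary_cylinder_mask(grid2, Centerline(cl.points + shift), 3.0, 0.5, 8.0)
        assert np.array_equal(m1.voxels, m2.voxels)

    def test_too_short_centerline_is_a_geometry_error(self):
        grid = make_volume(np.zeros((5, 5, 5)))
        cl = Centerline([[0.0, 0.0, 0.0], [0.0, 0.0, 5.0]])
        with pytest.raises(GeometryError):
            pericoronary_cylinder_mask(grid, cl, 2.0, start_offset=2.0, length=4.0)
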