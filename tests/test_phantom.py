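"""Segmentation, HU overwrite, cropping, fixtures, and phantom I/O."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from kvplan import phantom as ph
from kvplan import xsdata


def grid_of(hu_value, shape=(4, 4, 4), voxel=(2.0, 2.0, 2.0)):
    return ph.HUGrid(np.full(shape, hu_value, dtype=np.int16), voxel)


class TestSegmentation:
    def test_all_air_below_first_tissue(self):
        p = ph.segment(grid_of(-1000))
        assert p.materials[p.material_index[0, 0, 0]] == "air"
        assert np.all(p.material_index == p.material_index[0, 0, 0])
        assert np.allclose(p.density, xsdata.get_material("air").nominal_density)

    def test_hu_zero_is_unit_density_soft_tissue(self):
        p = ph.segment(grid_of(0))
        name = p.materials[p.material_index[0, 0, 0]]
        assert name in ("muscle", "soft_tissue", "water")
        assert np.allclose(p.density, 1.00)

    def test_one_voxel_per_interval_midpoint(self):
        scheme = ph.default_scheme("torso")
        mids = [lo + min((hi - lo) // 2, 1000)
                for _, (lo, hi), _ in scheme.entries]
        grid = ph.HUGrid(np.array(mids, dtype=np.int32).reshape(-1, 1, 1),
                         (2.0, 2.0, 2.0))
        p = ph.segment(grid, scheme)
        counts = np.bincount(p.material_index.ravel(),
                             minlength=len(scheme.entries))
        assert np.all(counts == 1)

    def test_clamping_counts_out_of_range(self):
        grid = grid_of(-4000, shape=(2, 2, 2))
        p = ph.segment(grid)
        assert p.n_clamped == 8
        assert p.materials[p.material_index[0, 0, 0]] == "air"

    @given(st.integers(min_value=-1024, max_value=39999))
    def test_every_hu_maps_to_exactly_one_material(self, hu):
        scheme = ph.default_scheme("head-neck")
        hits = [name for name, (lo, hi), _ in scheme.entries if lo <= hu < hi]
        assert len(hits) == 1


class TestSchemeValidation:
    def test_gap_rejected(self):
        with pytest.raises(ValueError, match="contiguous"):
            ph.SegmentationScheme("bad", [
                ("air", (ph.HU_MIN, -900), "air"),
                ("tissue", (-800, ph.HU_MAX), "muscle"),
            ])

    def test_incomplete_coverage_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            ph.SegmentationScheme("bad", [
                ("air", (ph.HU_MIN, 0), "air"),
                ("tissue", (0, 100), "muscle"),
            ])

    def test_unknown_material_rejected(self):
        with pytest.raises(KeyError):
            ph.SegmentationScheme("bad", [
                ("air", (ph.HU_MIN, ph.HU_MAX), "vibranium"),
            ])


class TestDensityCurve:
    def test_water_point_and_clamping(self):
        curve = ph.default_density_curve()
        assert curve(0) == pytest.approx(1.00)
        assert curve(-5000) == curve(-1000)  # clamped
        assert curve(99999) == curve(1500)

    def test_monotone_required(self):
        with pytest.raises(ValueError, match="monotone"):
            ph.DensityCurve([-1000, 0, 1000], [0.5, 1.2, 1.0])


class TestOverwrite:
    def test_empty_mask_is_identity(self):
        grid = grid_of(0)
        mask = ph.StructureMask(np.zeros(grid.shape, dtype=bool))
        out = ph.overwrite_structure(grid, mask, 3000)
        assert np.array_equal(out.values, grid.values)

    def test_full_mask_then_segment_gives_lead(self):
        grid = grid_of(0)
        mask = ph.StructureMask(np.ones(grid.shape, dtype=bool))
        out = ph.overwrite_structure(grid, mask, 30000)
        p = ph.segment(out)
        assert all(p.materials[i] == "Pb"
                   for i in np.unique(p.material_index))

    def test_disk_mask_voxel_count(self):
        grid = grid_of(0, shape=(21, 21, 5))
        xx, yy = np.meshgrid(np.arange(21) - 10, np.arange(21) - 10,
                             indexing="ij")
        disk2d = xx**2 + yy**2 <= 25
        mask = np.zeros(grid.shape, dtype=bool)
        mask[:, :, 0] = disk2d
        out = ph.overwrite_structure(grid, ph.StructureMask(mask), 30000)
        p = ph.segment(out)
        lead_idx = p.materials.index("Pb")
        assert np.count_nonzero(p.material_index == lead_idx) == disk2d.sum()

    def test_input_not_modified_and_shape_checked(self):
        grid = grid_of(0)
        before = grid.values.copy()
        mask = ph.StructureMask(np.ones(grid.shape, dtype=bool))
        ph.overwrite_structure(grid, mask, 500)
        assert np.array_equal(grid.values, before)
        with pytest.raises(ValueError, match="shape"):
            ph.overwrite_structure(grid, ph.StructureMask(np.ones((2, 2, 2))), 0)

    def test_overwrite_commutes_with_segmentation(self):
        rng = np.random.default_rng(7)
        grid = ph.HUGrid(rng.integers(-1000, 1500, (5, 5, 5)), (2, 2, 2))
        mask = ph.StructureMask(rng.random((5, 5, 5)) > 0.5)
        seg_after = ph.segment(ph.overwrite_structure(grid, mask, 250))
        direct = grid.values.copy()
        direct[mask.values] = 250
        seg_direct = ph.segment(ph.HUGrid(direct, (2, 2, 2)))
        assert np.array_equal(seg_after.material_index,
                              seg_direct.material_index)


class TestCrop:
    def test_full_range_identity(self):
        grid = grid_of(100, shape=(4, 5, 6))
        out = ph.crop(grid, ((0, 4), (0, 5), (0, 6)))
        assert np.array_equal(out.values, grid.values)
        assert out.origin == grid.origin

    def test_subbox_shape_and_origin_shift(self):
        grid = ph.HUGrid(np.arange(120).reshape(4, 5, 6), (1.0, 2.0, 3.0))
        out = ph.crop(grid, ((1, 3), (2, 5), (0, 4)))
        assert out.shape == (2, 3, 4)
        assert out.origin == (1.0, 4.0, 0.0)
        assert np.array_equal(out.values, grid.values[1:3, 2:5, 0:4])

    def test_bad_bounds_rejected(self):
        grid = grid_of(0)
        with pytest.raises(ValueError):
            ph.crop(grid, ((0, 0), (0, 4), (0, 4)))
        with pytest.raises(ValueError):
            ph.crop(grid, ((0, 9), (0, 4), (0, 4)))


class TestFixtures:
    def test_watertank_paper_dimensions(self):
        tank = ph.make_watertank((40.0, 40.0, 30.0), (2.0, 2.0, 2.0))
        assert tank.shape == (200, 200, 150)
        assert tank.materials == ["water"]

    def test_single_voxel_tank_mass(self):
        tank = ph.make_watertank((0.2, 0.2, 0.2), (2.0, 2.0, 2.0))
        assert tank.shape == (1, 1, 1)
        assert tank.total_mass_g() == pytest.approx(0.008, rel=1e-9)

    def test_tank_mass_is_volume_times_unit_density(self):
        tank = ph.make_watertank((10.0, 10.0, 5.0), (2.0, 2.0, 2.0))
        assert tank.total_mass_g() == pytest.approx(10 * 10 * 5, rel=1e-9)

    def test_three_compartment_all_water_is_tank(self):
        p, _ = ph.make_three_compartment(("water", "water", "water"))
        assert np.all(p.material_index == 0)
        assert np.allclose(p.density, 1.0)

    def test_three_compartment_counts_and_centers(self):
        p, centers = ph.make_three_compartment()
        assert set(centers) == {"water", "adipose", "muscle"}
        adipose_idx = p.materials.index("adipose")
        count = np.count_nonzero(p.material_index == adipose_idx)
        # middle third of x, full y, 6 cm of depth at 2 mm voxels
        assert count == 20 * 60 * 30
        assert np.allclose(
            p.density[p.material_index == adipose_idx],
            xsdata.get_material("adipose").nominal_density)


class TestPhantomIO:
    def test_roundtrip_identity(self, tmp_path):
        p, _ = ph.make_three_compartment()
        path = tmp_path / "p.egsphant"
        ph.write_phantom(p, path)
        back = ph.read_phantom(path)
        assert back.materials == p.materials
        assert np.array_equal(back.material_index, p.material_index)
        assert np.allclose(back.density, p.density, rtol=1e-6)
        assert np.allclose(back.voxel_size, p.voxel_size, rtol=1e-6)

    def test_corrupted_header_reports_line(self, tmp_path):
        path = tmp_path / "bad.egsphant"
        path.write_text("not-a-number\nwater\n")
        with pytest.raises(ValueError, match="line"):
            ph.read_phantom(path)
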