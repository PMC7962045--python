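"""Domain construction: layer stacks, lesion embedding, sensor layout."""

import numpy as np
import pytest

from thermosole import (
    LESION,
    TISSUE,
    GridResolution,
    LayerSpec,
    LesionSpec,
    MaterialProps,
    build_domain,
    default_sensor_layout,
    embed_lesion,
    foot_tissue_layers,
    insole_shoe_layers,
)
from thermosole.geometry import AIR, voxelized_lesion_volume


class TestMaterials:
    def test_invalid_properties_rejected(self):
        with pytest.raises(ValueError):
            MaterialProps("bad", -1.0, 0.5, 1000.0)
        with pytest.raises(ValueError):
            MaterialProps("bad", 1000.0, 0.0, 1000.0)
        with pytest.raises(ValueError):
            MaterialProps("bad", 1000.0, 0.5, 1000.0, metabolic_heat=-1)
        # non-biological materials cannot perfuse or generate metabolic heat
        with pytest.raises(ValueError):
            MaterialProps(
                "bad", 1000.0, 0.5, 1000.0, perfusion_rate=1e-3, biological=False
            )

    def test_ischemia_blood_runs_cooler(self):
        assert LESION["ischemia"].blood_temperature == 35.0
        assert LESION["inflammation"].blood_temperature == 37.0

    def test_zero_thickness_layer_rejected(self):
        with pytest.raises(ValueError):
            LayerSpec(TISSUE["fat"], 0.0)


class TestBuildDomain:
    def test_tissue_interfaces_at_cumulative_thicknesses(self):
        """Tissue interfaces fall at the cumulative depths of the published
        thicknesses 0.46/1.67/1.67/5/25 mm: 0.46, 2.13, 3.80, 8.80, 33.80 mm
        below the skin, to machine precision."""
        grid = build_domain(foot_tissue_layers(), insole_shoe_layers(),
                            resolution=GridResolution(dx=0.013, dy=0.0045))
        skin = grid.skin_z
        depths = sorted(skin - z0 for z0, _ in grid.layer_z_spans[:5])
        np.testing.assert_allclose(
            depths, [0.46e-3, 2.13e-3, 3.80e-3, 8.80e-3, 33.80e-3], rtol=0, atol=1e-12
        )
        # grid lines sit exactly on every interface
        for z0, z1 in grid.layer_z_spans:
            assert np.isclose(grid.z_edges, z0, atol=1e-15).any()
            assert np.isclose(grid.z_edges, z1, atol=1e-15).any()

    def test_insole_stack_thicknesses(self):
        grid = build_domain(foot_tissue_layers(), insole_shoe_layers(),
                            resolution=GridResolution(dx=0.013, dy=0.0045))
        spans = grid.layer_z_spans[5:]
        thick = [z1 - z0 for z0, z1 in spans]
        np.testing.assert_allclose(
            thick, [1e-3, 0.36e-3, 0.018e-3, 3e-3, 15e-3], atol=1e-12
        )

    def test_min_cells_per_layer(self):
        grid = build_domain(foot_tissue_layers(), insole_shoe_layers(),
                            resolution=GridResolution(dx=0.013, dy=0.0045))
        for i in range(len(grid.layers)):
            assert (grid.cell_layer == i).any(axis=(0, 1)).sum() >= 3

    def test_single_layer_degenerate_stack(self, slab_material):
        grid = build_domain([LayerSpec(slab_material, 0.01)],
                            footprint=(0.02, 0.02),
                            resolution=GridResolution(dx=0.01, dy=0.01))
        assert (grid.cell_layer == 0).all()

    def test_footprint_too_small_rejected(self, slab_material):
        with pytest.raises(ValueError):
            build_domain([LayerSpec(slab_material, 0.01)], footprint=(0.003, 0.02),
                         resolution=GridResolution(dx=0.002, dy=0.002))

    def test_contact_patch_voids_tissue_only(self):
        grid = build_domain(
            foot_tissue_layers(), insole_shoe_layers(),
            resolution=GridResolution(dx=0.01, dy=0.01),
            contact_patch=(0.05, 0.21, 0.02, 0.07),
        )
        void = grid.cell_layer == AIR
        assert void.any()
        # void never reaches below the skin interface
        zc = grid.z_centers
        assert not void[:, :, zc > grid.skin_z].any()
        # insole cells span the full footprint
        iz = grid.insole_top_cell_index
        assert (grid.cell_layer[:, :, iz] >= 0).all()


class TestEmbedLesion:
    res = GridResolution(dx=2e-3, dy=2e-3)

    def grid(self):
        return build_domain(foot_tissue_layers(), insole_shoe_layers(),
                            footprint=(0.12, 0.09), resolution=self.res)

    def lesion(self, depth=2.6e-3, volume=1.5e-6, **kw):
        return LesionSpec("inflammation", depth, (0.06, 0.045),
                          volume=volume, **kw)

    def test_lateral_semi_axis_from_height_and_volume(self):
        """Height 2.5 mm and volume 1.5 cm^3 give an oblate ellipsoid with
        c = 1.25 mm and a = b = sqrt(V / (4/3 pi c)) ~ 16.9 mm."""
        les = self.lesion()
        assert les.vertical_semi_axis == pytest.approx(1.25e-3)
        assert les.lateral_semi_axis == pytest.approx(16.93e-3, abs=0.05e-3)

    def test_reassigned_depth_span(self):
        """A 2.6 mm deep lesion center reassigns cells spanning depths
        ~1.35-3.85 mm (center +/- c)."""
        grid = embed_lesion(self.grid(), self.lesion())
        mask = grid.cell_layer == len(grid.layers) - 1
        assert mask.any()
        zc = grid.z_centers
        depths = grid.skin_z - zc[mask.any(axis=(0, 1))]
        assert depths.min() > 1.35e-3 - 0.5e-3
        assert depths.max() < 3.85e-3 + 0.5e-3

    def test_voxelized_volume_within_10pct_at_default_resolution(self):
        grid = embed_lesion(self.grid(), self.lesion())
        vol = voxelized_lesion_volume(grid)
        assert vol == pytest.approx(1.5e-6, rel=0.10)

    def test_volume_converges_with_resolution(self):
        """Voxelization error shrinks as the lateral cell size is halved."""
        errs = []
        for dx in (4e-3, 2e-3, 1e-3):
            res = GridResolution(dx=dx, dy=dx, dz_fine=dx / 4)
            g = build_domain(foot_tissue_layers(), insole_shoe_layers(),
                             footprint=(0.12, 0.09), resolution=res)
            g = embed_lesion(g, self.lesion())
            errs.append(abs(voxelized_lesion_volume(g) - 1.5e-6) / 1.5e-6)
        assert errs[2] < errs[0]
        assert errs[2] < 0.05

    def test_idempotent(self):
        g1 = embed_lesion(self.grid(), self.lesion())
        g2 = embed_lesion(g1, self.lesion())
        # same cells carry lesion material in both grids
        m1 = g1.layer_mask("inflammation")
        m2 = g2.layer_mask("inflammation")
        np.testing.assert_array_equal(m1, m2)

    def test_zero_volume_leaves_grid_unchanged(self):
        g0 = self.grid()
        g1 = embed_lesion(g0, self.lesion(volume=0.0))
        np.testing.assert_array_equal(g0.cell_layer, g1.cell_layer)

    def test_volume_inconsistent_with_height_rejected(self):
        # a < c: volume smaller than the sphere of radius c
        with pytest.raises(ValueError):
            self.lesion(volume=1e-9)

    def test_lesion_outside_footprint_rejected(self):
        grid = self.grid()
        with pytest.raises(ValueError):
            embed_lesion(grid, LesionSpec("inflammation", 2.6e-3, (0.005, 0.045)))


class TestSensorLayout:
    def test_positions_inside_foot_length(self):
        lay = default_sensor_layout(0.247)
        assert lay.positions.shape == (8, 2)
        assert (lay.positions[:, 0] >= 0).all()
        assert (lay.positions[:, 0] <= 0.247).all()
        assert lay.detection_threshold == 0.1

    def test_linear_scaling(self):
        a = default_sensor_layout(0.24)
        b = default_sensor_layout(0.24 * 1.25)
        np.testing.assert_allclose(b.positions, a.positions * 1.25)

    def test_override_passthrough(self):
        pos = np.column_stack([np.linspace(0.02, 0.2, 8), np.full(8, 0.05)])
        lay = default_sensor_layout(0.26, positions=pos)
        np.testing.assert_array_equal(lay.positions, pos)

    def test_out_of_range_foot_length_rejected(self):
        for bad in (0.1, 0.4):
            with pytest.raises(ValueError):
                default_sensor_layout(bad)

    def test_s3_s5_are_nearest_neighbors_of_s4(self):
        """The two sensors flanking S4 in the layout are S3 and S5."""
        lay = default_sensor_layout(0.26)
        s4 = lay.positions[3]
        d = np.linalg.norm(lay.positions - s4, axis=1)
        order = np.argsort(d)
        assert set(order[1:3]) == {2, 4}
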