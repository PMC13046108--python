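"""Layered-phantom geometry, lookup and mass audit."""

import numpy as np
import pytest

from inkdose import build_phantom, material_at, mix_density, tattoo_mixture
from inkdose.errors import GeometryError
from inkdose.phantom import QUADRANTS


class TestStack:
    def test_epidermis_spans_first_tenth_millimetre(self, control_phantom):
        zb = control_phantom.z_bounds
        assert zb[6] == pytest.approx(0.1001)

    def test_scoring_mesh_covers_skin_slab(self, control_phantom):
        ze = control_phantom.z_edges
        assert ze[0] == 0.0 and ze[-1] == pytest.approx(2.4)
        assert len(ze) == 25
        assert control_phantom.x_edges[0] == -5.0
        assert control_phantom.x_edges[-1] == 5.0

    def test_layers_tile_without_gaps(self, brown_phantom):
        layers = brown_phantom.layers
        for a, b in zip(layers[:-1], layers[1:]):
            assert a.z_bottom == pytest.approx(b.z_top)

    def test_tattoo_inside_reticular_dermis(self, brown_phantom):
        t = brown_phantom.layers[brown_phantom.tattoo_layer_index]
        assert (t.z_top, t.z_bottom) == (1.25, 1.55)
        assert brown_phantom.layers[brown_phantom.tattoo_layer_index - 1].z_top < 1.25
        assert brown_phantom.layers[brown_phantom.tattoo_layer_index + 1].z_bottom > 1.55


class TestMaterialAt:
    def test_tattoo_centre_is_pigment_mixture(self, brown_phantom, brown100):
        assert material_at(brown_phantom, 0, 0, 1.40).name == brown100.name

    def test_mid_epidermis_is_stratum_spinosum(self, control_phantom):
        # 50 um lies within the 42.1-92.1 um stratum spinosum
        assert material_at(control_phantom, 0, 0, 0.05).name == "stratum_spinosum"

    def test_backing_region_is_water(self, control_phantom):
        assert material_at(control_phantom, 0, 0, 3.0).name == "water"

    def test_control_tattoo_band_is_dermis(self, control_phantom):
        for z in np.linspace(1.25, 1.5499, 7):
            assert material_at(control_phantom, 0, 0, z).name == "reticular_dermis"

    def test_boundary_point_belongs_to_deeper_layer(self, brown_phantom):
        assert material_at(brown_phantom, 0, 0, 1.25).name != "reticular_dermis"
        assert material_at(brown_phantom, 0, 0, 1.55).name == "reticular_dermis"

    def test_out_of_bounds_signalled(self, control_phantom):
        with pytest.raises(GeometryError):
            material_at(control_phantom, 0, 0, -0.01)
        with pytest.raises(GeometryError):
            material_at(control_phantom, 20.0, 0, 1.0)

    def test_agrees_with_interval_search_oracle(self, brown_phantom):
        # independent oracle: linear scan over the layer intervals
        rng = np.random.default_rng(42)
        zb = brown_phantom.z_bounds
        for _ in range(10_000):
            x, y = rng.uniform(-14.9, 14.9, size=2)
            z = rng.uniform(0, zb[-1] - 1e-9)
            expected = None
            for layer in brown_phantom.layers:
                if layer.z_top <= z < layer.z_bottom:
                    expected = layer.material.name
                    break
            got = material_at(brown_phantom, x, y, z).name
            assert got == expected


class TestQuadrantLayout:
    @pytest.fixture(scope="class")
    def quad_phantom(self, tables):
        inks = {
            "top_left": None,
            "top_right": tattoo_mixture("black", 100, tables),
            "bottom_left": tattoo_mixture("orange", 100, tables),
            "bottom_right": tattoo_mixture("brown", 100, tables),
        }
        return build_phantom(layout="quadrant", quadrant_inks=inks, tables=tables)

    def test_published_quadrant_assignment(self, quad_phantom):
        assert quad_phantom.quadrant_map["top_left"] is None
        assert "black" in quad_phantom.quadrant_map["top_right"]
        assert "orange" in quad_phantom.quadrant_map["bottom_left"]
        assert "brown" in quad_phantom.quadrant_map["bottom_right"]

    def test_lookup_respects_quadrants(self, quad_phantom):
        assert material_at(quad_phantom, -2, 2, 1.4).name == "reticular_dermis"
        assert "black" in material_at(quad_phantom, 2, 2, 1.4).name
        assert "orange" in material_at(quad_phantom, -2, -2, 1.4).name
        assert "brown" in material_at(quad_phantom, 2, -2, 1.4).name

    def test_quadrant_scoring_bins_nest(self, quad_phantom):
        # 2.5 mm bins align with the 0-centred quadrant edges
        assert 0.0 in quad_phantom.x_edges
        assert len(quad_phantom.x_edges) == 5

    def test_missing_assignment_rejected(self, tables):
        with pytest.raises(GeometryError):
            build_phantom(layout="quadrant", quadrant_inks={"top_left": None})


class TestMassAudit:
    def test_loading_changes_mass_as_mix_density_predicts(self, tables):
        area_cm2 = 1.0  # scoring voxels cover well-defined columns
        m0 = build_phantom(tables=tables).scoring_mass_grid().sum()
        for pct in (25, 50, 100):
            mat = tattoo_mixture("brown", pct, tables)
            m = build_phantom(tattoo_material=mat, tables=tables)
            delta = m.scoring_mass_grid().sum() - m0
            rho = mix_density(pct / 100, 5.3, 1.1)
            expected = (rho - 1.1) * 0.03 * area_cm2  # 0.3 mm over 1 cm^2
            assert delta == pytest.approx(expected, rel=1e-9)

    def test_total_mass_consistent_with_layer_sum(self, control_phantom):
        by_layers = sum(
            l.material.density * (l.z_bottom - l.z_top) / 10.0 * 9.0
            for l in control_phantom.layers
        )
        assert control_phantom.total_mass() == pytest.approx(by_layers)
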