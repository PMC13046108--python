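"""Mixture rules, skin materials and the printed density table."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inkdose import (
    Material,
    MixtureSpec,
    blend_materials,
    ink_material,
    mix_density,
    mixture_mass_fractions,
    skin_material,
    table1_densities,
    tattoo_mixture,
)
from inkdose.errors import DomainError


class TestMixDensity:
    @pytest.mark.parametrize(
        "v, rho_ink, expected_rounded",
        [
            (0.50, 5.3, 3.2),
            (0.0, 5.3, 1.1),
            (0.75, 2.4, 2.1),  # exact 2.075
        ],
    )
    def test_printed_examples(self, v, rho_ink, expected_rounded):
        assert round(mix_density(v, rho_ink, 1.1), 1) == expected_rounded

    def test_rejects_out_of_range_volume(self):
        with pytest.raises(DomainError):
            mix_density(1.2, 5.3, 1.1)
        with pytest.raises(DomainError):
            mix_density(-0.1, 5.3, 1.1)

    @given(v=st.floats(0, 1), dv=st.floats(0, 1))
    @settings(max_examples=50, derandomize=True)
    def test_monotone_when_ink_denser(self, v, dv):
        v2 = min(v + dv, 1.0)
        assert mix_density(v2, 5.3, 1.1) >= mix_density(v, 5.3, 1.1)

    def test_full_printed_table_reproduced(self, tables):
        df = table1_densities(tables)
        assert len(df) == 21
        from importlib import resources

        with resources.as_file(
            resources.files("inkdose") / "data" / "table1_printed.csv"
        ) as p:
            import pandas as pd

            printed = pd.read_csv(p, comment="#")
        merged = df.merge(printed, on=["color", "loading_vol_percent"])
        assert np.allclose(merged["rounded"], merged["printed_density"])


class TestMassFractions:
    def test_hand_computed_binary_mix(self):
        w = mixture_mass_fractions([0.5, 0.5], [5.3, 1.1])
        assert w == pytest.approx([0.828125, 0.171875], abs=1e-4)
        assert w.sum() == pytest.approx(1.0)

    def test_single_component_and_equal_densities(self):
        assert mixture_mass_fractions([1.0, 0.0], [5.3, 1.1]) == pytest.approx(
            [1.0, 0.0]
        )
        v = [0.3, 0.7]
        assert mixture_mass_fractions(v, [2.0, 2.0]) == pytest.approx(v)

    def test_denser_component_gets_larger_weight(self):
        w = mixture_mass_fractions([0.5, 0.5], [2.0, 1.0])
        assert w[0] > w[1]

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DomainError):
            mixture_mass_fractions([0.5, 0.4], [1.0, 1.0])  # volumes != 1
        with pytest.raises(DomainError):
            mixture_mass_fractions([0.5, 0.5], [0.0, 0.0])  # zero mass


class TestBlend:
    def test_single_component_identity(self, dermis):
        out = blend_materials(MixtureSpec(components=[(dermis, 1.0)]))
        assert out.density == dermis.density
        for el, f in dermis.elemental_fractions.items():
            assert out.elemental_fractions[el] == pytest.approx(f)

    def test_full_loading_is_pure_pigment(self, tables):
        m = tattoo_mixture("brown", 100, tables)
        pig = ink_material("brown", tables)
        assert m.density == 5.3
        assert m.elemental_fractions["Fe"] == pytest.approx(
            pig.elemental_fractions["Fe"]
        )

    def test_half_loading_iron_scales_with_mass_weight(self, tables):
        pig = ink_material("brown", tables)
        m = tattoo_mixture("brown", 50, tables)
        w_pigment = 0.5 * 5.3 / (0.5 * 5.3 + 0.5 * 1.1)
        expected = w_pigment * pig.elemental_fractions["Fe"]
        # dermis carries a trace of Fe as well
        assert m.elemental_fractions["Fe"] == pytest.approx(expected, rel=2e-3)

    @given(v=st.floats(0.0, 1.0))
    @settings(max_examples=30, derandomize=True)
    def test_mass_conservation_under_blending(self, v, tables):
        pig = ink_material("orange", tables)
        der = skin_material("reticular_dermis", tables)
        out = blend_materials(
            MixtureSpec(components=[(pig, v), (der, 1.0 - v)])
        )
        assert sum(out.elemental_fractions.values()) == pytest.approx(
            1.0, abs=1e-9
        )


class TestSkinMaterials:
    @pytest.mark.parametrize(
        "layer, density",
        [("reticular_dermis", 1.1), ("upper_SC", 1.3), ("middle_SC", 1.2)],
    )
    def test_printed_layer_densities(self, tables, layer, density):
        m = skin_material(layer, tables)
        assert m.density == density
        assert sum(m.elemental_fractions.values()) == pytest.approx(1.0)

    def test_unknown_layer_rejected(self, tables):
        with pytest.raises(KeyError):
            skin_material("hypodermis", tables)


class TestMaterialCard:
    def test_round_trip(self, brown100):
        again = Material.from_card(brown100.to_card())
        assert again.name == brown100.name
        assert again.density == brown100.density
        assert again.elemental_fractions == dict(brown100.elemental_fractions)

    def test_invalid_material_rejected(self):
        with pytest.raises(DomainError):
            Material(name="bad", density=-1.0, elemental_fractions={"H": 1.0})
        with pytest.raises(DomainError):
            Material(name="bad", density=1.0, elemental_fractions={"H": 0.5})
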