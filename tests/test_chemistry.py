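"""Wet/dry conversion, pigment closure and REACH compliance."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inkdose import (
    InkComposition,
    Verdict,
    dry_mass_fractions,
    packaged_ink,
    reach_compliance,
    wet_to_dry,
)
from inkdose.chemistry import ink_from_csv, ink_to_csv
from inkdose.errors import CompositionError, DomainError

FE2O3_O_PER_FE = 3 * 15.999 / (2 * 55.845)


class TestWetToDry:
    @pytest.mark.parametrize(
        "c_wet, f_dry, expected",
        [
            (88400, 0.47, 188085.1),  # brown Fe
            (1830, 0.47, 3893.6),  # orange Al
            (123.4, 1.0, 123.4),  # all-solids identity
        ],
    )
    def test_quotient(self, c_wet, f_dry, expected):
        assert wet_to_dry(c_wet, f_dry) == pytest.approx(expected, abs=0.05)

    @pytest.mark.parametrize("f_dry", [0.0, -0.1, 1.5])
    def test_domain_errors(self, f_dry):
        with pytest.raises(DomainError):
            wet_to_dry(100.0, f_dry)

    @given(
        c=st.floats(0, 1e6, allow_nan=False),
        f=st.floats(0.01, 1.0, exclude_min=True),
        k=st.floats(0.1, 10),
    )
    @settings(max_examples=50, derandomize=True)
    def test_linear_in_concentration_and_inverse_in_dry_fraction(self, c, f, k):
        assert wet_to_dry(k * c, f) == pytest.approx(k * wet_to_dry(c, f), rel=1e-12)
        assert wet_to_dry(c, f) * f == pytest.approx(c, rel=1e-12)


# printed compliance column: element -> set of inks exceeding the limit
PRINTED_EXCEEDS = {
    "Cr": {"brown", "orange", "black"},
    "Co": {"brown", "orange"},
    "Ni": {"brown", "orange"},
    "Cu": {"brown"},
    "Cd": set(),
    "Ba": set(),
    "Hg": set(),
    "Pb": {"brown", "orange"},
}


class TestCompliance:
    @pytest.fixture(scope="class")
    def reports(self, tables):
        return {
            c: reach_compliance(packaged_ink(c, tables), tables.reach_limits)
            for c in ("brown", "orange", "black")
        }

    @pytest.mark.parametrize("element", sorted(PRINTED_EXCEEDS))
    def test_reproduces_printed_verdict_column(self, reports, element):
        for color, rep in reports.items():
            v = rep.verdicts[element]
            if color in PRINTED_EXCEEDS[element]:
                assert v is Verdict.EXCEEDS
            elif v is not Verdict.BELOW_LOQ:
                assert v is Verdict.WITHIN

    def test_unlimited_elements_not_applicable(self, reports):
        for rep in reports.values():
            assert rep.verdicts["Fe"] is Verdict.NOT_APPLICABLE
            assert rep.verdicts["Al"] is Verdict.NOT_APPLICABLE

    def test_orange_copper_below_loq(self, reports):
        assert reports["orange"].verdicts["Cu"] is Verdict.BELOW_LOQ

    def test_exceeds_iff_strictly_above_limit(self, tables):
        ink = InkComposition(
            color="edge",
            wet_ppm={"Cd": 0.5, "Pb": 0.7000001},
            dry_matter_fraction=0.47,
            dominant_compound="carbon-black",
            bulk_density=1.8,
        )
        rep = reach_compliance(ink, tables.reach_limits)
        assert rep.verdicts["Cd"] is Verdict.WITHIN  # at the limit, not above
        assert rep.verdicts["Pb"] is Verdict.EXCEEDS


class TestDryMassFractions:
    def test_black_is_almost_pure_carbon(self, tables):
        fr, rho = dry_mass_fractions(packaged_ink("black", tables))
        assert fr["C"] > 0.99
        assert rho == 1.8

    def test_brown_oxygen_bound_stoichiometrically(self, tables):
        fr, rho = dry_mass_fractions(packaged_ink("brown", tables))
        assert rho == 5.3
        assert fr["O"] >= FE2O3_O_PER_FE * fr["Fe"] - 1e-12

    @pytest.mark.parametrize("color", ["brown", "orange", "black"])
    def test_fractions_sum_to_one(self, tables, color):
        fr, _ = dry_mass_fractions(packaged_ink(color, tables))
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(v >= 0 for v in fr.values())

    def test_overfull_composition_rejected(self):
        ink = InkComposition(
            color="impossible",
            wet_ppm={"Fe": 400000.0},
            dry_matter_fraction=0.31,
            dominant_compound="Fe2O3",
            bulk_density=5.3,
        )
        with pytest.raises(CompositionError):
            dry_mass_fractions(ink, closure="binder")
        ink2 = InkComposition(
            color="impossible2",
            wet_ppm={"Cu": 400000.0},
            dry_matter_fraction=0.31,
            dominant_compound="carbon-black",
            bulk_density=1.8,
        )
        with pytest.raises(CompositionError):
            dry_mass_fractions(ink2)

    def test_compound_closure_makes_brown_iron_oxide_dominant(self, tables):
        fr, _ = dry_mass_fractions(packaged_ink("brown", tables))
        fe2o3 = fr["Fe"] + fr["O"]
        assert fe2o3 > 0.99
        # binder closure instead leaves the assayed iron content intact
        fr_b, _ = dry_mass_fractions(
            packaged_ink("brown", tables), closure="binder"
        )
        assert fr_b["Fe"] == pytest.approx(0.0884 / 0.47, rel=1e-6)
        assert fr_b["C"] > 0.5

    def test_ink_csv_round_trip(self, tables, tmp_path):
        for color in ("brown", "orange"):
            ink = packaged_ink(color, tables)
            path = tmp_path / f"{color}.csv"
            ink_to_csv(ink, path)
            again = ink_from_csv(path)
            assert again == ink

    def test_random_inks_make_valid_materials(self):
        from inkdose import Material

        for seed in range(20):
            from inkdose import make_random_ink

            ink = make_random_ink(seed, 4)
            fr, rho = dry_mass_fractions(ink)
            Material(name="t", density=rho, elemental_fractions=fr)
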