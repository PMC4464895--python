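"""Food-chemistry derivations: AP, TNC, fuel-value energy, AP:NPE, substitution."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nutgeom import food_composition as fc

conc = st.floats(0, 100, allow_nan=False)


def _energy_terms(ap, tnc, fat, ndf, adf, lignin):
    """Independent term-by-term oracle for the fuel-value sum (kJ/g)."""
    return [
        ap / 100 * 16.736,
        tnc / 100 * 16.736,
        fat / 100 * 37.656,
        0.3911 * (adf - lignin) / 100 * 12.552,
        0.5197 * (ndf - adf) / 100 * 12.552,
    ]


class TestAvailableProtein:
    @pytest.mark.parametrize("cp,adicp,expected", [(10, 2, 8), (5, 5, 0)])
    def test_subtraction(self, cp, adicp, expected):
        assert fc.available_protein(cp, adicp) == expected

    def test_adicp_above_cp_names_food(self):
        with pytest.raises(fc.CompositionError, match="badfood"):
            fc.available_protein(4, 6, food_id="badfood")


class TestTnc:
    @pytest.mark.parametrize("args,expected", [
        ((5, 10, 2, 5, 40), 42),
        ((0, 0, 0, 0, 0), 100),
    ])
    def test_by_difference(self, args, expected):
        assert fc.compute_tnc(*args) == expected

    def test_negative_clamps_with_warning(self):
        with pytest.warns(fc.NutrientWarning):
            assert fc.compute_tnc(30, 40, 0, 20, 40) == 0

    def test_mass_closure_when_unclamped(self):
        ap = fc.available_protein(12, 3)
        tnc = fc.compute_tnc(4, 12, 3, 6, 38)
        assert ap + tnc + 4 + 6 + 38 == pytest.approx(100, abs=1e-12)


class TestEnergyDensity:
    def test_pure_fat_gives_fat_fuel_value(self):
        assert fc.energy_density(0, 0, 100, 0, 0, 0) == pytest.approx(37.656)

    def test_empty_food_is_zero(self):
        assert fc.energy_density(0, 0, 0, 0, 0, 0) == 0

    def test_against_term_sum_oracle(self):
        terms = _energy_terms(10, 40, 5, 45, 30, 10)
        assert fc.energy_density(10, 40, 5, 45, 30, 10) == pytest.approx(
            sum(terms), rel=1e-12)
        assert sum(terms) == pytest.approx(12.2111, abs=5e-4)

    def test_fiber_cascade_violation_rejected(self):
        with pytest.raises(fc.CompositionError):
            fc.energy_density(5, 20, 2, 30, 40, 5)   # ADF > NDF

    @given(ap=st.floats(0, 30), tnc=st.floats(0, 60), fat=st.floats(0, 30),
           ndf=st.floats(0, 60), f_adf=st.floats(0, 1), f_lig=st.floats(0, 1))
    def test_term_sum_property(self, ap, tnc, fat, ndf, f_adf, f_lig):
        adf = ndf * f_adf
        lignin = adf * f_lig
        expected = sum(_energy_terms(ap, tnc, fat, ndf, adf, lignin))
        assert fc.energy_density(ap, tnc, fat, ndf, adf, lignin) == pytest.approx(
            expected, rel=1e-12, abs=1e-15)

    def test_monotone_in_each_macronutrient(self):
        base = fc.energy_density(5, 30, 3, 40, 25, 10)
        assert fc.energy_density(6, 30, 3, 40, 25, 10) > base
        assert fc.energy_density(5, 31, 3, 40, 25, 10) > base
        assert fc.energy_density(5, 30, 4, 40, 25, 10) > base


class TestApNpe:
    def test_zero_protein_food_is_zero(self):
        # zero available protein forces the ratio to 0 whatever the fiber
        # energy convention assumes about ADF and lignin
        for adf, lignin in [(30, 15), (46.6, 0), (20, 20)]:
            assert fc.food_ap_npe(0, 20.1, 25.3, 46.6, adf, lignin) == 0.0

    def test_ratio_of_energies(self):
        # AP kJ = 100, NPE kJ = 1000 -> 0.1 (built from round numbers)
        ap = 100 / 16.736 * 100 / 100  # % DM giving 100 kJ per 100 g
        ratio = fc.food_ap_npe(ap, tnc=0, fat=0, ndf=100, adf=100, lignin=0)
        fiber_kj = 0.3911 * 1.0 * 12.552
        assert ratio == pytest.approx((ap / 100 * 16.736) / fiber_kj)

    def test_leaf_example_against_oracle(self):
        terms = _energy_terms(11.5, 52.1, 5.7, 29.5, 20, 8)
        npe = sum(terms[1:])
        ratio = fc.food_ap_npe(11.5, 52.1, 5.7, 29.5, 20, 8)
        assert ratio == pytest.approx(terms[0] / npe, rel=1e-12)
        # including digestible-fiber energy in NPE lowers the ratio below
        # its fiber-free value (~0.177 for this leaf)
        fiber_free = terms[0] / sum(terms[1:3])
        assert fiber_free == pytest.approx(0.177, abs=1e-3)
        assert ratio < fiber_free

    def test_no_npe_errors(self):
        with pytest.raises(fc.CompositionError):
            fc.food_ap_npe(10, 0, 0, 0, 0, 0)

    def test_scale_invariance(self):
        """The ratio depends on composition, not on food amount."""
        r = fc.food_ap_npe(8, 40, 4, 40, 25, 10)
        day_ap_kj = 250.0 * 8 / 100 * 16.736     # any amount eaten
        day_npe = day_ap_kj / r
        assert day_ap_kj / day_npe == pytest.approx(r, rel=1e-12)


class TestShares:
    @given(ap=st.floats(0.1, 30), tnc=st.floats(0.1, 60), fat=st.floats(0, 30))
    def test_sum_to_100(self, ap, tnc, fat):
        shares = fc.macronutrient_energy_shares(ap, tnc, fat)
        assert sum(shares) == pytest.approx(100, abs=1e-9)

    def test_zero_energy_errors(self):
        with pytest.raises(fc.CompositionError):
            fc.macronutrient_energy_shares(0, 0, 0)


class TestDeriveFrame:
    def test_matches_scalar_path(self, library_frame):
        derived = fc.derive_frame(library_frame)
        row = library_frame.iloc[4]
        rec = fc.FoodComposition(**row.to_dict())
        scalar = fc.derive(rec)
        got = derived.iloc[4]
        assert got["ap"] == pytest.approx(scalar.ap, rel=1e-12)
        assert got["tnc"] == pytest.approx(scalar.tnc, rel=1e-12)
        assert got["energy_kj_per_g"] == pytest.approx(
            scalar.energy_density, rel=1e-12)
        assert got["ap_npe"] == pytest.approx(scalar.ap_npe, rel=1e-12)

    def test_mass_closure(self, derived_library):
        total = (derived_library["ap"] + derived_library["tnc"]
                 + derived_library["fat"] + derived_library["ash"]
                 + derived_library["ndf"])
        assert np.allclose(total, 100.0)


def _rec(food_id, genus, part, fat, measured=True, **over):
    base = dict(species=f"{genus} sp", cp=8.0, adicp=2.0, ash=5.0,
                ndf=40.0, adf=28.0, lignin=10.0)
    base.update(over)
    return fc.FoodComposition(food_id=food_id, genus=genus, part_code=part,
                              fat=fat, measured=measured, **base)


class TestSubstitution:
    def test_direct_record_returned(self):
        lib = [_rec("A", "Ficus", "YL", fat=2.0)]
        got = fc.substitute_composition("A", "Ficus sp", "Ficus", "YL", lib)
        assert got.provenance == "direct" and got.fat == 2.0

    def test_congener_mean(self):
        lib = [_rec("A", "Ficus", "YL", fat=2.0), _rec("B", "Ficus", "YL", fat=4.0),
               _rec("C", "Maesa", "YL", fat=9.0)]
        got = fc.substitute_composition("X", "Ficus nova", "Ficus", "YL", lib)
        assert got.provenance == "congener"
        assert got.fat == pytest.approx(3.0)

    def test_part_average_fallback(self):
        lib = [_rec("A", "Ficus", "YL", fat=2.0), _rec("B", "Maesa", "YL", fat=4.0)]
        got = fc.substitute_composition("X", "Other sp", "Other", "YL", lib)
        assert got.provenance == "part_average"
        assert got.fat == pytest.approx(3.0)

    def test_young_leaf_missing_fat_filled_with_part_average(self):
        # unassayed young-leaf fat takes the young-leaf average (here 1.8%)
        lib = [_rec("A", "Ficus", "YL", fat=None),
               _rec("B", "Maesa", "YL", fat=1.2),
               _rec("C", "Garcinia", "YL", fat=2.4)]
        got = fc.substitute_composition("A", "Ficus sp", "Ficus", "YL", lib)
        assert got.fat == pytest.approx(1.8)

    def test_unresolvable_part_errors(self):
        lib = [_rec("A", "Ficus", "YL", fat=2.0)]
        with pytest.raises(fc.CompositionError):
            fc.substitute_composition("X", "s", "g", "SD", lib)

    def test_unknown_part_code_rejected(self):
        with pytest.raises(fc.CompositionError):
            _rec("A", "Ficus", "LEAF", fat=1.0)
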