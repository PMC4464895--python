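"""Bout-to-daily-intake accumulation, rate pooling, seasons, scaling."""

import numpy as np
import pandas as pd
import pytest

from nutgeom import food_composition as fc
from nutgeom import intake_engine as ie


class TestSeasons:
    @pytest.mark.parametrize("period,season,lean", [
        (1, 1, True), (2, 1, True), (3, 2, False), (5, 2, False),
        (6, 3, False), (8, 3, False), (9, 4, True), (10, 4, True),
        (11, 5, True), (12, 5, True),
    ])
    def test_mapping(self, period, season, lean):
        assert ie.assign_season(period) == (season, lean)

    @pytest.mark.parametrize("bad", [0, 13, -1, "x"])
    def test_out_of_range(self, bad):
        with pytest.raises(ie.IntakeError):
            ie.assign_season(bad)


class TestRatePooling:
    def test_duration_weighted(self):
        recs = [ie.IntakeRateRecord("f", "count_per_interval", 10, 60),
                ie.IntakeRateRecord("f", "count_per_interval", 20, 40)]
        assert ie.pool_intake_rate(recs) == pytest.approx(0.30)

    def test_single_record(self):
        recs = [ie.IntakeRateRecord("f", "per_item_duration", 6, 60)]
        assert ie.pool_intake_rate(recs) == pytest.approx(0.10)

    def test_empty_errors(self):
        with pytest.raises(ie.IntakeError):
            ie.pool_intake_rate([])

    def test_modes_pool_identically(self):
        a = [ie.IntakeRateRecord("f", "count_per_interval", 12, 120)]
        b = [ie.IntakeRateRecord("f", "per_item_duration", 12, 120)]
        assert ie.pool_intake_rate(a) == ie.pool_intake_rate(b)

    def test_mixed_foods_rejected(self):
        recs = [ie.IntakeRateRecord("f", "count_per_interval", 1, 10),
                ie.IntakeRateRecord("g", "count_per_interval", 1, 10)]
        with pytest.raises(ie.IntakeError):
            ie.pool_intake_rate(recs)


class TestScaling:
    def test_unit_mass_identity(self):
        assert ie.scale_energy(1673.6, 1.0) == pytest.approx(1673.6)

    def test_five_kg_oracle(self):
        assert ie.scale_energy(1704.5, 5.0) == pytest.approx(
            1704.5 / 5 ** 0.762, rel=1e-12)
        assert ie.scale_energy(1704.5, 5.0) == pytest.approx(500, abs=0.02)

    def test_zero_energy(self):
        assert ie.scale_energy(0, 5.0) == 0

    def test_nonpositive_mass_errors(self):
        with pytest.raises(ie.IntakeError):
            ie.scale_energy(100, 0)


class TestProteinRequirement:
    @pytest.mark.parametrize("g_per_kg,mass,expected", [
        (2.8, 5, 234), (1.8, 5, 151), (1.0, 1, 17),
    ])
    def test_conversion(self, g_per_kg, mass, expected):
        assert ie.protein_requirement_kj(g_per_kg, mass) == expected


def _single_food_frame():
    comp = pd.DataFrame([{
        "food_id": "L1", "species": "s", "genus": "g", "part_code": "YL",
        "cp": 9.0, "adicp": 1.0, "fat": 2.0, "ash": 5.0,
        "ndf": 40.0, "adf": 28.0, "lignin": 10.0,
    }])
    # composition with AP 8%, energy from the fuel-value sum
    return fc.derive_frame(comp)


class TestDailyIntake:
    def test_single_bout_products(self):
        derived = _single_food_frame()
        bout = ie.FeedingBout("a1", "G1", "2006-06-20", 1, "L1", 60.0)
        di = ie.daily_intake([bout], {"L1": 0.5}, {"L1": ie.FoodHandling("L1", 0.2)},
                             derived, ie.BodyMass("a1", 5.0))
        assert di.dry_mass_g == pytest.approx(6.0)
        assert di.ap_g == pytest.approx(6.0 * 0.08)
        assert di.energy_kj == pytest.approx(
            6.0 * derived["energy_kj_per_g"].iat[0], rel=1e-12)
        assert di.season == 1 and di.lean

    def test_empty_day_is_zero_with_missing_ratio(self):
        di = ie.daily_intake([], {}, {}, _single_food_frame(),
                             ie.BodyMass("a1", 5.0))
        assert di.dry_mass_g == 0 and di.energy_kj == 0
        assert di.ap_npe is None

    def test_bout_additivity(self):
        derived = _single_food_frame()
        rates, handling = {"L1": 0.5}, {"L1": ie.FoodHandling("L1", 0.2)}
        bm = ie.BodyMass("a1", 5.0)
        one = ie.daily_intake(
            [ie.FeedingBout("a1", "G1", "2006-06-20", 1, "L1", 60.0)],
            rates, handling, derived, bm)
        two = ie.daily_intake(
            [ie.FeedingBout("a1", "G1", "2006-06-20", 1, "L1", 30.0),
             ie.FeedingBout("a1", "G1", "2006-06-20", 1, "L1", 30.0)],
            rates, handling, derived, bm)
        for attr in ("dry_mass_g", "energy_kj", "ap_g", "tnc_g", "ndf_g"):
            assert getattr(two, attr) == pytest.approx(
                getattr(one, attr), rel=1e-9)

    def test_soil_excluded_but_audited(self):
        derived = _single_food_frame()
        bouts = [ie.FeedingBout("a1", "G1", "2006-06-20", 1, "L1", 60.0),
                 ie.FeedingBout("a1", "G1", "2006-06-20", 1, "soil", 45.0,
                                is_soil=True)]
        di = ie.daily_intake(bouts, {"L1": 0.5},
                             {"L1": ie.FoodHandling("L1", 0.2)}, derived,
                             ie.BodyMass("a1", 5.0))
        assert di.soil_time_s == 45.0
        assert di.feeding_time_s == 60.0
        assert di.dry_mass_g == pytest.approx(6.0)

    def test_unresolvable_food_names_food(self):
        with pytest.raises(ie.IntakeError, match="mystery"):
            ie.daily_intake(
                [ie.FeedingBout("a1", "G1", "2006-06-20", 1, "mystery", 60.0)],
                {"mystery": 0.5}, {"mystery": ie.FoodHandling("mystery", 0.2)},
                _single_food_frame(), ie.BodyMass("a1", 5.0))


class TestBatchAgainstNaiveOracle:
    """The vectorised pipeline must equal a naive per-bout accumulation."""

    @staticmethod
    def _naive(bouts, pooled, handling, derived, masses):
        comp = derived.set_index("food_id")
        rows = {}
        for b in bouts.itertuples(index=False):
            if b.is_soil:
                continue
            key = (b.focal_id, b.date)
            r = rows.setdefault(key, dict.fromkeys(
                ("mass", "energy", "ap", "fruit"), 0.0))
            c = comp.loc[b.food_id]
            h = handling.set_index("food_id").loc[b.food_id]
            m = (b.duration_s * pooled[b.food_id]
                 * h["unit_mass_g"] * h["conversion_factor"])
            r["mass"] += m
            r["energy"] += m * c["energy_kj_per_g"]
            r["ap"] += m * c["ap"] / 100
            if c["part_code"] in fc.FRUIT_SEED_PARTS:
                r["fruit"] += m
        return rows

    def test_randomised_days(self, noisy_daily):
        # regenerate the same study and compare against the naive loop
        from nutgeom import synthetic_data as sd
        study = sd.gen_study(sd.StudyConfig(seed=2), noise=True)
        derived = fc.derive_frame(study.foods)
        pooled = ie.pool_rates(study.rates).to_dict()
        sample_days = noisy_daily.sample(30, random_state=0)
        keys = set(zip(sample_days["focal_id"], sample_days["date"]))
        bouts = study.bouts[
            [k in keys for k in zip(study.bouts["focal_id"], study.bouts["date"])]]
        naive = self._naive(bouts, pooled, study.handling, derived,
                            study.body_masses)
        got = noisy_daily.set_index(["focal_id", "date"])
        for key, r in naive.items():
            row = got.loc[key]
            assert row["dry_mass_g"] == pytest.approx(r["mass"], rel=1e-9)
            assert row["energy_kj"] == pytest.approx(r["energy"], rel=1e-9)
            assert row["ap_g"] == pytest.approx(r["ap"], rel=1e-9)
            frac = r["fruit"] / r["mass"] if r["mass"] else 0.0
            assert row["frac_mass_fruit_seed"] == pytest.approx(frac, rel=1e-9)


class TestDayInvariants:
    def test_scale_equivariance(self, noise_free_study):
        """Doubling all durations doubles amounts, fixes ratios."""
        study = noise_free_study
        derived = fc.derive_frame(study.foods)
        doubled = study.bouts.copy()
        doubled["duration_s"] *= 2.0
        base = ie.compute_daily_intakes(study.bouts, study.rates, study.handling,
                                        derived, study.body_masses)
        twice = ie.compute_daily_intakes(doubled, study.rates, study.handling,
                                         derived, study.body_masses)
        assert np.allclose(twice["dry_mass_g"], 2 * base["dry_mass_g"])
        assert np.allclose(twice["energy_kj"], 2 * base["energy_kj"])
        assert np.allclose(twice["ap_npe"], base["ap_npe"])
        assert np.allclose(twice["frac_mass_fruit_seed"],
                           base["frac_mass_fruit_seed"])

    def test_energy_consistency(self, noisy_daily):
        """Day energy equals AP kJ + NPE kJ recomputed from nutrient totals."""
        ap_kj = noisy_daily["ap_g"] * fc.FUEL.kj_protein
        npe_kj = ap_kj / noisy_daily["ap_npe"]
        assert np.allclose(noisy_daily["energy_kj"], ap_kj + npe_kj, rtol=1e-9)

    def test_monotone_in_duration(self):
        derived = _single_food_frame()
        rates, handling = {"L1": 0.5}, {"L1": ie.FoodHandling("L1", 0.2)}
        bm = ie.BodyMass("a1", 5.0)
        prev = 0.0
        for dur in (10.0, 20.0, 40.0):
            di = ie.daily_intake(
                [ie.FeedingBout("a1", "G1", "2006-06-20", 1, "L1", dur)],
                rates, handling, derived, bm)
            assert di.dry_mass_g > prev
            prev = di.dry_mass_g
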