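"""Daily intake estimation from timed focal-animal feeding bouts.

Daily intake of quantity y follows the bout-accumulation formula

    DI_y = sum_i D_i * R_x * M_x * C_x * Q_{x,y}

where D_i is the duration (s) of bout i on food x, R_x the pooled intake
rate (units/s), M_x the dry mass per unit (g), C_x a food-specific
conversion factor, and Q_{x,y} the concentration of y in food x (g/g for
nutrients, kJ/g for energy).  Energy intakes are additionally scaled to
metabolic body mass (kJ·BM_kg^-0.762·day^-1) and protein to body mass
(g·BM_kg^-1·day^-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .food_composition import (
    FRUIT_SEED_PARTS,
    FUEL,
    FuelConstants,
    NutrientWarning,
)

__all__ = [
    "SEASON_OF_PERIOD",
    "LEAN_SEASONS",
    "FeedingBout",
    "IntakeRateRecord",
    "FoodHandling",
    "BodyMass",
    "DailyIntake",
    "IntakeError",
    "assign_season",
    "pool_intake_rate",
    "pool_rates",
    "scale_energy",
    "protein_requirement_kj",
    "daily_intake",
    "compute_daily_intakes",
    "DAILY_INTAKE_COLUMNS",
]


class IntakeError(ValueError):
    """A bout or rate record cannot be resolved into an intake."""


# Periods 1-2 (early lean), 3-5 and 6-8 (abundant), 9-10 and 11-12 (lean).
SEASON_OF_PERIOD: Mapping[int, int] = {
    1: 1, 2: 1,
    3: 2, 4: 2, 5: 2,
    6: 3, 7: 3, 8: 3,
    9: 4, 10: 4,
    11: 5, 12: 5,
}

LEAN_SEASONS = frozenset({1, 4, 5})


def assign_season(period: int) -> tuple[int, bool]:
    """Map a data-collection period (1-12) to (season 1-5, lean flag)."""
    try:
        season = SEASON_OF_PERIOD[int(period)]
    except (KeyError, ValueError, TypeError):
        raise IntakeError(f"period must be an integer in 1..12, got {period!r}")
    return season, season in LEAN_SEASONS


# --------------------------------------------------------------------------
# Domain records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FeedingBout:
    focal_id: str
    group_id: str
    date: str            # ISO 8601
    period: int
    food_id: str
    duration_s: float
    is_soil: bool = False

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise IntakeError(f"bout duration must be > 0 s, got {self.duration_s}")
        assign_season(self.period)


@dataclass(frozen=True)
class IntakeRateRecord:
    """One intake-rate observation for a food.

    ``count_per_interval`` records come from one-minute interval counts of
    rapidly consumed items; ``per_item_duration`` records from timed handling
    of larger items (units = items observed, duration = summed handling
    time).  Both pool identically as units per second.
    """

    food_id: str
    mode: str            # count_per_interval | per_item_duration
    units: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.mode not in ("count_per_interval", "per_item_duration"):
            raise IntakeError(f"unknown rate mode {self.mode!r}")
        if self.units < 0 or self.duration_s <= 0:
            raise IntakeError(
                f"{self.food_id}: need units >= 0 and duration > 0, "
                f"got {self.units}, {self.duration_s}"
            )


@dataclass(frozen=True)
class FoodHandling:
    food_id: str
    unit_mass_g: float
    conversion_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.unit_mass_g <= 0 or self.conversion_factor <= 0:
            raise IntakeError(f"{self.food_id}: unit mass and conversion factor "
                              "must be positive")


@dataclass(frozen=True)
class BodyMass:
    focal_id: str
    mass_kg: float
    age_class: str = "adult"

    def __post_init__(self) -> None:
        if self.mass_kg <= 0:
            raise IntakeError(f"{self.focal_id}: body mass must be positive")


@dataclass
class DailyIntake:
    """Per focal-day totals of mass, energy, macronutrients and ratios."""

    focal_id: str
    group_id: str
    date: str
    period: int
    season: int
    lean: bool
    feeding_time_s: float
    dry_mass_g: float
    frac_mass_fruit_seed: float
    energy_kj: float
    ap_g: float
    fat_g: float
    tnc_g: float
    ndf_g: float
    adf_g: float
    lignin_g: float
    ap_npe: float | None           # None when the day has no mass
    energy_per_mbm: float          # kJ·BM_kg^-0.762·day^-1
    ap_per_bm: float               # g·BM_kg^-1·day^-1
    soil_time_s: float = 0.0       # audit tally; excluded from intakes


DAILY_INTAKE_COLUMNS = [
    "focal_id", "group_id", "date", "period", "season", "lean",
    "feeding_time_s", "dry_mass_g", "frac_mass_fruit_seed", "energy_kj",
    "ap_g", "fat_g", "tnc_g", "ndf_g", "adf_g", "lignin_g",
    "ap_npe", "energy_per_mbm", "ap_per_bm", "soil_time_s",
]


# --------------------------------------------------------------------------
# Intake rates
# --------------------------------------------------------------------------

def pool_intake_rate(records: Sequence[IntakeRateRecord]) -> float:
    """Duration-weighted pooled intake rate (units/s) for one food.

    Pools across individuals and sites: total units divided by total
    observed seconds, which is robust to very short observation intervals.
    """
    if not records:
        raise IntakeError("no intake-rate records to pool")
    food_ids = {r.food_id for r in records}
    if len(food_ids) != 1:
        raise IntakeError(f"records mix foods: {sorted(food_ids)}")
    total_units = sum(r.units for r in records)
    total_s = sum(r.duration_s for r in records)
    return total_units / total_s


def pool_rates(rates: pd.DataFrame) -> pd.Series:
    """Pooled units/s per food_id from a rate table (food_id, units, duration_s)."""
    if rates.empty:
        raise IntakeError("rate table is empty")
    g = rates.groupby("food_id")
    return g["units"].sum() / g["duration_s"].sum()


def _rate_with_fallback(food_id: str, pooled: pd.Series,
                        part_of_food: Mapping[str, str],
                        part_rates: Mapping[str, float]) -> float:
    """Pooled rate for a food, falling back to its part-code pooled rate."""
    if food_id in pooled.index:
        return float(pooled.loc[food_id])
    part = part_of_food.get(food_id)
    if part is not None and part in part_rates:
        warnings.warn(
            f"{food_id}: no intake-rate records; using pooled {part} rate",
            NutrientWarning, stacklevel=2,
        )
        return float(part_rates[part])
    raise IntakeError(f"{food_id}: no intake rate and no part-code fallback")


# --------------------------------------------------------------------------
# Scaling and requirement conversions
# --------------------------------------------------------------------------

def scale_energy(energy_kj: float, mass_kg: float,
                 constants: FuelConstants = FUEL) -> float:
    """Energy intake per metabolic body mass, kJ·BM_kg^-0.762·day^-1."""
    if mass_kg <= 0:
        raise IntakeError(f"body mass must be positive, got {mass_kg}")
    return energy_kj / mass_kg ** constants.metabolic_exponent


def protein_requirement_kj(g_per_kg: float, mass_kg: float,
                           constants: FuelConstants = FUEL) -> int:
    """Convert a protein requirement (g·BM_kg^-1·day^-1) to kJ/day.

    Uses the protein fuel value (16.736 kJ/g); rounded to the nearest kJ for
    display, e.g. 2.8 g/kg/day at 5 kg -> 234 kJ/day.
    """
    if g_per_kg <= 0 or mass_kg <= 0:
        raise IntakeError("requirement and body mass must be positive")
    return round(g_per_kg * mass_kg * constants.kj_protein)


# --------------------------------------------------------------------------
# Daily intake accumulation
# --------------------------------------------------------------------------

def daily_intake(bouts: Sequence[FeedingBout],
                 rates: Mapping[str, float],
                 handling: Mapping[str, FoodHandling],
                 compositions: pd.DataFrame,
                 body_mass: BodyMass,
                 constants: FuelConstants = FUEL) -> DailyIntake:
    """Accumulate one focal-day of bouts into a :class:`DailyIntake`.

    ``compositions`` is a derived composition frame (see
    :func:`nutgeom.food_composition.derive_frame`) indexed or keyed by
    food_id.  Soil bouts are excluded from all nutritional sums but tallied
    in ``soil_time_s``.  All non-soil bouts must share one (focal, date).
    """
    comp = compositions.set_index("food_id") if "food_id" in compositions.columns \
        else compositions

    feeding = [b for b in bouts if not b.is_soil]
    soil_time = sum(b.duration_s for b in bouts if b.is_soil)
    if bouts:
        keys = {(b.focal_id, b.date) for b in bouts}
        if len(keys) != 1:
            raise IntakeError(f"bouts span multiple focal-days: {sorted(keys)}")
        focal_id, date = next(iter(keys))
        group_id, period = bouts[0].group_id, bouts[0].period
    else:
        focal_id = body_mass.focal_id
        date, group_id, period = "", "", 1
    season, lean = assign_season(period)

    totals = dict.fromkeys(
        ("mass", "energy", "ap", "fat", "tnc", "ndf", "adf", "lignin",
         "ap_kj", "npe_kj", "fruit_seed_mass", "time"), 0.0)

    for b in feeding:
        if b.food_id not in rates:
            raise IntakeError(f"{b.food_id}: no intake rate")
        if b.food_id not in handling:
            raise IntakeError(f"{b.food_id}: no handling record (unit mass)")
        try:
            row = comp.loc[b.food_id]
        except KeyError:
            raise IntakeError(f"{b.food_id}: no composition after substitution")
        h = handling[b.food_id]
        mass = b.duration_s * rates[b.food_id] * h.unit_mass_g * h.conversion_factor
        totals["time"] += b.duration_s
        totals["mass"] += mass
        totals["energy"] += mass * row["energy_kj_per_g"]
        totals["ap"] += mass * row["ap"] / 100.0
        totals["fat"] += mass * row["fat"] / 100.0
        totals["tnc"] += mass * row["tnc"] / 100.0
        totals["ndf"] += mass * row["ndf"] / 100.0
        totals["adf"] += mass * row["adf"] / 100.0
        totals["lignin"] += mass * row["lignin"] / 100.0
        fiber_kj_per_g = (constants.dig_cell * (row["adf"] - row["lignin"])
                          + constants.dig_hc * (row["ndf"] - row["adf"])
                          ) / 100.0 * constants.kj_fiber
        totals["ap_kj"] += mass * row["ap"] / 100.0 * constants.kj_protein
        totals["npe_kj"] += mass * (row["tnc"] / 100.0 * constants.kj_tnc
                                    + row["fat"] / 100.0 * constants.kj_fat
                                    + fiber_kj_per_g)
        if row["part_code"] in FRUIT_SEED_PARTS:
            totals["fruit_seed_mass"] += mass

    if totals["mass"] > 0:
        frac_fruit = totals["fruit_seed_mass"] / totals["mass"]
        ap_npe: float | None = totals["ap_kj"] / totals["npe_kj"]
    else:
        if totals["time"] > 0:
            warnings.warn(
                f"{focal_id} {date}: zero dry mass despite "
                f"{totals['time']:.0f} s feeding; AP:NPE undefined",
                NutrientWarning, stacklevel=2,
            )
        frac_fruit, ap_npe = 0.0, None

    return DailyIntake(
        focal_id=focal_id, group_id=group_id, date=date, period=period,
        season=season, lean=lean,
        feeding_time_s=totals["time"],
        dry_mass_g=totals["mass"],
        frac_mass_fruit_seed=frac_fruit,
        energy_kj=totals["energy"],
        ap_g=totals["ap"], fat_g=totals["fat"], tnc_g=totals["tnc"],
        ndf_g=totals["ndf"], adf_g=totals["adf"], lignin_g=totals["lignin"],
        ap_npe=ap_npe,
        energy_per_mbm=scale_energy(totals["energy"], body_mass.mass_kg, constants),
        ap_per_bm=totals["ap"] / body_mass.mass_kg,
        soil_time_s=soil_time,
    )


def compute_daily_intakes(bouts: pd.DataFrame,
                          rates: pd.DataFrame,
                          handling: pd.DataFrame,
                          compositions: pd.DataFrame,
                          body_masses: pd.DataFrame,
                          constants: FuelConstants = FUEL) -> pd.DataFrame:
    """Vectorised pipeline: all focal-days of a bout table at once.

    Inputs are the CSV-schema frames (see module docstrings); compositions
    must already be derived (``derive_frame``) and resolved (no missing
    foods).  Returns one row per (focal_id, date) with the
    :data:`DAILY_INTAKE_COLUMNS` schema.

    Body-mass lookup: per-individual value from ``body_masses``; individuals
    without a record fall back to their group mean (logged as a warning).
    """
    comp = compositions.set_index("food_id")
    pooled = pool_rates(rates)
    part_of_food = comp["part_code"].to_dict()

    # Part-code pooled fallback rates (mirrors the composition substitution).
    r = rates.merge(compositions[["food_id", "part_code"]], on="food_id", how="left")
    gp = r.dropna(subset=["part_code"]).groupby("part_code")
    part_rates = (gp["units"].sum() / gp["duration_s"].sum()).to_dict()

    feeding = bouts.loc[~bouts["is_soil"].astype(bool)].copy()
    unknown = set(feeding["food_id"]) - set(comp.index)
    if unknown:
        raise IntakeError(f"foods without composition: {sorted(unknown)}")

    h = handling.set_index("food_id")
    missing_h = set(feeding["food_id"]) - set(h.index)
    if missing_h:
        raise IntakeError(f"foods without handling records: {sorted(missing_h)}")

    feeding["rate"] = [
        _rate_with_fallback(f, pooled, part_of_food, part_rates)
        for f in feeding["food_id"]
    ]
    feeding = feeding.join(h[["unit_mass_g", "conversion_factor"]], on="food_id")
    feeding = feeding.join(
        comp[["part_code", "energy_kj_per_g", "ap", "fat", "tnc",
              "ndf", "adf", "lignin"]], on="food_id")

    feeding["mass"] = (feeding["duration_s"] * feeding["rate"]
                       * feeding["unit_mass_g"] * feeding["conversion_factor"])
    for nut in ("ap", "fat", "tnc", "ndf", "adf", "lignin"):
        feeding[f"{nut}_g"] = feeding["mass"] * feeding[nut] / 100.0
    feeding["energy"] = feeding["mass"] * feeding["energy_kj_per_g"]
    fiber_kj_per_g = (constants.dig_cell * (feeding["adf"] - feeding["lignin"])
                      + constants.dig_hc * (feeding["ndf"] - feeding["adf"])
                      ) / 100.0 * constants.kj_fiber
    feeding["ap_kj"] = feeding["ap_g"] * constants.kj_protein
    feeding["npe_kj"] = feeding["mass"] * (
        feeding["tnc"] / 100.0 * constants.kj_tnc
        + feeding["fat"] / 100.0 * constants.kj_fat
        + fiber_kj_per_g)
    feeding["fruit_seed_mass"] = np.where(
        feeding["part_code"].isin(FRUIT_SEED_PARTS), feeding["mass"], 0.0)

    day = feeding.groupby(["focal_id", "date"], as_index=False).agg(
        group_id=("group_id", "first"),
        period=("period", "first"),
        feeding_time_s=("duration_s", "sum"),
        dry_mass_g=("mass", "sum"),
        fruit_seed_mass=("fruit_seed_mass", "sum"),
        energy_kj=("energy", "sum"),
        ap_g=("ap_g", "sum"),
        fat_g=("fat_g", "sum"),
        tnc_g=("tnc_g", "sum"),
        ndf_g=("ndf_g", "sum"),
        adf_g=("adf_g", "sum"),
        lignin_g=("lignin_g", "sum"),
        ap_kj=("ap_kj", "sum"),
        npe_kj=("npe_kj", "sum"),
    )
    day["season"] = day["period"].map(SEASON_OF_PERIOD)
    day["lean"] = day["season"].isin(LEAN_SEASONS)
    day["frac_mass_fruit_seed"] = np.where(
        day["dry_mass_g"] > 0, day["fruit_seed_mass"] / day["dry_mass_g"], 0.0)
    day["ap_npe"] = np.where(day["npe_kj"] > 0, day["ap_kj"] / day["npe_kj"], np.nan)

    # soil audit tally
    soil = (bouts.loc[bouts["is_soil"].astype(bool)]
            .groupby(["focal_id", "date"])["duration_s"].sum()
            .rename("soil_time_s"))
    day = day.join(soil, on=["focal_id", "date"])
    day["soil_time_s"] = day["soil_time_s"].fillna(0.0)

    # body-mass lookup with group-mean fallback
    bm = body_masses.set_index("focal_id")["mass_kg"]
    group_mean = body_masses.merge(
        bouts[["focal_id", "group_id"]].drop_duplicates(), on="focal_id",
        how="left").groupby("group_id")["mass_kg"].mean()
    mass = day["focal_id"].map(bm)
    if mass.isna().any():
        missing = day.loc[mass.isna(), "focal_id"].unique().tolist()
        warnings.warn(
            f"no body-mass record for {missing}; using group means",
            NutrientWarning, stacklevel=2,
        )
        mass = mass.fillna(day["group_id"].map(group_mean))
    if mass.isna().any():
        raise IntakeError("body mass unresolvable for some focal-days")
    day["energy_per_mbm"] = day["energy_kj"] / mass ** constants.metabolic_exponent
    day["ap_per_bm"] = day["ap_g"] / mass

    return day[DAILY_INTAKE_COLUMNS].sort_values(["focal_id", "date"],
                                                 ignore_index=True)
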