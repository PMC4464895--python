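"""Food chemistry and derived nutritional quantities.

Concentrations are stored as percent of dry matter (0-100 scale); energy
densities are physiological fuel values in kJ per g dry matter.  Available
protein (AP) is crude protein minus acid-detergent-insoluble crude protein
(ADICP); total non-structural carbohydrate (TNC) is computed by difference
from 100% dry matter; fiber energy is credited only for the digestible
fractions of cellulose (ADF - lignin) and hemicellulose (NDF - ADF).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FUEL",
    "FuelConstants",
    "FoodComposition",
    "DerivedComposition",
    "PART_CODES",
    "FRUIT_SEED_PARTS",
    "NutrientWarning",
    "CompositionError",
    "available_protein",
    "compute_tnc",
    "digestible_fiber_energy",
    "energy_density",
    "food_ap_npe",
    "macronutrient_energy_shares",
    "derive",
    "derive_frame",
    "substitute_composition",
    "resolve_library",
]


# --------------------------------------------------------------------------
# Constants and vocabulary
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FuelConstants:
    """Physiological fuel values and digestibility coefficients.

    Fuel values are in kJ per g; ``dig_cell`` and ``dig_hc`` are the assumed
    digestible fractions of cellulose and hemicellulose.  The metabolic
    exponent scales daily energy intake to metabolic body mass
    (kJ·BM_kg^-0.762·day^-1).
    """

    kj_protein: float = 16.736
    kj_tnc: float = 16.736
    kj_fat: float = 37.656
    kj_fiber: float = 12.552
    dig_cell: float = 0.3911
    dig_hc: float = 0.5197
    metabolic_exponent: float = 0.762


#: Read-only default fuel constants used throughout the package.
FUEL = FuelConstants()

#: Plant part / phenological stage codes: young leaf, shoot, flower, flower
#: bud, fruit without seed, fruit with seed, seed, unripe fruit with seed.
PART_CODES = frozenset({"YL", "SH", "FL", "BD", "F", "FSD", "SD", "URFSD"})

#: Parts counted as fruit/seed when computing the frugivory mass fraction.
FRUIT_SEED_PARTS = frozenset({"F", "FSD", "SD", "URFSD"})


class NutrientWarning(UserWarning):
    """Raised as a warning when a derived nutrient value needed clamping."""


class CompositionError(ValueError):
    """A food composition violates its chemical invariants."""


# --------------------------------------------------------------------------
# Domain records
# --------------------------------------------------------------------------

@dataclass
class FoodComposition:
    """One species x plant-part chemistry record (percent dry matter).

    ``fat`` may be ``None`` for records whose ether-extract assay was not
    run; substitution fills it from the part-code average before use.
    """

    food_id: str
    species: str
    genus: str
    part_code: str
    cp: float
    adicp: float
    fat: float | None
    ash: float
    ndf: float
    adf: float
    lignin: float
    measured: bool = True
    provenance: str = "direct"

    def __post_init__(self) -> None:
        if self.part_code not in PART_CODES:
            raise CompositionError(
                f"{self.food_id}: unknown part code {self.part_code!r}; "
                f"expected one of {sorted(PART_CODES)}"
            )
        conc = {
            "cp": self.cp, "adicp": self.adicp, "ash": self.ash,
            "ndf": self.ndf, "adf": self.adf, "lignin": self.lignin,
        }
        if self.fat is not None:
            conc["fat"] = self.fat
        for name, v in conc.items():
            if not (0.0 <= v <= 100.0):
                raise CompositionError(
                    f"{self.food_id}: {name}={v} outside [0, 100]% DM"
                )
        if not (self.ndf >= self.adf >= self.lignin):
            raise CompositionError(
                f"{self.food_id}: fiber fractions must satisfy "
                f"NDF >= ADF >= lignin (got {self.ndf}, {self.adf}, {self.lignin})"
            )
        if self.adicp > self.cp:
            raise CompositionError(
                f"{self.food_id}: ADICP ({self.adicp}) exceeds CP ({self.cp})"
            )


@dataclass(frozen=True)
class DerivedComposition:
    """Derived nutritional quantities for one food."""

    ap: float                      # available protein, % DM
    tnc: float                     # total non-structural carbohydrate, % DM
    energy_density: float          # kJ per g DM
    ap_npe: float                  # available protein kJ : non-protein kJ
    macronutrient_energy_shares: tuple[float, float, float]  # (protein, fat, carb) %


# --------------------------------------------------------------------------
# Elementary derived quantities
# --------------------------------------------------------------------------

def available_protein(cp: float, adicp: float, *, food_id: str = "?") -> float:
    """Available protein (% DM): crude protein minus acid-detergent-insoluble CP."""
    if not (0.0 <= adicp <= cp <= 100.0):
        raise CompositionError(
            f"{food_id}: need 0 <= ADICP <= CP <= 100, got CP={cp}, ADICP={adicp}"
        )
    return cp - adicp


def compute_tnc(fat: float, cp: float, adicp: float, ash: float, ndf: float,
                *, food_id: str = "?") -> float:
    """Total non-structural carbohydrate by difference (% DM).

    TNC = 100 - (fat + AP + ash + NDF).  Assay rounding can push the
    difference slightly negative; negative values are clamped to zero with a
    :class:`NutrientWarning`.
    """
    for name, v in (("fat", fat), ("cp", cp), ("adicp", adicp),
                    ("ash", ash), ("ndf", ndf)):
        if not (0.0 <= v <= 100.0):
            raise CompositionError(f"{food_id}: {name}={v} outside [0, 100]% DM")
    tnc = 100.0 - (fat + (cp - adicp) + ash + ndf)
    if tnc < 0.0:
        warnings.warn(
            f"{food_id}: TNC by difference is negative ({tnc:.3f}%); clamped to 0",
            NutrientWarning,
            stacklevel=2,
        )
        tnc = 0.0
    return tnc


def digestible_fiber_energy(ndf: float, adf: float, lignin: float,
                            constants: FuelConstants = FUEL) -> float:
    """Energy (kJ/g DM) credited to digestible cellulose and hemicellulose."""
    if not (ndf >= adf >= lignin >= 0.0):
        raise CompositionError(
            f"fiber fractions must satisfy NDF >= ADF >= lignin >= 0 "
            f"(got {ndf}, {adf}, {lignin})"
        )
    cellulose = (adf - lignin) / 100.0
    hemicellulose = (ndf - adf) / 100.0
    return (constants.dig_cell * cellulose * constants.kj_fiber
            + constants.dig_hc * hemicellulose * constants.kj_fiber)


def energy_density(ap: float, tnc: float, fat: float, ndf: float, adf: float,
                   lignin: float, constants: FuelConstants = FUEL) -> float:
    """Energy content (kJ/g DM) as the sum of physiological fuel values.

    E = AP*16.736 + TNC*16.736 + fat*37.656
        + dig_cell*(ADF - lignin)*12.552 + dig_hc*(NDF - ADF)*12.552

    with all concentrations converted from % DM to g/g, so a pure-fat food
    returns the fat fuel value 37.656 kJ/g.
    """
    for name, v in (("ap", ap), ("tnc", tnc), ("fat", fat)):
        if not (0.0 <= v <= 100.0):
            raise CompositionError(f"{name}={v} outside [0, 100]% DM")
    return (ap / 100.0 * constants.kj_protein
            + tnc / 100.0 * constants.kj_tnc
            + fat / 100.0 * constants.kj_fat
            + digestible_fiber_energy(ndf, adf, lignin, constants))


def food_ap_npe(ap: float, tnc: float, fat: float, ndf: float, adf: float,
                lignin: float, constants: FuelConstants = FUEL) -> float:
    """Ratio of available-protein energy to non-protein energy for one food.

    NPE includes carbohydrate, fat and the digestible fiber energy.  A food
    with no available protein has ratio 0 regardless of the fiber-energy
    convention; a food with no non-protein energy has no defined ratio.
    """
    ap_kj = ap / 100.0 * constants.kj_protein
    npe_kj = (tnc / 100.0 * constants.kj_tnc
              + fat / 100.0 * constants.kj_fat
              + digestible_fiber_energy(ndf, adf, lignin, constants))
    if npe_kj <= 0.0:
        raise CompositionError(
            "AP:NPE undefined: non-protein energy is zero"
            + (" while AP > 0" if ap_kj > 0 else "")
        )
    return ap_kj / npe_kj


def macronutrient_energy_shares(ap: float, tnc: float, fat: float,
                                constants: FuelConstants = FUEL
                                ) -> tuple[float, float, float]:
    """Percent of fiber-free macronutrient kJ from (protein, fat, carbohydrate)."""
    p = ap / 100.0 * constants.kj_protein
    f = fat / 100.0 * constants.kj_fat
    c = tnc / 100.0 * constants.kj_tnc
    total = p + f + c
    if total <= 0.0:
        raise CompositionError("macronutrient energy shares undefined: zero energy")
    return (100.0 * p / total, 100.0 * f / total, 100.0 * c / total)


def derive(rec: FoodComposition, constants: FuelConstants = FUEL) -> DerivedComposition:
    """Compute all derived quantities for one composition record."""
    if rec.fat is None:
        raise CompositionError(
            f"{rec.food_id}: fat is missing; substitute it before deriving"
        )
    ap = available_protein(rec.cp, rec.adicp, food_id=rec.food_id)
    tnc = compute_tnc(rec.fat, rec.cp, rec.adicp, rec.ash, rec.ndf,
                      food_id=rec.food_id)
    e = energy_density(ap, tnc, rec.fat, rec.ndf, rec.adf, rec.lignin, constants)
    ratio = food_ap_npe(ap, tnc, rec.fat, rec.ndf, rec.adf, rec.lignin, constants)
    shares = macronutrient_energy_shares(ap, tnc, rec.fat, constants)
    return DerivedComposition(ap=ap, tnc=tnc, energy_density=e, ap_npe=ratio,
                              macronutrient_energy_shares=shares)


def derive_frame(comps: pd.DataFrame, constants: FuelConstants = FUEL) -> pd.DataFrame:
    """Vectorised :func:`derive` over a composition table.

    Input columns: food_id, species, genus, part_code, cp, adicp, fat, ash,
    ndf, adf, lignin (and optionally measured/provenance).  Returns a copy
    with ap, tnc, energy_kj_per_g, ap_npe, share_protein, share_fat,
    share_carb appended.
    """
    out = comps.copy()
    if out["fat"].isna().any():
        bad = out.loc[out["fat"].isna(), "food_id"].tolist()
        raise CompositionError(f"fat missing for {bad}; run substitution first")
    if (out["adicp"] > out["cp"]).any():
        bad = out.loc[out["adicp"] > out["cp"], "food_id"].tolist()
        raise CompositionError(f"ADICP exceeds CP for {bad}")
    out["ap"] = out["cp"] - out["adicp"]
    tnc = 100.0 - (out["fat"] + out["ap"] + out["ash"] + out["ndf"])
    if (tnc < 0).any():
        bad = out.loc[tnc < 0, "food_id"].tolist()
        warnings.warn(f"TNC clamped to 0 for {bad}", NutrientWarning, stacklevel=2)
    out["tnc"] = tnc.clip(lower=0.0)
    fiber_kj = (constants.dig_cell * (out["adf"] - out["lignin"])
                + constants.dig_hc * (out["ndf"] - out["adf"])) / 100.0 * constants.kj_fiber
    ap_kj = out["ap"] / 100.0 * constants.kj_protein
    fat_kj = out["fat"] / 100.0 * constants.kj_fat
    tnc_kj = out["tnc"] / 100.0 * constants.kj_tnc
    out["energy_kj_per_g"] = ap_kj + tnc_kj + fat_kj + fiber_kj
    npe = tnc_kj + fat_kj + fiber_kj
    out["ap_npe"] = ap_kj / npe
    macro = ap_kj + fat_kj + tnc_kj
    out["share_protein"] = 100.0 * ap_kj / macro
    out["share_fat"] = 100.0 * fat_kj / macro
    out["share_carb"] = 100.0 * tnc_kj / macro
    return out


# --------------------------------------------------------------------------
# Substitution hierarchy for unsampled foods
# --------------------------------------------------------------------------

_MEAN_FIELDS = ("cp", "adicp", "ash", "ndf", "adf", "lignin")


def _mean_composition(records: Sequence[FoodComposition], food_id: str,
                      species: str, genus: str, part_code: str,
                      provenance: str) -> FoodComposition:
    def fmean(vals: Iterable[float | None]) -> float | None:
        present = [v for v in vals if v is not None]
        return float(np.mean(present)) if present else None

    kwargs = {f: fmean(getattr(r, f) for r in records) for f in _MEAN_FIELDS}
    fat = fmean(r.fat for r in records)
    # Mean ADF can exceed mean NDF only if inputs were invalid; records are
    # validated on construction, and means preserve the ordering.
    return FoodComposition(food_id=food_id, species=species, genus=genus,
                           part_code=part_code, fat=fat, measured=False,
                           provenance=provenance, **kwargs)


def substitute_composition(food_id: str, species: str, genus: str,
                           part_code: str,
                           library: Sequence[FoodComposition]
                           ) -> FoodComposition:
    """Resolve a food's composition through the substitution hierarchy.

    1. a directly assayed record for ``food_id`` is returned as-is;
    2. otherwise the unweighted mean over sampled congeners (same genus) of
       the same plant part/stage (provenance ``congener``);
    3. otherwise the mean over all sampled foods of that part/stage
       (provenance ``part_average``).

    Young-leaf records missing fat are filled with the average fat of
    sampled young-leaf records before use.
    """
    if not library:
        raise CompositionError("composition library is empty")

    sampled = [r for r in library if r.measured]

    def fill_missing_fat(rec: FoodComposition) -> FoodComposition:
        if rec.fat is not None:
            return rec
        same_part_fats = [r.fat for r in sampled
                          if r.part_code == rec.part_code and r.fat is not None]
        if not same_part_fats:
            raise CompositionError(
                f"{rec.food_id}: fat unassayed and no {rec.part_code} record "
                "provides a substitute average"
            )
        return replace(rec, fat=float(np.mean(same_part_fats)))

    direct = [r for r in library if r.food_id == food_id]
    if direct:
        return fill_missing_fat(direct[0])

    congeners = [r for r in sampled
                 if r.genus == genus and r.part_code == part_code]
    if congeners:
        congeners = [fill_missing_fat(r) for r in congeners]
        return _mean_composition(congeners, food_id, species, genus,
                                 part_code, "congener")

    same_part = [r for r in sampled if r.part_code == part_code]
    if same_part:
        same_part = [fill_missing_fat(r) for r in same_part]
        return _mean_composition(same_part, food_id, species, genus,
                                 part_code, "part_average")

    raise CompositionError(
        f"{food_id}: no sampled composition anywhere for part {part_code!r}"
    )


def resolve_library(foods: pd.DataFrame,
                    library: Sequence[FoodComposition]) -> list[FoodComposition]:
    """Resolve every row of a foods table (food_id, species, genus, part_code)."""
    return [
        substitute_composition(r.food_id, r.species, r.genus, r.part_code, library)
        for r in foods.itertuples(index=False)
    ]
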