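"""Synthetic study generator with exported ground truth.

Emulates the structure of a focal-animal feeding study of a folivorous
primate across a habitat-disturbance gradient: five groups (18 individuals)
followed over 12 collection periods mapped to 5 seasons, with seasonally
varying frugivory and daily dry-mass intake, and a food library of
fruit-like and leaf-like items with heterogeneous protein-to-nonprotein-
energy content.

Key mechanisms
--------------
* Daily dry-mass intake targets: the lean-season target is common to all
  groups and equals ``lean_intake_multiplier`` x the undisturbed abundant-
  season target; each group's abundant-season target interpolates between
  the lean target and the undisturbed target according to its disturbance
  score (lean-season intakes converge across groups; abundant-season
  intakes grow with habitat quality).
* Dietary balance: each food pool (fruit-like, leaf-like) is calibrated so
  its intake-flux-weighted AP:NPE equals ``target_ap_npe``; any mixture of
  the pools then hits the target in expectation, so the configured
  frugivory and the configured nutrient balance are satisfiable at once.
* Bouts: bout counts are Poisson, durations gamma; with ``noise=False``
  the generator emits one deterministic bout per food with exact time
  shares, and the pipeline's daily intakes equal the exported truth
  exactly.

All randomness flows from ``numpy.random.default_rng(seed)`` (PCG64), so
output is reproducible across platforms for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .food_composition import FRUIT_SEED_PARTS, FUEL, FuelConstants
from .intake_engine import SEASON_OF_PERIOD, LEAN_SEASONS

__all__ = [
    "StudyConfig",
    "SyntheticTruth",
    "SyntheticStudy",
    "gen_food_library",
    "gen_study",
    "gen_lmm_table",
]

_FRUIT_PARTS = ("F", "FSD", "SD", "URFSD")
_LEAF_PARTS = ("YL", "SH", "FL", "BD")


@dataclass(frozen=True)
class StudyConfig:
    """Generator parameters: the study conditions the analysis assumes.

    ``disturbance`` is a basal-area proxy in (0, 1], 1 = undisturbed.
    ``abundant_mass_g`` is the undisturbed group's abundant-season daily
    dry-mass target; the common lean-season target is
    ``lean_intake_multiplier`` x that value (daily intake in the lean season
    drops to roughly 40% of abundant-season intake).  ``target_ap_npe`` is
    the dietary available-protein : non-protein-energy balance the food
    pools are calibrated to.  Frugivory entries are fruit/seed dry-mass
    fractions per group.
    """

    seed: int = 0
    group_names: tuple[str, ...] = ("G1", "G2", "G3", "G4", "G5")
    disturbance: tuple[float, ...] = (0.89, 1.0, 0.39, 0.21, 0.51)
    n_individuals: tuple[int, ...] = (5, 4, 3, 2, 4)
    n_periods: int = 12
    n_foods: int = 24
    days_per_individual_period: int = 2
    lean_intake_multiplier: float = 0.4
    target_ap_npe: float = 0.105
    frugivory_abundant: tuple[float, ...] = (0.60, 0.62, 0.39, 0.22, 0.64)
    frugivory_lean: tuple[float, ...] = (0.15, 0.15, 0.15, 0.15, 0.15)
    abundant_mass_g: float = 450.0
    mean_bouts_per_day: float = 50.0
    bout_shape: float = 2.0          # gamma shape for bout durations
    adult_mass_kg: tuple[float, float] = (5.8, 0.5)   # mean, sd
    immature_mass_kg: tuple[float, float] = (4.0, 4.5)  # uniform range

    def __post_init__(self) -> None:
        n = len(self.group_names)
        for name in ("disturbance", "n_individuals", "frugivory_abundant",
                     "frugivory_lean"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per group")
        if not all(0.0 < d <= 1.0 for d in self.disturbance):
            raise ValueError("disturbance scores must lie in (0, 1]")
        if not (0.0 < self.lean_intake_multiplier <= 1.0):
            raise ValueError("lean_intake_multiplier must lie in (0, 1]")
        if not all(0.0 <= f <= 1.0 for f in
                   (*self.frugivory_abundant, *self.frugivory_lean)):
            raise ValueError("frugivory fractions must lie in [0, 1]")
        if self.n_foods < 4:
            raise ValueError("need at least 4 foods (one fruit-like and one "
                             "leaf-like per pool at minimum)")


@dataclass
class SyntheticTruth:
    """Ground truth exported alongside a synthetic study."""

    config: StudyConfig
    foods: pd.DataFrame              # raw calibrated compositions
    expected_daily: pd.DataFrame     # analytic per focal-day expectations
    group_season_mass: pd.DataFrame  # group, season, mass target, frugivory
    pool_ap_npe: dict[str, float]    # flux-weighted AP:NPE per pool


@dataclass
class SyntheticStudy:
    """A generated study in the exact CSV schemas the pipeline consumes."""

    bouts: pd.DataFrame
    rates: pd.DataFrame
    handling: pd.DataFrame
    body_masses: pd.DataFrame
    foods: pd.DataFrame
    truth: SyntheticTruth


# --------------------------------------------------------------------------
# Food library
# --------------------------------------------------------------------------

def _npe_kj_per_g(ap, tnc, fat, ndf, adf, lignin,
                  c: FuelConstants = FUEL) -> np.ndarray:
    fiber = (c.dig_cell * (adf - lignin) + c.dig_hc * (ndf - adf)) / 100.0 * c.kj_fiber
    return tnc / 100.0 * c.kj_tnc + fat / 100.0 * c.kj_fat + fiber


def gen_food_library(seed: int, n_foods: int = 24) -> pd.DataFrame:
    """Generate a composition library of fruit-like and leaf-like foods.

    Concentration spans follow the ranges observed in wild folivore food
    libraries (available protein 0-13%, TNC 20-57%, fat 0-25%, NDF 28-54%
    of dry matter); mass closure holds (AP + TNC + fat + ash + NDF = 100)
    and the fiber cascade NDF >= ADF >= lignin is enforced by construction.
    Deterministic for a fixed seed.
    """
    if n_foods < 4:
        raise ValueError("need at least 4 foods")
    rng = np.random.default_rng(seed)
    n_fruit = max(2, n_foods // 2)
    rows = []
    for i in range(n_foods):
        fruitlike = i < n_fruit
        if fruitlike:
            part = _FRUIT_PARTS[i % len(_FRUIT_PARTS)]
            ap = rng.uniform(0.0, 6.0)
            fat = rng.uniform(0.5, 25.0)
            ndf = rng.uniform(28.0, 48.0)
            ash = rng.uniform(2.0, 6.0)
        else:
            part = _LEAF_PARTS[i % len(_LEAF_PARTS)]
            ap = rng.uniform(1.0, 13.2)
            fat = rng.uniform(0.0, 6.0)
            ndf = rng.uniform(30.0, 54.2)
            ash = rng.uniform(3.0, 8.0)
        # keep TNC inside its observed span by shrinking fat+NDF if needed
        tnc = 100.0 - (ap + fat + ash + ndf)
        if tnc < 20.0:
            scale = 1.0 - (20.0 - tnc) / (fat + ndf)
            fat, ndf = fat * scale, ndf * scale
        adicp = rng.uniform(0.5, 2.5)
        adf = ndf * rng.uniform(0.55, 0.80)
        lignin = adf * rng.uniform(0.30, 0.60)
        genus = f"Genus{i % max(n_foods // 2, 1):02d}"
        rows.append({
            "food_id": f"{part}-{i:03d}",
            "species": f"{genus} taxon{i:03d}",
            "genus": genus,
            "part_code": part,
            "cp": ap + adicp,
            "adicp": adicp,
            "fat": fat,
            "ash": ash,
            "ndf": ndf,
            "adf": adf,
            "lignin": lignin,
        })
    return pd.DataFrame(rows)


def _calibrate_pool(foods: pd.DataFrame, flux: np.ndarray, target: float,
                    c: FuelConstants = FUEL, max_iter: int = 20) -> pd.DataFrame:
    """Shift crude protein within a pool so its flux-weighted AP:NPE = target.

    A uniform shift of AP (%DM) across the pool's free foods moves protein
    energy up and carbohydrate (by-difference) energy down; foods whose AP
    would leave [0, cp-bound] are clamped and the shift re-solved over the
    remainder.
    """
    out = foods.copy().reset_index(drop=True)
    free = np.ones(len(out), dtype=bool)
    kj = c.kj_protein / 100.0
    for _ in range(max_iter):
        ap = (out["cp"] - out["adicp"]).to_numpy()
        tnc = 100.0 - (out["fat"] + ap + out["ash"] + out["ndf"])
        ap_kj = ap * kj
        npe_kj = _npe_kj_per_g(ap, tnc.to_numpy(), out["fat"].to_numpy(),
                               out["ndf"].to_numpy(), out["adf"].to_numpy(),
                               out["lignin"].to_numpy(), c)
        sa = float(np.sum(flux * ap_kj))
        sn = float(np.sum(flux * npe_kj))
        if abs(sa - target * sn) < 1e-12 * max(sn, 1.0):
            return out
        w_free = float(np.sum(flux[free]))
        if w_free == 0.0:
            raise ValueError("pool calibration infeasible: all foods clamped")
        delta = (target * sn - sa) / (kj * w_free * (1.0 + target))
        new_ap = ap.copy()
        new_ap[free] = ap[free] + delta
        # feasibility bounds: AP >= 0 and TNC >= 1 (% DM)
        hi = 99.0 - (out["fat"] + out["ash"] + out["ndf"]).to_numpy()
        clamped = free & ((new_ap < 0.0) | (new_ap > hi))
        new_ap = np.clip(new_ap, 0.0, hi)
        out["cp"] = new_ap + out["adicp"]
        if not clamped.any():
            # loop once more to verify convergence on next residual check
            continue
        free &= ~clamped
    return out


def _derived_arrays(foods: pd.DataFrame, c: FuelConstants = FUEL) -> pd.DataFrame:
    """Per-gram energy and nutrient quantities used by the generator's truth."""
    d = foods.copy()
    d["ap"] = d["cp"] - d["adicp"]
    d["tnc"] = 100.0 - (d["fat"] + d["ap"] + d["ash"] + d["ndf"])
    d["ap_kj_per_g"] = d["ap"] / 100.0 * c.kj_protein
    d["npe_kj_per_g"] = _npe_kj_per_g(
        d["ap"].to_numpy(), d["tnc"].to_numpy(), d["fat"].to_numpy(),
        d["ndf"].to_numpy(), d["adf"].to_numpy(), d["lignin"].to_numpy(), c)
    d["energy_kj_per_g"] = d["ap_kj_per_g"] + d["npe_kj_per_g"]
    return d


# --------------------------------------------------------------------------
# Study generator
# --------------------------------------------------------------------------

_STUDY_START = pd.Timestamp("2006-06-16")


def _period_date(period: int, day: int) -> str:
    return str((_STUDY_START + pd.Timedelta(days=(period - 1) * 30 + day)).date())


def gen_study(config: StudyConfig, noise: bool = True) -> SyntheticStudy:
    """Generate bouts, rates, handling, body masses and ground truth.

    With ``noise=False`` every focal-day consists of one bout per food with
    exact time shares, so the pipeline's daily intakes reproduce
    ``truth.expected_daily`` exactly; with ``noise=True`` bout counts,
    durations and food choices are randomised around the same expectations.
    """
    rng = np.random.default_rng(config.seed)
    foods = gen_food_library(config.seed, config.n_foods)

    is_fruit = foods["part_code"].isin(FRUIT_SEED_PARTS).to_numpy()
    n = len(foods)

    # intake fluxes phi = R * M * C (g dry matter per second of feeding)
    rate = np.where(is_fruit, rng.uniform(1 / 40.0, 1 / 10.0, n),
                    rng.uniform(0.3, 1.2, n))
    unit_mass = np.where(is_fruit, rng.uniform(0.3, 1.5, n),
                         rng.uniform(0.02, 0.08, n))
    conv = np.ones(n)
    flux = rate * unit_mass * conv

    # calibrate each pool's flux-weighted AP:NPE to the configured target
    pools = {}
    for name, mask in (("fruit", is_fruit), ("leaf", ~is_fruit)):
        pools[name] = _calibrate_pool(foods.loc[mask], flux[mask],
                                      config.target_ap_npe)
    foods = pd.concat([pools["fruit"], pools["leaf"]], ignore_index=True)
    order = np.argsort(np.concatenate([np.flatnonzero(is_fruit),
                                       np.flatnonzero(~is_fruit)]))
    foods = foods.iloc[order].reset_index(drop=True)
    d = _derived_arrays(foods)

    pool_ratio = {}
    for name, mask in (("fruit", is_fruit), ("leaf", ~is_fruit)):
        pool_ratio[name] = (float(np.sum(flux[mask] * d["ap_kj_per_g"][mask]))
                            / float(np.sum(flux[mask] * d["npe_kj_per_g"][mask])))

    # rate and handling tables (two records per food; pooled rate is exact)
    rate_rows, handling_rows = [], []
    for i, fid in enumerate(foods["food_id"]):
        mode = "per_item_duration" if is_fruit[i] else "count_per_interval"
        for dur in (60.0, 240.0):
            rate_rows.append({"food_id": fid, "mode": mode,
                              "units": rate[i] * dur, "duration_s": dur})
        handling_rows.append({"food_id": fid, "unit_mass_g": unit_mass[i],
                              "conversion_factor": conv[i]})
    rates = pd.DataFrame(rate_rows)
    handling = pd.DataFrame(handling_rows)

    # body masses: last individual of groups with >2 animals is an immature
    mass_rows = []
    focal_ids: dict[str, list[str]] = {}
    for gi, gname in enumerate(config.group_names):
        ids = [f"{gname}-A{j}" for j in range(config.n_individuals[gi])]
        focal_ids[gname] = ids
        for j, fid in enumerate(ids):
            immature = j == len(ids) - 1 and len(ids) > 2
            if immature:
                mass = rng.uniform(*config.immature_mass_kg)
            else:
                mass = max(float(rng.normal(*config.adult_mass_kg)), 3.0)
            mass_rows.append({"focal_id": fid, "mass_kg": mass,
                              "age_class": "immature" if immature else "adult"})
    body_masses = pd.DataFrame(mass_rows)

    # group x season daily dry-mass targets and frugivory
    lean_mass = config.lean_intake_multiplier * config.abundant_mass_g
    gs_rows = []
    for gi, gname in enumerate(config.group_names):
        abundant_mass = (lean_mass + (config.abundant_mass_g - lean_mass)
                         * config.disturbance[gi])
        for season in range(1, 6):
            lean = season in LEAN_SEASONS
            gs_rows.append({
                "group_id": gname, "season": season, "lean": lean,
                "mass_target_g": lean_mass if lean else abundant_mass,
                "frugivory": (config.frugivory_lean[gi] if lean
                              else config.frugivory_abundant[gi]),
            })
    group_season = pd.DataFrame(gs_rows)
    gs_index = group_season.set_index(["group_id", "season"])

    fruit_idx = np.flatnonzero(is_fruit)
    leaf_idx = np.flatnonzero(~is_fruit)
    mean_flux = {"fruit": float(np.mean(flux[fruit_idx])),
                 "leaf": float(np.mean(flux[leaf_idx]))}

    def pool_mean(col: str, idx: np.ndarray) -> float:
        return float(np.mean(flux[idx] * d[col].to_numpy()[idx]))

    nutrient_cols = {
        "energy_kj": "energy_kj_per_g",
        "ap_g": "ap", "fat_g": "fat", "tnc_g": "tnc",
        "ndf_g": "ndf", "adf_g": "adf", "lignin_g": "lignin",
    }

    bout_rows, truth_rows = [], []
    mass_by_focal = body_masses.set_index("focal_id")["mass_kg"]
    for gi, gname in enumerate(config.group_names):
        for fid in focal_ids[gname]:
            for period in range(1, config.n_periods + 1):
                season = SEASON_OF_PERIOD[period]
                cell = gs_index.loc[(gname, season)]
                m_target = float(cell["mass_target_g"])
                frug = float(cell["frugivory"])
                # time share of fruit-pool feeding that yields the target
                # fruit/seed mass fraction
                t_f = (mean_flux["leaf"] * frug
                       / (mean_flux["fruit"] * (1 - frug)
                          + mean_flux["leaf"] * frug))
                mean_phi = (t_f * mean_flux["fruit"]
                            + (1 - t_f) * mean_flux["leaf"])
                t_total = m_target / mean_phi          # expected feeding s/day
                for day in range(config.days_per_individual_period):
                    date = _period_date(period, day)
                    if noise:
                        n_bouts = max(int(rng.poisson(config.mean_bouts_per_day)), 1)
                        theta = t_total / (n_bouts * config.bout_shape)
                        durs = rng.gamma(config.bout_shape, theta, n_bouts)
                        from_fruit = rng.random(n_bouts) < t_f
                        choice = np.where(
                            from_fruit,
                            rng.choice(fruit_idx, n_bouts),
                            rng.choice(leaf_idx, n_bouts))
                        for dur, ci in zip(durs, choice):
                            bout_rows.append({
                                "focal_id": fid, "group_id": gname,
                                "date": date, "period": period,
                                "food_id": foods["food_id"].iat[int(ci)],
                                "duration_s": float(dur), "is_soil": False})
                    else:
                        for ci in fruit_idx:
                            bout_rows.append({
                                "focal_id": fid, "group_id": gname,
                                "date": date, "period": period,
                                "food_id": foods["food_id"].iat[int(ci)],
                                "duration_s": t_f * t_total / len(fruit_idx),
                                "is_soil": False})
                        for ci in leaf_idx:
                            bout_rows.append({
                                "focal_id": fid, "group_id": gname,
                                "date": date, "period": period,
                                "food_id": foods["food_id"].iat[int(ci)],
                                "duration_s": (1 - t_f) * t_total / len(leaf_idx),
                                "is_soil": False})
                    # analytic expectations for this focal-day
                    mass_kg = float(mass_by_focal[fid])
                    truth = {"focal_id": fid, "group_id": gname, "date": date,
                             "period": period, "season": season,
                             "lean": season in LEAN_SEASONS,
                             "feeding_time_s": t_total,
                             "dry_mass_g": m_target,
                             "frac_mass_fruit_seed": frug}
                    for out_col, src in nutrient_cols.items():
                        per_g = 1.0 if src == "energy_kj_per_g" else 1.0 / 100.0
                        val = t_total * (t_f * pool_mean(src, fruit_idx)
                                         + (1 - t_f) * pool_mean(src, leaf_idx))
                        truth[out_col] = val * (per_g if src != "energy_kj_per_g" else 1.0)
                    ap_kj = t_total * (t_f * pool_mean("ap_kj_per_g", fruit_idx)
                                       + (1 - t_f) * pool_mean("ap_kj_per_g", leaf_idx))
                    npe_kj = t_total * (t_f * pool_mean("npe_kj_per_g", fruit_idx)
                                        + (1 - t_f) * pool_mean("npe_kj_per_g", leaf_idx))
                    truth["ap_npe"] = ap_kj / npe_kj
                    truth["energy_per_mbm"] = (truth["energy_kj"]
                                               / mass_kg ** FUEL.metabolic_exponent)
                    truth["ap_per_bm"] = truth["ap_g"] / mass_kg
                    truth_rows.append(truth)

    bouts = pd.DataFrame(bout_rows)
    expected = pd.DataFrame(truth_rows)
    truth = SyntheticTruth(config=config, foods=foods, expected_daily=expected,
                           group_season_mass=group_season, pool_ap_npe=pool_ratio)
    return SyntheticStudy(bouts=bouts, rates=rates, handling=handling,
                          body_masses=body_masses, foods=foods, truth=truth)


# --------------------------------------------------------------------------
# Stage-level tables for mixed-model power / error-rate simulation
# --------------------------------------------------------------------------

def gen_lmm_table(seed: int,
                  group_means: Sequence[float] = (3759.0, 4753.0, 2279.0,
                                                  1309.0, 3561.0),
                  period_offsets: Sequence[float] | None = None,
                  n_individuals: Sequence[int] = (5, 4, 3, 2, 4),
                  n_periods: int = 12,
                  subject_sd: float = 400.0,
                  resid_sd: float = 1500.0,
                  response: str = "energy_kj") -> pd.DataFrame:
    """Simulate an individual x period mean table with known effects.

    Each cell is ``group mean + period offset + individual intercept +
    residual``; defaults mirror a strong habitat-quality contrast in daily
    energy intake with no period effect.  Setting all group means equal
    yields a null table for type-I error studies.
    """
    rng = np.random.default_rng(seed)
    if period_offsets is None:
        period_offsets = np.zeros(n_periods)
    period_offsets = np.asarray(period_offsets, dtype=float)
    if period_offsets.size != n_periods:
        raise ValueError("period_offsets must have one entry per period")
    rows = []
    for gi, gmean in enumerate(group_means):
        gname = f"G{gi + 1}"
        for j in range(n_individuals[gi]):
            fid = f"{gname}-A{j}"
            intercept = rng.normal(0.0, subject_sd)
            for p in range(1, n_periods + 1):
                rows.append({
                    "focal_id": fid, "group_id": gname, "period": p,
                    "n_days": 1,
                    response: gmean + period_offsets[p - 1] + intercept
                    + rng.normal(0.0, resid_sd),
                })
    return pd.DataFrame(rows)
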