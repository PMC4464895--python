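"""Readers, writers, pipeline orchestration and the command-line interface.

All tabular inputs and outputs are RFC 4180 CSV with a required header,
UTF-8, percentages on the 0-100 scale; the daily-intake replication loader
also reads XLSX.  Re-running the pipeline with identical inputs and seed is
bit-reproducible for every tabular output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import click
import pandas as pd
import yaml

from . import food_composition as fc
from . import intake_engine as ie
from . import nutritional_geometry as ng
from . import seasonal_models as sm
from . import synthetic_data as sd

__all__ = [
    "PipelineConfig",
    "IOError_",
    "read_composition_csv",
    "read_bouts_csv",
    "read_rates_csv",
    "read_handling_csv",
    "read_body_mass_csv",
    "write_derived_composition",
    "load_s1_table",
    "replication_summary",
    "run_pipeline",
    "write_study",
    "cli",
]


class IOError_(ValueError):
    """An input table is missing, malformed, or missing mandatory columns."""


# --------------------------------------------------------------------------
# Readers
# --------------------------------------------------------------------------

_SCHEMAS = {
    "composition": ["food_id", "species", "genus", "part_code", "cp", "adicp",
                    "fat", "ash", "ndf", "adf", "lignin"],
    "bouts": ["focal_id", "group_id", "date", "period", "food_id",
              "duration_s", "is_soil"],
    "rates": ["food_id", "mode", "units", "duration_s"],
    "handling": ["food_id", "unit_mass_g", "conversion_factor"],
    "body_mass": ["focal_id", "mass_kg", "age_class"],
}


def _read(path: str | Path, schema: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IOError_(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in _SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise IOError_(f"{path}: missing mandatory columns {missing}")
    return df


def read_composition_csv(path: str | Path) -> pd.DataFrame:
    """Composition table; empty cells mean 'not assayed' (fat only)."""
    df = _read(path, "composition")
    bad = set(df["part_code"]) - set(fc.PART_CODES)
    if bad:
        raise IOError_(f"{path}: unknown part codes {sorted(bad)}")
    return df


def read_bouts_csv(path: str | Path) -> pd.DataFrame:
    df = _read(path, "bouts")
    if (df["duration_s"] <= 0).any():
        raise IOError_(f"{path}: bout durations must be positive")
    if ~df["period"].between(1, 12).all():
        raise IOError_(f"{path}: periods must be integers in 1..12")
    return df


def read_rates_csv(path: str | Path) -> pd.DataFrame:
    return _read(path, "rates")


def read_handling_csv(path: str | Path) -> pd.DataFrame:
    return _read(path, "handling")


def read_body_mass_csv(path: str | Path) -> pd.DataFrame:
    return _read(path, "body_mass")


def write_derived_composition(comps: pd.DataFrame, path: str | Path) -> None:
    """Write a derived-composition CSV (adds ap, tnc, energy, ratio, shares)."""
    cols = [*_SCHEMAS["composition"], "ap", "tnc", "energy_kj_per_g", "ap_npe",
            "share_protein", "share_fat", "share_carb"]
    if "provenance" in comps.columns:
        cols.append("provenance")
    comps[cols].to_csv(path, index=False)


# --------------------------------------------------------------------------
# Replication loader for an external daily-intake spreadsheet
# --------------------------------------------------------------------------

#: Canonical daily-intake columns and name fragments used to auto-map the
#: column headers of an external per-focal-day spreadsheet.
_S1_CANDIDATES: dict[str, list[str]] = {
    "focal_id": ["focal", "individual", "animal", "id"],
    "group_id": ["group"],
    "date": ["date"],
    "period": ["period"],
    "feeding_time_s": ["feedingtime", "feedtime", "timefeeding"],
    "dry_mass_g": ["drymass", "massingested", "mass"],
    "frac_mass_fruit_seed": ["fruitseed", "fruit"],
    "energy_kj": ["energy"],
    "ap_g": ["availableprotein", "protein", "ap"],
    "fat_g": ["fat", "lipid"],
    "tnc_g": ["tnc", "carbohydrate"],
    "ndf_g": ["ndf"],
    "adf_g": ["adf"],
    "lignin_g": ["lignin"],
    "ap_npe": ["apnpe", "ratio"],
    "energy_per_mbm": ["metabolic", "mbm"],
    "ap_per_bm": ["perbm", "proteinbm"],
}

_S1_MANDATORY = ["focal_id", "group_id", "date", "period", "energy_kj", "ap_g"]


def _norm(name: str) -> str:
    return re.sub(r"[^a-z0-9]", "", str(name).lower())


def load_s1_table(path: str | Path,
                  column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Load an external per-focal-day intake spreadsheet (XLSX or CSV).

    Column headers are auto-mapped onto the daily-intake schema by
    normalised name fragments; ``column_map`` (canonical -> source name)
    overrides the automatic mapping.  Unmapped source columns are preserved
    as extras.  Missing mandatory columns are reported by name.
    """
    path = Path(path)
    if not path.exists():
        raise IOError_(f"replication file not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    if raw.empty:
        raise IOError_(f"{path}: no data rows")

    mapping: dict[str, str] = {}
    if column_map:
        mapping.update(column_map)
    normalised = {_norm(c): c for c in raw.columns}
    for canonical, fragments in _S1_CANDIDATES.items():
        if canonical in mapping:
            continue
        if canonical in raw.columns:
            mapping[canonical] = canonical
            continue
        for frag in fragments:
            hit = next((src for key, src in normalised.items()
                        if frag in key and src not in mapping.values()), None)
            if hit is not None:
                mapping[canonical] = hit
                break

    missing = [c for c in _S1_MANDATORY if c not in mapping]
    if missing:
        raise IOError_(
            f"{path}: could not locate mandatory columns {missing}; "
            "pass column_map={canonical: source_header}")

    df = raw.rename(columns={src: dst for dst, src in mapping.items()})
    if "season" not in df.columns:
        seasons = df["period"].map(ie.SEASON_OF_PERIOD)
        df["season"] = seasons
        df["lean"] = seasons.isin(ie.LEAN_SEASONS)
    return df


def replication_summary(daily: pd.DataFrame) -> dict:
    """Row/cell counts and headline means used for replication checks."""
    pt = sm.build_period_table(daily)
    by_group = daily.groupby("group_id")["ap_g"].mean()
    return {
        "n_days": int(len(daily)),
        "n_individuals": pt.n_individuals,
        "n_cells": pt.n_cells,
        "mean_energy_kj": float(daily["energy_kj"].mean()),
        "mean_ap_g_by_group": {str(k): float(v) for k, v in by_group.items()},
    }


# --------------------------------------------------------------------------
# Pipeline configuration and orchestration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """File paths, options, and constants for one pipeline run."""

    output_dir: str = "nutgeom_out"
    composition_csv: str | None = None
    bouts_csv: str | None = None
    rates_csv: str | None = None
    handling_csv: str | None = None
    body_mass_csv: str | None = None
    seed: int = 0
    simulate: bool = False           # generate inputs instead of reading them
    fit_models: bool = True
    model_variables: tuple[str, ...] = ("energy_kj", "dry_mass_g", "ap_npe")
    protein_requirement_g_per_kg: float = 2.8
    energy_requirement_per_mbm: float = 500.0
    reference_mass_kg: float = 5.0
    make_plots: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise IOError_(f"unknown config keys: {sorted(unknown)}")
        if "model_variables" in raw:
            raw["model_variables"] = tuple(raw["model_variables"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_study(study: sd.SyntheticStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write a synthetic study in the exact CSV schemas the pipeline reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "composition_csv": out / "composition.csv",
        "bouts_csv": out / "bouts.csv",
        "rates_csv": out / "rates.csv",
        "handling_csv": out / "handling.csv",
        "body_mass_csv": out / "body_mass.csv",
        "truth_csv": out / "truth_daily.csv",
    }
    study.foods.to_csv(paths["composition_csv"], index=False)
    study.bouts.to_csv(paths["bouts_csv"], index=False)
    study.rates.to_csv(paths["rates_csv"], index=False)
    study.handling.to_csv(paths["handling_csv"], index=False)
    study.body_masses.to_csv(paths["body_mass_csv"], index=False)
    study.truth.expected_daily.to_csv(paths["truth_csv"], index=False)
    return paths


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute composition -> intake -> geometry -> summaries.

    Returns a report bundle dict (also written to the output directory):
    paths of all CSV/plot outputs, per-variable model summaries, and a
    provenance record (input checksums, seed, fuel constants).
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        study = sd.gen_study(sd.StudyConfig(seed=config.seed))
        inputs = write_study(study, out / "inputs")
        config = dataclasses.replace(
            config, **{k: str(v) for k, v in inputs.items()
                       if k in {f.name for f in dataclasses.fields(config)}})

    stage = "composition"
    try:
        comps = read_composition_csv(config.composition_csv)
        bouts = read_bouts_csv(config.bouts_csv)
        rates = read_rates_csv(config.rates_csv)
        handling = read_handling_csv(config.handling_csv)
        body_mass = read_body_mass_csv(config.body_mass_csv)

        # resolve substitutions for any fed-on food lacking a direct record
        library = [fc.FoodComposition(**{k: (None if pd.isna(v) else v)
                                         for k, v in row.items()})
                   for row in comps[_SCHEMAS["composition"]].to_dict("records")]
        fed = bouts.loc[~bouts["is_soil"].astype(bool), "food_id"].unique()
        known = set(comps["food_id"])
        # re-resolving direct records fills unassayed fat from part averages
        resolved = [fc.substitute_composition(r.food_id, r.species, r.genus,
                                              r.part_code, library)
                    for r in library]
        for food in fed:
            if food not in known:
                part = food.split("-")[0]
                resolved.append(fc.substitute_composition(
                    food, species="?", genus="?", part_code=part,
                    library=library))
        comp_frame = pd.DataFrame([{
            "food_id": r.food_id, "species": r.species, "genus": r.genus,
            "part_code": r.part_code, "cp": r.cp, "adicp": r.adicp,
            "fat": r.fat, "ash": r.ash, "ndf": r.ndf, "adf": r.adf,
            "lignin": r.lignin, "provenance": r.provenance,
        } for r in resolved])
        derived = fc.derive_frame(comp_frame)
        write_derived_composition(derived, out / "derived_composition.csv")

        stage = "intake"
        daily = ie.compute_daily_intakes(bouts, rates, handling, derived,
                                         body_mass)
        daily.to_csv(out / "daily_intake.csv", index=False)

        stage = "geometry"
        ap_kj = daily["ap_g"] * fc.FUEL.kj_protein
        fat_kj = daily["fat_g"] * fc.FUEL.kj_fat
        tnc_kj = daily["tnc_g"] * fc.FUEL.kj_tnc
        npe_kj = ap_kj / daily["ap_npe"]
        coords = pd.DataFrame({
            "focal_id": daily["focal_id"], "date": daily["date"],
            "group_id": daily["group_id"], "season": daily["season"],
            "ap_kj": ap_kj, "fat_kj": fat_kj, "tnc_kj": tnc_kj,
            "npe_kj": npe_kj,
            "x_protein": 100 * ap_kj / (ap_kj + fat_kj + tnc_kj),
            "y_fat": 100 * fat_kj / (ap_kj + fat_kj + tnc_kj),
        })
        coords["z_carb"] = 100 - coords["x_protein"] - coords["y_fat"]
        coords.to_csv(out / "rmt_coordinates.csv", index=False)

        # rails fitted on group x season mean intakes
        gs = coords.groupby(["group_id", "season"], as_index=False)[
            ["ap_kj", "npe_kj"]].mean()
        rail_rows = []
        for g, sub in gs.groupby("group_id"):
            if len(sub) >= 2:
                fit = ng.fit_rail(sub["ap_kj"], sub["npe_kj"])
                rail_rows.append({"group_id": g, "slope": fit.slope,
                                  "implied_ap_npe": fit.implied_ap_npe,
                                  "n_points": fit.n_points,
                                  "residual_spread_pct": fit.residual_spread})
        rails = pd.DataFrame(rail_rows)
        rails.to_csv(out / "rails.csv", index=False)

        thresholds = ng.threshold_lines(config.protein_requirement_g_per_kg,
                                        config.energy_requirement_per_mbm,
                                        config.reference_mass_kg)
        if config.make_plots:
            pts = [ng.RMTPoint(x, y, z) for x, y, z in
                   zip(coords["x_protein"], coords["y_fat"], coords["z_carb"])]
            ng.plot_rmt(pts, labels=list(coords["group_id"]),
                        path=str(out / "rmt.svg"))
            ng.plot_rail(gs["ap_kj"], gs["npe_kj"], thresholds=thresholds,
                         path=str(out / "rail.svg"))

        stage = "summaries"
        tables = sm.descriptive_tables(daily)
        for name, frame in tables.items():
            frame.to_csv(out / f"summary_{name}.csv", index=False)
        period_table = sm.build_period_table(daily)
        period_table.table.to_csv(out / "period_means.csv", index=False)

        model_reports = []
        if config.fit_models:
            for var in config.model_variables:
                transform = sm.DEFAULT_TRANSFORMS.get(var, "none")
                res = sm.fit_group_period_model(
                    period_table, sm.LmmSpec(response=var, transform=transform))
                model_reports.append(res.to_dict())
        (out / "model_report.json").write_text(
            json.dumps(model_reports, indent=2, default=float))
    except Exception as exc:
        raise IOError_(f"pipeline stage '{stage}' failed: {exc}") from exc

    provenance = {
        "seed": config.seed,
        "fuel_constants": dataclasses.asdict(fc.FUEL),
        "thresholds_kj": {"protein_min": thresholds.protein_min_kj,
                          "energy_min": thresholds.energy_min_kj},
        "inputs": {k: {"path": str(getattr(config, k)),
                       "sha256": _sha256(Path(getattr(config, k)))}
                   for k in ("composition_csv", "bouts_csv", "rates_csv",
                             "handling_csv", "body_mass_csv")
                   if getattr(config, k)},
        "n_focal_days": int(len(daily)),
        "period_matrix": {"individuals": period_table.n_individuals,
                          "periods": period_table.n_periods,
                          "populated_cells": period_table.n_cells},
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))

    return {"output_dir": str(out), "provenance": provenance,
            "models": model_reports, "rails": rails.to_dict("records")}


# --------------------------------------------------------------------------
# Command-line interface
# --------------------------------------------------------------------------

@click.group()
def cli() -> None:
    """Nutritional-geometry analysis of focal-animal feeding data."""


@cli.command()
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "out_dir", type=click.Path(), default="synthetic_study",
              show_default=True)
def simulate(seed: int, out_dir: str) -> None:
    """Generate a synthetic study (bouts, rates, handling, masses, truth)."""
    study = sd.gen_study(sd.StudyConfig(seed=seed))
    paths = write_study(study, out_dir)
    click.echo(json.dumps({k: str(v) for k, v in paths.items()}, indent=2))


@cli.command()
@click.argument("composition_csv", type=click.Path(exists=True))
@click.option("--out", type=click.Path(), default="derived_composition.csv",
              show_default=True)
def compose(composition_csv: str, out: str) -> None:
    """Derive AP, TNC, energy density and AP:NPE for a composition table."""
    derived = fc.derive_frame(read_composition_csv(composition_csv))
    write_derived_composition(derived, out)
    click.echo(f"wrote {out} ({len(derived)} foods)")


@cli.command(name="run")
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None, help="YAML pipeline configuration.")
@click.option("--simulate/--no-simulate", default=False,
              help="Generate synthetic inputs instead of reading files.")
@click.option("--seed", type=int, default=0, show_default=True)
@click.option("--out", "output_dir", type=click.Path(), default=None)
def run_cmd(config_path: str | None, simulate: bool, seed: int,
            output_dir: str | None) -> None:
    """Run the full pipeline: composition -> intake -> geometry -> summaries."""
    cfg = PipelineConfig.from_yaml(config_path) if config_path else PipelineConfig()
    overrides = {"seed": seed}
    if simulate:
        overrides["simulate"] = True
    if output_dir:
        overrides["output_dir"] = output_dir
    cfg = dataclasses.replace(cfg, **overrides)
    report = run_pipeline(cfg)
    click.echo(json.dumps(report["provenance"], indent=2))


@cli.command(name="replicate-s1")
@click.argument("spreadsheet", type=click.Path(exists=True))
def replicate_s1(spreadsheet: str) -> None:
    """Load an external per-focal-day intake table and print its summary."""
    daily = load_s1_table(spreadsheet)
    click.echo(json.dumps(replication_summary(daily), indent=2))


if __name__ == "__main__":
    cli()
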