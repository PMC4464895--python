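"""Seasonal and inter-group statistical summaries of daily intakes.

Daily intakes are first averaged within individual x collection period to
balance the design, then analysed with a linear mixed model: fixed effects
of group, period and their interaction, and a random intercept per
individual (individuals are nested in groups).  Restricted maximum
likelihood fitting is delegated to statsmodels' MixedLM; this module builds
the design, computes Wald F-tests with containment-style denominator
degrees of freedom, estimated marginal means (back-transformed when a
variance-stabilising transform was applied) and unadjusted (LSD) pairwise
letter groupings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.formula.api as smf
from patsy import build_design_matrices

__all__ = [
    "INTAKE_VARIABLES",
    "DEFAULT_TRANSFORMS",
    "PeriodTable",
    "LmmSpec",
    "LmmResult",
    "ModelError",
    "build_period_table",
    "apply_transform",
    "inverse_transform",
    "fit_group_period_model",
    "descriptive_tables",
]


class ModelError(ValueError):
    pass


#: The intake variables summarised per individual x period.
INTAKE_VARIABLES = [
    "feeding_time_s", "dry_mass_g", "frac_mass_fruit_seed", "energy_kj",
    "ap_g", "fat_g", "tnc_g", "ndf_g", "adf_g", "lignin_g", "ap_npe",
]

#: Transforms applied before model fitting: the fruit/seed proportion is
#: arcsine-square-root transformed; available protein is log-transformed
#: (raw-scale fits of strongly right-skewed protein intakes converge poorly);
#: the ratio is analysed untransformed.
DEFAULT_TRANSFORMS = {
    "frac_mass_fruit_seed": "arcsine_sqrt",
    "ap_g": "log",
}


@dataclass(frozen=True)
class LmmSpec:
    """Model specification for one response variable."""

    response: str
    transform: str = "none"      # none | arcsine_sqrt | log
    alpha: float = 0.05          # level for LSD letter groupings


@dataclass
class LmmResult:
    """Fixed-effect F-tests, estimated marginal means, and letter groups."""

    response: str
    transform: str
    anova: pd.DataFrame          # effect, F, df_num, df_den, p
    emm: pd.DataFrame            # group, emm (transformed scale), emm_raw, se, letters
    converged: bool
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "response": self.response,
            "transform": self.transform,
            "anova": self.anova.to_dict(orient="records"),
            "emm": self.emm.to_dict(orient="records"),
            "converged": self.converged,
            "notes": self.notes,
        }


# --------------------------------------------------------------------------
# Aggregation and transforms
# --------------------------------------------------------------------------

@dataclass
class PeriodTable:
    """Individual x period means and the fill of the design matrix."""

    table: pd.DataFrame
    n_individuals: int
    n_periods: int
    n_cells: int                 # populated (individual, period) cells

    @property
    def fill(self) -> float:
        denom = self.n_individuals * self.n_periods
        return self.n_cells / denom if denom else 0.0


def build_period_table(daily: pd.DataFrame, n_periods: int = 12) -> PeriodTable:
    """Average daily intakes within individual x collection period.

    Returns one row per populated (focal_id, period) cell with per-variable
    means and ``n_days``, plus the matrix-fill audit (individuals x periods
    vs populated cells).  Order-independent and idempotent.
    """
    if daily.empty:
        empty = pd.DataFrame(columns=["focal_id", "group_id", "period", "n_days",
                                      *INTAKE_VARIABLES])
        return PeriodTable(empty, 0, n_periods, 0)
    variables = [v for v in INTAKE_VARIABLES if v in daily.columns]
    g = daily.groupby(["focal_id", "period"], as_index=False)
    table = g.agg(group_id=("group_id", "first"), n_days=("date", "size"),
                  **{v: (v, "mean") for v in variables})
    table = table.sort_values(["focal_id", "period"], ignore_index=True)
    return PeriodTable(
        table=table[["focal_id", "group_id", "period", "n_days", *variables]],
        n_individuals=daily["focal_id"].nunique(),
        n_periods=n_periods,
        n_cells=len(table),
    )


def apply_transform(values, transform: str):
    """Apply a variance-stabilising transform (none | arcsine_sqrt | log)."""
    v = np.asarray(values, dtype=float)
    if transform == "none":
        return v
    if transform == "arcsine_sqrt":
        if np.any((v < 0) | (v > 1)):
            raise ModelError("arcsine_sqrt requires proportions in [0, 1]")
        return np.arcsin(np.sqrt(v))
    if transform == "log":
        if np.any(v <= 0):
            raise ModelError("log transform requires positive values")
        return np.log(v)
    raise ModelError(f"unknown transform {transform!r}")


def inverse_transform(values, transform: str):
    """Back-transform model-scale values to the raw scale."""
    v = np.asarray(values, dtype=float)
    if transform == "none":
        return v
    if transform == "arcsine_sqrt":
        return np.sin(v) ** 2
    if transform == "log":
        return np.exp(v)
    raise ModelError(f"unknown transform {transform!r}")


# --------------------------------------------------------------------------
# Mixed model
# --------------------------------------------------------------------------

def _wald_f(beta: np.ndarray, cov: np.ndarray, L: np.ndarray,
            df_den: float) -> tuple[float, int, float]:
    """Wald F-test that the contrasts ``L @ beta`` are jointly zero."""
    Lb = L @ beta
    LcL = L @ cov @ L.T
    q = int(np.linalg.matrix_rank(LcL))
    stat = float(Lb @ np.linalg.pinv(LcL) @ Lb) / q
    p = float(st.f.sf(stat, q, df_den))
    return stat, q, p


def _letter_groups(order: list[str], nonsig: dict[frozenset, bool]) -> dict[str, str]:
    """Compact letter display: shared letters mark non-significant pairs.

    ``order`` lists group names sorted by mean; insert-and-absorb over
    maximal runs of mutually non-different groups.
    """
    runs: list[tuple[int, int]] = []
    n = len(order)
    for i in range(n):
        j = i
        while j + 1 < n and all(
            nonsig.get(frozenset((order[a], order[b])), False)
            for a in range(i, j + 2) for b in range(a + 1, j + 2)
        ):
            j += 1
        runs.append((i, j))
    # absorb runs contained in earlier ones
    maximal = [r for r in runs
               if not any(o != r and o[0] <= r[0] and r[1] <= o[1] for o in runs)]
    letters = {g: "" for g in order}
    for k, (i, j) in enumerate(sorted(set(maximal))):
        ch = chr(ord("a") + k)
        for g in order[i:j + 1]:
            letters[g] += ch
    return letters


def fit_group_period_model(period_table: pd.DataFrame | PeriodTable,
                           spec: LmmSpec) -> LmmResult:
    """Fit the group x period mixed model for one intake variable.

    REML fit of ``response ~ group * period`` (both categorical) with a
    random intercept per individual, delegated to statsmodels MixedLM.
    Returns Wald F-tests for the three fixed effects (containment-style
    denominator dof: between-individual dof for group, within dof for period
    and the interaction), per-group estimated marginal means averaged over
    periods (back-transformed when a transform was used), and LSD letter
    groupings at ``spec.alpha``.
    """
    table = period_table.table if isinstance(period_table, PeriodTable) else period_table
    data = table.dropna(subset=[spec.response]).copy()
    groups = sorted(data["group_id"].unique())
    periods = sorted(data["period"].unique())
    if len(groups) < 2 or len(periods) < 2:
        raise ModelError("model needs at least 2 groups and 2 periods")

    data["_y"] = apply_transform(data[spec.response], spec.transform)
    notes = [
        "denominator dof: containment approximation "
        "(between-individual for group; within for period and interaction)",
        "random intercept per individual; homoscedastic residual",
    ]

    model = smf.mixedlm("_y ~ C(group_id) * C(period)", data,
                        groups=data["focal_id"])
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=True)
            converged = bool(getattr(res, "converged", True))
        except Exception as exc:   # singular fits on degenerate inputs
            raise ModelError(f"mixed-model fit failed: {exc}") from exc
    if not converged:
        notes.append("REML fit did not converge; treat results as preliminary")

    beta = np.asarray(res.fe_params)
    k = beta.size
    cov = np.asarray(res.cov_params())[:k, :k]
    design_info = res.model.data.design_info

    n_obs = len(data)
    n_subj = data["focal_id"].nunique()
    df_between = max(n_subj - len(groups), 1)
    p_within = sum(sl.stop - sl.start
                   for t, sl in design_info.term_name_slices.items()
                   if "C(period)" in t)
    df_within = max(n_obs - n_subj - p_within, 1)

    # EMM row vectors: average the fixed-effect design over all periods
    # (per group) or over all groups (per period).
    emm_vectors = {}
    for g in groups:
        grid = pd.DataFrame({"group_id": g, "period": periods})
        (X,) = build_design_matrices([design_info], grid)
        emm_vectors[g] = np.asarray(X).mean(axis=0)
    period_vectors = {}
    for p in periods:
        grid = pd.DataFrame({"group_id": groups, "period": p})
        (X,) = build_design_matrices([design_info], grid)
        period_vectors[p] = np.asarray(X).mean(axis=0)

    # Marginal (type-III style) effect tests: equality of marginal means for
    # the main effects; the interaction coefficients jointly zero.
    L_group = np.array([emm_vectors[g] - emm_vectors[groups[0]]
                        for g in groups[1:]])
    L_period = np.array([period_vectors[p] - period_vectors[periods[0]]
                         for p in periods[1:]])
    sl = design_info.term_name_slices["C(group_id):C(period)"]
    L_inter = np.zeros((sl.stop - sl.start, k))
    for r, c in enumerate(range(sl.start, sl.stop)):
        L_inter[r, c] = 1.0

    rows = []
    for effect, L, df_den in (("group", L_group, df_between),
                              ("period", L_period, df_within),
                              ("group:period", L_inter, df_within)):
        f, q, p = _wald_f(beta, cov, L, df_den)
        rows.append({"effect": effect, "F": f, "df_num": q,
                     "df_den": df_den, "p": p})
    anova = pd.DataFrame(rows)
    emm_rows = []
    for g in groups:
        m = emm_vectors[g]
        est = float(m @ beta)
        se = float(np.sqrt(m @ cov @ m))
        emm_rows.append({"group": g, "emm": est,
                         "emm_raw": float(inverse_transform(est, spec.transform)),
                         "se": se})
    emm = pd.DataFrame(emm_rows)

    # Unadjusted (LSD) pairwise comparisons -> letter groups.
    nonsig: dict[frozenset, bool] = {}
    for i, g in enumerate(groups):
        for h in groups[i + 1:]:
            d = emm_vectors[g] - emm_vectors[h]
            se_d = float(np.sqrt(d @ cov @ d))
            t = float(d @ beta) / se_d if se_d > 0 else 0.0
            p = 2 * float(st.t.sf(abs(t), df_between))
            nonsig[frozenset((g, h))] = p >= spec.alpha
    order = emm.sort_values("emm")["group"].tolist()
    letters = _letter_groups(order, nonsig)
    emm["letters"] = emm["group"].map(letters)

    return LmmResult(response=spec.response, transform=spec.transform,
                     anova=anova, emm=emm, converged=converged, notes=notes)


# --------------------------------------------------------------------------
# Descriptive tables
# --------------------------------------------------------------------------

def _mean_sd(s: pd.Series) -> tuple[float, float]:
    return float(s.mean()), float(s.std(ddof=1)) if len(s) > 1 else 0.0


def descriptive_tables(daily: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Group, group x season, and macronutrient-share summaries.

    Returns three frames:

    ``by_group``          n days, daily energy (kJ) and available protein (g)
                          mean +/- SD, plus their body-mass-scaled versions;
    ``by_group_season``   energy per metabolic body mass and protein per body
                          mass, mean +/- SD per group and season;
    ``macronutrient_shares`` per-day percent contributions of protein, fat
                          and carbohydrate to fiber-free macronutrient kJ
                          (mean +/- SD per group and overall), dietary AP:NPE
                          mean +/- SD and its coefficient of variation.

    Shares and ratios are averaged over focal-days (mean of daily values).
    """
    if daily.empty:
        raise ModelError("daily intake table is empty")
    d = daily.copy()

    def block(sub: pd.DataFrame) -> dict:
        e_m, e_sd = _mean_sd(sub["energy_kj"])
        p_m, p_sd = _mean_sd(sub["ap_g"])
        return {
            "n_days": len(sub),
            "energy_kj_mean": e_m, "energy_kj_sd": e_sd,
            "energy_per_mbm_mean": float(sub["energy_per_mbm"].mean()),
            "ap_g_mean": p_m, "ap_g_sd": p_sd,
            "ap_per_bm_mean": float(sub["ap_per_bm"].mean()),
        }

    rows = [{"group": g, **block(sub)} for g, sub in d.groupby("group_id")]
    rows.append({"group": "TOTAL", **block(d)})
    by_group = pd.DataFrame(rows)

    gs_rows = []
    for (g, s), sub in d.groupby(["group_id", "season"]):
        em, esd = _mean_sd(sub["energy_per_mbm"])
        pm, psd = _mean_sd(sub["ap_per_bm"])
        gs_rows.append({"group": g, "season": s, "n_days": len(sub),
                        "energy_per_mbm_mean": em, "energy_per_mbm_sd": esd,
                        "ap_per_bm_mean": pm, "ap_per_bm_sd": psd})
    by_group_season = pd.DataFrame(gs_rows)

    # per-day fiber-free macronutrient shares
    from .food_composition import FUEL
    ap_kj = d["ap_g"] * FUEL.kj_protein
    fat_kj = d["fat_g"] * FUEL.kj_fat
    tnc_kj = d["tnc_g"] * FUEL.kj_tnc
    macro = ap_kj + fat_kj + tnc_kj
    ok = macro > 0
    d.loc[ok, "share_protein"] = 100 * ap_kj[ok] / macro[ok]
    d.loc[ok, "share_fat"] = 100 * fat_kj[ok] / macro[ok]
    d.loc[ok, "share_carb"] = 100 * tnc_kj[ok] / macro[ok]

    def share_block(sub: pd.DataFrame) -> dict:
        out = {}
        for v in ("share_protein", "share_fat", "share_carb", "ap_npe"):
            m, sd = _mean_sd(sub[v].dropna())
            out[f"{v}_mean"], out[f"{v}_sd"] = m, sd
        ratios = sub["ap_npe"].dropna()
        out["ap_npe_cv"] = (100 * float(ratios.std(ddof=1)) / float(ratios.mean())
                            if len(ratios) > 1 and ratios.mean() != 0 else np.nan)
        return out

    sh_rows = [{"group": g, **share_block(sub)} for g, sub in d.groupby("group_id")]
    sh_rows.append({"group": "TOTAL", **share_block(d)})
    shares = pd.DataFrame(sh_rows)

    return {"by_group": by_group, "by_group_season": by_group_season,
            "macronutrient_shares": shares}
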