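"""Geometric-framework representations of macronutrient intake.

Right-angled mixture triangles (RMT) place protein on x and fat on y as
percentages of fiber-free macronutrient energy; carbohydrate is the implicit
axis z = 100 - x - y.  Nutritional rails are through-origin regressions of
daily non-protein energy (NPE, fiber included) on available-protein energy:
a population that balances its macronutrient ratio lies along one rail, and
the reciprocal of the rail slope is the implied AP:NPE ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .food_composition import FUEL, FuelConstants

__all__ = [
    "RMTPoint",
    "RailFit",
    "ThresholdLines",
    "GeometryError",
    "rmt_coords",
    "carb_isoline",
    "proportion_to_ratio",
    "ratio_to_proportion",
    "fit_rail",
    "coefficient_of_variation",
    "threshold_lines",
    "plot_rmt",
    "plot_rail",
]


class GeometryError(ValueError):
    pass


@dataclass(frozen=True)
class RMTPoint:
    """A point on the right-angled mixture triangle (percent of macronutrient kJ)."""

    x_protein: float
    y_fat: float
    z_carb: float


@dataclass(frozen=True)
class RailFit:
    """Through-origin regression of NPE kJ on AP kJ (a nutritional rail)."""

    slope: float                 # kJ NPE per kJ AP
    n_points: int
    implied_ap_npe: float        # 1 / slope
    residual_spread: float       # % ; SD of perpendicular deviations over
                                 # mean distance of points from the origin


@dataclass(frozen=True)
class ThresholdLines:
    """Requirement thresholds in the AP-NPE plane (kJ/day).

    ``protein_min_kj`` is a vertical line (minimum protein energy);
    ``energy_min_kj`` an oblique line AP + NPE = const (minimum total
    energy).  Points left of the vertical line or below the oblique line
    fall short of a requirement.
    """

    protein_min_kj: float
    energy_min_kj: float

    def __post_init__(self) -> None:
        if self.protein_min_kj <= 0 or self.energy_min_kj <= 0:
            raise GeometryError("threshold energies must be positive")


def rmt_coords(ap_kj: float, fat_kj: float, tnc_kj: float) -> RMTPoint:
    """Percent contributions of protein/fat/carbohydrate to macronutrient kJ.

    Fiber energy is excluded from the axes (it contributes little of the
    macronutrient energy in folivore diets and would require a fourth axis).
    """
    if min(ap_kj, fat_kj, tnc_kj) < 0:
        raise GeometryError("energy inputs must be nonnegative")
    total = ap_kj + fat_kj + tnc_kj
    if total <= 0:
        raise GeometryError("total macronutrient energy is zero")
    return RMTPoint(100.0 * ap_kj / total, 100.0 * fat_kj / total,
                    100.0 * tnc_kj / total)


def carb_isoline(z_percent: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Endpoints of the constant-carbohydrate isoline x + y = 100 - z.

    Returned as ((x0, y0), (x1, y1)) clipped to the first quadrant; at
    z = 100 it degenerates to the origin.
    """
    if not (0.0 <= z_percent <= 100.0):
        raise GeometryError(f"z must be in [0, 100], got {z_percent}")
    c = 100.0 - z_percent
    return ((c, 0.0), (0.0, c))


def proportion_to_ratio(p_protein: float) -> float:
    """AP:NPE ratio from the proportion of macronutrient kJ that is protein."""
    if not (0.0 <= p_protein < 1.0):
        raise GeometryError(f"proportion must be in [0, 1), got {p_protein}")
    return p_protein / (1.0 - p_protein)


def ratio_to_proportion(ratio: float) -> float:
    """Inverse of :func:`proportion_to_ratio`: r -> r / (1 + r)."""
    if ratio < 0:
        raise GeometryError(f"ratio must be nonnegative, got {ratio}")
    return ratio / (1.0 + ratio)


def fit_rail(ap_kj: Sequence[float], npe_kj: Sequence[float]) -> RailFit:
    """Fit a nutritional rail: least squares NPE = slope * AP through the origin.

    slope = sum(ap * npe) / sum(ap^2); the implied dietary AP:NPE ratio is
    1/slope.  ``residual_spread`` is the SD of perpendicular deviations from
    the rail expressed as a percentage of the mean distance of the points
    from the origin (scale-free).
    """
    ap = np.asarray(ap_kj, dtype=float)
    npe = np.asarray(npe_kj, dtype=float)
    if ap.shape != npe.shape or ap.ndim != 1:
        raise GeometryError("ap and npe must be 1-d sequences of equal length")
    if ap.size < 2:
        raise GeometryError("need at least 2 points to fit a rail")
    denom = float(np.sum(ap * ap))
    if denom == 0.0:
        raise GeometryError("degenerate rail fit: all AP values are zero")
    slope = float(np.sum(ap * npe)) / denom
    perp = (npe - slope * ap) / np.hypot(1.0, slope)
    dist = np.hypot(ap, npe)
    mean_dist = float(np.mean(dist))
    spread = 100.0 * float(np.std(perp, ddof=1)) / mean_dist if mean_dist > 0 else 0.0
    if slope <= 0:
        raise GeometryError(f"rail slope must be positive, got {slope}")
    return RailFit(slope=slope, n_points=int(ap.size),
                   implied_ap_npe=1.0 / slope, residual_spread=spread)


def coefficient_of_variation(values: Sequence[float]) -> float:
    """Sample coefficient of variation, in percent: 100 * SD / mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise GeometryError("CV needs at least 2 values")
    mean = float(np.mean(v))
    if mean == 0.0:
        raise GeometryError("CV undefined for zero mean")
    return 100.0 * float(np.std(v, ddof=1)) / mean


def threshold_lines(protein_g_per_kg: float, energy_per_mbm: float,
                    mass_kg: float, constants: FuelConstants = FUEL
                    ) -> ThresholdLines:
    """Requirement thresholds for an animal of given mass.

    ``protein_g_per_kg`` (g·BM_kg^-1·day^-1) converts through the protein
    fuel value to a vertical protein-energy line; ``energy_per_mbm``
    (kJ·BM_kg^-0.762·day^-1) scales back up to a total-energy oblique line.
    """
    if min(protein_g_per_kg, energy_per_mbm, mass_kg) <= 0:
        raise GeometryError("thresholds and mass must be positive")
    protein_kj = protein_g_per_kg * mass_kg * constants.kj_protein
    energy_kj = energy_per_mbm * mass_kg ** constants.metabolic_exponent
    return ThresholdLines(protein_min_kj=protein_kj, energy_min_kj=energy_kj)


# --------------------------------------------------------------------------
# Plot exports
# --------------------------------------------------------------------------

def plot_rmt(points: Sequence[RMTPoint], labels: Sequence[str] | None = None,
             isolines: Sequence[float] = (60.0, 80.0), path: str | None = None):
    """RMT scatter (protein on x, fat on y) with carbohydrate isolines.

    Returns the matplotlib figure; writes it to ``path`` (SVG/PNG by
    extension) when given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    x = [p.x_protein for p in points]
    y = [p.y_fat for p in points]
    if labels is None:
        ax.scatter(x, y, s=25, alpha=0.7)
    else:
        for lab in sorted(set(labels)):
            xs = [xi for xi, li in zip(x, labels) if li == lab]
            ys = [yi for yi, li in zip(y, labels) if li == lab]
            ax.scatter(xs, ys, s=25, alpha=0.7, label=str(lab))
        ax.legend(fontsize=8)
    for z in isolines:
        (x0, y0), (x1, y1) = carb_isoline(z)
        ax.plot([x0, x1], [y0, y1], ls=":", color="grey", lw=1)
        ax.annotate(f"{z:g}% carb", xy=((x0 + x1) / 2, (y0 + y1) / 2),
                    fontsize=7, color="grey")
    lim = max(30.0, max(x + y) * 1.1 if x else 30.0)
    ax.set(xlim=(0, lim), ylim=(0, lim),
           xlabel="Protein (% macronutrient kJ)",
           ylabel="Fat (% macronutrient kJ)")
    if path:
        fig.savefig(path, bbox_inches="tight")
    return fig


def plot_rail(ap_kj: Sequence[float], npe_kj: Sequence[float],
              rail: RailFit | None = None,
              thresholds: ThresholdLines | None = None,
              path: str | None = None):
    """Bivariate AP-NPE plot with the fitted rail and shaded requirement region."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ap = np.asarray(ap_kj, dtype=float)
    npe = np.asarray(npe_kj, dtype=float)
    if rail is None:
        rail = fit_rail(ap, npe)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    ax.scatter(ap, npe, s=25, alpha=0.7)
    xmax = float(np.max(ap)) * 1.15 if ap.size else 1.0
    ymax = float(np.max(npe)) * 1.15 if npe.size else 1.0
    xs = np.linspace(0, xmax, 50)
    ax.plot(xs, rail.slope * xs, color="k", lw=1,
            label=f"rail (AP:NPE = {rail.implied_ap_npe:.3f})")
    if thresholds is not None:
        ax.axvline(thresholds.protein_min_kj, color="grey", lw=1)
        # oblique total-energy line: AP + NPE = E_min
        ax.plot([0, thresholds.energy_min_kj], [thresholds.energy_min_kj, 0],
                color="grey", lw=1)
        ax.fill_betweenx([0, ymax], 0, thresholds.protein_min_kj,
                         color="grey", alpha=0.15)
        ax.fill_between(xs, 0, np.clip(thresholds.energy_min_kj - xs, 0, None),
                        color="grey", alpha=0.15)
    ax.set(xlim=(0, xmax), ylim=(0, ymax),
           xlabel="Available protein (kJ/day)",
           ylabel="Non-protein energy (kJ/day)")
    ax.legend(fontsize=8)
    if path:
        fig.savefig(path, bbox_inches="tight")
    return fig
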