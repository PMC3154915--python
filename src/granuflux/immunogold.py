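"""Quantitative immunogold cytochemistry pipeline.

Implements the standard density-based workflow for immunogold electron
micrographs, operating on particle coordinates rather than pixels (as in
the original manual counting):

1. **Assignment** of each gold particle to a tissue compartment.  Membrane
   compartments claim particles whose centres lie within 30 nm on either
   side of the membrane trace; SLMVs claim particles within 30 nm of their
   outer border (boundary inclusive).  For soluble antigens (fixed amino
   acids) granules and mitochondria claim particles by containment in
   their profile; the SLMV halo rule applies in both classes.  Ambiguity
   precedence: SLMV halo > membrane bands > granule core > mitochondrion >
   cytosol.
2. **Stereological area estimation** with a regular point grid: the area of
   a compartment is (grid points hitting it) × spacing².  Analytic areas
   are exposed alongside as the oracle the estimator converges to.
3. **Densities**: raw = count/area; net = raw − background, where the
   background stream is chosen by compartment class (mitochondrial outer
   membrane for membrane compartments, mitochondrial matrix for interiors
   of protein labellings, empty resin for amino acids).  Negative net
   densities are preserved and flagged, never clipped.
4. **Ratios and group tests**: per-cell compartment ratios, group
   mean ± SD/SEM, and two-tailed Mann–Whitney U comparisons (exact for
   small samples).
5. **Calibration**: least-squares line through test-section densities at
   known concentrations, with inverse prediction density → mM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_em import (
    CalibrationSeries,
    ParticlePattern,
    SectionModel,
)

__all__ = [
    "AssignmentRule",
    "BackgroundModel",
    "CalibrationCurve",
    "classify_points",
    "assign_particles",
    "estimate_areas",
    "compute_densities",
    "quantify_cell",
    "cell_ratios",
    "mann_whitney",
    "ratio_stats",
    "calibrate_concentration",
    "estimate_mM",
    "anchored_curve",
]


@dataclass(frozen=True)
class AssignmentRule:
    """Particle/grid-point inclusion rule.

    ``mode`` selects the antigen class: 'solute' (amino acids; granules
    and mitochondria counted by profile containment) or 'membrane'
    (transporter proteins; 30 nm bands around membrane traces).  The
    30 nm distances are boundary inclusive.
    """

    membrane_halfwidth_nm: float = 30.0
    slmv_halo_nm: float = 30.0
    mode: str = "solute"

    def __post_init__(self) -> None:
        if self.membrane_halfwidth_nm <= 0 or self.slmv_halo_nm <= 0:
            raise ValueError("rule distances must be strictly positive")
        if self.mode not in ("solute", "membrane"):
            raise ValueError(f"unknown rule mode {self.mode!r}")


@dataclass(frozen=True)
class BackgroundModel:
    """Background labelling rates (particles/µm²) by reference compartment.

    ``membrane`` — over mitochondrial outer membranes, subtracted from
    membrane compartments of protein labellings; ``matrix`` — over the
    mitochondrial matrix, subtracted from non-membrane compartments of
    protein labellings; ``resin`` — over empty resin, subtracted from every
    compartment for amino-acid labellings.
    """

    membrane: float = 0.0
    matrix: float = 0.0
    resin: float = 0.0
    antigen_class: str = "solute"  # 'solute' | 'membrane'

    _MEMBRANE_LABELS = frozenset(
        {"granule_membrane", "plasma_membrane", "mito_membrane"}
    )

    def rate_for(self, label: str) -> float:
        if self.antigen_class == "solute":
            return self.resin
        if label in self._MEMBRANE_LABELS:
            return self.membrane
        return self.matrix


# --------------------------------------------------------------------------
# assignment
# --------------------------------------------------------------------------


def _circle_masks(xy: np.ndarray, circles) -> tuple[np.ndarray, np.ndarray]:
    """Squared distance of each point to its nearest circle centre and that
    circle's radius (vectorised over points, looped over circles)."""
    n = len(xy)
    best_d2 = np.full(n, np.inf)
    best_r = np.zeros(n)
    for c in circles:
        d2 = (xy[:, 0] - c.x) ** 2 + (xy[:, 1] - c.y) ** 2
        closer = d2 - c.r**2 < best_d2 - best_r**2  # nearest by signed margin
        best_d2 = np.where(closer, d2, best_d2)
        best_r = np.where(closer, c.r, best_r)
    return best_d2, best_r


def classify_points(
    section: SectionModel, xy: np.ndarray, rule: AssignmentRule
) -> np.ndarray:
    """Label an (N, 2) array of nm coordinates with compartment names.

    Every point inside the section rectangle receives exactly one label;
    points outside the cell (beyond the plasma-membrane band) are 'resin'.
    """
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    n = len(xy)
    labels = np.full(n, "resin", dtype=object)
    if n == 0:
        return labels
    x, y = xy[:, 0], xy[:, 1]
    in_outer = section.contains_outer(x, y)
    in_inner = section.contains_inner(x, y)
    # lowest priority first; later assignments overwrite earlier ones
    labels[in_outer] = "plasma_membrane"
    labels[in_inner] = "cytosol"

    h = rule.membrane_halfwidth_nm
    halo = rule.slmv_halo_nm

    if rule.mode == "solute":
        if section.mitochondria:
            d2, r = _circle_masks(xy, section.mitochondria)
            labels[d2 <= r**2] = "mitochondrion"
        if section.granules:
            d2, r = _circle_masks(xy, section.granules)
            labels[d2 <= r**2] = "granule"
    else:
        if section.mitochondria:
            d2, r = _circle_masks(xy, section.mitochondria)
            d = np.sqrt(d2)
            labels[d <= r - h] = "mito_matrix"
            labels[np.abs(d - r) <= h] = "mito_membrane"
        if section.granules:
            d2, r = _circle_masks(xy, section.granules)
            d = np.sqrt(d2)
            labels[d <= r - h] = "granule_core"
            labels[np.abs(d - r) <= h] = "granule_membrane"
    if section.slmvs:
        d2, r = _circle_masks(xy, section.slmvs)
        labels[d2 <= (r + halo) ** 2] = "slmv"
    return labels


def assign_particles(
    section: SectionModel,
    pattern: ParticlePattern,
    rule: AssignmentRule = AssignmentRule(),
) -> pd.DataFrame:
    """Assign each particle to exactly one compartment.

    Returns a frame with columns x, y, size_nm, compartment and (when the
    pattern carries it) the generator's provenance tag.  Raises
    ``ValueError`` for particles outside the section bounds.
    """
    xy = pattern.xy
    x0, y0, x1, y1 = section.rect
    if len(xy):
        out = (
            (xy[:, 0] < x0) | (xy[:, 0] > x1) | (xy[:, 1] < y0) | (xy[:, 1] > y1)
        )
        if np.any(out):
            raise ValueError(
                f"{int(out.sum())} particle(s) fall outside the section bounds"
            )
    labels = classify_points(section, xy, rule)
    return pd.DataFrame(
        {
            "x": xy[:, 0] if len(xy) else np.array([]),
            "y": xy[:, 1] if len(xy) else np.array([]),
            "size_nm": pattern.size_nm,
            "compartment": labels,
            "provenance": pattern.provenance,
        }
    )


# --------------------------------------------------------------------------
# stereological areas
# --------------------------------------------------------------------------


def estimate_areas(
    section: SectionModel,
    grid_spacing_nm: float = 20.0,
    rule: AssignmentRule = AssignmentRule(),
) -> dict[str, float]:
    """Point-grid area estimates (µm²) for every compartment.

    A regular square grid with the given spacing is laid over the section
    (offset half a spacing from the rectangle corner); each grid point is
    classified with the same rule as the particles and the compartment
    area is points × spacing².  Converges to the analytic area as the
    spacing shrinks, with error O(spacing).
    """
    if grid_spacing_nm <= 0:
        raise ValueError("grid spacing must be positive")
    x0, y0, x1, y1 = section.rect
    s = grid_spacing_nm
    gx = np.arange(x0 + s / 2.0, x1, s)
    gy = np.arange(y0 + s / 2.0, y1, s)
    XX, YY = np.meshgrid(gx, gy)
    pts = np.column_stack([XX.ravel(), YY.ravel()])
    labels = classify_points(section, pts, rule)
    areas: dict[str, float] = {}
    uniq, counts = np.unique(labels, return_counts=True)
    for lab, cnt in zip(uniq, counts):
        areas[str(lab)] = cnt * s**2 / 1e6
    # compartments present in the section but missed by the grid get 0
    for lab in section.analytic_areas(rule.mode):
        areas.setdefault(lab, 0.0)
    return areas


# --------------------------------------------------------------------------
# densities
# --------------------------------------------------------------------------


def compute_densities(
    assigned: pd.DataFrame,
    areas: Mapping[str, float],
    background: BackgroundModel,
    cell_id=0,
) -> pd.DataFrame:
    """Raw and background-corrected densities per compartment for one cell.

    net = raw − background for the compartment's background stream;
    negative nets are preserved and flagged (clipping would bias the
    estimator upward).  A compartment with particles but zero measured
    area is an error.
    """
    counts = assigned["compartment"].value_counts().to_dict()
    rows = []
    for lab, area in sorted(areas.items()):
        cnt = int(counts.pop(lab, 0))
        if area <= 0:
            if cnt > 0:
                raise ValueError(
                    f"compartment {lab!r} has {cnt} particles but zero area"
                )
            continue
        raw = cnt / area
        net = raw - background.rate_for(lab)
        rows.append(
            dict(
                cell_id=cell_id,
                compartment=lab,
                count=cnt,
                area_um2=area,
                raw_density=raw,
                net_density=net,
                negative_net=net < 0,
            )
        )
    if counts:
        raise ValueError(f"particles assigned to compartments with no area: {sorted(counts)}")
    return pd.DataFrame(rows)


def quantify_cell(
    section: SectionModel,
    pattern: ParticlePattern,
    background: BackgroundModel,
    rule: AssignmentRule = AssignmentRule(),
    grid_spacing_nm: float = 20.0,
    cell_id=0,
    analytic_areas: bool = False,
) -> pd.DataFrame:
    """Full single-cell pipeline: assign → areas → corrected densities."""
    assigned = assign_particles(section, pattern, rule)
    areas = (
        section.analytic_areas(rule.mode)
        if analytic_areas
        else estimate_areas(section, grid_spacing_nm, rule)
    )
    return compute_densities(assigned, areas, background, cell_id=cell_id)


# --------------------------------------------------------------------------
# ratios and group statistics
# --------------------------------------------------------------------------


def cell_ratios(
    table: pd.DataFrame,
    numerators: Sequence[str] = ("granule", "slmv"),
    denominator: str = "cytosol",
) -> pd.DataFrame:
    """Per-cell net-density ratios (e.g. granule/cytosol, SLMV/cytosol).

    Cells whose denominator net density is ≤ 0 are excluded with a
    warning (the ratio is undefined there).
    """
    wide = table.pivot_table(
        index="cell_id", columns="compartment", values="net_density"
    )
    rows = []
    for cell_id, row in wide.iterrows():
        den = row.get(denominator, np.nan)
        if not np.isfinite(den) or den <= 0:
            warnings.warn(
                f"cell {cell_id!r}: {denominator} net density {den!r} not positive; "
                "ratios undefined, cell excluded"
            )
            continue
        rec = {"cell_id": cell_id}
        for num in numerators:
            val = row.get(num, np.nan)
            rec[f"{num}_over_{denominator}"] = val / den if np.isfinite(val) else np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> dict:
    """Two-tailed Mann–Whitney U test; exact null for small samples.

    Uses the exact rank-permutation distribution whenever both groups
    have ≤ 20 observations and no ties span the groups, the normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    small = max(len(x), len(y)) <= 20
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if small and not ties else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return {
        "U": float(res.statistic),
        "p": float(min(res.pvalue, 1.0)),
        "method": method,
        "n1": len(x),
        "n2": len(y),
    }


def _summary(values: np.ndarray) -> dict:
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    n = len(values)
    sd = float(np.std(values, ddof=1)) if n > 1 else float("nan")
    return {
        "n": n,
        "mean": float(np.mean(values)) if n else float("nan"),
        "sd": sd,
        "sem": sd / math.sqrt(n) if n > 1 else float("nan"),
    }


def ratio_stats(
    tables: Mapping[str, pd.DataFrame],
    numerators: Sequence[str] = ("granule", "slmv"),
    denominator: str = "cytosol",
) -> dict:
    """Group summaries and pairwise Mann–Whitney comparisons.

    ``tables`` maps group name → long per-cell density table.  For each
    group, per-cell ratios are summarised (mean ± SD and SEM) both as
    mean-of-per-cell-ratios and as ratio-of-pooled-mean-densities (the two
    statistics differ and are reported side by side).  Pairwise two-tailed
    Mann–Whitney U tests compare per-cell ratios and per-cell compartment
    densities between groups.
    """
    groups: dict[str, dict] = {}
    ratio_frames: dict[str, pd.DataFrame] = {}
    for name, table in tables.items():
        ratios = cell_ratios(table, numerators, denominator)
        ratio_frames[name] = ratios
        ginfo: dict = {"ratios": {}, "densities": {}, "pooled_ratio": {}}
        wide = table.pivot_table(index="cell_id", columns="compartment", values="net_density")
        for num in numerators:
            col = f"{num}_over_{denominator}"
            if col in ratios:
                ginfo["ratios"][col] = _summary(ratios[col].to_numpy())
            if num in wide and denominator in wide:
                pooled = wide[num].mean() / wide[denominator].mean()
                ginfo["pooled_ratio"][col] = float(pooled)
        for comp in wide.columns:
            ginfo["densities"][comp] = _summary(wide[comp].to_numpy())
        groups[name] = ginfo
    tests: dict[str, dict] = {}
    names = list(tables)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pair: dict = {}
            for num in numerators:
                col = f"{num}_over_{denominator}"
                if col in ratio_frames[a] and col in ratio_frames[b]:
                    xa = ratio_frames[a][col].dropna()
                    xb = ratio_frames[b][col].dropna()
                    if len(xa) >= 2 and len(xb) >= 2:
                        pair[col] = mann_whitney(xa, xb)
            wa = tables[a].pivot_table(index="cell_id", columns="compartment", values="net_density")
            wb = tables[b].pivot_table(index="cell_id", columns="compartment", values="net_density")
            for comp in set(wa.columns) & set(wb.columns):
                if len(wa[comp].dropna()) >= 2 and len(wb[comp].dropna()) >= 2:
                    pair[f"net_{comp}"] = mann_whitney(wa[comp].dropna(), wb[comp].dropna())
            tests[f"{a}_vs_{b}"] = pair
    return {"groups": groups, "tests": tests, "per_cell_ratios": ratio_frames}


# --------------------------------------------------------------------------
# density → concentration calibration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear density-vs-concentration calibration with fit uncertainty.

    density = intercept + slope · concentration.  ``through_origin`` marks
    a fit with the intercept constrained to zero; inverse prediction of a
    density below the intercept is then undefined.
    """

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    cov_slope_intercept: float
    through_origin: bool
    n: int

    def predict_density(self, conc_mM: float) -> float:
        return self.intercept + self.slope * conc_mM


def calibrate_concentration(
    series: CalibrationSeries,
    through_origin: bool | None = None,
) -> CalibrationCurve:
    """Least-squares line through a calibration series.

    With ``through_origin=None`` the intercept is kept if it differs from
    zero by more than 2 standard errors, otherwise the through-origin fit
    is returned (both behaviours can be forced).  Raises on a singular
    design (fewer than 2 distinct concentrations).
    """
    import statsmodels.api as sm

    x = np.asarray(series.concentrations_mM, dtype=float)
    y = np.asarray(series.densities, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("singular design: need at least 2 distinct concentrations")

    def fit_free() -> CalibrationCurve:
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        cov = res.cov_params()
        return CalibrationCurve(
            slope=float(res.params[1]),
            intercept=float(res.params[0]),
            slope_se=float(res.bse[1]),
            intercept_se=float(res.bse[0]),
            cov_slope_intercept=float(cov[0, 1]),
            through_origin=False,
            n=len(x),
        )

    def fit_origin() -> CalibrationCurve:
        res = sm.OLS(y, x).fit()
        return CalibrationCurve(
            slope=float(res.params[0]),
            intercept=0.0,
            slope_se=float(res.bse[0]),
            intercept_se=0.0,
            cov_slope_intercept=0.0,
            through_origin=True,
            n=len(x),
        )

    if through_origin is True:
        return fit_origin()
    free = fit_free()
    if through_origin is False:
        return free
    if free.intercept_se > 0 and abs(free.intercept) < 2.0 * free.intercept_se:
        return fit_origin()
    return free


def estimate_mM(curve: CalibrationCurve, net_density: float) -> tuple[float, float]:
    """Inverse prediction: concentration (mM) and its delta-method SE."""
    if curve.slope == 0:
        raise ValueError("calibration slope is zero; inverse undefined")
    if curve.through_origin and net_density < curve.intercept:
        raise ValueError(
            "density below the intercept; inverse of a through-origin fit undefined"
        )
    c = (net_density - curve.intercept) / curve.slope
    # var(c) ≈ (var_b + c² var_m + 2 c cov_bm) / m²
    var = (
        curve.intercept_se**2
        + c**2 * curve.slope_se**2
        + 2.0 * c * curve.cov_slope_intercept
    ) / curve.slope**2
    return c, math.sqrt(max(var, 0.0))


def anchored_curve(net_density: float, conc_mM: float) -> CalibrationCurve:
    """Through-origin curve pinned to one (density, concentration) anchor.

    Used to read other compartments' densities in mM relative to a
    compartment of assumed concentration.
    """
    if net_density <= 0 or conc_mM <= 0:
        raise ValueError("anchor density and concentration must be positive")
    return CalibrationCurve(
        slope=net_density / conc_mM,
        intercept=0.0,
        slope_se=0.0,
        intercept_se=0.0,
        cov_slope_intercept=0.0,
        through_origin=True,
        n=1,
    )
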