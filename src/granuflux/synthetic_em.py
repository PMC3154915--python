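"""Synthetic ultrathin-section generator for immunogold quantification.

Emulates the data structure of a quantitative immunogold experiment on
pancreatic islet cells: an irregular cell profile containing dense-core
secretory granules (core + 60 nm limiting-membrane band), synaptic-like
microvesicles (SLMVs, ~40 nm), mitochondria (background reference), the
plasma-membrane trace and cytosol, surrounded by empty resin.  Gold
particles are laid down as independent homogeneous Poisson processes, one
per compartment at its true net labelling intensity, superposed with a
uniform background process over the whole section — the sampling model
implicitly assumed by density-based immunogold statistics.

Every particle carries its generating compartment as a provenance tag so
the assignment rule of the quantification pipeline can be scored against
ground truth.  All geometry is in nm; intensities are particles/µm².

Antigen classes
---------------
``solute`` antigens (fixed amino acids such as glutamate) label compartment
interiors: the full granule profile, the SLMV including its 30 nm halo
(the region the counting rule also measures), mitochondria, cytosol.
``membrane`` antigens (transporter proteins) label 60 nm bands straddling
membrane traces, plus granule cores and cytosol.  In both classes the
region particles are generated over is exactly the region the pipeline's
rule measures, so recovered net densities are unbiased for the specified
intensities.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

__all__ = [
    "Circle",
    "SectionModel",
    "LabelSpec",
    "ParticlePattern",
    "CalibrationSeries",
    "EMPreset",
    "PRESETS",
    "PAPER_BACKGROUNDS",
    "generate_geometry",
    "generate_particles",
    "generate_calibration",
    "generate_cell",
    "section_to_dict",
    "section_from_dict",
    "pattern_to_dict",
    "pattern_from_dict",
    "save_section_json",
    "load_section_json",
]

NM2_PER_UM2 = 1e6


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Circle:
    """A circular compartment profile: centre (nm) and radius (nm)."""

    x: float
    y: float
    r: float

    def area_um2(self) -> float:
        return math.pi * self.r**2 / NM2_PER_UM2


@dataclass
class SectionModel:
    """Synthetic 2-D ultrastructure for one cell profile.

    ``boundary`` is the plasma-membrane trace (closed shapely polygon).
    Granule circles give the outer radius of the limiting membrane; the
    membrane band is ±``membrane_halfwidth_nm`` around that trace and the
    core is the interior disc.  Compartments are packed so that no two
    bands or halos overlap.
    """

    cell_type: str
    condition: str
    boundary: Polygon
    granules: list[Circle]
    slmvs: list[Circle]
    mitochondria: list[Circle]
    membrane_halfwidth_nm: float = 30.0
    slmv_halo_nm: float = 30.0
    margin_nm: float = 400.0

    def __post_init__(self) -> None:
        h = self.membrane_halfwidth_nm
        self._inner = self.boundary.buffer(-h)
        self._outer = self.boundary.buffer(+h)
        self._prep_inner = prep(self._inner)
        self._prep_outer = prep(self._outer)

    # -- geometry queries -------------------------------------------------

    @property
    def rect(self) -> tuple[float, float, float, float]:
        """Section bounding rectangle including the resin margin (nm)."""
        x0, y0, x1, y1 = self.boundary.bounds
        m = self.margin_nm
        return (x0 - m, y0 - m, x1 + m, y1 + m)

    @property
    def rect_area_um2(self) -> float:
        x0, y0, x1, y1 = self.rect
        return (x1 - x0) * (y1 - y0) / NM2_PER_UM2

    @property
    def pm_band_area_um2(self) -> float:
        return (self._outer.area - self._inner.area) / NM2_PER_UM2

    def analytic_areas(self, mode: str = "solute") -> dict[str, float]:
        """Exact per-compartment areas (µm²) for the given antigen class.

        These are the oracle values the grid-point estimator converges to.
        """
        h = self.membrane_halfwidth_nm
        halo = self.slmv_halo_nm
        slmv = sum(math.pi * (c.r + halo) ** 2 for c in self.slmvs) / NM2_PER_UM2
        pm = self.pm_band_area_um2
        if mode == "solute":
            gran = sum(math.pi * c.r**2 for c in self.granules) / NM2_PER_UM2
            mito = sum(math.pi * c.r**2 for c in self.mitochondria) / NM2_PER_UM2
            excl = (
                sum(math.pi * c.r**2 for c in self.granules)
                + sum(math.pi * (c.r + halo) ** 2 for c in self.slmvs)
                + sum(math.pi * c.r**2 for c in self.mitochondria)
            ) / NM2_PER_UM2
            cyto = self._inner.area / NM2_PER_UM2 - excl
            areas = {
                "granule": gran,
                "slmv": slmv,
                "mitochondrion": mito,
                "plasma_membrane": pm,
                "cytosol": cyto,
            }
        elif mode == "membrane":
            core = sum(math.pi * max(c.r - h, 0.0) ** 2 for c in self.granules) / NM2_PER_UM2
            band = sum(
                math.pi * ((c.r + h) ** 2 - max(c.r - h, 0.0) ** 2) for c in self.granules
            ) / NM2_PER_UM2
            matrix = sum(math.pi * max(c.r - h, 0.0) ** 2 for c in self.mitochondria) / NM2_PER_UM2
            mito_mem = sum(
                math.pi * ((c.r + h) ** 2 - max(c.r - h, 0.0) ** 2) for c in self.mitochondria
            ) / NM2_PER_UM2
            excl = (
                sum(math.pi * (c.r + h) ** 2 for c in self.granules)
                + sum(math.pi * (c.r + halo) ** 2 for c in self.slmvs)
                + sum(math.pi * (c.r + h) ** 2 for c in self.mitochondria)
            ) / NM2_PER_UM2
            cyto = self._inner.area / NM2_PER_UM2 - excl
            areas = {
                "granule_core": core,
                "granule_membrane": band,
                "slmv": slmv,
                "mito_matrix": matrix,
                "mito_membrane": mito_mem,
                "plasma_membrane": pm,
                "cytosol": cyto,
            }
        else:
            raise ValueError(f"unknown antigen mode {mode!r}")
        x0, y0, x1, y1 = self.rect
        areas["resin"] = (x1 - x0) * (y1 - y0) / NM2_PER_UM2 - self._outer.area / NM2_PER_UM2
        return areas

    def contains_inner(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        import shapely

        return shapely.contains_xy(self._inner, x, y)

    def contains_outer(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        import shapely

        return shapely.contains_xy(self._outer, x, y)


@dataclass(frozen=True)
class LabelSpec:
    """Specification of one immunogold labelling experiment.

    ``intensities`` maps compartment role to true net labelling intensity
    (particles/µm² above background); ``background`` is the uniform
    section-wide background intensity.  The seed fully determines the
    generated pattern.
    """

    antigen: str = "glutamate"
    mode: str = "solute"  # 'solute' | 'membrane'
    intensities: Mapping[str, float] = field(default_factory=dict)
    background: float = 1.7
    gold_size_nm: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background < 0:
            raise ValueError("background intensity must be non-negative")
        for k, v in self.intensities.items():
            if v < 0:
                raise ValueError(f"intensity for {k!r} must be non-negative")


@dataclass
class ParticlePattern:
    """Gold-particle coordinates (nm) with provenance tags.

    ``provenance`` records the compartment each particle was generated
    from ('background' for the uniform stream) — for oracle tests only;
    the quantification pipeline never reads it.
    """

    xy: np.ndarray  # (N, 2) float, nm
    size_nm: np.ndarray  # (N,) float
    provenance: np.ndarray  # (N,) str

    def __len__(self) -> int:
        return len(self.xy)


# --------------------------------------------------------------------------
# geometry generation
# --------------------------------------------------------------------------


def _blob_polygon(rng: np.random.Generator, area_um2: float, n_vertices: int = 128) -> Polygon:
    """Irregular smooth cell outline with exactly the requested area."""
    R0 = math.sqrt(area_um2 * NM2_PER_UM2 / math.pi)
    theta = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    r = np.full(n_vertices, 1.0)
    for k in range(2, 6):
        amp = rng.uniform(-0.05, 0.05) / (k - 1)
        phase = rng.uniform(0, 2 * math.pi)
        r += amp * np.cos(k * theta + phase)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)]) * R0
    poly = Polygon(pts)
    scale = math.sqrt(area_um2 * NM2_PER_UM2 / poly.area)
    return Polygon(pts * scale)


def generate_geometry(
    cell_type: str = "beta",
    n_granules: int = 30,
    n_slmv: int = 20,
    n_mito: int = 4,
    seed=0,
    condition: str = "rat",
    profile_area_um2: float = 25.0,
    granule_diam_nm: tuple[float, float] = (250.0, 350.0),
    slmv_diam_nm: tuple[float, float] = (35.0, 45.0),
    mito_diam_nm: tuple[float, float] = (500.0, 700.0),
    clearance_nm: float = 80.0,
    boundary_clearance_nm: float = 120.0,
    max_tries: int = 4000,
) -> SectionModel:
    """Reproducibly pack one synthetic cell profile.

    Objects are placed by rejection sampling with pairwise clearance
    ``clearance_nm`` (edge to edge) and clearance from the plasma-membrane
    trace, so that membrane bands and SLMV halos never overlap and every
    point of the profile belongs to exactly one areal compartment.  Raises
    ``RuntimeError`` if the packing is infeasible within ``max_tries``
    candidate draws per object.
    """
    if min(n_granules, n_slmv, n_mito) < 0:
        raise ValueError("object counts must be non-negative")
    rng = _rng(seed)
    boundary = _blob_polygon(rng, profile_area_um2)
    x0, y0, x1, y1 = boundary.bounds
    placed: list[Circle] = []

    def place(n: int, diam: tuple[float, float]) -> list[Circle]:
        out = []
        ring = boundary.exterior
        for _ in range(n):
            r_obj = rng.uniform(*diam) / 2.0
            for attempt in range(max_tries):
                x = rng.uniform(x0, x1)
                y = rng.uniform(y0, y1)
                p = Point(x, y)
                if not boundary.contains(p):
                    continue
                if ring.distance(p) < r_obj + boundary_clearance_nm:
                    continue
                ok = True
                for c in placed + out:
                    if math.hypot(x - c.x, y - c.y) < r_obj + c.r + clearance_nm:
                        ok = False
                        break
                if ok:
                    out.append(Circle(x, y, r_obj))
                    break
            else:
                raise RuntimeError(
                    f"could not place object of radius {r_obj:.0f} nm after {max_tries} tries; "
                    "reduce object counts or enlarge the profile"
                )
        return out

    mitochondria = place(n_mito, mito_diam_nm)
    placed += mitochondria
    granules = place(n_granules, granule_diam_nm)
    placed += granules
    slmvs = place(n_slmv, slmv_diam_nm)
    return SectionModel(
        cell_type=cell_type,
        condition=condition,
        boundary=boundary,
        granules=granules,
        slmvs=slmvs,
        mitochondria=mitochondria,
    )


# --------------------------------------------------------------------------
# particle generation
# --------------------------------------------------------------------------


def _sample_disc(rng: np.random.Generator, cx: float, cy: float, r: float, n: int) -> np.ndarray:
    u = rng.uniform(0.0, 1.0, n)
    rad = r * np.sqrt(u)
    th = rng.uniform(0.0, 2.0 * math.pi, n)
    return np.column_stack([cx + rad * np.cos(th), cy + rad * np.sin(th)])


def _sample_annulus(
    rng: np.random.Generator, cx: float, cy: float, r0: float, r1: float, n: int
) -> np.ndarray:
    u = rng.uniform(0.0, 1.0, n)
    rad = np.sqrt(r0**2 + u * (r1**2 - r0**2))
    th = rng.uniform(0.0, 2.0 * math.pi, n)
    return np.column_stack([cx + rad * np.cos(th), cy + rad * np.sin(th)])


def _sample_pm_band(section: SectionModel, rng: np.random.Generator, n: int) -> np.ndarray:
    """Points within ±halfwidth of the plasma-membrane trace."""
    ring = section.boundary.exterior
    h = section.membrane_halfwidth_nm
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(2 * (n - len(out)), 16)
        s = rng.uniform(0.0, ring.length, m)
        pts = np.array([ring.interpolate(si).coords[0] for si in s])
        # local tangent by finite difference along the ring
        eps = 1.0
        pts2 = np.array([ring.interpolate((si + eps) % ring.length).coords[0] for si in s])
        tang = pts2 - pts
        norm = np.column_stack([-tang[:, 1], tang[:, 0]])
        norm /= np.linalg.norm(norm, axis=1, keepdims=True)
        off = rng.uniform(-h, h, m)[:, None]
        cand = pts + off * norm
        # keep points actually inside the band (corners of an irregular
        # outline can push offsets outside)
        keep = np.abs(off[:, 0]) <= h
        out = np.vstack([out, cand[keep]])
    return out[:n]


def _cytosol_exclusion_circles(section: SectionModel, mode: str) -> list[Circle]:
    h = section.membrane_halfwidth_nm
    halo = section.slmv_halo_nm
    if mode == "solute":
        grans = section.granules
        mitos = section.mitochondria
    else:
        grans = [replace(c, r=c.r + h) for c in section.granules]
        mitos = [replace(c, r=c.r + h) for c in section.mitochondria]
    slmvs = [replace(c, r=c.r + halo) for c in section.slmvs]
    return list(grans) + slmvs + list(mitos)


def _sample_cytosol(
    section: SectionModel, rng: np.random.Generator, n: int, mode: str
) -> np.ndarray:
    """Rejection sampling of the cytosolic remainder of the profile."""
    excl = _cytosol_exclusion_circles(section, mode)
    cx = np.array([c.x for c in excl])
    cy = np.array([c.y for c in excl])
    cr2 = np.array([c.r**2 for c in excl])
    x0, y0, x1, y1 = section.boundary.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(3 * (n - len(out)), 32)
        xs = rng.uniform(x0, x1, m)
        ys = rng.uniform(y0, y1, m)
        keep = section.contains_inner(xs, ys)
        if cr2.size:
            d2 = (xs[:, None] - cx) ** 2 + (ys[:, None] - cy) ** 2
            keep &= ~np.any(d2 <= cr2, axis=1)
        out = np.vstack([out, np.column_stack([xs, ys])[keep]])
    return out[:n]


def generate_particles(section: SectionModel, spec: LabelSpec) -> ParticlePattern:
    """Superpose per-compartment Poisson labelling and uniform background.

    The particle count of each compartment is Poisson with mean
    intensity × measured area, points uniform within the compartment's
    labelling region; the background stream is uniform over the whole
    section rectangle at ``spec.background``.
    """
    rng = _rng(spec.seed)
    h = section.membrane_halfwidth_nm
    halo = section.slmv_halo_nm
    chunks: list[np.ndarray] = []
    tags: list[str] = []

    def add(points: np.ndarray, tag: str) -> None:
        if len(points):
            chunks.append(points)
            tags.extend([tag] * len(points))

    inten = dict(spec.intensities)

    def npois(area_um2: float, rate: float) -> int:
        return int(rng.poisson(rate * area_um2)) if rate > 0 and area_um2 > 0 else 0

    if spec.mode == "solute":
        for c in section.granules:
            add(_sample_disc(rng, c.x, c.y, c.r, npois(c.area_um2(), inten.get("granule", 0.0))), "granule")
        for c in section.slmvs:
            a = math.pi * (c.r + halo) ** 2 / NM2_PER_UM2
            add(_sample_disc(rng, c.x, c.y, c.r + halo, npois(a, inten.get("slmv", 0.0))), "slmv")
        for c in section.mitochondria:
            add(_sample_disc(rng, c.x, c.y, c.r, npois(c.area_um2(), inten.get("mitochondrion", 0.0))), "mitochondrion")
        n_pm = npois(section.pm_band_area_um2, inten.get("plasma_membrane", 0.0))
        add(_sample_pm_band(section, rng, n_pm), "plasma_membrane")
        a_cyto = section.analytic_areas("solute")["cytosol"]
        add(_sample_cytosol(section, rng, npois(a_cyto, inten.get("cytosol", 0.0)), "solute"), "cytosol")
    elif spec.mode == "membrane":
        for c in section.granules:
            core_r = max(c.r - h, 0.0)
            a_core = math.pi * core_r**2 / NM2_PER_UM2
            a_band = math.pi * ((c.r + h) ** 2 - core_r**2) / NM2_PER_UM2
            add(_sample_disc(rng, c.x, c.y, core_r, npois(a_core, inten.get("granule_core", 0.0))), "granule_core")
            add(_sample_annulus(rng, c.x, c.y, core_r, c.r + h, npois(a_band, inten.get("granule_membrane", 0.0))), "granule_membrane")
        for c in section.slmvs:
            a = math.pi * (c.r + halo) ** 2 / NM2_PER_UM2
            add(_sample_disc(rng, c.x, c.y, c.r + halo, npois(a, inten.get("slmv", 0.0))), "slmv")
        for c in section.mitochondria:
            mr = max(c.r - h, 0.0)
            a_mat = math.pi * mr**2 / NM2_PER_UM2
            a_mem = math.pi * ((c.r + h) ** 2 - mr**2) / NM2_PER_UM2
            add(_sample_disc(rng, c.x, c.y, mr, npois(a_mat, inten.get("mito_matrix", 0.0))), "mito_matrix")
            add(_sample_annulus(rng, c.x, c.y, mr, c.r + h, npois(a_mem, inten.get("mito_membrane", 0.0))), "mito_membrane")
        n_pm = npois(section.pm_band_area_um2, inten.get("plasma_membrane", 0.0))
        add(_sample_pm_band(section, rng, n_pm), "plasma_membrane")
        a_cyto = section.analytic_areas("membrane")["cytosol"]
        add(_sample_cytosol(section, rng, npois(a_cyto, inten.get("cytosol", 0.0)), "membrane"), "cytosol")
    else:
        raise ValueError(f"unknown antigen mode {spec.mode!r}")

    # uniform background over the full section rectangle
    x0, y0, x1, y1 = section.rect
    n_bg = npois(section.rect_area_um2, spec.background)
    bg = np.column_stack([rng.uniform(x0, x1, n_bg), rng.uniform(y0, y1, n_bg)])
    add(bg, "background")

    xy = np.vstack(chunks) if chunks else np.empty((0, 2))
    return ParticlePattern(
        xy=xy,
        size_nm=np.full(len(xy), spec.gold_size_nm),
        provenance=np.array(tags, dtype=object),
    )


# --------------------------------------------------------------------------
# calibration test sections
# --------------------------------------------------------------------------


@dataclass
class CalibrationSeries:
    """Test sections with known fixed amino-acid concentrations.

    Observed densities are Poisson counts over ``area_um2`` around the
    linear model density = intercept + slope · concentration.
    """

    concentrations_mM: np.ndarray
    densities: np.ndarray  # observed particles/µm²
    counts: np.ndarray
    area_um2: float
    slope_true: float
    intercept_true: float

    def expected_density(self, conc_mM: float) -> float:
        return self.intercept_true + self.slope_true * conc_mM


def generate_calibration(
    concentrations_mM: Sequence[float],
    slope: float = 10.0,
    intercept: float = 0.0,
    area_um2: float = 4.0,
    seed=0,
) -> CalibrationSeries:
    """Poisson-noisy calibration series around a linear density model."""
    conc = np.asarray(list(concentrations_mM), dtype=float)
    if len(np.unique(conc)) < 2:
        raise ValueError("need at least 2 distinct calibration concentrations")
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    rng = _rng(seed)
    lam = (intercept + slope * conc) * area_um2
    counts = rng.poisson(np.maximum(lam, 0.0))
    return CalibrationSeries(
        concentrations_mM=conc,
        densities=counts / area_um2,
        counts=counts,
        area_um2=area_um2,
        slope_true=slope,
        intercept_true=intercept,
    )


# --------------------------------------------------------------------------
# presets encoding the printed study conditions
# --------------------------------------------------------------------------

#: Published background labelling rates (particles/µm²): membrane-protein
#: backgrounds over mitochondrial outer membranes / matrix, amino-acid
#: background over empty resin.
PAPER_BACKGROUNDS = {
    "EAAT2": {"membrane": 3.7, "matrix": 4.9},
    "VGLUT3": {"membrane": 1.3, "matrix": 2.7},
    "glutamate": {"resin": 1.7},
    "D-aspartate": {"resin": 1.7},
}


@dataclass(frozen=True)
class EMPreset:
    """One study condition: geometry defaults plus true net intensities."""

    name: str
    cell_type: str
    condition: str
    antigen: str
    mode: str
    intensities: Mapping[str, float]
    background: float
    n_cells: int = 5
    n_animals: int | None = None
    n_granules: int = 30
    n_slmv: int = 20
    n_mito: int = 4
    profile_area_um2: float = 25.0

    def label_spec(self, seed) -> LabelSpec:
        return LabelSpec(
            antigen=self.antigen,
            mode=self.mode,
            intensities=dict(self.intensities),
            background=self.background,
            seed=seed,
        )

    def geometry_kwargs(self) -> dict:
        return dict(
            cell_type=self.cell_type,
            condition=self.condition,
            n_granules=self.n_granules,
            n_slmv=self.n_slmv,
            n_mito=self.n_mito,
            profile_area_um2=self.profile_area_um2,
        )


PRESETS: dict[str, EMPreset] = {
    # Rat alpha/beta glutamate: net granule and cytosol densities as
    # printed for 5 cells of each kind; SLMV intensity chosen well above
    # both (the SLMV/cytosol ratio is reported only as "much higher").
    "rat_alpha": EMPreset(
        name="rat_alpha",
        cell_type="alpha",
        condition="rat",
        antigen="glutamate",
        mode="solute",
        intensities={"granule": 33.6, "cytosol": 21.1, "slmv": 100.0},
        background=1.7,
    ),
    "rat_beta": EMPreset(
        name="rat_beta",
        cell_type="beta",
        condition="rat",
        antigen="glutamate",
        mode="solute",
        intensities={"granule": 19.7, "cytosol": 30.2, "slmv": 100.0},
        background=1.7,
    ),
    # Mouse wild-type / EAAT2-knockout glutamate (4 animals each; ~45
    # granules per animal as in the published 119/179-granule samples).
    "mouse_wt": EMPreset(
        name="mouse_wt",
        cell_type="beta",
        condition="mouse_wt",
        antigen="glutamate",
        mode="solute",
        intensities={"granule": 9.0, "cytosol": 12.2, "slmv": 60.0},
        background=1.7,
        n_cells=5,
        n_animals=4,
        n_granules=9,
        n_slmv=12,
        n_mito=3,
        profile_area_um2=12.0,
    ),
    "mouse_ko": EMPreset(
        name="mouse_ko",
        cell_type="beta",
        condition="mouse_ko",
        antigen="glutamate",
        mode="solute",
        intensities={"granule": 17.7, "cytosol": 10.5, "slmv": 60.0},
        background=1.7,
        n_cells=5,
        n_animals=4,
        n_granules=9,
        n_slmv=12,
        n_mito=3,
        profile_area_um2=12.0,
    ),
}


def generate_cell(preset: EMPreset | str, seed) -> tuple[SectionModel, ParticlePattern]:
    """Generate one cell profile and its gold pattern for a preset."""
    if isinstance(preset, str):
        preset = PRESETS[preset]
    ss = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    geo_seed, part_seed = ss.spawn(2)
    section = generate_geometry(seed=np.random.default_rng(geo_seed), **preset.geometry_kwargs())
    pattern = generate_particles(section, replace_seed(preset.label_spec(0), np.random.default_rng(part_seed)))
    return section, pattern


def replace_seed(spec: LabelSpec, seed) -> LabelSpec:
    return LabelSpec(
        antigen=spec.antigen,
        mode=spec.mode,
        intensities=dict(spec.intensities),
        background=spec.background,
        gold_size_nm=spec.gold_size_nm,
        seed=seed,
    )


# --------------------------------------------------------------------------
# serialization (plain JSON, nm coordinates)
# --------------------------------------------------------------------------


def section_to_dict(section: SectionModel) -> dict:
    return {
        "cell_type": section.cell_type,
        "condition": section.condition,
        "boundary_nm": [list(p) for p in section.boundary.exterior.coords],
        "granules": [[c.x, c.y, c.r] for c in section.granules],
        "slmvs": [[c.x, c.y, c.r] for c in section.slmvs],
        "mitochondria": [[c.x, c.y, c.r] for c in section.mitochondria],
        "membrane_halfwidth_nm": section.membrane_halfwidth_nm,
        "slmv_halo_nm": section.slmv_halo_nm,
        "margin_nm": section.margin_nm,
    }


def section_from_dict(d: Mapping) -> SectionModel:
    return SectionModel(
        cell_type=d["cell_type"],
        condition=d["condition"],
        boundary=Polygon(d["boundary_nm"]),
        granules=[Circle(*c) for c in d["granules"]],
        slmvs=[Circle(*c) for c in d["slmvs"]],
        mitochondria=[Circle(*c) for c in d["mitochondria"]],
        membrane_halfwidth_nm=d.get("membrane_halfwidth_nm", 30.0),
        slmv_halo_nm=d.get("slmv_halo_nm", 30.0),
        margin_nm=d.get("margin_nm", 400.0),
    )


def pattern_to_dict(pattern: ParticlePattern) -> dict:
    return {
        "xy_nm": pattern.xy.tolist(),
        "size_nm": pattern.size_nm.tolist(),
        "provenance": pattern.provenance.tolist(),
    }


def pattern_from_dict(d: Mapping) -> ParticlePattern:
    xy = np.asarray(d["xy_nm"], dtype=float).reshape(-1, 2)
    return ParticlePattern(
        xy=xy,
        size_nm=np.asarray(d["size_nm"], dtype=float),
        provenance=np.asarray(d["provenance"], dtype=object),
    )


def save_section_json(path, section: SectionModel, pattern: ParticlePattern, meta: Mapping | None = None) -> None:
    doc = {"section": section_to_dict(section), "particles": pattern_to_dict(pattern)}
    if meta:
        doc["meta"] = dict(meta)
    Path(path).write_text(json.dumps(doc))


def load_section_json(path) -> tuple[SectionModel, ParticlePattern, dict]:
    doc = json.loads(Path(path).read_text())
    return (
        section_from_dict(doc["section"]),
        pattern_from_dict(doc["particles"]),
        doc.get("meta", {}),
    )
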