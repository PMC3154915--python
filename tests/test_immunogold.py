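"""Tests of the quantification pipeline: assignment, areas, densities,
statistics and calibration."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from granuflux.immunogold import (
    AssignmentRule,
    BackgroundModel,
    anchored_curve,
    assign_particles,
    calibrate_concentration,
    cell_ratios,
    classify_points,
    compute_densities,
    estimate_areas,
    estimate_mM,
    mann_whitney,
    quantify_cell,
    ratio_stats,
)
from granuflux.synthetic_em import (
    PRESETS,
    CalibrationSeries,
    LabelSpec,
    ParticlePattern,
    generate_geometry,
    generate_particles,
)


class TestAssignmentRule:
    def test_particle_at_granule_centre(self, toy_section):
        labels = classify_points(toy_section, np.array([[0.0, 0.0]]), AssignmentRule())
        assert labels[0] == "granule"

    def test_slmv_halo_is_30nm_inclusive(self, toy_section):
        # SLMV at (1500, 0) with r = 20; outer border at x = 1520
        rule = AssignmentRule()
        at_29 = classify_points(toy_section, np.array([[1549.0, 0.0]]), rule)
        at_30 = classify_points(toy_section, np.array([[1550.0, 0.0]]), rule)
        at_31 = classify_points(toy_section, np.array([[1551.0, 0.0]]), rule)
        assert at_29[0] == "slmv"
        assert at_30[0] == "slmv"  # boundary inclusive
        assert at_31[0] == "cytosol"

    def test_membrane_band_rule_30nm_either_side(self, toy_section):
        rule = AssignmentRule(mode="membrane")
        # granule membrane trace at r = 150
        inside_band = classify_points(toy_section, np.array([[121.0, 0.0]]), rule)
        outside_band = classify_points(toy_section, np.array([[181.0, 0.0]]), rule)
        core = classify_points(toy_section, np.array([[119.0, 0.0]]), rule)
        assert inside_band[0] == "granule_membrane"
        assert outside_band[0] == "cytosol"
        assert core[0] == "granule_core"

    def test_plasma_membrane_band(self, toy_section):
        rule = AssignmentRule()
        # cell boundary at x = 3000
        assert classify_points(toy_section, np.array([[2980.0, 0.0]]), rule)[0] == "plasma_membrane"
        assert classify_points(toy_section, np.array([[3029.0, 0.0]]), rule)[0] == "plasma_membrane"
        assert classify_points(toy_section, np.array([[3100.0, 0.0]]), rule)[0] == "resin"

    def test_slmv_halo_takes_precedence_over_membrane_band(self):
        """When an SLMV sits against a granule membrane, a particle in the
        overlap of halo and band belongs to the SLMV."""
        from granuflux.synthetic_em import Circle, SectionModel
        from shapely.geometry import Polygon

        h = 3000.0
        sec = SectionModel(
            cell_type="beta",
            condition="rat",
            boundary=Polygon([(-h, -h), (h, -h), (h, h), (-h, h)]),
            granules=[Circle(0.0, 0.0, 150.0)],
            slmvs=[Circle(200.0, 0.0, 20.0)],
            mitochondria=[],
        )
        rule = AssignmentRule(mode="membrane")
        # (175, 0): 25 nm outside the granule trace (in its band) and
        # 5 nm from the SLMV border (in its halo)
        assert classify_points(sec, np.array([[175.0, 0.0]]), rule)[0] == "slmv"

    def test_particles_outside_section_rejected(self, toy_section):
        pat = ParticlePattern(
            xy=np.array([[1e6, 1e6]]),
            size_nm=np.array([15.0]),
            provenance=np.array(["background"], dtype=object),
        )
        with pytest.raises(ValueError, match="outside the section"):
            assign_particles(toy_section, pat, AssignmentRule())

    def test_assignment_matches_provenance_without_background(self):
        """Oracle equivalence: with no background stream, the rule must
        recover the generating compartment for ≥ 99 % of particles."""
        preset = PRESETS["rat_beta"]
        sec = generate_geometry(seed=21, **preset.geometry_kwargs())
        spec = LabelSpec(
            antigen="glutamate",
            mode="solute",
            intensities=dict(preset.intensities),
            background=0.0,
            seed=21,
        )
        pat = generate_particles(sec, spec)
        assigned = assign_particles(sec, pat, AssignmentRule())
        acc = np.mean(assigned["compartment"].to_numpy() == assigned["provenance"].to_numpy())
        assert acc >= 0.99


class TestAreas:
    def test_grid_estimate_within_2pct_at_10nm(self):
        sec = generate_geometry(
            n_granules=1, n_slmv=0, n_mito=0, seed=3, profile_area_um2=4.0,
            granule_diam_nm=(600.0, 600.0),
        )
        est = estimate_areas(sec, 10.0)["granule"]
        exact = math.pi * 0.3**2
        assert abs(est - exact) / exact < 0.02

    def test_error_shrinks_with_spacing(self):
        sec = generate_geometry(
            n_granules=1, n_slmv=0, n_mito=0, seed=3, profile_area_um2=4.0,
            granule_diam_nm=(600.0, 600.0),
        )
        exact = math.pi * 0.3**2
        errs = [abs(estimate_areas(sec, s)["granule"] - exact) / exact for s in (80.0, 40.0, 10.0)]
        assert errs[2] < errs[0]

    def test_total_grid_area_partitions_the_section(self):
        sec = generate_geometry(seed=5)
        areas = estimate_areas(sec, 40.0)
        x0, y0, x1, y1 = sec.rect
        assert sum(areas.values()) == pytest.approx((x1 - x0) * (y1 - y0) / 1e6, rel=0.01)

    def test_invalid_spacing_rejected(self, toy_section):
        with pytest.raises(ValueError):
            estimate_areas(toy_section, 0.0)


class TestDensities:
    BG = BackgroundModel(resin=1.7, antigen_class="solute")

    def _assigned(self, counts: dict) -> pd.DataFrame:
        rows = []
        for comp, n in counts.items():
            rows += [{"x": 0.0, "y": 0.0, "size_nm": 15.0, "compartment": comp, "provenance": comp}] * n
        return pd.DataFrame(rows, columns=["x", "y", "size_nm", "compartment", "provenance"])

    def test_resin_background_subtraction(self):
        # 107 particles over 5 µm² = 21.4/µm² raw → 19.7 net after the
        # 1.7/µm² empty-resin correction
        table = compute_densities(self._assigned({"granule": 107}), {"granule": 5.0}, self.BG)
        row = table.set_index("compartment").loc["granule"]
        assert row["raw_density"] == pytest.approx(21.4)
        assert row["net_density"] == pytest.approx(19.7)
        assert not row["negative_net"]

    def test_zero_counts_preserve_negative_net_with_flag(self):
        table = compute_densities(self._assigned({}), {"cytosol": 2.0}, self.BG)
        row = table.set_index("compartment").loc["cytosol"]
        assert row["net_density"] == pytest.approx(-1.7)
        assert bool(row["negative_net"])

    def test_zero_area_with_counts_is_an_error(self):
        with pytest.raises(ValueError, match="zero area"):
            compute_densities(self._assigned({"granule": 3}), {"granule": 0.0}, self.BG)

    def test_membrane_class_uses_membrane_background(self):
        bg = BackgroundModel(membrane=3.7, matrix=4.9, antigen_class="membrane")
        table = compute_densities(
            self._assigned({"granule_membrane": 10, "granule_core": 10}),
            {"granule_membrane": 1.0, "granule_core": 1.0},
            bg,
        )
        t = table.set_index("compartment")
        assert t.loc["granule_membrane", "net_density"] == pytest.approx(10 - 3.7)
        assert t.loc["granule_core", "net_density"] == pytest.approx(10 - 4.9)

    def test_full_pipeline_beta_preset_orders_granule_below_cytosol(self):
        preset = PRESETS["rat_beta"]
        sec = generate_geometry(seed=30, **preset.geometry_kwargs())
        pat = generate_particles(sec, preset.label_spec(30))
        table = quantify_cell(sec, pat, self.BG, grid_spacing_nm=20.0)
        t = table.set_index("compartment")
        assert t.loc["granule", "net_density"] < t.loc["cytosol", "net_density"]
        assert t.loc["slmv", "net_density"] > t.loc["granule", "net_density"]


class TestGroupStats:
    def test_identical_groups_p_is_one(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res["p"] == pytest.approx(1.0)

    def test_fully_separated_4v4_exact_p(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [5.0, 6.0, 7.0, 8.0])
        assert res["method"] == "exact"
        assert res["p"] == pytest.approx(2.0 / 70.0, rel=1e-12)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([1.0], [2.0, 3.0])

    def test_nonpositive_cytosol_excluded_with_warning(self):
        table = pd.DataFrame(
            [
                {"cell_id": 0, "compartment": "granule", "net_density": 5.0},
                {"cell_id": 0, "compartment": "cytosol", "net_density": -0.2},
                {"cell_id": 1, "compartment": "granule", "net_density": 6.0},
                {"cell_id": 1, "compartment": "cytosol", "net_density": 10.0},
            ]
        )
        with pytest.warns(UserWarning, match="not positive"):
            ratios = cell_ratios(table, numerators=("granule",))
        assert len(ratios) == 1
        assert ratios.iloc[0]["granule_over_cytosol"] == pytest.approx(0.6)

    def test_rat_presets_reproduce_ratio_directions(self):
        """α granule/cytosol > 1, β < 1, SLMV/cytosol far above both —
        the printed ordering of the rat cell types."""
        from granuflux.workflow import quantify_preset_cells

        tables = {
            name: quantify_preset_cells(name, 5, seed)
            for name, seed in [("rat_alpha", 41), ("rat_beta", 42)]
        }
        report = ratio_stats(tables)
        a = report["groups"]["rat_alpha"]["ratios"]["granule_over_cytosol"]["mean"]
        b = report["groups"]["rat_beta"]["ratios"]["granule_over_cytosol"]["mean"]
        assert a > 1.0 > b
        for name in tables:
            g = report["groups"][name]
            assert g["ratios"]["slmv_over_cytosol"]["mean"] > g["ratios"]["granule_over_cytosol"]["mean"]
        # both per-cell-ratio means and pooled-means ratios are reported
        assert "granule_over_cytosol" in report["groups"]["rat_beta"]["pooled_ratio"]
        assert "rat_alpha_vs_rat_beta" in report["tests"]


class TestCalibrationCurve:
    def _exact_series(self) -> CalibrationSeries:
        return CalibrationSeries(
            concentrations_mM=np.array([0.0, 3.0]),
            densities=np.array([0.0, 30.0]),
            counts=np.array([0, 120]),
            area_um2=4.0,
            slope_true=10.0,
            intercept_true=0.0,
        )

    def test_exact_line_and_inverse(self):
        curve = calibrate_concentration(self._exact_series())
        assert curve.slope == pytest.approx(10.0)
        assert curve.intercept == pytest.approx(0.0)
        conc, _ = estimate_mM(curve, 20.0)
        assert conc == pytest.approx(2.0)

    def test_singular_design_rejected(self):
        series = self._exact_series()
        series.concentrations_mM = np.array([2.0, 2.0])
        with pytest.raises(ValueError, match="singular"):
            calibrate_concentration(series)

    def test_through_origin_refuses_density_below_intercept(self):
        curve = calibrate_concentration(self._exact_series(), through_origin=True)
        with pytest.raises(ValueError, match="below the intercept"):
            estimate_mM(curve, -1.0)

    def test_anchored_curve_reads_relative_concentration(self):
        curve = anchored_curve(30.2, 3.0)
        conc, se = estimate_mM(curve, 19.7)
        assert conc == pytest.approx(3.0 * 19.7 / 30.2, rel=1e-12)
        assert se == 0.0

    def test_inverse_uncertainty_propagates(self):
        from granuflux.synthetic_em import generate_calibration

        series = generate_calibration(list(np.linspace(0, 8, 8)), slope=12.0, seed=3)
        curve = calibrate_concentration(series, through_origin=False)
        conc, se = estimate_mM(curve, 36.0)
        assert se > 0.0
        assert conc == pytest.approx((36.0 - curve.intercept) / curve.slope)
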