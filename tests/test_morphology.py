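"""Contour meshing, cell dimensions, volume, fluorescence and aggregation."""

import numpy as np
import pandas as pd
import pytest

from phenoscreen.morphology import (
    CellContour,
    RodShapeError,
    cell_dimensions,
    cell_fluorescence,
    cell_volume,
    filter_and_summarize,
    instantaneous_growth,
    mesh_contour,
    plate_correct,
    principal_axis_dims,
    segment_mask,
    spherocylinder_volume,
)
from phenoscreen.simulate import (
    CellSimConfig,
    rasterize_contour,
    simulate_cell_population,
    simulate_time_lapse,
    spherocylinder_contour,
)

SPHERO_VOL_4X1 = np.pi * 0.5 ** 2 * 3 + 4 / 3 * np.pi * 0.5 ** 3  # 2.8798


class TestMeshContour:
    def test_spherocylinder_midline_and_rib_widths(self, sphero_4x1):
        mesh = mesh_contour(sphero_4x1)
        assert mesh.midline_length == pytest.approx(4.0, rel=0.01)
        pos = mesh.arc_positions
        interior = (pos > 0.6) & (pos < mesh.midline_length - 0.6)
        np.testing.assert_allclose(mesh.rib_widths[interior], 1.0, rtol=0.01)

    def test_circle_raises_rod_shape_error(self, circle_contour):
        with pytest.raises(RodShapeError):
            mesh_contour(circle_contour)

    def test_bent_rod_constant_width_and_centerline_length(self, banana_contour):
        # tube of width 1 around a 5 um-radius, 60 degree arc:
        # pole-to-pole midline = centerline arc + two cap extensions
        mesh = mesh_contour(banana_contour)
        truth_len = 5.0 * (np.pi / 3) + 1.0
        assert mesh.midline_length == pytest.approx(truth_len, rel=0.02)
        pos = mesh.arc_positions
        interior = (pos > 0.7) & (pos < mesh.midline_length - 0.7)
        np.testing.assert_allclose(mesh.rib_widths[interior], 1.0, rtol=0.02)

    def test_rigid_motion_invariance(self):
        dims0 = cell_dimensions(
            CellContour("c", spherocylinder_contour(4, 1, 256)))
        for ang in np.linspace(0, np.pi, 12, endpoint=False):
            c = CellContour("c", spherocylinder_contour(
                4, 1, 256, center=(5.0, -7.0), angle=ang))
            d = cell_dimensions(c)
            assert d.length == pytest.approx(dims0.length, rel=0.005)
            assert d.width == pytest.approx(dims0.width, rel=0.005)


class TestCellDimensions:
    def test_spherocylinder_dimensions_via_mesh(self, sphero_4x1):
        d = cell_dimensions(sphero_4x1)
        assert d.method == "mesh"
        assert d.length == pytest.approx(4.0, rel=0.01)
        assert d.width == pytest.approx(1.0, rel=0.01)

    def test_circle_falls_back_to_principal_axes(self, circle_contour):
        d = cell_dimensions(circle_contour)
        assert d.method == "principal_axes"
        assert d.length == pytest.approx(1.0, rel=0.01)
        assert d.width == pytest.approx(1.0, rel=0.01)

    def test_septal_constriction_excluded_from_width(self, dumbbell_contour):
        # dividing cell: two 1-um lobes, 0.5-um neck; septal ribs must not
        # drag the mean width toward the neck
        d = cell_dimensions(dumbbell_contour)
        assert d.method == "mesh"
        assert d.width == pytest.approx(1.0, rel=0.03)

    def test_mesh_and_principal_axes_agree_on_straight_rods(self):
        for L in (2.0, 3.0, 4.0):
            c = CellContour("c", spherocylinder_contour(L, 1.0, 256))
            dm = cell_dimensions(c)
            dp = principal_axis_dims(c)
            assert dm.length == pytest.approx(dp.length, rel=0.03)
            assert dm.width == pytest.approx(dp.width, rel=0.03)

    def test_force_principal_axes_flag(self, sphero_4x1):
        d = cell_dimensions(sphero_4x1, force_principal_axes=True)
        assert d.method == "principal_axes"


class TestCellVolume:
    def test_spherocylinder_closed_form(self, sphero_4x1):
        mesh = mesh_contour(sphero_4x1)
        assert cell_volume(mesh) == pytest.approx(SPHERO_VOL_4X1, rel=0.02)

    def test_sphere_closed_form_fallback(self):
        assert spherocylinder_volume(1.0, 1.0) == pytest.approx(
            4 / 3 * np.pi * 0.5 ** 3)
        assert spherocylinder_volume(1.0, 1.0) == pytest.approx(0.524, abs=5e-4)

    def test_volume_scales_cubically(self):
        v1 = cell_volume(mesh_contour(
            CellContour("a", spherocylinder_contour(3, 1, 256))))
        v2 = cell_volume(mesh_contour(
            CellContour("b", spherocylinder_contour(6, 2, 256))))
        assert v2 == pytest.approx(8 * v1, rel=0.01)

    def test_volume_error_decreases_with_contour_resolution(self):
        errs = []
        for npts in (64, 128, 256, 512):
            mesh = mesh_contour(
                CellContour("c", spherocylinder_contour(4, 1, npts)))
            errs.append(abs(cell_volume(mesh) - SPHERO_VOL_4X1))
        assert all(a > b for a, b in zip(errs, errs[1:]))


class TestInstantaneousGrowth:
    def test_exponential_track_recovers_rate(self):
        track, _ = simulate_time_lapse(0.03, 12, 5.0)
        rate = instantaneous_growth(track)
        np.testing.assert_allclose(rate[2:-2], 0.03, rtol=0.05)

    def test_constant_volume_rate_zero(self):
        track, _ = simulate_time_lapse(0.0, 8, 5.0)
        rate = instantaneous_growth(track)
        np.testing.assert_allclose(rate, 0.0, atol=1e-6)

    def test_linear_volume_rate_strictly_decreasing(self):
        track, _ = simulate_time_lapse(0.0, 10, 5.0, mode="linear",
                                       linear_slope=0.02)
        rate = instantaneous_growth(track)
        assert np.all(np.diff(rate[1:-1]) < 0)


class TestCellFluorescence:
    def _square(self, x0, y0, side, n=24):
        # axis-aligned square contour sampled along its perimeter
        per = np.linspace(0, 4 * side, n, endpoint=False)
        pts = []
        for s in per:
            edge, u = divmod(s, side)
            pts.append({0: (x0 + u, y0), 1: (x0 + side, y0 + u),
                        2: (x0 + side - u, y0 + side),
                        3: (x0, y0 + side - u)}[int(edge)])
        return CellContour("sq", np.array(pts))

    def test_uniform_image_background_subtracted(self):
        img = np.full((20, 20), 10.0)
        val = cell_fluorescence(img, self._square(5, 5, 10), background=2.0)
        assert val == pytest.approx(8.0, rel=1e-9)

    def test_background_equal_to_signal_gives_zero(self):
        img = np.full((20, 20), 7.0)
        val = cell_fluorescence(img, self._square(5, 5, 10), background=7.0)
        assert val == pytest.approx(0.0, abs=1e-12)

    def test_two_level_image_placement_independent(self):
        for x0 in (3, 6, 9):
            img = np.full((25, 25), 2.0)
            img[4:4 + 10, x0:x0 + 10] = 12.0  # rows y, cols x
            val = cell_fluorescence(img, self._square(x0, 4, 10),
                                    background=2.0)
            assert val == pytest.approx(10.0, rel=1e-9)

    def test_contour_outside_image_raises(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError, match="no pixel centers"):
            cell_fluorescence(img, self._square(50, 50, 5), background=0)


class TestFilterAndSummarize:
    def test_width_bounds_are_strict_eliminations(self):
        dims = pd.DataFrame({
            "strain_id": "s1", "plate_id": "p1",
            "length_um": [2.0, 2.0, 2.0, 2.0],
            "width_um": [0.5, 0.7, 1.0, 2.5],
        })
        out = filter_and_summarize(dims, min_cells=1)
        assert int(out["n_cells"].iloc[0]) == 2

    def test_min_cell_rule_flags_strain(self):
        dims = pd.DataFrame({
            "strain_id": "s1", "plate_id": "p1",
            "length_um": np.full(99, 3.0), "width_um": np.full(99, 1.0),
        })
        out = filter_and_summarize(dims, min_cells=100)
        assert not bool(out["included"].iloc[0])

    def test_robust_cv_hand_value(self):
        dims = pd.DataFrame({
            "strain_id": "s1", "plate_id": "p1",
            "length_um": [1.0, 2.0, 3.0, 4.0, 100.0],
            "width_um": np.full(5, 1.0),
        })
        out = filter_and_summarize(dims, min_cells=1)
        assert out["median_length"].iloc[0] == pytest.approx(3.0)
        # robust SD = 1.4826 * MAD = 1.4826; CV = 1.4826 / 3
        assert out["cv_length"].iloc[0] == pytest.approx(1.4826 / 3, rel=1e-9)


class TestPlateCorrect:
    def test_hand_example_two_plates(self):
        df = pd.DataFrame({
            "strain_id": ["a", "b", "c", "d"],
            "plate_id": ["A", "A", "B", "B"],
            "median_length": [3.0, 3.0, 3.0, 3.0],
            "median_width": [1.0, 1.2, 1.4, 1.6],
        })
        out = plate_correct(df)
        np.testing.assert_allclose(sorted(out["corrected_width"]),
                                   [1.2, 1.2, 1.4, 1.4])
        for _, grp in out.groupby("plate_id"):
            assert grp["corrected_width"].median() == pytest.approx(
                out["median_width"].median())

    def test_single_plate_unchanged(self):
        df = pd.DataFrame({
            "strain_id": ["a", "b", "c"], "plate_id": "A",
            "median_length": [2.0, 3.0, 4.0],
            "median_width": [0.9, 1.0, 1.1],
        })
        out = plate_correct(df)
        np.testing.assert_allclose(out["corrected_length"], df["median_length"])

    def test_global_median_preserved_and_plate_medians_equalised(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "strain_id": [f"s{i}" for i in range(30)],
            "plate_id": np.repeat(["A", "B", "C"], 10),
            "median_length": rng.normal(3, 0.3, 30)
                             + np.repeat([0.0, 0.4, -0.2], 10),
            "median_width": rng.normal(1, 0.05, 30)
                            + np.repeat([0.0, 0.1, 0.05], 10),
        })
        out = plate_correct(df)
        for col in ("corrected_length", "corrected_width"):
            plate_medians = out.groupby("plate_id")[col].median()
            np.testing.assert_allclose(plate_medians,
                                       plate_medians.iloc[0], atol=1e-12)

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            plate_correct(pd.DataFrame(columns=["plate_id", "median_length",
                                                "median_width"]))


class TestSegmentMask:
    def test_rasterized_cell_roundtrip(self):
        c = CellContour("c", spherocylinder_contour(4, 1, 128, center=(6, 5)))
        mask = rasterize_contour(c, 0.065, shape=(160, 160))
        contours = segment_mask(mask, 0.065)
        assert len(contours) == 1
        d = cell_dimensions(contours[0])
        assert d.length == pytest.approx(4.0, rel=0.02, abs=0.065)
        assert d.width == pytest.approx(1.0, rel=0.02, abs=0.065)

    def test_two_cells_two_contours(self):
        a = rasterize_contour(CellContour(
            "a", spherocylinder_contour(3, 1, 64, center=(3, 2))),
            0.065, shape=(200, 200))
        b = rasterize_contour(CellContour(
            "b", spherocylinder_contour(3, 1, 64, center=(9, 9))),
            0.065, shape=(200, 200))
        contours = segment_mask(a + b, 0.065)
        assert len(contours) == 2

    def test_border_touching_cell_dropped(self):
        c = CellContour("c", spherocylinder_contour(4, 1, 64, center=(2, 0.4)))
        mask = rasterize_contour(c, 0.065, shape=(60, 100))
        assert segment_mask(mask, 0.065) == []

    def test_empty_mask_empty_collection(self):
        assert segment_mask(np.zeros((32, 32), dtype=bool), 0.065) == []


class TestPopulationRecovery:
    def test_simulated_population_contours_are_simple_with_correct_area(self):
        cfg = CellSimConfig(n_cells=20, contour_points=64, seed=9)
        cells, truth = simulate_cell_population(cfg)
        for (plate, contour), (_, row) in zip(cells, truth.iterrows()):
            poly = contour.polygon
            assert poly.is_valid
            L, W = row["length_um"], row["width_um"]
            analytic = (L - W) * W + np.pi * (W / 2) ** 2
            assert poly.area == pytest.approx(analytic, rel=0.005)

    def test_plate_offsets_recovered_by_correction(self):
        cfg = CellSimConfig(
            n_cells=240, length_mean=3.0, length_sd=0.25,
            width_mean=1.0, width_sd=0.04,
            plate_offsets={"A": (0.0, 0.0), "B": (0.0, 0.2)}, seed=21)
        cells, truth = simulate_cell_population(cfg)
        rows = [(f"s{i % 4}", plate, *_lw(contour))
                for i, (plate, contour) in enumerate(cells)]
        dims = pd.DataFrame(rows, columns=["strain_id", "plate_id",
                                           "length_um", "width_um"])
        summary = filter_and_summarize(dims, min_cells=10, max_width=2.5)
        corrected = plate_correct(summary)
        # plate B's +0.2 um width offset is removed up to sampling noise
        meds = corrected.groupby("plate_id")["corrected_width"].median()
        assert abs(meds["A"] - meds["B"]) < 0.01


def _lw(contour):
    d = cell_dimensions(contour)
    return d.length, d.width
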