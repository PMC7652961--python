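import numpy as np
import pytest

from ritdose.cellular import (CompartmentTIA, SubcellularTimeCourse,
                              cell_bound_fraction, major_contributor,
                              nucleus_dose, percent_cell_bound,
                              scale_dose_to_activity,
                              time_integrated_activity)
from ritdose.simulate import gen_subcellular


def brute_force_tia(times_h, series, a0, window, dt_s=1.0):
    """Independent oracle: fine-grid quadrature of the linear interpolant."""
    t = np.concatenate(([0.0], times_h)) if times_h[0] > 0 else times_h
    a = np.concatenate(([a0], series)) if times_h[0] > 0 else series
    grid = np.arange(window[0] * 3600, window[1] * 3600 + dt_s / 2, dt_s)
    vals = np.interp(grid / 3600, t, a)
    return np.trapezoid(vals, grid)


class TestTimeIntegratedActivity:
    def test_constant_activity_is_rectangle(self):
        course = SubcellularTimeCourse(
            np.array([0.0, 8.0, 24.0]),
            {"CS": np.full(3, 100.0), "Cy": np.zeros(3), "N": np.zeros(3)},
            added_activity_bq=1e6)
        tia = time_integrated_activity(course, (0, 16))
        assert tia.tia_bq_s["CS"] == pytest.approx(100 * 57600)

    def test_linear_ramp_is_triangle(self):
        course = SubcellularTimeCourse(
            np.array([16.0, 24.0]),
            {"CS": np.array([100.0, 150.0]), "Cy": np.zeros(2),
             "N": np.zeros(2)},
            added_activity_bq=1e6)
        tia = time_integrated_activity(course, (0, 16))
        assert tia.tia_bq_s["CS"] == pytest.approx(0.5 * 100 * 57600)

    def test_matches_brute_force_quadrature_on_synthetic_course(self):
        course = gen_subcellular(seed=11, noise_cv=0.1)
        tia = time_integrated_activity(course, (0, 16))
        for comp, series in course.activity.items():
            oracle = brute_force_tia(course.times_h, series, 0.0, (0, 16))
            assert tia.tia_bq_s[comp] == pytest.approx(oracle, rel=1e-6)
        oracle_med = brute_force_tia(course.times_h, course.medium_series(),
                                     course.added_activity_bq, (0, 16))
        assert tia.tia_bq_s["medium"] == pytest.approx(oracle_med, rel=1e-6)

    def test_optional_decay_inside_integral_matches_closed_form(self):
        from ritdose.radioactivity import get_nuclide
        nuc = get_nuclide("Lu-177")
        course = SubcellularTimeCourse(
            np.array([0.0, 24.0]),
            {"CS": np.full(2, 100.0), "Cy": np.zeros(2), "N": np.zeros(2)},
            added_activity_bq=1e6)
        tia = time_integrated_activity(course, (0, 16), decay_in_integral=nuc)
        lam = nuc.decay_constant
        closed = 100.0 * (1 - np.exp(-lam * 57600)) / lam
        assert tia.tia_bq_s["CS"] == pytest.approx(closed, rel=1e-6)

    def test_window_beyond_last_sample_rejected(self):
        course = gen_subcellular(seed=0)
        with pytest.raises(ValueError, match="beyond last sample"):
            time_integrated_activity(course, (0, 48))


class TestNucleusDose:
    def test_single_compartment_product(self, s_table):
        tia = CompartmentTIA({"CS": 9.77e3})
        rep = nucleus_dose(tia, s_table, "Lu-177")
        assert rep.dose_gy["CS"] == pytest.approx(3.47, abs=0.005)

    def test_worked_example_column_breakdown(self, worked_example):
        rep = worked_example["DOTA-In111"]
        assert round(rep["total_dose_gy"], 2) == 1.21
        rounded = {k: round(v, 2) for k, v in rep["dose_gy"].items()}
        assert rounded == {"CS": 0.68, "Cy": 0.10, "N": 0.34, "medium": 0.09}

    def test_zero_tia_gives_zero_dose(self, s_table):
        tia = CompartmentTIA({c: 0.0 for c in ("CS", "Cy", "N", "medium")})
        rep = nucleus_dose(tia, s_table, "Lu-177")
        assert rep.total_dose_gy == 0.0

    def test_missing_s_value_names_the_source(self, s_table):
        tia = CompartmentTIA({"CS": 1.0})
        with pytest.raises(KeyError, match="CS"):
            nucleus_dose(tia, s_table, "Ac-225")

    def test_linearity_in_tia(self, s_table, table1_tia):
        nuclide, tia = table1_tia["DOTA-Lu177"]
        doubled = CompartmentTIA({k: 2 * v for k, v in tia.tia_bq_s.items()})
        base = nucleus_dose(tia, s_table, nuclide)
        twice = nucleus_dose(doubled, s_table, nuclide)
        for comp in base.dose_gy:
            assert twice.dose_gy[comp] == 2 * base.dose_gy[comp]

    def test_total_is_sum_of_parts(self, s_table, table1_tia):
        for nuclide, tia in table1_tia.values():
            rep = nucleus_dose(tia, s_table, nuclide)
            assert rep.total_dose_gy == pytest.approx(
                sum(rep.dose_gy.values()), abs=1e-12)
            assert sum(rep.fractions.values()) == pytest.approx(1.0)


class TestMajorContributor:
    def test_membrane_dominates_beta_column(self, s_table, table1_tia):
        rep = nucleus_dose(table1_tia["DOTA-Lu177"][1], s_table, "Lu-177")
        assert major_contributor(rep) == (["CS"], 74)

    def test_membrane_dominates_dota_auger_column(self, s_table, table1_tia):
        rep = nucleus_dose(table1_tia["DOTA-In111"][1], s_table, "In-111")
        assert major_contributor(rep) == (["CS"], 56)

    def test_tied_sources_reported_jointly(self, s_table, table1_tia):
        # CS and N both deliver 0.20 Gy (at report precision) for this column
        rep = nucleus_dose(table1_tia["MCP-In111"][1], s_table, "In-111")
        labels, _ = major_contributor(rep)
        assert labels == ["CS", "N"]

    def test_zero_total_rejected(self, s_table):
        tia = CompartmentTIA({"CS": 0.0})
        rep = nucleus_dose(tia, s_table, "Lu-177")
        with pytest.raises(ValueError):
            major_contributor(rep)


class TestCellBoundFractionAndScaling:
    def test_beta_column_cell_bound_share(self, s_table, table1_tia):
        rep = nucleus_dose(table1_tia["DOTA-Lu177"][1], s_table, "Lu-177")
        assert cell_bound_fraction(rep) == pytest.approx(0.94, abs=0.005)
        # 4.39 is arithmetic on 2-decimal rounded parts (4.68 − 0.29);
        # full precision gives 4.3836
        assert rep.total_cell_dose_gy == pytest.approx(4.39, abs=0.01)

    def test_no_medium_dose_means_fraction_one(self, s_table):
        rep = nucleus_dose(CompartmentTIA({"CS": 1e3}), s_table, "Lu-177")
        assert cell_bound_fraction(rep) == 1.0

    def test_linear_activity_scaling(self, s_table, table1_tia):
        rep = nucleus_dose(table1_tia["DOTA-Lu177"][1], s_table, "Lu-177")
        quarter = scale_dose_to_activity(rep, ref_mbq=1.2, target_mbq=0.3)
        assert quarter.total_dose_gy == pytest.approx(4.68 / 4, abs=0.005)
        assert scale_dose_to_activity(rep, 1.2, 1.2).total_dose_gy == \
            rep.total_dose_gy
        assert scale_dose_to_activity(rep, 1.2, 0.0).total_dose_gy == 0.0


class TestPercentCellBound:
    def test_round_trips_generator_fractions(self):
        course = gen_subcellular(seed=5, uptake_plateau_fraction=0.05,
                                 uptake_rate_per_h=0.3, noise_cv=0.0)
        pct = percent_cell_bound(course)
        expected = 5.0 * (1 - np.exp(-0.3 * course.times_h))
        np.testing.assert_allclose(pct, expected, rtol=1e-12)

    def test_all_bound_is_hundred_percent(self):
        course = SubcellularTimeCourse(
            np.array([1.0]), {"CS": np.array([60.0]), "Cy": np.array([30.0]),
                              "N": np.array([10.0])}, added_activity_bq=100.0)
        assert percent_cell_bound(course)[0] == pytest.approx(100.0)
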