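"""Saturation binding, internalization, autoradiography, selectivity."""

import numpy as np
import pytest

from gipet import simulate
from gipet.binding import (
    SaturationDataset,
    arg_quantify,
    internalization_fractions,
    load_builtin_potency_table,
    percent_inhibition,
    saturation_fit,
    selectivity_ratio,
    specific_binding,
)
from gipet.core import AlignmentError, ReferenceLookupError, ValidationError


class TestSpecificBinding:
    def test_total_equals_nonspecific_gives_zeros(self):
        spec, n = specific_binding([1.0, 2.0], [1.0, 2.0])
        np.testing.assert_array_equal(spec, 0.0)
        assert n == 0

    def test_elementwise_difference(self):
        spec, _ = specific_binding([1.0, 2.0], [0.2, 0.5])
        np.testing.assert_allclose(spec, [0.8, 1.5])

    def test_negative_clamped_and_counted(self):
        spec, n = specific_binding([1.0, 0.1], [0.2, 0.5])
        np.testing.assert_allclose(spec, [0.8, 0.0])
        assert n == 1

    def test_grid_mismatch_rejected(self):
        with pytest.raises(AlignmentError):
            specific_binding([1.0, 2.0], [0.2])

    def test_noise_free_generator_recovers_hyperbola(self):
        cfg = simulate.AssaySimConfig(noise_cv=0.0)
        ds, truth = simulate.simulate_saturation_assay(cfg, seed=3)
        spec, _ = specific_binding(ds.total_bound.mean(axis=1),
                                   ds.nonspecific_bound.mean(axis=1))
        np.testing.assert_allclose(spec, truth["specific_curve"], rtol=1e-12)


class TestSaturationFit:
    def test_noise_free_exact_recovery(self):
        cfg = simulate.AssaySimConfig(kd_nm=10.0, bmax_pmol_per_mcells=5.0,
                                      noise_cv=0.0)
        ds, _ = simulate.simulate_saturation_assay(cfg, seed=0)
        fit = saturation_fit(ds)
        assert fit.kd_nm == pytest.approx(10.0, rel=1e-6)
        assert fit.bmax_pmol_per_mcells == pytest.approx(5.0, rel=1e-6)

    def test_half_occupancy_at_kd(self):
        cfg = simulate.AssaySimConfig(kd_nm=10.0, bmax_pmol_per_mcells=5.0,
                                      noise_cv=0.0)
        ds, _ = simulate.simulate_saturation_assay(cfg, seed=0)
        fit = saturation_fit(ds)
        assert fit.predict(fit.kd_nm) == pytest.approx(
            fit.bmax_pmol_per_mcells / 2.0, rel=1e-9)

    def test_matches_independent_grid_search(self):
        """Fitted (Kd, Bmax) agree with a dense 1-D grid over Kd with the
        conditionally-optimal Bmax solved in closed form — an independent
        minimizer of the same least-squares loss."""
        ds, _ = simulate.simulate_saturation_assay(
            simulate.AssaySimConfig(noise_cv=0.10), seed=42)
        c = ds.concentrations_nm
        y, _ = specific_binding(ds.total_bound.mean(axis=1),
                                ds.nonspecific_bound.mean(axis=1))
        kd_grid = np.geomspace(0.5, 500.0, 40001)
        x = c[None, :] / (kd_grid[:, None] + c[None, :])
        bmax_opt = (x * y).sum(axis=1) / (x * x).sum(axis=1)
        sse = ((bmax_opt[:, None] * x - y) ** 2).sum(axis=1)
        i = int(np.argmin(sse))
        fit = saturation_fit(ds)
        assert fit.kd_nm == pytest.approx(kd_grid[i], rel=0.01)
        assert fit.bmax_pmol_per_mcells == pytest.approx(bmax_opt[i], rel=0.01)

    def test_scale_equivariance(self):
        ds, _ = simulate.simulate_saturation_assay(
            simulate.AssaySimConfig(noise_cv=0.10), seed=5)
        fit = saturation_fit(ds)
        scaled = SaturationDataset(ds.concentrations_nm, ds.total_bound * 3.0,
                                   ds.nonspecific_bound * 3.0)
        fit3 = saturation_fit(scaled)
        assert fit3.kd_nm == pytest.approx(fit.kd_nm, rel=1e-6)
        assert fit3.bmax_pmol_per_mcells == pytest.approx(
            3.0 * fit.bmax_pmol_per_mcells, rel=1e-6)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValidationError):
            saturation_fit(SaturationDataset(
                [1.0, 10.0, 100.0], [[0.1], [0.5], [1.0]], [[0.0]] * 3))

    def test_total_binding_mode_recovers_ns_slope(self):
        cfg = simulate.AssaySimConfig(kd_nm=15.0, bmax_pmol_per_mcells=3.0,
                                      ns_slope=0.004, noise_cv=0.0)
        ds, _ = simulate.simulate_saturation_assay(cfg, seed=0)
        fit = saturation_fit(ds, fit_ns_term=True)
        assert fit.kd_nm == pytest.approx(15.0, rel=1e-4)
        assert fit.ns_slope == pytest.approx(0.004, rel=1e-4)


class TestInternalization:
    def test_share_of_total(self):
        tc = internalization_fractions([60.0], [60.0], [40.0], standard_counts=100.0)
        assert tc.internalized_share[0] == pytest.approx(40.0)

    def test_all_zero_time_zero_share_undefined_not_nan_everywhere(self):
        tc = internalization_fractions([0.0, 30.0], [0.0, 50.0], [0.0, 50.0],
                                       standard_counts=100.0)
        assert np.isnan(tc.internalized_share[0])
        assert tc.internalized_share[1] == pytest.approx(50.0)

    def test_zero_standard_rejected(self):
        with pytest.raises(ValidationError):
            internalization_fractions([0.0], [1.0], [1.0], standard_counts=0.0)

    def test_cold_incubation_suppresses_internalization(self):
        cfg = simulate.AssaySimConfig(noise_cv=0.0, k_int_per_h_4c=0.0)
        _warm, cold, _truth = simulate.simulate_internalization(cfg, seed=0)
        np.testing.assert_array_equal(cold.internalized_pct_id, 0.0)

    def test_warm_internalized_fraction_grows(self):
        cfg = simulate.AssaySimConfig(noise_cv=0.0)
        warm, _cold, _ = simulate.simulate_internalization(cfg, seed=0)
        shares = internalization_fractions(
            warm.times_min, warm.membrane_pct_id, warm.internalized_pct_id,
            standard_counts=100.0).internalized_share
        assert np.all(np.diff(shares[1:]) > 0)


class TestAutoradiography:
    def test_calibration_identity(self):
        # ROI at the reference's own count density reads back the
        # reference's Bq/mm2
        img, truth = simulate.simulate_autoradiogram(
            {"pellet": 2.0}, reference_activity_bq=100.0, background_counts=0.0,
            poisson=False, seed=0)
        ref = arg_quantify(img, "reference")
        ref_area = img.rois["reference"].sum() * img.pixel_area_mm2
        assert ref["bq_per_mm2"] == pytest.approx(100.0 / ref_area, rel=1e-12)

    def test_molar_activity_division(self):
        img, _ = simulate.simulate_autoradiogram(
            {"pellet": 5.0}, molar_activity_bq_per_fmol=10.0,
            background_counts=0.0, poisson=False, seed=0)
        res = arg_quantify(img, "pellet")
        assert res["fmol_per_mm2"] == pytest.approx(
            res["bq_per_mm2"] / 10.0, rel=1e-12)

    def test_noise_free_grid_recovers_density_exactly(self):
        img, truth = simulate.simulate_autoradiogram(
            {"pellet": 3.0}, background_counts=0.0, poisson=False, seed=0)
        res = arg_quantify(img, "pellet")
        assert res["fmol_per_mm2"] == pytest.approx(3.0, rel=1e-12)

    def test_doubled_exposure_leaves_quantification_unchanged(self):
        a, _ = simulate.simulate_autoradiogram(
            {"pellet": 3.0}, exposure_factor=50.0, background_counts=0.0,
            poisson=False, seed=0)
        b, _ = simulate.simulate_autoradiogram(
            {"pellet": 3.0}, exposure_factor=100.0, background_counts=0.0,
            poisson=False, seed=0)
        assert arg_quantify(a, "pellet")["fmol_per_mm2"] == pytest.approx(
            arg_quantify(b, "pellet")["fmol_per_mm2"], rel=1e-12)

    def test_poisson_grid_recovers_density_within_noise(self):
        img, _ = simulate.simulate_autoradiogram(
            {"pellet": 3.0}, background_counts=1.0, exposure_factor=200.0,
            seed=11)
        res = arg_quantify(img, "pellet", background_roi="background")
        assert res["fmol_per_mm2"] == pytest.approx(3.0, rel=0.05)

    def test_unknown_roi_rejected(self):
        img, _ = simulate.simulate_autoradiogram({"pellet": 1.0}, seed=0)
        with pytest.raises(ReferenceLookupError):
            arg_quantify(img, "nope")


class TestBlockingAndSelectivity:
    @pytest.mark.parametrize("baseline, blocked, expected", [
        (10.0, 0.0, 100.0),
        (10.0, 10.0, 0.0),
        (10.0, 0.8, 92.0),
        (10.0, 0.1, 99.0),
    ])
    def test_percent_inhibition(self, baseline, blocked, expected):
        assert percent_inhibition(baseline, blocked) == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValidationError):
            percent_inhibition(0.0, 1.0)

    def test_fold_selectivity_from_builtin_potency_table(self):
        pt = load_builtin_potency_table()
        r1 = selectivity_ratio(pt, "C803-GIP", "human", "GIPR", "GLP-1R")
        assert r1 == pytest.approx(704000.0 / 0.7, rel=1e-9)  # ~1.0e6
        r2 = selectivity_ratio(pt, "Ga-C803-GIP", "human", "GIPR", "GLP-1R")
        assert r2 == pytest.approx(35700.0 / 0.8, rel=1e-9)  # ~4.5e4

    def test_identical_ec50s_give_ratio_one(self):
        from gipet.binding import PotencyTable
        pt = PotencyTable({("x", "A", "h"): 5.0, ("x", "B", "h"): 5.0})
        assert selectivity_ratio(pt, "x", "h", "A", "B") == 1.0

    def test_missing_entry_rejected(self):
        pt = load_builtin_potency_table()
        with pytest.raises(ReferenceLookupError):
            selectivity_ratio(pt, "C803-GIP", "dog", "GIPR", "GLP-1R")
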