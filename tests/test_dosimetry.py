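"""Residence times, MIRD organ doses, ICRP-60 effective dose, end-to-end."""

import math

import numpy as np
import pytest

from gipet import reference, simulate
from gipet.biodistribution import SUVCurve
from gipet.core import (
    Radionuclide,
    StateError,
    SValueTable,
    ValidationError,
)
from gipet.dosimetry import (
    HumanOrganFractionCurve,
    OrganDoseTable,
    ResidenceTime,
    ResidenceTimeSet,
    canonical_organ,
    dosimetry_report,
    effective_dose,
    human_organ_fraction,
    load_reported_organ_doses,
    marrow_residence,
    organ_doses,
    remainder_residence,
    residence_time,
)

T_HALF_H = 67.71 / 60.0
TAU_BOUND_H = T_HALF_H / math.log(2)  # ~1.628 h


def _suv_curve(organ, times_min, suv, corrected=False):
    suv = np.asarray(suv, float)
    return SUVCurve(organ, np.asarray(times_min, float), suv,
                    np.zeros_like(suv), np.ones(suv.shape, int), corrected)


class TestHumanOrganFraction:
    def test_zero_suv_gives_zero_fraction(self, phantom_male):
        c = _suv_curve("liver", [5.0, 10.0], [0.0, 0.0])
        f = human_organ_fraction(c, phantom_male)
        np.testing.assert_array_equal(f.fraction, 0.0)

    def test_arithmetic_with_consistent_units(self, phantom_male):
        # SUV_A 2 in a 300 g organ of a 73.7 kg body -> 600/73700
        c = _suv_curve("liver", [5.0], [2.0])
        f = human_organ_fraction(c, phantom_male)
        expected = 2.0 * phantom_male.mass_g("liver") / 73700.0
        assert f.fraction[0] == pytest.approx(expected, rel=1e-12)

    def test_whole_body_organ_at_suv_one_gives_fraction_one(self):
        from gipet.core import Phantom
        ph = Phantom("male", 70.0, {"everything": 69999.9})
        c = _suv_curve("everything", [5.0], [1.0])
        assert human_organ_fraction(c, ph).fraction[0] == pytest.approx(
            69999.9 / 70000.0)

    def test_decay_corrected_input_rejected(self, phantom_male):
        c = _suv_curve("liver", [5.0], [1.0], corrected=True)
        with pytest.raises(StateError):
            human_organ_fraction(c, phantom_male)

    def test_unknown_organ_lists_aliases(self, phantom_male):
        c = _suv_curve("gizzard", [5.0], [1.0])
        with pytest.raises(Exception, match="gizzard"):
            human_organ_fraction(c, phantom_male)

    def test_alias_resolution(self):
        assert canonical_organ("Osteogenic Cells") == "bone_surface"
        assert canonical_organ("urinary bladder (rinsed)") == "urinary_bladder_wall"
        assert canonical_organ("Kidney") == "kidneys"


class TestResidenceTime:
    def test_pure_physical_decay_gives_t_half_over_ln2(self, ga68):
        # all activity in one organ, decaying physically; dense sampling
        t_min = np.linspace(0.0, 20 * 60.0, 4000)
        lam = ga68.decay_constant_per_hour
        f = np.exp(-lam * t_min / 60.0)
        rt = residence_time(HumanOrganFractionCurve("organ", t_min, f), ga68)
        assert rt.tau_h == pytest.approx(TAU_BOUND_H, rel=1e-4)

    def test_pure_decay_at_study_design_within_5_percent(self, ga68):
        t_min = np.asarray(simulate.BIODIST_TIMES_MIN)
        lam = ga68.decay_constant_per_hour
        f = np.exp(-lam * t_min / 60.0)
        rt = residence_time(HumanOrganFractionCurve("organ", t_min, f), ga68)
        assert rt.tau_h == pytest.approx(TAU_BOUND_H, rel=0.05)
        assert rt.tail_rule in ("exp_fit", "physical_clamp")

    def test_piecewise_constant_then_physical_tail(self, ga68):
        # constant 0.5 over [0, 60 min]: trapezoid part = 0.5 h;
        # tail from an exponential at the physical rate adds 0.5/lambda
        lam = ga68.decay_constant_per_hour
        t_min = np.array([0.0, 30.0, 60.0, 90.0, 120.0])
        f = np.where(t_min <= 60.0, 0.5,
                     0.5 * np.exp(-lam * (t_min - 60.0) / 60.0))
        rt = residence_time(HumanOrganFractionCurve("organ", t_min, f), ga68,
                            tail_points=3)
        trap_expected = 0.5  # h, exact for the constant segment
        # trapezoid over the decaying segment + analytic tail
        t_h = t_min / 60.0
        trap_decay = np.trapezoid(f[2:], t_h[2:])
        tail_expected = f[-1] / lam
        assert rt.trapezoid_h == pytest.approx(trap_expected + trap_decay, rel=1e-9)
        assert rt.tail_h == pytest.approx(tail_expected, rel=1e-6)

    def test_trapezoid_exact_for_piecewise_linear(self, ga68):
        t_min = np.array([0.0, 30.0, 60.0, 120.0])
        f = np.array([0.0, 0.4, 0.2, 0.0])
        rt = residence_time(HumanOrganFractionCurve("organ", t_min, f), ga68)
        analytic = 0.5 * 0.5 * 0.4 + 0.5 * (0.4 + 0.2) * 0.5 + 0.5 * 0.2 * 1.0
        assert rt.trapezoid_h == pytest.approx(analytic, rel=1e-12)
        assert rt.tail_h == 0.0  # ends at zero: nothing to extrapolate

    def test_accumulating_organ_engages_physical_clamp(self, ga68):
        # kidney-like monotone increase in decay-uncorrected data: the
        # fitted tail rate would imply accumulation forever; clamped
        t_min = np.asarray(simulate.BIODIST_TIMES_MIN)
        f = 0.2 * (1.0 - np.exp(-0.02 * t_min))
        rt = residence_time(HumanOrganFractionCurve("kidneys", t_min, f), ga68)
        assert rt.tail_rule == "physical_clamp"

    def test_all_zero_curve_gives_zero_tau(self, ga68):
        rt = residence_time(
            HumanOrganFractionCurve("organ", np.array([5.0, 10.0]),
                                    np.zeros(2)), ga68)
        assert rt.tau_h == 0.0
        assert rt.tail_rule == "none"


class TestMarrowModel:
    def _blood(self, phantom):
        t_min = np.asarray(simulate.BIODIST_TIMES_MIN)
        f = 0.3 * np.exp(-2.0 * t_min / 60.0)
        return HumanOrganFractionCurve("blood", t_min, f)

    def test_zero_rmblr_gives_zero_tau(self, phantom_male, ga68):
        rt = marrow_residence(self._blood(phantom_male), phantom_male, ga68,
                              rmblr=0.0)
        assert rt.tau_h == 0.0

    def test_rmblr_one_equal_masses_reproduces_blood_tau(self, ga68):
        from gipet.core import Phantom
        ph = Phantom("male", 70.0, {"red_marrow": 1120.0, "blood": 1120.0})
        blood = self._blood(ph)
        tau_blood = residence_time(blood, ga68).tau_h
        rt = marrow_residence(blood, ph, ga68, rmblr=1.0)
        assert rt.tau_h == pytest.approx(tau_blood, rel=1e-12)

    def test_linearity_in_rmblr_and_mass_ratio(self, phantom_male, ga68):
        blood = self._blood(phantom_male)
        base = marrow_residence(blood, phantom_male, ga68, rmblr=1.0).tau_h
        half = marrow_residence(blood, phantom_male, ga68, rmblr=0.5).tau_h
        assert half == pytest.approx(0.5 * base, rel=1e-12)

    def test_requires_blood_curve(self, phantom_male, ga68):
        liver = HumanOrganFractionCurve("liver", np.array([5.0, 10.0]),
                                        np.array([0.1, 0.05]))
        with pytest.raises(ValidationError):
            marrow_residence(liver, phantom_male, ga68)


class TestRemainder:
    def test_no_organs_gives_full_physical_bound(self, ga68):
        tau, warns = remainder_residence({}, ga68, mode="no_excretion")
        assert tau == pytest.approx(TAU_BOUND_H, rel=1e-9)
        assert not warns

    def test_organs_at_bound_give_zero(self, ga68):
        tau, _ = remainder_residence({"kidneys": TAU_BOUND_H}, ga68)
        assert tau == 0.0

    def test_whole_body_identical_to_single_organ_gives_zero(self, ga68):
        tau, _ = remainder_residence({"kidneys": 0.4}, ga68,
                                     mode="whole_body_curve",
                                     whole_body_tau_h=0.4)
        assert tau == 0.0

    def test_exceeding_bound_is_error(self, ga68):
        with pytest.raises(ValidationError):
            remainder_residence({"a": 1.2, "b": 0.8}, ga68)


class TestOrganDoses:
    def _tau_set(self, taus, ga68, remainder=0.0):
        organs = {o: ResidenceTime(o, v, v, 0.0, "none", 0)
                  for o, v in taus.items()}
        return ResidenceTimeSet(organs=organs, remainder_tau_h=remainder,
                                nuclide=ga68)

    def test_single_source_single_target(self, ga68):
        s = SValueTable("Ga-68", "male", {("liver", "liver"): 0.1})
        doses = organ_doses(self._tau_set({"liver": 1.0}, ga68), s)
        assert doses.dose("liver") == pytest.approx(0.1)

    def test_linearity_in_tau(self, ga68):
        s = SValueTable("Ga-68", "male", {
            ("liver", "liver"): 0.1, ("liver", "kidneys"): 0.02,
            ("kidneys", "kidneys"): 0.3, ("kidneys", "liver"): 0.01})
        d1 = organ_doses(self._tau_set({"liver": 0.2, "kidneys": 0.4}, ga68), s)
        d2 = organ_doses(self._tau_set({"liver": 0.4, "kidneys": 0.8}, ga68), s)
        for organ in d1.doses_msv_per_mbq:
            assert d2.dose(organ) == pytest.approx(2 * d1.dose(organ), rel=1e-12)

    def test_equals_dense_matrix_product_oracle(self, ga68, rng):
        organs = ["a", "b", "c"]
        s_mat = rng.uniform(0.01, 1.0, size=(3, 3))
        entries = {(t, s): s_mat[i, j] for i, t in enumerate(organs)
                   for j, s in enumerate(organs)}
        taus = rng.uniform(0.0, 0.5, size=3)
        table = SValueTable("Ga-68", "male", entries)
        result = organ_doses(self._tau_set(dict(zip(organs, taus)), ga68), table)
        oracle = s_mat @ taus
        for i, organ in enumerate(organs):
            assert result.dose(organ) == pytest.approx(oracle[i], rel=1e-12)

    def test_missing_source_rejected(self, ga68):
        s = SValueTable("Ga-68", "male", {("liver", "liver"): 0.1})
        with pytest.raises(ValidationError, match="kidneys"):
            organ_doses(self._tau_set({"kidneys": 0.5}, ga68), s)


class TestEffectiveDose:
    def test_all_zero_doses_give_zero(self, icrp60, phantom_male):
        table = load_reported_organ_doses("male")
        zero = OrganDoseTable("male", {k: 0.0 for k in table.doses_msv_per_mbq})
        res = effective_dose(zero, icrp60, phantom_male)
        assert res.effective_dose_msv_per_mbq == 0.0

    def test_linearity(self, icrp60, phantom_male):
        table = load_reported_organ_doses("male")
        scaled = OrganDoseTable("male", {k: 3.0 * v
                                         for k, v in table.doses_msv_per_mbq.items()})
        e1 = effective_dose(table, icrp60, phantom_male)
        e3 = effective_dose(scaled, icrp60, phantom_male)
        assert e3.effective_dose_msv_per_mbq == pytest.approx(
            3.0 * e1.effective_dose_msv_per_mbq, rel=1e-12)

    def test_contributions_sum_to_effective_dose(self, icrp60, phantom_male):
        res = effective_dose(load_reported_organ_doses("male"), icrp60,
                             phantom_male)
        assert sum(res.contributions.values()) == pytest.approx(
            res.effective_dose_msv_per_mbq, abs=1e-12)

    def test_kidney_triggers_split_remainder(self, icrp60, phantom_male):
        res = effective_dose(load_reported_organ_doses("male"), icrp60,
                             phantom_male)
        assert res.remainder_report["rule"] == "split"
        assert res.remainder_report["highest_organ"] == "kidneys"

    def test_mass_weighted_mean_rule_without_dominant_remainder(
            self, icrp60, phantom_male):
        table = load_reported_organ_doses("male").doses_msv_per_mbq.copy()
        table["kidneys"] = 0.001  # no longer out-dosing the named tissues
        res = effective_dose(OrganDoseTable("male", table), icrp60, phantom_male)
        assert res.remainder_report["rule"] == "mass_weighted_mean"


class TestEndToEnd:
    def test_single_organ_pure_decay_chain(self, phantom_male, icrp60, ga68):
        # one organ holding everything, pure physical decay: tau ~ 1.628 h
        # and every dose milligray flows from that organ
        kin = {"liver": simulate.OrganKinetics(1.0, 1e6, 0.0, 12.0)}
        cfg = simulate.BiodistConfig(kinetics=kin, noise_cv=0.0)
        ds, truth = simulate.simulate_biodistribution(cfg, ga68, seed=3)
        s = reference.selfdose_svalue_table(phantom_male, ga68)
        rep = dosimetry_report(ds, phantom_male, ga68, s, icrp60)
        tau_liver = rep.residence_times.organs["liver"].tau_h
        expected = truth.residence_time_h("liver", phantom_male.mass_g("liver"),
                                          phantom_male.body_mass_kg)
        # the closed form is (T_half/ln2) * (BW_rat/m_liver_rat) * m_h/BW_h
        assert expected == pytest.approx(
            TAU_BOUND_H * (324.0 / 12.0) * phantom_male.mass_g("liver") / 73700.0,
            rel=1e-6)
        assert tau_liver == pytest.approx(expected, rel=0.05)
        assert rep.organ_dose_table.dose("liver") > 0
        assert rep.organ_dose_table.dose("spleen") == 0.0

    def test_zero_activity_dataset_gives_zero_report(self, phantom_male,
                                                     icrp60, ga68):
        kin = {"liver": simulate.OrganKinetics(1e-300, 1e6, 0.0, 12.0)}
        cfg = simulate.BiodistConfig(kinetics=kin, noise_cv=0.0)
        ds, _ = simulate.simulate_biodistribution(cfg, ga68, seed=3)
        s = reference.selfdose_svalue_table(phantom_male, ga68)
        rep = dosimetry_report(ds, phantom_male, ga68, s, icrp60)
        assert rep.organ_dose_table.dose("liver") == pytest.approx(0.0, abs=1e-250)

    def test_pipeline_tau_matches_generator_closed_form(self, phantom_male, ga68,
                                                        icrp60):
        cfg = simulate.BiodistConfig(noise_cv=0.0)
        ds, truth = simulate.simulate_biodistribution(cfg, ga68, seed=9)
        s = reference.selfdose_svalue_table(phantom_male, ga68)
        rep = dosimetry_report(ds, phantom_male, ga68, s, icrp60)
        from gipet.dosimetry import canonical_organ as canon
        rat_to_human = {canon(o): o for o in cfg.kinetics}
        for organ, rt in rep.residence_times.organs.items():
            if organ == "red_marrow":
                continue  # marrow comes from the blood model, not an organ
            analytic = truth.residence_time_h(
                rat_to_human[organ], phantom_male.mass_g(organ),
                phantom_male.body_mass_kg)
            assert rt.tau_h == pytest.approx(analytic, rel=0.05), organ

    def test_report_serialization_is_deterministic(self, phantom_male, icrp60,
                                                   ga68, tmp_path):
        cfg = simulate.BiodistConfig(noise_cv=0.05)
        s = reference.selfdose_svalue_table(phantom_male, ga68)
        ds1, _ = simulate.simulate_biodistribution(cfg, ga68, seed=21)
        ds2, _ = simulate.simulate_biodistribution(cfg, ga68, seed=21)
        r1 = dosimetry_report(ds1, phantom_male, ga68, s, icrp60)
        r2 = dosimetry_report(ds2, phantom_male, ga68, s, icrp60)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        r1.to_json(p1)
        r2.to_json(p2)
        assert p1.read_text() == p2.read_text()
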