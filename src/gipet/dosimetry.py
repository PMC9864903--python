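"""Rat-to-human internal dosimetry.

The chain: decay-uncorrected rat SUV curves are scaled by reference-phantom
organ masses into human fraction-of-injected-activity curves,

    fraction_organ(t) = SUV_A(t) * m_organ(g) / (1000 * m_body(kg)),

integrated into residence times (linear trapezoid over the sampled span
plus a single-exponential tail to infinity), completed with a bone-marrow
blood-volume model and a remainder term, pushed through the MIRD schema
D(target) = sum_source tau_source * S(target <- source), and finally
weighted with ICRP-60 tissue-weighting factors into the effective dose.

Conventions follow classic OLINDA 1.1 usage of ICRP-60: the colon dose is
0.57*ULI + 0.43*LLI, the thymus stands in for the esophagus, gonads are
testes (male) or ovaries (female), and the remainder weight of 0.05 splits
in half onto the highest-dosed remainder organ when that organ out-doses
every named tissue (the kidney of a renally excreted tracer routinely
triggers this rule).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .biodistribution import SUVCurve, build_suv_curves
from .core import (
    Dataset,
    Phantom,
    Radionuclide,
    ReferenceLookupError,
    StateError,
    SValueTable,
    TissueWeights,
    ValidationError,
)

log = logging.getLogger(__name__)

#: editable map from counted-sample / reported-tissue labels to canonical
#: phantom organ names
ORGAN_ALIASES: dict[str, str] = {
    "adrenal": "adrenals",
    "kidney": "kidneys",
    "lung": "lungs",
    "heart": "heart_wall",
    "bone": "bone_surface",
    "osteogenic_cells": "bone_surface",
    "bone_marrow": "red_marrow",
    "marrow": "red_marrow",
    "large_intestine": "uli_wall",
    "uli": "uli_wall",
    "lli": "lli_wall",
    "urinary_bladder": "urinary_bladder_wall",
    "urinary_bladder_rinsed": "urinary_bladder_wall",
    "bladder": "urinary_bladder_wall",
    "gallbladder": "gallbladder_wall",
    "stomach": "stomach_wall",
    "breast": "breasts",
    "testis": "testes",
    "ovary": "ovaries",
    "testes_ovaries": "gonads",
    "remainder": "rest_of_body",
}


def canonical_organ(name: str) -> str:
    """Normalize an organ label: lowercase, underscores, alias-resolved."""
    key = name.strip().lower().replace("-", "_").replace("/", "_")
    key = "_".join(key.replace("(", " ").replace(")", " ").split())
    return ORGAN_ALIASES.get(key, key)


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass
class HumanOrganFractionCurve:
    """Decay-uncorrected fraction of injected activity in one human organ."""

    organ: str
    times_min: np.ndarray
    fraction: np.ndarray

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValidationError(f"{self.organ}: times must be strictly increasing")
        if np.any(self.fraction < 0):
            raise ValidationError(f"{self.organ}: fractions must be >= 0")


@dataclass
class ResidenceTime:
    organ: str
    tau_h: float
    trapezoid_h: float
    tail_h: float
    tail_rule: str          # "exp_fit" | "physical_clamp" | "none"
    tail_points: int

    def __post_init__(self):
        if self.tau_h < 0:
            raise ValidationError(f"{self.organ}: tau must be >= 0")


@dataclass
class ResidenceTimeSet:
    """Per-source-organ residence times (MBq·h/MBq = h) plus remainder."""

    organs: dict[str, ResidenceTime]
    remainder_tau_h: float
    nuclide: Radionuclide
    remainder_mode: str = "no_excretion"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        bound = self.nuclide.half_life_min / 60.0 / math.log(2.0)
        total = sum(r.tau_h for r in self.organs.values()) + self.remainder_tau_h
        if total > bound * (1.0 + 0.05):
            raise ValidationError(
                f"total residence time {total:.3f} h exceeds the physical "
                f"no-excretion bound {bound:.3f} h")

    @property
    def total_tau_h(self) -> float:
        return sum(r.tau_h for r in self.organs.values()) + self.remainder_tau_h


@dataclass
class OrganDoseTable:
    """Per-target-organ equivalent dose, mSv/MBq (w_R = 1, so numerically
    mGy/MBq), for one phantom sex."""

    sex: str
    doses_msv_per_mbq: dict[str, float]

    def __post_init__(self):
        for organ, d in self.doses_msv_per_mbq.items():
            if d < 0:
                raise ValidationError(f"dose for {organ!r} must be >= 0")

    def dose(self, organ: str) -> float:
        key = canonical_organ(organ)
        try:
            return self.doses_msv_per_mbq[key]
        except KeyError:
            raise ReferenceLookupError(
                f"no dose for {organ!r} (canonical {key!r}); known: "
                + ", ".join(sorted(self.doses_msv_per_mbq))
            ) from None


@dataclass
class EffectiveDoseResult:
    sex: str
    effective_dose_msv_per_mbq: float
    contributions: dict[str, float]
    remainder_report: dict

    def __post_init__(self):
        total = sum(self.contributions.values())
        if abs(total - self.effective_dose_msv_per_mbq) > 1e-9:
            raise ValidationError("contributions do not sum to the effective dose")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def human_organ_fraction(suv_a: SUVCurve, phantom: Phantom,
                         organ: str | None = None) -> HumanOrganFractionCurve:
    """Scale a decay-uncorrected SUV curve by phantom masses into the
    fraction of injected activity in the human organ.

    Requires the curve to be flagged decay-uncorrected: the physical decay
    must remain in the data for residence-time integration.
    """
    if suv_a.decay_corrected:
        raise StateError(
            f"{suv_a.organ}: human organ fractions require decay-uncorrected "
            "SUVs (SUV_A); got a decay-corrected curve")
    name = canonical_organ(organ or suv_a.organ)
    if name == "gonads":
        name = "testes" if phantom.sex == "male" else "ovaries"
    m_organ = phantom.mass_g(name)
    fraction = suv_a.mean_suv * m_organ / (1000.0 * phantom.body_mass_kg)
    return HumanOrganFractionCurve(organ=name, times_min=suv_a.times_min.copy(),
                                   fraction=fraction)


def _fit_tail(t_h: np.ndarray, f: np.ndarray) -> tuple[float, float]:
    """Log-linear least-squares single-exponential fit; returns (A, k)."""
    if np.any(f <= 0):
        raise ValidationError("tail fit needs positive fractions")
    slope, intercept = np.polyfit(t_h, np.log(f), 1)
    return float(np.exp(intercept)), float(-slope)


def residence_time(curve: HumanOrganFractionCurve, nuclide: Radionuclide,
                   tail_points: int = 3) -> ResidenceTime:
    """Residence time tau (h): trapezoid over the sampled span plus a
    single-exponential tail to infinity.

    (0, 0) is prepended when the curve starts after injection.  The tail
    rate comes from a least-squares single-exponential fit to the last
    ``tail_points`` points; a fitted rate slower than physical decay
    (apparent accumulation, impossible for decay-uncorrected data at
    infinity) is clamped to the physical decay constant, as is any failed
    fit.  An all-zero curve has tau = 0.
    """
    t_h = curve.times_min / 60.0
    f = curve.fraction
    if np.all(f == 0):
        return ResidenceTime(curve.organ, 0.0, 0.0, 0.0, "none", 0)
    if t_h[0] > 0:
        t_h = np.concatenate([[0.0], t_h])
        f = np.concatenate([[0.0], f])
    trapezoid = float(np.trapezoid(f, t_h))

    lam = nuclide.decay_constant_per_hour
    f_last = float(f[-1])
    rule, n_used = "none", 0
    tail = 0.0
    if f_last > 0:
        n_used = min(tail_points, int(np.sum(curve.fraction > 0)))
        try:
            if n_used < 2:
                raise ValidationError("too few positive points for tail fit")
            tt = curve.times_min[-n_used:] / 60.0
            ff = curve.fraction[-n_used:]
            amp, k = _fit_tail(tt, ff)
            if k < lam:
                k = lam
                rule = "physical_clamp"
                tail = f_last / k
            else:
                rule = "exp_fit"
                tail = amp * math.exp(-k * t_h[-1]) / k
        except (ValidationError, np.linalg.LinAlgError) as err:
            log.warning("%s: tail fit failed (%s); physical-decay fallback",
                        curve.organ, err)
            rule = "physical_clamp"
            tail = f_last / lam
    return ResidenceTime(curve.organ, trapezoid + tail, trapezoid, tail,
                         rule, n_used)


def marrow_residence(blood_curve: HumanOrganFractionCurve, phantom: Phantom,
                     nuclide: Radionuclide, rmblr: float = 1.0,
                     tail_points: int = 3) -> ResidenceTime:
    """Red-marrow residence time from the blood-volume model.

    Marrow activity concentration = blood activity concentration * RMBLR
    (red-marrow-to-blood activity concentration ratio, default 1), so the
    marrow fraction curve is blood_fraction * RMBLR * m_marrow / m_blood;
    the ordinary residence-time integration then applies.
    """
    if canonical_organ(blood_curve.organ) != "blood":
        raise ValidationError(
            f"marrow model needs the blood curve, got {blood_curve.organ!r}")
    if rmblr < 0:
        raise ValidationError("RMBLR must be >= 0")
    m_marrow = phantom.mass_g("red_marrow")
    m_blood = phantom.mass_g("blood")
    marrow = HumanOrganFractionCurve(
        organ="red_marrow",
        times_min=blood_curve.times_min.copy(),
        fraction=blood_curve.fraction * rmblr * m_marrow / m_blood,
    )
    return residence_time(marrow, nuclide, tail_points=tail_points)


def remainder_residence(organ_taus: Mapping[str, float], nuclide: Radionuclide,
                        mode: str = "no_excretion",
                        whole_body_tau_h: float | None = None
                        ) -> tuple[float, list[str]]:
    """Residence time of activity not assigned to any source organ.

    ``no_excretion``: T_half/ln2 minus the organ sum (all activity stays in
    the body until it decays).  ``whole_body_curve``: the integrated
    whole-body curve minus the organ sum.  Both clamp at zero with a
    warning when the organ sum already exceeds the reference.
    """
    warnings: list[str] = []
    bound = nuclide.half_life_min / 60.0 / math.log(2.0)
    organ_sum = float(sum(organ_taus.values()))
    if organ_sum > bound * 1.05:
        raise ValidationError(
            f"organ residence times sum to {organ_sum:.3f} h, exceeding the "
            f"physical bound {bound:.3f} h")
    if mode == "no_excretion":
        reference = bound
    elif mode == "whole_body_curve":
        if whole_body_tau_h is None:
            raise ValidationError("whole_body_curve mode needs whole_body_tau_h")
        reference = whole_body_tau_h
    else:
        raise ValueError(f"unknown remainder mode {mode!r}")
    remainder = reference - organ_sum
    if remainder < 0:
        warnings.append(
            f"organ sum {organ_sum:.3f} h exceeds reference {reference:.3f} h; "
            "remainder clamped to 0")
        remainder = 0.0
    return remainder, warnings


def organ_doses(taus: ResidenceTimeSet, s_table: SValueTable) -> OrganDoseTable:
    """MIRD schema: D(target) = sum over sources of tau_source * S(T<-S)."""
    sources = {organ: rt.tau_h for organ, rt in taus.organs.items()}
    if taus.remainder_tau_h > 0:
        sources["rest_of_body"] = sources.get("rest_of_body", 0.0) + taus.remainder_tau_h
    for source, tau in sources.items():
        if tau > 0 and source not in s_table.sources:
            raise ValidationError(
                f"source organ {source!r} (tau={tau:.3g} h) missing from the "
                "S-value table")
    doses = {}
    for target in sorted(s_table.targets):
        doses[target] = float(sum(
            tau * s_table.s(target, source)
            for source, tau in sources.items() if tau > 0
        ))
    return OrganDoseTable(sex=s_table.sex, doses_msv_per_mbq=doses)


def effective_dose(doses: OrganDoseTable, w: TissueWeights,
                   phantom: Phantom) -> EffectiveDoseResult:
    """ICRP-60 effective dose E = sum_T w_T * H_T with the OLINDA-style
    conventions (colon split, esophagus surrogate, split remainder).

    Remainder rule: the remainder organs are pooled by mass-weighted mean
    dose; but when the highest-dosed remainder organ exceeds every named
    tissue's dose, it receives half the remainder weight itself and the
    mass-weighted mean of the *other* remainder organs receives the rest.
    """
    dose_of = doses.doses_msv_per_mbq
    contributions: dict[str, float] = {}

    def named_dose(tissue: str) -> float:
        if tissue == "gonads":
            organ = "testes" if phantom.sex == "male" else "ovaries"
            key = "gonads" if "gonads" in dose_of else organ
        elif tissue == "colon":
            return float(sum(frac * doses.dose(seg)
                             for seg, frac in w.colon_split.items()))
        elif tissue == "esophagus":
            key = "esophagus" if "esophagus" in dose_of else w.esophagus_surrogate
        else:
            key = tissue
        return doses.dose(key)

    for tissue, weight in w.weights.items():
        contributions[tissue] = weight * named_dose(tissue)

    # remainder: organs present in both the phantom's remainder list and
    # the dose table
    remainder = [(o, phantom.mass_g(o), dose_of[canonical_organ(o)])
                 for o in phantom.remainder_organs
                 if canonical_organ(o) in dose_of]
    if not remainder:
        raise ValidationError("no remainder organ doses available")
    named_max = max(named_dose(t) for t in w.weights)
    rem_sorted = sorted(remainder, key=lambda x: x[2], reverse=True)
    top_organ, _top_mass, top_dose = rem_sorted[0]
    split = top_dose > named_max and len(rem_sorted) > 1
    if split:
        rest = rem_sorted[1:]
        rest_mean = (sum(m * d for _o, m, d in rest) / sum(m for _o, m, _d in rest))
        contributions["remainder"] = (
            0.5 * w.remainder_weight * top_dose
            + 0.5 * w.remainder_weight * rest_mean)
        report = {"rule": "split", "highest_organ": top_organ,
                  "highest_dose": top_dose,
                  "organs": [o for o, _m, _d in remainder]}
    else:
        mean = (sum(m * d for _o, m, d in remainder)
                / sum(m for _o, m, _d in remainder))
        contributions["remainder"] = w.remainder_weight * mean
        report = {"rule": "mass_weighted_mean",
                  "organs": [o for o, _m, _d in remainder]}

    e = float(sum(contributions.values()))
    return EffectiveDoseResult(sex=doses.sex, effective_dose_msv_per_mbq=e,
                               contributions=contributions,
                               remainder_report=report)


def load_reported_organ_doses(sex: str) -> OrganDoseTable:
    """Organ equivalent doses (mSv/MBq) reported for the Ga-68 GIPR-targeting
    peptide tracer, extrapolated from rat biodistribution; shipped as a
    worked example and as input to the ICRP-60 effective-dose weighting."""
    if sex not in ("male", "female"):
        raise ValidationError("sex must be 'male' or 'female'")
    path = resources.files("gipet.data").joinpath("ga68_gipr_tracer_organ_doses.csv")
    df = pd.read_csv(str(path))
    col = f"{sex}_mSv_per_MBq"
    doses = {}
    for r in df.itertuples():
        organ = canonical_organ(str(r.tissue))
        if organ == "gonads":
            organ = "testes" if sex == "male" else "ovaries"
        doses[organ] = float(getattr(r, col))
    return OrganDoseTable(sex=sex, doses_msv_per_mbq=doses)


# ---------------------------------------------------------------------------
# end-to-end report
# ---------------------------------------------------------------------------


@dataclass
class DosimetryReport:
    """Full audit trail of one rat-to-human dosimetry run."""

    sex: str
    suv_a_curves: list[SUVCurve]
    fraction_curves: list[HumanOrganFractionCurve]
    residence_times: ResidenceTimeSet
    organ_dose_table: OrganDoseTable
    effective: EffectiveDoseResult

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "suv_a": {c.organ: {"times_min": c.times_min.tolist(),
                                "mean_suv": c.mean_suv.tolist()}
                      for c in self.suv_a_curves},
            "fractions": {c.organ: {"times_min": c.times_min.tolist(),
                                    "fraction": c.fraction.tolist()}
                          for c in self.fraction_curves},
            "residence_times_h": {o: rt.tau_h
                                  for o, rt in self.residence_times.organs.items()},
            "tail_rules": {o: rt.tail_rule
                           for o, rt in self.residence_times.organs.items()},
            "remainder_tau_h": self.residence_times.remainder_tau_h,
            "organ_doses_msv_per_mbq": self.organ_dose_table.doses_msv_per_mbq,
            "effective_dose_msv_per_mbq": self.effective.effective_dose_msv_per_mbq,
            "effective_contributions": self.effective.contributions,
            "remainder_report": self.effective.remainder_report,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def dosimetry_report(ds: Dataset, phantom: Phantom, nuclide: Radionuclide,
                     s_table: SValueTable, weights: TissueWeights,
                     rmblr: float = 1.0, tail_points: int = 3,
                     remainder_mode: str = "no_excretion",
                     group: str | None = "baseline") -> DosimetryReport:
    """End-to-end chain: rat dataset -> SUV_A -> human fractions ->
    residence times (+ marrow blood model, + remainder) -> MIRD organ
    doses -> ICRP-60 effective dose, with every intermediate retained."""
    if group is not None and not any(g == group for g in ds.groups.values()):
        group = None  # ungrouped dataset: use all animals
    suv_a = build_suv_curves(ds, nuclide, decay_corrected=False, group=group)

    fractions: list[HumanOrganFractionCurve] = []
    taus: dict[str, ResidenceTime] = {}
    blood_curve = None
    for curve in suv_a:
        name = canonical_organ(curve.organ)
        if name not in phantom.organ_masses_g and name != "blood":
            log.info("organ %r not in the %s phantom; skipped as a source",
                     curve.organ, phantom.sex)
            continue
        frac = human_organ_fraction(curve, phantom, organ=name)
        fractions.append(frac)
        if name == "blood":
            blood_curve = frac
            continue  # blood itself is not a MIRD source organ here
        taus[name] = residence_time(frac, nuclide, tail_points=tail_points)
    if blood_curve is not None and "red_marrow" not in taus:
        taus["red_marrow"] = marrow_residence(blood_curve, phantom, nuclide,
                                              rmblr=rmblr, tail_points=tail_points)
    remainder, warns = remainder_residence(
        {o: rt.tau_h for o, rt in taus.items()}, nuclide, mode=remainder_mode)
    tau_set = ResidenceTimeSet(organs=taus, remainder_tau_h=remainder,
                               nuclide=nuclide, remainder_mode=remainder_mode,
                               warnings=warns)
    dose_table = organ_doses(tau_set, s_table)
    eff = effective_dose(dose_table, weights, phantom)
    return DosimetryReport(sex=phantom.sex, suv_a_curves=suv_a,
                           fraction_curves=fractions, residence_times=tau_set,
                           organ_dose_table=dose_table, effective=eff)
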