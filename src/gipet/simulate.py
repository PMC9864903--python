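"""Synthetic-data generators emulating each study stage.

Every generator is seed-deterministic (a single seed fans out to
per-generator substreams via :func:`numpy.random.SeedSequence.spawn`) and
returns, next to the dataset, a machine-readable *truth record* holding the
generating parameters and the closed-form quantities every downstream
estimate can be scored against.  With zero noise each analysis stage must
recover its truth exactly (up to integration error of the sampling design).

Default parameter values follow the study designs they emulate: an
8-time-point rat biodistribution with two animals per time point and
monotone kidney accumulation, a subcutaneous plasma profile sampled at
3-240 min with below-LOD censoring, triplicate 7-concentration saturation
assays, internalization time courses at 37 and 4 degrees C, and cell-pellet
autoradiograms with a calibrated reference droplet.  Organ kinetics are
illustrative of the qualitative pattern (fast washout everywhere, kidney
accumulation, liver SUV < 1 after 5 min), not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .binding import (
    Autoradiogram,
    InternalizationTimecourse,
    INTERNALIZATION_TIMES_MIN,
    SATURATION_CONCENTRATIONS_NM,
    SaturationDataset,
)
from .core import (
    Dataset,
    InjectionRecord,
    Radionuclide,
    TimeActivitySample,
    ValidationError,
)
from .pharmacokinetics import DEFAULT_PK_TIMES_MIN, PlasmaProfile

#: biodistribution sampling design: minutes post injection
BIODIST_TIMES_MIN = (5.0, 10.0, 20.0, 40.0, 60.0, 90.0, 120.0, 180.0)


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Substream ``stream`` of the global ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(stream + 1)[stream])


# ---------------------------------------------------------------------------
# biodistribution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrganKinetics:
    """Biological (decay-corrected) fraction-of-injected model for one organ.

    Washout organs: fraction(t) = peak_fraction * normalized
    (exp(-k_washout*t) - exp(-k_uptake_inverse*t)); requires
    k_uptake > k_washout >= 0 (rates per hour).  Kidney-like organs use the
    monotone variant fraction(t) = peak_fraction * (1 - exp(-k_uptake*t)).
    ``rat_organ_mass_g`` converts fractions to SUVs for the rat.
    """

    peak_fraction: float
    k_uptake_per_h: float
    k_washout_per_h: float
    rat_organ_mass_g: float
    monotone: bool = False

    def __post_init__(self):
        if self.monotone:
            if self.k_uptake_per_h <= 0:
                raise ValidationError("monotone uptake needs k_uptake > 0")
        elif not self.k_uptake_per_h > self.k_washout_per_h >= 0:
            raise ValidationError(
                f"washout organ needs k_uptake > k_washout >= 0, got "
                f"{self.k_uptake_per_h}, {self.k_washout_per_h}")
        if not self.peak_fraction > 0 or not self.rat_organ_mass_g > 0:
            raise ValidationError("peak_fraction and organ mass must be > 0")

    def _norm(self) -> float:
        ku, kw = self.k_uptake_per_h, self.k_washout_per_h
        if self.monotone:
            return 1.0
        t_peak = math.log(ku / kw) / (ku - kw) if kw > 0 else math.log(ku) / ku
        if kw == 0:
            # pure uptake-limited: sup is 1
            return 1.0
        return math.exp(-kw * t_peak) - math.exp(-ku * t_peak)

    def fraction(self, t_h) -> np.ndarray:
        """Biological fraction of injected activity at t (hours)."""
        t = np.asarray(t_h, dtype=float)
        ku, kw = self.k_uptake_per_h, self.k_washout_per_h
        if self.monotone:
            return self.peak_fraction * (1.0 - np.exp(-ku * t))
        return self.peak_fraction / self._norm() * (np.exp(-kw * t) - np.exp(-ku * t))

    def integral_uncorrected_h(self, lam_per_h: float) -> float:
        """Closed-form integral over [0, inf) of fraction(t)*exp(-lam*t)."""
        ku, kw = self.k_uptake_per_h, self.k_washout_per_h
        if self.monotone:
            return self.peak_fraction * (1.0 / lam_per_h - 1.0 / (ku + lam_per_h))
        return (self.peak_fraction / self._norm()
                * (1.0 / (kw + lam_per_h) - 1.0 / (ku + lam_per_h)))


#: illustrative rat organ models (rates per hour, masses g for a ~324 g rat)
DEFAULT_RAT_KINETICS: dict[str, OrganKinetics] = {
    "blood": OrganKinetics(0.35, 60.0, 1.6, 19.0),
    "liver": OrganKinetics(0.045, 30.0, 0.45, 12.0),
    "kidneys": OrganKinetics(0.30, 1.2, 0.0, 2.4, monotone=True),
    "heart": OrganKinetics(0.004, 40.0, 1.5, 1.1),
    "lungs": OrganKinetics(0.006, 40.0, 1.4, 1.6),
    "spleen": OrganKinetics(0.002, 30.0, 0.9, 0.8),
    "pancreas": OrganKinetics(0.003, 30.0, 1.0, 1.1),
    "small_intestine": OrganKinetics(0.02, 20.0, 0.8, 7.0),
    "muscle": OrganKinetics(0.10, 15.0, 1.2, 140.0),
}


@dataclass
class BiodistConfig:
    """Study design + noise for the synthetic rat biodistribution."""

    kinetics: Mapping[str, OrganKinetics] = field(
        default_factory=lambda: dict(DEFAULT_RAT_KINETICS))
    times_min: Sequence[float] = BIODIST_TIMES_MIN
    animals_per_time: int = 2
    noise_cv: float = 0.10
    body_weight_g: float = 324.0
    injected_mbq: float = 1.33   # 4.1 MBq/kg at 324 g

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")


@dataclass
class BiodistTruth:
    """Generating parameters plus closed-form integrals for scoring."""

    kinetics: Mapping[str, OrganKinetics]
    #: per organ: integral over [0,inf) of SUV_A(t) dt, hours
    suv_a_integral_h: dict[str, float]
    nuclide: Radionuclide
    body_weight_g: float

    def residence_time_h(self, organ: str, phantom_organ_mass_g: float,
                         phantom_body_mass_kg: float) -> float:
        """Analytic human residence time for this organ and phantom."""
        return (self.suv_a_integral_h[organ] * phantom_organ_mass_g
                / (1000.0 * phantom_body_mass_kg))


def simulate_biodistribution(cfg: BiodistConfig, nuclide: Radionuclide,
                             seed: int, blocked_arm: bool = False,
                             blocked_factor: float = 1.0
                             ) -> tuple[Dataset, BiodistTruth]:
    """Generate gamma-counter samples for the 8-point, 2-animals-per-time
    design with multiplicative lognormal noise.

    Activities are as-counted (decay-uncorrected).  With ``blocked_arm`` an
    extra group of animals at 20 min receives uptake scaled by
    ``blocked_factor`` (1 = no displacement, matching the observed absence
    of blocking in vivo).
    """
    rng = _rng(seed, 0)
    lam = nuclide.decay_constant_per_hour
    sigma = math.sqrt(math.log(1.0 + cfg.noise_cv ** 2))

    injections: dict[str, InjectionRecord] = {}
    samples: list[TimeActivitySample] = []
    groups: dict[str, str] = {}

    def add_animal(animal: str, t_min: float, group: str, factor: float):
        injections[animal] = InjectionRecord(
            animal_id=animal, injected_activity_mbq=cfg.injected_mbq,
            body_weight_g=cfg.body_weight_g)
        groups[animal] = group
        t_h = t_min / 60.0
        for organ, kin in cfg.kinetics.items():
            frac_bio = float(kin.fraction(t_h)) * factor
            activity = cfg.injected_mbq * frac_bio * math.exp(-lam * t_h)
            if cfg.noise_cv > 0:
                activity *= float(rng.lognormal(-0.5 * sigma ** 2, sigma))
            samples.append(TimeActivitySample(
                organ=organ, time_pi_min=t_min, activity_mbq=activity,
                sample_mass_g=kin.rat_organ_mass_g, animal_id=animal,
                decay_corrected=False))

    idx = 0
    for t_min in cfg.times_min:
        for _ in range(cfg.animals_per_time):
            add_animal(f"rat{idx:03d}", t_min, "baseline", 1.0)
            idx += 1
    if blocked_arm:
        for _ in range(cfg.animals_per_time):
            add_animal(f"rat{idx:03d}", 20.0, "blocked", blocked_factor)
            idx += 1

    ds = Dataset(injections=injections, samples=samples, groups=groups,
                 species="rat")
    truth = BiodistTruth(
        kinetics=dict(cfg.kinetics),
        suv_a_integral_h={
            organ: (kin.integral_uncorrected_h(lam)
                    * cfg.body_weight_g / kin.rat_organ_mass_g)
            for organ, kin in cfg.kinetics.items()
        },
        nuclide=nuclide,
        body_weight_g=cfg.body_weight_g,
    )
    return ds, truth


# ---------------------------------------------------------------------------
# plasma PK
# ---------------------------------------------------------------------------


@dataclass
class PKSimConfig:
    """One-compartment, first-order-absorption subcutaneous profile."""

    dose_mg_per_kg: float = 1.0
    t_half_abs_h: float = 0.1
    t_half_el_h: float = 0.38
    clearance_l_per_h_kg: float = 0.73
    lod_ng_per_ml: float = 5.0
    times_min: Sequence[float] = DEFAULT_PK_TIMES_MIN
    noise_cv: float = 0.0

    def __post_init__(self):
        if self.t_half_abs_h <= 0 or self.t_half_el_h <= 0:
            raise ValidationError("half-lives must be positive")
        if abs(self.t_half_abs_h - self.t_half_el_h) < 1e-12:
            raise ValidationError("absorption and elimination half-lives must differ")


@dataclass
class PKTruth:
    t_half_h: float
    auc_inf_h_ng_per_ml: float
    clearance_l_per_h_kg: float

    def conc(self, cfg: PKSimConfig, t_h) -> np.ndarray:
        ka = math.log(2.0) / cfg.t_half_abs_h
        ke = math.log(2.0) / cfg.t_half_el_h
        v_l_per_kg = cfg.clearance_l_per_h_kg / ke
        c0 = cfg.dose_mg_per_kg * 1e6 / (v_l_per_kg * 1e3)  # ng/mL
        t = np.asarray(t_h, dtype=float)
        return c0 * ka / (ka - ke) * (np.exp(-ke * t) - np.exp(-ka * t))


def simulate_plasma_pk(cfg: PKSimConfig, seed: int) -> tuple[PlasmaProfile, PKTruth]:
    """Sample the closed-form absorption model at the design times.

    Values below the LOD are censored: assigned zero and flagged, the
    study's own reporting convention.  The truth record carries the
    analytic AUC_inf = dose/CL and the terminal (elimination) half-life.
    """
    rng = _rng(seed, 1)
    truth = PKTruth(
        t_half_h=cfg.t_half_el_h,
        auc_inf_h_ng_per_ml=cfg.dose_mg_per_kg * 1000.0 / cfg.clearance_l_per_h_kg,
        clearance_l_per_h_kg=cfg.clearance_l_per_h_kg,
    )
    t_min = np.asarray(cfg.times_min, dtype=float)
    conc = truth.conc(cfg, t_min / 60.0)
    if cfg.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + cfg.noise_cv ** 2))
        conc = conc * rng.lognormal(-0.5 * sigma ** 2, sigma, size=conc.shape)
    censored = conc < cfg.lod_ng_per_ml
    conc = np.where(censored, 0.0, conc)
    profile = PlasmaProfile(times_min=t_min, conc_ng_per_ml=conc,
                            dose_mg_per_kg=cfg.dose_mg_per_kg,
                            censored=censored, lod_ng_per_ml=cfg.lod_ng_per_ml,
                            route="sc")
    return profile, truth


# ---------------------------------------------------------------------------
# saturation binding & internalization
# ---------------------------------------------------------------------------


@dataclass
class AssaySimConfig:
    """One-site binding + internalization generating parameters."""

    kd_nm: float = 18.3
    bmax_pmol_per_mcells: float = 2.4
    ns_slope: float = 0.002       # (pmol/Mcells)/nM linear non-specific term
    noise_cv: float = 0.10
    concentrations_nm: Sequence[float] = SATURATION_CONCENTRATIONS_NM
    replicates: int = 3
    # internalization kinetics (per hour)
    k_bind_per_h: float = 3.0          # approach of surface binding to plateau
    surface_plateau_pct_id: float = 45.0
    k_int_per_h_37c: float = 0.7       # surface -> internalized at 37 C
    k_int_per_h_4c: float = 0.0        # suppressed on ice

    def __post_init__(self):
        if self.kd_nm <= 0 or self.bmax_pmol_per_mcells <= 0:
            raise ValidationError("Kd and Bmax must be positive")
        if self.noise_cv < 0 or self.ns_slope < 0:
            raise ValidationError("noise_cv and ns_slope must be >= 0")
        if self.k_int_per_h_4c > self.k_int_per_h_37c:
            raise ValidationError("4 C internalization rate cannot exceed 37 C rate")
        if min(self.k_bind_per_h, self.k_int_per_h_37c, self.k_int_per_h_4c) < 0:
            raise ValidationError("rates must be >= 0")


def simulate_saturation_assay(cfg: AssaySimConfig, seed: int
                              ) -> tuple[SaturationDataset, dict]:
    """Total = one-site hyperbola + linear NS + proportional Gaussian noise;
    the non-specific arm (receptor blocked) is the NS line + noise."""
    rng = _rng(seed, 2)
    c = np.asarray(cfg.concentrations_nm, dtype=float)
    specific = cfg.bmax_pmol_per_mcells * c / (cfg.kd_nm + c)
    ns = cfg.ns_slope * c

    def noisy(mean: np.ndarray) -> np.ndarray:
        base = np.repeat(mean[:, None], cfg.replicates, axis=1)
        if cfg.noise_cv == 0:
            return base
        out = base * (1.0 + cfg.noise_cv * rng.standard_normal(base.shape))
        return np.clip(out, 0.0, None)

    ds = SaturationDataset(
        concentrations_nm=c,
        total_bound=noisy(specific + ns),
        nonspecific_bound=noisy(ns),
        temperature_c=4.0,
    )
    truth = {"kd_nm": cfg.kd_nm, "bmax_pmol_per_mcells": cfg.bmax_pmol_per_mcells,
             "ns_slope": cfg.ns_slope, "specific_curve": specific}
    return ds, truth


def _internalization_model(cfg: AssaySimConfig, k_int: float, t_h: np.ndarray
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Surface/internalized solution of dS/dt = kb*(P - S) - ki*S,
    dI/dt = ki*S with S(0) = I(0) = 0."""
    kb, plateau = cfg.k_bind_per_h, cfg.surface_plateau_pct_id
    k_tot = kb + k_int
    s_eq = kb * plateau / k_tot if k_tot > 0 else 0.0
    surface = s_eq * (1.0 - np.exp(-k_tot * t_h))
    if k_int == 0:
        internal = np.zeros_like(t_h)
    else:
        internal = k_int * s_eq * (t_h + (np.exp(-k_tot * t_h) - 1.0) / k_tot)
    return surface, internal


def simulate_internalization(cfg: AssaySimConfig, seed: int
                             ) -> tuple[InternalizationTimecourse,
                                        InternalizationTimecourse, dict]:
    """Two time courses (37 C and 4 C) of the surface <-> internalized
    kinetics at the design times; at 4 C internalization is suppressed."""
    rng = _rng(seed, 3)
    t_min = np.asarray(INTERNALIZATION_TIMES_MIN, dtype=float)
    t_h = t_min / 60.0
    out = []
    for temp, k_int in ((37.0, cfg.k_int_per_h_37c), (4.0, cfg.k_int_per_h_4c)):
        surface, internal = _internalization_model(cfg, k_int, t_h)
        if cfg.noise_cv > 0:
            surface = np.clip(
                surface * (1 + cfg.noise_cv * rng.standard_normal(surface.shape)),
                0, None)
            internal = np.clip(
                internal * (1 + cfg.noise_cv * rng.standard_normal(internal.shape)),
                0, None)
        out.append(InternalizationTimecourse(
            times_min=t_min, membrane_pct_id=surface,
            internalized_pct_id=internal, temperature_c=temp))
    truth = {"k_int_per_h": {37.0: cfg.k_int_per_h_37c, 4.0: cfg.k_int_per_h_4c},
             "k_bind_per_h": cfg.k_bind_per_h,
             "surface_plateau_pct_id": cfg.surface_plateau_pct_id}
    return out[0], out[1], truth


# ---------------------------------------------------------------------------
# autoradiogram
# ---------------------------------------------------------------------------


def simulate_autoradiogram(pellet_densities_fmol_per_mm2: Mapping[str, float],
                           molar_activity_bq_per_fmol: float = 59.8,
                           reference_activity_bq: float = 100.0,
                           exposure_factor: float = 50.0,
                           pixel_size_mm: float = 0.5,
                           background_counts: float = 2.0,
                           seed: int = 0,
                           poisson: bool = True
                           ) -> tuple[Autoradiogram, dict]:
    """Pixel grid with one square pellet ROI per entry plus a reference
    droplet of known activity.

    Expected counts per pixel are density * molar activity * exposure
    factor * pixel area (+ flat background); Poisson sampling unless
    ``poisson=False`` (noise-free expectation grid).  Doubling the exposure
    factor doubles all counts including the reference, so calibrated
    Bq/mm2 is exposure-invariant.
    """
    for name, d in pellet_densities_fmol_per_mm2.items():
        if d < 0:
            raise ValidationError(f"density for {name!r} must be >= 0")
    rng = _rng(seed, 4)
    n_pellets = len(pellet_densities_fmol_per_mm2)
    size = 12
    width = (n_pellets + 1) * (size + 4) + 4
    grid = np.full((size + 8, width), float(background_counts))
    rois: dict[str, np.ndarray] = {}
    area = pixel_size_mm ** 2

    # reference droplet occupies the first block; its *known activity* is
    # reference_activity_bq spread uniformly over the ROI
    x0 = 4
    ref_mask = np.zeros_like(grid, dtype=bool)
    ref_mask[4:4 + size, x0:x0 + size] = True
    ref_area = ref_mask.sum() * area
    ref_bq_per_mm2 = reference_activity_bq / ref_area
    grid[ref_mask] += ref_bq_per_mm2 * exposure_factor * area
    rois["reference"] = ref_mask
    x0 += size + 4

    bg_mask = np.zeros_like(grid, dtype=bool)
    bg_mask[0:2, :] = True  # top margin carries background only
    rois["background"] = bg_mask

    truth_bq = {}
    for name, density in pellet_densities_fmol_per_mm2.items():
        mask = np.zeros_like(grid, dtype=bool)
        mask[4:4 + size, x0:x0 + size] = True
        bq_per_mm2 = density * molar_activity_bq_per_fmol
        grid[mask] += bq_per_mm2 * exposure_factor * area
        rois[name] = mask
        truth_bq[name] = bq_per_mm2
        x0 += size + 4

    counts = rng.poisson(grid).astype(float) if poisson else grid
    img = Autoradiogram(
        counts=counts, pixel_size_mm=pixel_size_mm, rois=rois,
        reference_roi="reference", reference_activity_bq=reference_activity_bq,
        molar_activity_bq_per_fmol=molar_activity_bq_per_fmol)
    truth = {"densities_fmol_per_mm2": dict(pellet_densities_fmol_per_mm2),
             "bq_per_mm2": truth_bq,
             "background_counts": background_counts}
    return img, truth
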