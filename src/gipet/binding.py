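"""In vitro pharmacology: saturation binding, internalization,
autoradiography calibration and potency/selectivity ratios.

Saturation binding follows the one-site model B(C) = Bmax*C/(Kd + C) fitted
to specific binding (total minus the blocked, non-specific arm).  Kd is the
equilibrium dissociation constant in nM, Bmax the binding-site density in
pmol per million cells.  Autoradiograms are calibrated through a co-exposed
reference droplet of known activity and the molar activity of the tracer:
counts/mm2 -> Bq/mm2 -> fmol/mm2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import (
    AlignmentError,
    FitError,
    ReferenceLookupError,
    ValidationError,
)

log = logging.getLogger(__name__)

#: concentration ladder of the saturation assay design (nM)
SATURATION_CONCENTRATIONS_NM = (0.3, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0)
#: sampling times of the internalization time course (min)
INTERNALIZATION_TIMES_MIN = (0.0, 30.0, 60.0, 90.0, 120.0)


@dataclass
class SaturationDataset:
    """Triplicate total / non-specific binding over a concentration ladder.

    ``total_bound`` and ``nonspecific_bound`` are (n_conc, n_replicates)
    arrays in pmol per million cells.
    """

    concentrations_nm: np.ndarray
    total_bound: np.ndarray
    nonspecific_bound: np.ndarray
    temperature_c: float = 4.0

    def __post_init__(self):
        self.concentrations_nm = np.asarray(self.concentrations_nm, dtype=float)
        self.total_bound = np.atleast_2d(np.asarray(self.total_bound, dtype=float))
        self.nonspecific_bound = np.atleast_2d(
            np.asarray(self.nonspecific_bound, dtype=float))
        if np.any(self.concentrations_nm <= 0):
            raise ValidationError("concentrations must be positive")
        if np.any(np.diff(self.concentrations_nm) <= 0):
            raise ValidationError("concentrations must be strictly increasing")
        for arr, name in ((self.total_bound, "total"),
                          (self.nonspecific_bound, "nonspecific")):
            if arr.shape[0] != self.concentrations_nm.size:
                raise AlignmentError(
                    f"{name} bound rows ({arr.shape[0]}) != concentrations "
                    f"({self.concentrations_nm.size})")
            if arr.shape[1] < 1:
                raise ValidationError(f"{name} bound needs >= 1 replicate")


@dataclass
class BindingFit:
    kd_nm: float
    bmax_pmol_per_mcells: float
    kd_se: float
    bmax_se: float
    ns_slope: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.kd_nm > 0:
            raise ValidationError(f"Kd must be > 0, got {self.kd_nm}")
        if not self.bmax_pmol_per_mcells > 0:
            raise ValidationError(f"Bmax must be > 0, got {self.bmax_pmol_per_mcells}")

    def predict(self, conc_nm) -> np.ndarray:
        c = np.asarray(conc_nm, dtype=float)
        b = self.bmax_pmol_per_mcells * c / (self.kd_nm + c)
        if self.ns_slope is not None:
            b = b + self.ns_slope * c
        return b


@dataclass
class InternalizationTimecourse:
    """Membrane-bound and internalized fractions, %ID per million cells."""

    times_min: np.ndarray
    membrane_pct_id: np.ndarray
    internalized_pct_id: np.ndarray
    temperature_c: float
    internalized_share: np.ndarray | None = None  # of total; nan = undefined

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.membrane_pct_id = np.asarray(self.membrane_pct_id, dtype=float)
        self.internalized_pct_id = np.asarray(self.internalized_pct_id, dtype=float)
        if np.any(self.membrane_pct_id < 0) or np.any(self.internalized_pct_id < 0):
            raise ValidationError("fractions must be >= 0")

    @property
    def total_pct_id(self) -> np.ndarray:
        return self.membrane_pct_id + self.internalized_pct_id


@dataclass
class Autoradiogram:
    """A pixel grid of exposure counts with labeled ROIs and a calibrated
    reference droplet of known activity."""

    counts: np.ndarray               # counts per pixel
    pixel_size_mm: float
    rois: Mapping[str, np.ndarray]   # label -> boolean pixel mask
    reference_roi: str
    reference_activity_bq: float
    molar_activity_bq_per_fmol: float

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0):
            raise ValidationError("counts must be >= 0")
        if self.reference_roi not in self.rois:
            raise ValidationError(f"reference ROI {self.reference_roi!r} missing")
        if not np.any(self.rois[self.reference_roi]):
            raise ValidationError("reference ROI is empty")
        if not self.molar_activity_bq_per_fmol > 0:
            raise ValidationError("molar activity must be > 0")

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_size_mm ** 2


@dataclass(frozen=True)
class PotencyTable:
    """EC50 values in pM indexed by (compound, receptor, species)."""

    ec50_pm: Mapping[tuple[str, str, str], float]

    def __post_init__(self):
        for key, v in self.ec50_pm.items():
            if not v > 0:
                raise ValidationError(f"EC50 for {key} must be > 0, got {v}")

    def lookup(self, compound: str, receptor: str, species: str) -> float:
        try:
            return self.ec50_pm[(compound, receptor, species)]
        except KeyError:
            raise ReferenceLookupError(
                f"no EC50 for ({compound!r}, {receptor!r}, {species!r})"
            ) from None


def load_builtin_potency_table() -> PotencyTable:
    """EC50 table (pM) of the GIPR-targeting peptide and its Ga-loaded
    analog against the GIPR, GLP-1R and GCGR in three species, as reported
    in the functional cAMP assay."""
    path = resources.files("gipet.data").joinpath("gipr_tracer_potency_ec50_pm.csv")
    df = pd.read_csv(str(path))
    return PotencyTable(ec50_pm={
        (str(r.compound), str(r.receptor), str(r.species)): float(r.ec50_pM)
        for r in df.itertuples()
    })


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def specific_binding(total, nonspecific,
                     clamp_negative: bool = True) -> tuple[np.ndarray, int]:
    """Specific = total - non-specific, elementwise on a shared grid.

    Negative differences (noise) are clamped to 0; the count of clamped
    points is returned alongside.
    """
    total = np.asarray(total, dtype=float)
    nonspecific = np.asarray(nonspecific, dtype=float)
    if total.shape != nonspecific.shape:
        raise AlignmentError(
            f"total shape {total.shape} != nonspecific shape {nonspecific.shape}")
    spec = total - nonspecific
    n_clamped = 0
    if clamp_negative:
        n_clamped = int(np.sum(spec < 0))
        if n_clamped:
            log.warning("specific binding: clamped %d negative points to 0", n_clamped)
        spec = np.clip(spec, 0.0, None)
    return spec, n_clamped


def _one_site(c, bmax, kd):
    return bmax * c / (kd + c)


def _one_site_ns(c, bmax, kd, ns):
    return bmax * c / (kd + c) + ns * c


def saturation_fit(ds: SaturationDataset, fit_ns_term: bool = False) -> BindingFit:
    """Least-squares one-site fit of specific binding.

    Default: specific binding = mean(total) - mean(nonspecific) per
    concentration, fitted to Bmax*C/(Kd+C).  With ``fit_ns_term`` the mean
    total binding is fitted directly to a hyperbola plus a free linear
    non-specific term (for datasets lacking a blocking arm).

    Starting values are data-driven and deterministic: Bmax0 = max specific
    bound; Kd0 = concentration at half of Bmax0 by linear interpolation.
    """
    if ds.concentrations_nm.size < 4:
        raise ValidationError("saturation fit needs >= 4 distinct concentrations")
    c = ds.concentrations_nm
    total_mean = ds.total_bound.mean(axis=1)
    ns_mean = ds.nonspecific_bound.mean(axis=1)
    warnings: list[str] = []

    if fit_ns_term:
        y = total_mean
        bmax0 = float(max(y.max(), 1e-12))
        kd0 = _half_max_conc(c, y, bmax0)
        try:
            popt, pcov = curve_fit(_one_site_ns, c, y, p0=[bmax0, kd0, 0.0],
                                   maxfev=20000)
        except RuntimeError as err:
            raise FitError(f"saturation fit did not converge: {err}",
                           {"p0": [bmax0, kd0, 0.0]}) from None
        bmax, kd, ns = popt
        bmax_se, kd_se = np.sqrt(np.abs(np.diag(pcov)))[:2]
    else:
        y, n_clamped = specific_binding(total_mean, ns_mean)
        if n_clamped:
            warnings.append(f"{n_clamped} negative specific points clamped")
        bmax0 = float(max(y.max(), 1e-12))
        kd0 = _half_max_conc(c, y, bmax0)
        try:
            popt, pcov = curve_fit(_one_site, c, y, p0=[bmax0, kd0], maxfev=20000)
        except RuntimeError as err:
            raise FitError(f"saturation fit did not converge: {err}",
                           {"p0": [bmax0, kd0]}) from None
        bmax, kd = popt
        bmax_se, kd_se = np.sqrt(np.abs(np.diag(pcov)))
        ns = None

    if not (c.min() / 100.0 <= kd <= c.max() * 100.0):
        warnings.append(
            f"fitted Kd {kd:.3g} nM lies far outside the assayed range "
            f"[{c.min()}, {c.max()}] nM; extrapolation")
    return BindingFit(kd_nm=float(kd), bmax_pmol_per_mcells=float(bmax),
                      kd_se=float(kd_se), bmax_se=float(bmax_se),
                      ns_slope=None if ns is None else float(ns),
                      warnings=warnings)


def _half_max_conc(c: np.ndarray, y: np.ndarray, bmax0: float) -> float:
    """Concentration at half of bmax0, by interpolation on the measured curve."""
    half = bmax0 / 2.0
    if y[0] >= half:
        return float(c[0])
    idx = np.searchsorted(y, half)
    if idx >= c.size:
        return float(c[-1])
    lo, hi = idx - 1, idx
    if y[hi] == y[lo]:
        return float(c[hi])
    frac = (half - y[lo]) / (y[hi] - y[lo])
    return float(c[lo] + frac * (c[hi] - c[lo]))


def internalization_fractions(times_min, membrane_counts, internalized_counts,
                              standard_counts: float, cell_count: float = 1e6,
                              temperature_c: float = 37.0
                              ) -> InternalizationTimecourse:
    """Express acid-wash (membrane) and lysate (internalized) counts as
    %ID per million cells, with the internalized share of total binding.

    ``standard_counts`` is the counted added-dose standard; the share is
    NaN (undefined) at times where total binding is zero.
    """
    if not standard_counts > 0:
        raise ValidationError("added-dose standard counts must be > 0")
    if not cell_count > 0:
        raise ValidationError("cell count must be > 0")
    times = np.asarray(times_min, dtype=float)
    mem = np.asarray(membrane_counts, dtype=float)
    internal = np.asarray(internalized_counts, dtype=float)
    if not (times.shape == mem.shape == internal.shape):
        raise AlignmentError("times, membrane and internalized must align")
    scale = 100.0 / standard_counts / (cell_count / 1e6)
    mem_pct = mem * scale
    int_pct = internal * scale
    total = mem_pct + int_pct
    with np.errstate(invalid="ignore", divide="ignore"):
        share = np.where(total > 0, 100.0 * int_pct / np.where(total > 0, total, 1.0),
                         np.nan)
    return InternalizationTimecourse(
        times_min=times, membrane_pct_id=mem_pct, internalized_pct_id=int_pct,
        temperature_c=temperature_c, internalized_share=share)


def arg_quantify(img: Autoradiogram, roi: str,
                 background_roi: str | None = None) -> dict[str, float]:
    """Quantify an autoradiogram ROI in Bq/mm2 and fmol/mm2.

    counts/mm2 in the ROI are scaled by (reference activity / reference
    counts) and divided by the molar activity.  An optional background ROI
    is subtracted in counts/mm2 before calibration.
    """
    if roi not in img.rois:
        raise ReferenceLookupError(f"ROI {roi!r} not in {sorted(img.rois)}")
    ref_mask = img.rois[img.reference_roi]
    ref_counts = float(img.counts[ref_mask].sum())
    if ref_counts == 0:
        raise ValidationError("reference ROI has zero counts; cannot calibrate")
    bq_per_count = img.reference_activity_bq / ref_counts

    mask = img.rois[roi]
    counts_per_mm2 = float(img.counts[mask].mean()) / img.pixel_area_mm2
    if background_roi is not None:
        bg_mask = img.rois[background_roi]
        counts_per_mm2 -= float(img.counts[bg_mask].mean()) / img.pixel_area_mm2
        counts_per_mm2 = max(counts_per_mm2, 0.0)
    bq_per_mm2 = counts_per_mm2 * bq_per_count
    return {
        "counts_per_mm2": counts_per_mm2,
        "bq_per_mm2": bq_per_mm2,
        "fmol_per_mm2": bq_per_mm2 / img.molar_activity_bq_per_fmol,
    }


def percent_inhibition(baseline_uptake: float, blocked_uptake: float) -> float:
    """100 * (1 - blocked/baseline); the blocking percentage convention."""
    if not baseline_uptake > 0:
        raise ValidationError("baseline uptake must be > 0")
    return 100.0 * (1.0 - blocked_uptake / baseline_uptake)


def selectivity_ratio(pt: PotencyTable, compound: str, species: str,
                      target_receptor: str, offtarget_receptor: str) -> float:
    """Fold selectivity = EC50(off-target) / EC50(target)."""
    target = pt.lookup(compound, target_receptor, species)
    off = pt.lookup(compound, offtarget_receptor, species)
    return off / target
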