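"""Ex vivo biodistribution analysis: standardized uptake values, per-organ
time courses, tissue ratios and blocking statistics.

The standardized uptake value is the tissue activity concentration
normalized by injected activity per body mass,

    SUV = (A_tissue / m_tissue) / (A_injected / m_body),

dimensionless, so that a tissue holding the whole-body average
concentration has SUV = 1.  Activities may be decay-corrected to injection
time (the convention for reporting organ distributions) or left as counted
(the convention for residence-time integration); the flag is explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .core import (
    AlignmentError,
    Dataset,
    InjectionRecord,
    Radionuclide,
    StateError,
    TimeActivitySample,
    ValidationError,
    decay_transform,
)


@dataclass
class SUVCurve:
    """Per-organ mean +/- SD SUV versus time post injection."""

    organ: str
    times_min: np.ndarray
    mean_suv: np.ndarray
    sd_suv: np.ndarray
    n: np.ndarray
    decay_corrected: bool

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.mean_suv = np.asarray(self.mean_suv, dtype=float)
        self.sd_suv = np.asarray(self.sd_suv, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValidationError(f"{self.organ}: times must be strictly increasing")
        if np.any(self.n < 1):
            raise ValidationError(f"{self.organ}: n must be >= 1 at every time")
        if np.any(self.sd_suv < 0):
            raise ValidationError(f"{self.organ}: sd_suv must be >= 0")


@dataclass
class RatioCurve:
    """Elementwise ratio of two SUV curves on a shared time grid."""

    name: str
    times_min: np.ndarray
    ratio: np.ndarray
    defined: np.ndarray  # False where the denominator was zero


@dataclass
class BlockingResult:
    """Displacement of uptake by co-injected unlabeled ligand."""

    organ: str
    mean_baseline: float
    mean_blocked: float
    percent_block: float
    p_value: float
    f_statistic: float = math.nan
    multiple_testing_correction: str = "none"

    def __post_init__(self):
        if self.percent_block > 100 + 1e-12:
            raise ValidationError("percent_block cannot exceed 100")
        if not (0 <= self.p_value <= 1):
            raise ValidationError("p_value must lie in [0, 1]")


def compute_suv(sample: TimeActivitySample, inj: InjectionRecord,
                nuclide: Radionuclide, decay_corrected: bool = True) -> float:
    """Eq.-style SUV for one sample, in the requested decay state."""
    if sample.animal_id != inj.animal_id:
        raise ValidationError(
            f"sample animal {sample.animal_id!r} != injection animal {inj.animal_id!r}"
        )
    activity = sample.activity_mbq
    if decay_corrected and not sample.decay_corrected:
        activity = decay_transform(activity, sample.time_pi_min, nuclide, "correct")
    elif not decay_corrected and sample.decay_corrected:
        activity = decay_transform(activity, sample.time_pi_min, nuclide, "uncorrect")
    conc_tissue = activity / sample.sample_mass_g
    conc_body = inj.injected_activity_mbq / inj.body_weight_g
    return conc_tissue / conc_body


def build_suv_curves(ds: Dataset, nuclide: Radionuclide,
                     decay_corrected: bool = True,
                     group: str | None = None) -> list[SUVCurve]:
    """Per-organ mean and SD SUV over animals at each sampled time.

    SD uses the n-1 (sample) convention; a single animal yields SD = 0 with
    n = 1 so the sampling design stays visible.
    """
    states = {s.decay_corrected for s in ds.samples}
    if len(states) > 1:
        raise StateError("dataset mixes decay-corrected and uncorrected samples")
    curves = []
    for organ in ds.organs:
        times, means, sds, ns = [], [], [], []
        for t in ds.times_min:
            samples = ds.samples_for(organ, t, group=group)
            if not samples:
                continue
            suvs = [
                compute_suv(s, ds.injections[s.animal_id], nuclide, decay_corrected)
                for s in samples
            ]
            times.append(t)
            means.append(float(np.mean(suvs)))
            sds.append(float(np.std(suvs, ddof=1)) if len(suvs) > 1 else 0.0)
            ns.append(len(suvs))
        if times:
            curves.append(SUVCurve(organ, np.array(times), np.array(means),
                                   np.array(sds), np.array(ns), decay_corrected))
    return curves


def tissue_ratio(curve_a: SUVCurve, curve_b: SUVCurve) -> RatioCurve:
    """Elementwise curve_a / curve_b, e.g. liver-to-blood.

    The grids must match exactly; no implicit interpolation.  Times where
    the denominator is zero are flagged undefined, not returned as inf.
    """
    if (len(curve_a.times_min) != len(curve_b.times_min)
            or np.any(curve_a.times_min != curve_b.times_min)):
        raise AlignmentError(
            f"time grids of {curve_a.organ!r} and {curve_b.organ!r} differ"
        )
    defined = curve_b.mean_suv != 0
    ratio = np.full_like(curve_a.mean_suv, np.nan)
    ratio[defined] = curve_a.mean_suv[defined] / curve_b.mean_suv[defined]
    return RatioCurve(name=f"{curve_a.organ}/{curve_b.organ}",
                      times_min=curve_a.times_min.copy(), ratio=ratio,
                      defined=defined)


def one_way_anova(*groups: Sequence[float]) -> tuple[float, float]:
    """One-way ANOVA F statistic and p value across any number of groups.

    For two groups this reduces to the two-sample t-test (F = t^2).
    Degenerate inputs (zero within-group variance everywhere) return
    F = inf/nan as scipy defines them; identical groups yield p = 1.
    """
    f, p = stats.f_oneway(*[np.asarray(g, dtype=float) for g in groups])
    return float(f), float(p)


def blocking_effect(baseline: Sequence[float], blocked: Sequence[float],
                    organ: str = "") -> BlockingResult:
    """Percent displacement of uptake with an ANOVA group comparison.

    percent_block = 100 * (1 - mean_blocked / mean_baseline).  No multiple
    testing correction is applied across organs; the result says so.
    """
    baseline = np.asarray(baseline, dtype=float)
    blocked = np.asarray(blocked, dtype=float)
    if baseline.size == 0 or blocked.size == 0:
        raise ValidationError("both groups must be non-empty")
    mean_base = float(np.mean(baseline))
    mean_blk = float(np.mean(blocked))
    if mean_base == 0:
        raise ValidationError("mean baseline SUV is 0; percent block undefined")
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = one_way_anova(baseline, blocked)
    if math.isnan(p):  # zero variance in both groups
        p = 1.0 if mean_base == mean_blk else 0.0
    return BlockingResult(
        organ=organ,
        mean_baseline=mean_base,
        mean_blocked=mean_blk,
        percent_block=100.0 * (1.0 - mean_blk / mean_base),
        p_value=min(max(p, 0.0), 1.0),
        f_statistic=f,
    )
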