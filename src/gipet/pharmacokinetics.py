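"""Non-compartmental analysis of plasma concentration-time profiles.

Implements the three quantities a first-in-animal PK section reports for a
subcutaneously dosed peptide: terminal half-life from log-linear regression,
AUC extrapolated to infinity by linear trapezoid plus a terminal-slope tail,
and plasma clearance CL = dose / AUC_inf.

Below-LOD handling follows the unusual but explicit study convention of
assigning censored points the value zero: in the default mode those zeros
enter the trapezoid as observed data and no exponential tail is added
beyond a trailing zero.  An alternative mode excludes censored points and
extrapolates from the last positive observation; results are labeled with
the mode used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import FitError, ValidationError

#: default sampling design of the subcutaneous rat PK study (minutes)
DEFAULT_PK_TIMES_MIN = (3.0, 6.0, 9.6, 19.8, 30.0, 60.0, 120.0, 240.0)


@dataclass
class PlasmaProfile:
    """A plasma concentration-time profile from one dosing route."""

    times_min: np.ndarray
    conc_ng_per_ml: np.ndarray
    dose_mg_per_kg: float
    censored: np.ndarray | None = None  # True where below LOD (assigned 0)
    lod_ng_per_ml: float | None = None
    route: str = "sc"

    def __post_init__(self):
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.conc_ng_per_ml = np.asarray(self.conc_ng_per_ml, dtype=float)
        if self.censored is None:
            self.censored = np.zeros(self.times_min.shape, dtype=bool)
        else:
            self.censored = np.asarray(self.censored, dtype=bool)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.conc_ng_per_ml < 0):
            raise ValidationError("concentrations must be >= 0")
        if not self.dose_mg_per_kg > 0:
            raise ValidationError("dose must be > 0")


@dataclass
class HalfLifeResult:
    t_half_h: float
    slope_per_h: float
    intercept_ln: float
    r_squared: float
    points_used: int
    window_min: tuple[float, float]


@dataclass
class AUCResult:
    auc_h_ng_per_ml: float
    extrapolated_fraction: float
    auc_observed: float
    auc_tail: float
    censored_mode: str
    warnings: list[str] = field(default_factory=list)


@dataclass
class PKResult:
    t_half_h: float
    auc_inf_h_ng_per_ml: float
    clearance_l_per_h_kg: float
    terminal_points_used: int
    extrapolated_fraction: float


def terminal_half_life(profile: PlasmaProfile,
                       window_min: tuple[float, float] | None = None,
                       n_points: int = 3) -> HalfLifeResult:
    """Terminal half-life from least-squares regression of ln C on t.

    The regression window is either an explicit [t0, t1] range in minutes
    or, by default, the last ``n_points`` positive uncensored points.
    Censored/zero concentrations never enter the regression.
    """
    usable = (~profile.censored) & (profile.conc_ng_per_ml > 0)
    t = profile.times_min[usable]
    c = profile.conc_ng_per_ml[usable]
    if window_min is not None:
        in_win = (t >= window_min[0]) & (t <= window_min[1])
        t, c = t[in_win], c[in_win]
    else:
        t, c = t[-n_points:], c[-n_points:]
    if t.size < 2:
        raise FitError(f"terminal fit needs >= 2 usable points, got {t.size}")
    t_h = t / 60.0
    slope, intercept = np.polyfit(t_h, np.log(c), 1)
    if slope >= -1e-12:  # flat profiles regress to ~0 within rounding
        raise FitError("no terminal decline: regression slope is non-negative",
                       {"slope_per_h": float(slope)})
    pred = slope * t_h + intercept
    ss_res = float(np.sum((np.log(c) - pred) ** 2))
    ss_tot = float(np.sum((np.log(c) - np.mean(np.log(c))) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return HalfLifeResult(
        t_half_h=math.log(2.0) / abs(slope),
        slope_per_h=float(slope),
        intercept_ln=float(intercept),
        r_squared=r2,
        points_used=int(t.size),
        window_min=(float(t.min()), float(t.max())),
    )


def auc_trapezoid(times_h, conc) -> float:
    """Linear-trapezoid area under (times, conc); additive over subintervals."""
    return float(np.trapezoid(np.asarray(conc, float), np.asarray(times_h, float)))


def auc_inf(profile: PlasmaProfile,
            tail_rule: str = "terminal_slope",
            censored_mode: str = "zero_observed",
            terminal_kwargs: dict | None = None) -> AUCResult:
    """AUC to infinity: linear trapezoid plus C_last / k_terminal tail.

    For extravascular dosing (0, 0) is prepended when the profile does not
    start at t = 0.  ``censored_mode``:

    - ``"zero_observed"`` (default, the study convention): assigned-zero
      censored points participate in the trapezoid as real observations;
      if the profile ends on such a zero no tail is added.
    - ``"exclude_extrapolate"``: censored points are dropped and the tail
      is extrapolated from the last positive point.
    """
    if tail_rule != "terminal_slope":
        raise ValueError(f"unknown tail_rule {tail_rule!r}")
    if censored_mode not in ("zero_observed", "exclude_extrapolate"):
        raise ValueError(f"unknown censored_mode {censored_mode!r}")
    warnings: list[str] = []

    t = profile.times_min / 60.0  # hours
    c = profile.conc_ng_per_ml.copy()
    if censored_mode == "exclude_extrapolate":
        keep = ~profile.censored
        t, c = t[keep], c[keep]
    if t.size == 0 or np.all(c == 0):
        return AUCResult(0.0, 0.0, 0.0, 0.0, censored_mode,
                         ["all-zero profile: AUC is 0"])
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[0.0], c])
    auc_obs = auc_trapezoid(t, c)

    tail = 0.0
    if c[-1] > 0:
        tkw = dict(terminal_kwargs or {})
        try:
            hl = terminal_half_life(profile, **tkw)
            k = abs(hl.slope_per_h)
            tail = float(c[-1]) / k
        except FitError as err:
            warnings.append(f"no tail added: {err}")
    elif censored_mode == "zero_observed":
        warnings.append("profile ends on an assigned-zero point; no tail added")

    total = auc_obs + tail
    return AUCResult(
        auc_h_ng_per_ml=total,
        extrapolated_fraction=tail / total if total > 0 else 0.0,
        auc_observed=auc_obs,
        auc_tail=tail,
        censored_mode=censored_mode,
        warnings=warnings,
    )


def clearance(dose_mg_per_kg: float, auc_h_ng_per_ml: float) -> float:
    """Plasma clearance CL = dose / AUC_inf in L/h/kg.

    dose [mg/kg] = 1e6 ng/kg, AUC [h·ng/mL] = 1e3 h·ng/L, hence
    CL = 1000 * dose / AUC.
    """
    if not dose_mg_per_kg > 0:
        raise ValidationError("dose must be > 0")
    if not auc_h_ng_per_ml > 0:
        raise ValidationError("AUC must be > 0 to compute clearance")
    return 1000.0 * dose_mg_per_kg / auc_h_ng_per_ml


def nca(profile: PlasmaProfile, **kwargs) -> PKResult:
    """Full non-compartmental summary of one profile."""
    hl = terminal_half_life(profile, **kwargs.get("terminal_kwargs", {}))
    auc = auc_inf(profile, terminal_kwargs=kwargs.get("terminal_kwargs"),
                  censored_mode=kwargs.get("censored_mode", "zero_observed"))
    cl = clearance(profile.dose_mg_per_kg, auc.auc_h_ng_per_ml)
    return PKResult(
        t_half_h=hl.t_half_h,
        auc_inf_h_ng_per_ml=auc.auc_h_ng_per_ml,
        clearance_l_per_h_kg=cl,
        terminal_points_used=hl.points_used,
        extrapolated_fraction=auc.extrapolated_fraction,
    )
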