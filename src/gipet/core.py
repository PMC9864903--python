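"""Core domain types and physical-decay arithmetic.

Everything downstream (biodistribution SUVs, pharmacokinetics, binding
assays, dosimetry) shares these containers.  Times are stored in minutes
post injection (t = 0 at injection); pharmacokinetic and dosimetry outputs
are reported in hours.  Activities are MBq, masses in grams unless a field
name says otherwise.

Decay-correction state is carried explicitly: a measured activity is either
as-counted (physical decay of the nuclide included, "decay-uncorrected") or
corrected back to the moment of injection.  Operations that require one
state check the flag instead of guessing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

LN2 = math.log(2.0)

#: closed set of study-arm labels
GROUP_LABELS = frozenset({"baseline", "blocked"})


class GipetError(Exception):
    """Base class for all package errors."""


class ValidationError(GipetError, ValueError):
    """An object or table violates a type invariant."""


class SchemaError(ValidationError):
    """A required column is missing or mis-typed in an input table."""


class StateError(GipetError):
    """Decay-correction state of the input is not the one required."""


class AlignmentError(GipetError):
    """Two series that must share a grid do not."""


class LinkageError(GipetError):
    """A sample references an injection record that does not exist."""


class UnitError(GipetError):
    """Units cannot be resolved to the required dimension."""


class FitError(GipetError):
    """A non-linear or regression fit failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ReferenceLookupError(GipetError, KeyError):
    """Unknown builtin reference-data name."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Radionuclide:
    """A radionuclide with the constants internal dosimetry needs.

    Parameters
    ----------
    name:
        Nuclide label, e.g. ``"Ga-68"``.
    half_life_min:
        Physical half-life in minutes.
    np_energy_mev:
        Mean non-penetrating (beta/electron) energy emitted per decay,
        MeV/decay.  Optional; only the demonstration self-dose S-value
        table uses it.
    branching:
        Fraction of decays in the relevant branch (0 < b <= 1), optional.
    """

    name: str
    half_life_min: float
    np_energy_mev: float | None = None
    branching: float | None = None

    def __post_init__(self):
        if not self.half_life_min > 0:
            raise ValidationError(f"half_life_min must be > 0, got {self.half_life_min}")
        if self.branching is not None and not (0 < self.branching <= 1):
            raise ValidationError(f"branching must be in (0, 1], got {self.branching}")

    @property
    def decay_constant_per_min(self) -> float:
        return LN2 / self.half_life_min

    @property
    def decay_constant_per_hour(self) -> float:
        return 60.0 * LN2 / self.half_life_min


@dataclass(frozen=True)
class InjectionRecord:
    """One administration event; defines t = 0 for that animal."""

    animal_id: str
    injected_activity_mbq: float
    body_weight_g: float
    injection_time_min: float = 0.0
    peptide_dose_ug_per_kg: float | None = None

    def __post_init__(self):
        if not self.injected_activity_mbq > 0:
            raise ValidationError(
                f"injected_activity_mbq must be > 0, got {self.injected_activity_mbq}"
            )
        if not self.body_weight_g > 0:
            raise ValidationError(f"body_weight_g must be > 0, got {self.body_weight_g}")


@dataclass(frozen=True)
class TimeActivitySample:
    """One gamma-counter measurement of one tissue at one time."""

    organ: str
    time_pi_min: float
    activity_mbq: float
    sample_mass_g: float
    animal_id: str
    decay_corrected: bool = False
    decay_reference_min: float = 0.0

    def __post_init__(self):
        if self.time_pi_min < 0:
            raise ValidationError(f"time_pi_min must be >= 0, got {self.time_pi_min}")
        if not self.sample_mass_g > 0:
            raise ValidationError(f"sample_mass_g must be > 0, got {self.sample_mass_g}")
        if self.activity_mbq < 0:
            raise ValidationError(f"activity_mbq must be >= 0, got {self.activity_mbq}")


@dataclass(frozen=True)
class Phantom:
    """Reference human phantom: per-organ masses plus body mass.

    ``remainder_organs`` lists the organs pooled into the ICRP-60
    "remainder" tissue at effective-dose time.
    """

    sex: str
    body_mass_kg: float
    organ_masses_g: Mapping[str, float]
    remainder_organs: Sequence[str] = ()

    def __post_init__(self):
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if not self.body_mass_kg > 0:
            raise ValidationError("body_mass_kg must be > 0")
        for organ, m in self.organ_masses_g.items():
            if not m > 0:
                raise ValidationError(f"phantom mass for {organ!r} must be > 0, got {m}")
        if sum(self.organ_masses_g.values()) >= 1000.0 * self.body_mass_kg:
            raise ValidationError("sum of organ masses exceeds body mass")

    def mass_g(self, organ: str) -> float:
        try:
            return self.organ_masses_g[organ]
        except KeyError:
            raise ReferenceLookupError(
                f"organ {organ!r} not in {self.sex} phantom; known: "
                + ", ".join(sorted(self.organ_masses_g))
            ) from None


@dataclass(frozen=True)
class TissueWeights:
    """ICRP tissue-weighting scheme for the effective dose.

    ``weights`` maps named tissues to w_T; ``remainder_weight`` is the w_T
    of the pooled remainder; ``colon_split`` gives the (ULI, LLI) fractions
    of the colon weight; ``esophagus_surrogate`` names the organ whose dose
    stands in for the esophagus (the classic phantoms have none).
    """

    weights: Mapping[str, float]
    remainder_weight: float
    colon_split: Mapping[str, float]
    esophagus_surrogate: str = "thymus"
    name: str = "custom"

    def __post_init__(self):
        for tissue, w in self.weights.items():
            if w < 0:
                raise ValidationError(f"w_T for {tissue!r} must be >= 0, got {w}")
        total = math.fsum([*self.weights.values(), self.remainder_weight])
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"tissue weights must sum to 1, got {total!r}")
        split = sum(self.colon_split.values())
        if abs(split - 1.0) > 1e-9:
            raise ValidationError(f"colon split fractions must sum to 1, got {split!r}")


@dataclass(frozen=True)
class SValueTable:
    """MIRD S values: absorbed dose to target per unit cumulated activity
    in source, mGy/(MBq·h), for one nuclide and one phantom sex."""

    nuclide: str
    sex: str
    entries: Mapping[tuple[str, str], float]

    def __post_init__(self):
        targets = {t for (t, _s) in self.entries}
        for key, v in self.entries.items():
            if v < 0:
                raise ValidationError(f"S value for {key} must be >= 0, got {v}")
        for t in targets:
            if (t, t) not in self.entries:
                raise ValidationError(f"self-dose entry missing for target {t!r}")

    @property
    def targets(self) -> set[str]:
        return {t for (t, _s) in self.entries}

    @property
    def sources(self) -> set[str]:
        return {s for (_t, s) in self.entries}

    def s(self, target: str, source: str) -> float:
        try:
            return self.entries[(target, source)]
        except KeyError:
            raise ValidationError(
                f"S-value table has no ({target!r} <- {source!r}) entry"
            ) from None


@dataclass
class Dataset:
    """A biodistribution study: injections, counted samples, group labels."""

    injections: Mapping[str, InjectionRecord]
    samples: Sequence[TimeActivitySample]
    groups: Mapping[str, str] = field(default_factory=dict)
    species: str = "rat"
    ingest_report: dict = field(default_factory=dict)

    def __post_init__(self):
        for s in self.samples:
            if s.animal_id not in self.injections:
                raise LinkageError(
                    f"sample of {s.organ!r} references unknown animal {s.animal_id!r}"
                )
        for animal, g in self.groups.items():
            if g not in GROUP_LABELS:
                raise ValidationError(
                    f"group label {g!r} for animal {animal!r} not in {sorted(GROUP_LABELS)}"
                )

    @property
    def organs(self) -> list[str]:
        return sorted({s.organ for s in self.samples})

    @property
    def times_min(self) -> list[float]:
        return sorted({s.time_pi_min for s in self.samples})

    def samples_for(self, organ: str, time_min: float | None = None,
                    group: str | None = None) -> list[TimeActivitySample]:
        out = []
        for s in self.samples:
            if s.organ != organ:
                continue
            if time_min is not None and s.time_pi_min != time_min:
                continue
            if group is not None and self.groups.get(s.animal_id) != group:
                continue
            out.append(s)
        return out


# ---------------------------------------------------------------------------
# decay arithmetic
# ---------------------------------------------------------------------------


def decay_transform(value, t_min, nuclide: Radionuclide, direction: str):
    """Apply or remove physical decay over ``t_min`` minutes.

    ``direction="correct"`` multiplies by exp(+lambda*t) (counts measured at
    t referred back to injection time); ``direction="uncorrect"`` multiplies
    by exp(-lambda*t).  The round trip is the identity.  Works elementwise
    on arrays.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValidationError("decay_transform requires t >= 0")
    lam = nuclide.decay_constant_per_min
    if direction == "correct":
        factor = np.exp(lam * t)
    elif direction == "uncorrect":
        factor = np.exp(-lam * t)
    else:
        raise ValueError(f"direction must be 'correct' or 'uncorrect', got {direction!r}")
    out = np.asarray(value, dtype=float) * factor
    if np.ndim(value) == 0 and np.ndim(t) == 0:
        return float(out)
    return out
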