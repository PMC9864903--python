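"""Builtin reference data: nuclide constants, reference phantoms, ICRP-60
tissue weights, and a demonstration S-value table.

All builtins live as editable CSV/JSON under :mod:`gipet.data` so users can
substitute their own (e.g. ICRP-89 phantom masses or a full published
S-value library) without touching code.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import pandas as pd

from .core import (
    Phantom,
    Radionuclide,
    ReferenceLookupError,
    SValueTable,
    TissueWeights,
    ValidationError,
)

log = logging.getLogger(__name__)

_BUILTINS = {
    "nuclide": ("ga68",),
    "phantom": ("adult_male", "adult_female"),
    "weights": ("icrp60",),
    "svalues": ("selfdose_demo_male", "selfdose_demo_female"),
}

# MeV per decay -> mGy*g/(MBq*h): 3.6e9 decays/(MBq*h) * 1.602e-13 J/MeV
# deposited in m grams = 1e-3*m kg.
_MEV_TO_MGY_G_PER_MBQ_H = 3.6e9 * 1.602e-13 / 1e-3 * 1e3  # = 576.72


def _data_path(name: str) -> Path:
    return Path(str(resources.files("gipet.data").joinpath(name)))


def load_nuclide(path_or_name: str | Path = "ga68") -> Radionuclide:
    """Load a nuclide from JSON; ``"ga68"`` is builtin."""
    if str(path_or_name) == "ga68":
        path = _data_path("nuclide_ga68.json")
    else:
        path = Path(path_or_name)
    with open(path) as fh:
        raw = json.load(fh)
    log.info("nuclide %s loaded from %s", raw.get("name"), path)
    return Radionuclide(
        name=raw["name"],
        half_life_min=float(raw["half_life_min"]),
        np_energy_mev=raw.get("np_energy_mev"),
        branching=raw.get("branching"),
    )


def load_phantom(name_or_dir: str | Path = "adult_male") -> Phantom:
    """Load a phantom (mass CSV + metadata JSON); builtins:
    ``"adult_male"``, ``"adult_female"``."""
    name = str(name_or_dir)
    if name in _BUILTINS["phantom"]:
        masses_path = _data_path(f"phantom_{name}_masses.csv")
        meta_path = _data_path(f"phantom_{name}.json")
    else:
        # custom phantom: path to a metadata JSON carrying a "masses_csv"
        # entry (path relative to the JSON file)
        meta_path = Path(name_or_dir)
        with open(meta_path) as fh:
            meta = json.load(fh)
        masses_path = meta_path.parent / meta["masses_csv"]
    masses = pd.read_csv(masses_path)
    with open(meta_path) as fh:
        meta = json.load(fh)
    log.info("phantom %s loaded from %s", meta["sex"], masses_path)
    return Phantom(
        sex=meta["sex"],
        body_mass_kg=float(meta["body_mass_kg"]),
        organ_masses_g=dict(zip(masses["organ"], masses["mass_g"].astype(float))),
        remainder_organs=tuple(meta["remainder_organs"]),
    )


def load_tissue_weights(path_or_name: str | Path = "icrp60") -> TissueWeights:
    """Load a tissue-weighting scheme from JSON; ``"icrp60"`` is builtin."""
    if str(path_or_name) == "icrp60":
        path = _data_path("icrp60_weights.json")
    else:
        path = Path(path_or_name)
    with open(path) as fh:
        raw = json.load(fh)
    total = sum(raw["weights"].values()) + raw["remainder_weight"]
    if abs(total - 1.0) > 1e-9:
        raise ValidationError(f"tissue weights in {path} sum to {total!r}, not 1")
    log.info("tissue weights %s loaded from %s", raw.get("name", "custom"), path)
    return TissueWeights(
        weights=dict(raw["weights"]),
        remainder_weight=float(raw["remainder_weight"]),
        colon_split=dict(raw["colon_split"]),
        esophagus_surrogate=raw.get("esophagus_surrogate", "thymus"),
        name=raw.get("name", "custom"),
    )


def selfdose_svalue_table(phantom: Phantom, nuclide: Radionuclide) -> SValueTable:
    """Demonstration S-value table: non-penetrating self-dose only.

    S(T<-T) = Delta_np / m_T with all cross terms zero.  This is the
    locally-absorbed-electron approximation; it ignores photon cross-dose
    entirely and is shipped so the MIRD chain can run end-to-end without a
    published S-value library.  NOT for clinical dose estimates.
    """
    if nuclide.np_energy_mev is None:
        raise ValidationError(f"nuclide {nuclide.name} has no np_energy_mev")
    delta = nuclide.np_energy_mev * _MEV_TO_MGY_G_PER_MBQ_H  # mGy*g/(MBq*h)
    entries: dict[tuple[str, str], float] = {}
    organs = [o for o in phantom.organ_masses_g if o != "blood"]
    organs.append("rest_of_body")
    rest_mass = 1000.0 * phantom.body_mass_kg - sum(
        m for o, m in phantom.organ_masses_g.items() if o != "blood"
    )
    for t in organs:
        m_t = rest_mass if t == "rest_of_body" else phantom.mass_g(t)
        for s in organs:
            entries[(t, s)] = delta / m_t if t == s else 0.0
    return SValueTable(nuclide=nuclide.name, sex=phantom.sex, entries=entries)


def read_svalue_table(path: str | Path, nuclide: str = "", sex: str = "") -> SValueTable:
    """Read an S-value table CSV with columns target, source, mGy_per_MBq_h."""
    df = pd.read_csv(path)
    for col in ("target", "source", "mGy_per_MBq_h"):
        if col not in df.columns:
            raise ValidationError(f"S-value table {path} lacks column {col!r}")
    entries = {
        (str(r.target), str(r.source)): float(r.mGy_per_MBq_h)
        for r in df.itertuples()
    }
    return SValueTable(nuclide=nuclide, sex=sex, entries=entries)


def load_reference_data(kind: str, name_or_path: str | Path):
    """Dispatching loader for reference data.

    ``kind`` is one of ``nuclide``, ``phantom``, ``weights``, ``svalues``.
    ``name_or_path`` is a builtin name (see below) or a file path.
    Builtins: nuclide ``ga68``; phantoms ``adult_male``/``adult_female``;
    weights ``icrp60``; svalues ``selfdose_demo_male``/``selfdose_demo_female``.
    """
    if kind not in _BUILTINS:
        raise ReferenceLookupError(
            f"unknown reference kind {kind!r}; known: {sorted(_BUILTINS)}"
        )
    name = str(name_or_path)
    is_path = Path(name).exists() and name not in _BUILTINS[kind]
    if not is_path and name not in _BUILTINS[kind]:
        raise ReferenceLookupError(
            f"unknown builtin {name!r} for kind {kind!r}; "
            f"available: {list(_BUILTINS[kind])}"
        )
    if kind == "nuclide":
        return load_nuclide(name_or_path)
    if kind == "phantom":
        return load_phantom(name_or_path)
    if kind == "weights":
        return load_tissue_weights(name_or_path)
    # svalues
    if name == "selfdose_demo_male":
        return selfdose_svalue_table(load_phantom("adult_male"), load_nuclide("ga68"))
    if name == "selfdose_demo_female":
        return selfdose_svalue_table(load_phantom("adult_female"), load_nuclide("ga68"))
    return read_svalue_table(name_or_path)
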