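"""Readers and writers for the tidy CSV study tables.

CSV dialect throughout: comma-separated, UTF-8, mandatory header row,
decimal point.  Readers validate against the type invariants and address
errors by (zero-based) data row.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from .core import (
    Dataset,
    InjectionRecord,
    SchemaError,
    TimeActivitySample,
    ValidationError,
)

log = logging.getLogger(__name__)

SAMPLE_COLUMNS = {
    "animal_id": "animal_id",
    "organ": "organ",
    "time_min": "time_min",
    "activity_MBq": "activity_MBq",
    "sample_mass_g": "sample_mass_g",
}
INJECTION_COLUMNS = {
    "animal_id": "animal_id",
    "injected_MBq": "injected_MBq",
    "body_weight_g": "body_weight_g",
}


def _require(df: pd.DataFrame, columns, path) -> None:
    for col in columns:
        if col not in df.columns:
            raise SchemaError(f"{path}: required column {col!r} missing")


def read_injection_table(path: str | Path,
                         schema: Mapping[str, str] | None = None) -> dict[str, InjectionRecord]:
    """Read an injection CSV into a map animal_id -> InjectionRecord."""
    cols = dict(INJECTION_COLUMNS)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path)
    _require(df, cols.values(), path)
    records = {}
    for i, row in df.iterrows():
        try:
            rec = InjectionRecord(
                animal_id=str(row[cols["animal_id"]]),
                injected_activity_mbq=float(row[cols["injected_MBq"]]),
                body_weight_g=float(row[cols["body_weight_g"]]),
                peptide_dose_ug_per_kg=(
                    float(row["peptide_ug_per_kg"]) if "peptide_ug_per_kg" in df.columns
                    and pd.notna(row["peptide_ug_per_kg"]) else None
                ),
            )
        except ValidationError as err:
            raise ValidationError(f"{path} row {i}: {err}") from None
        records[rec.animal_id] = rec
    return records


def read_time_activity_table(samples_path: str | Path,
                             injections_path: str | Path,
                             schema: Mapping[str, str] | None = None,
                             species: str = "rat",
                             decay_corrected: bool = False) -> Dataset:
    """Read sample and injection CSVs into a validated :class:`Dataset`.

    Rows with a missing organ or time are rejected (not silently coerced)
    and reported in ``Dataset.ingest_report["rejected_rows"]``; rows with
    negative masses or activities raise a row-addressed ValidationError.
    Group labels come from an optional ``group`` column.
    """
    cols = dict(SAMPLE_COLUMNS)
    if schema:
        cols.update(schema)
    df = pd.read_csv(samples_path)
    _require(df, cols.values(), samples_path)
    injections = read_injection_table(injections_path)

    samples, rejected = [], []
    groups: dict[str, str] = {}
    for i, row in df.iterrows():
        organ = row[cols["organ"]]
        t = row[cols["time_min"]]
        if pd.isna(organ) or pd.isna(t):
            rejected.append(int(i))
            continue
        try:
            s = TimeActivitySample(
                organ=str(organ),
                time_pi_min=float(t),
                activity_mbq=float(row[cols["activity_MBq"]]),
                sample_mass_g=float(row[cols["sample_mass_g"]]),
                animal_id=str(row[cols["animal_id"]]),
                decay_corrected=decay_corrected,
            )
        except ValidationError as err:
            raise ValidationError(f"{samples_path} row {i}: {err}") from None
        samples.append(s)
        if "group" in df.columns and pd.notna(row["group"]):
            groups[s.animal_id] = str(row["group"])
    if rejected:
        log.warning("%s: rejected %d rows with missing organ/time: %s",
                    samples_path, len(rejected), rejected)
    ds = Dataset(injections=injections, samples=samples, groups=groups,
                 species=species)
    ds.ingest_report = {"rejected_rows": rejected, "n_samples": len(samples),
                        "units": {"time": "min", "activity": "MBq", "mass": "g"}}
    return ds


def write_time_activity_table(ds: Dataset, samples_path: str | Path,
                              injections_path: str | Path) -> None:
    """Write a Dataset back to the same CSV schema the reader consumes.

    Floats are written at full repr precision so a write -> read round trip
    reproduces every numeric field bit-identically.
    """
    rows = [
        {
            "animal_id": s.animal_id,
            "organ": s.organ,
            "time_min": repr(s.time_pi_min),
            "activity_MBq": repr(s.activity_mbq),
            "sample_mass_g": repr(s.sample_mass_g),
            "group": ds.groups.get(s.animal_id, ""),
        }
        for s in ds.samples
    ]
    pd.DataFrame(rows).to_csv(samples_path, index=False)
    inj_rows = [
        {
            "animal_id": r.animal_id,
            "injected_MBq": repr(r.injected_activity_mbq),
            "body_weight_g": repr(r.body_weight_g),
            "peptide_ug_per_kg": "" if r.peptide_dose_ug_per_kg is None
            else repr(r.peptide_dose_ug_per_kg),
        }
        for r in ds.injections.values()
    ]
    pd.DataFrame(inj_rows).to_csv(injections_path, index=False)
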