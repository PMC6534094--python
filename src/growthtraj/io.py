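"""Reading and writing the extract CSV schemas.

All extract files are plain CSV with ISO-8601 dates:

* ``patients.csv``: patient_id, sex, birth_date, emr_start, emr_end
* ``prescriptions.csv``: patient_id, drug_name, drug_class, dose_label,
  start_date, days_supply
* ``diagnoses.csv``: patient_id, date, icd9_code
* ``measurements.csv``: patient_id, date, type (weight|height), value,
  unit (kg|cm)
* ``lms.csv``: long layout measure, sex, age_months, L, M, S (the
  published wide CDC layout with sex coded 1/2 and ``agemos`` is also
  accepted by :meth:`growthtraj.growth_standards.LmsTable.from_csv`).
"""

from __future__ import annotations

from datetime import date
from pathlib import Path

import pandas as pd

from .growth_standards import LmsTable

EXTRACT_SCHEMAS = {
    "patients": ["patient_id", "sex", "birth_date", "emr_start", "emr_end"],
    "prescriptions": ["patient_id", "drug_name", "drug_class", "dose_label", "start_date", "days_supply"],
    "diagnoses": ["patient_id", "date", "icd9_code"],
    "measurements": ["patient_id", "date", "type", "value", "unit"],
}

DATE_COLUMNS = {
    "patients": ["birth_date", "emr_start", "emr_end"],
    "prescriptions": ["start_date"],
    "diagnoses": ["date"],
    "measurements": ["date"],
}


class SchemaError(ValueError):
    """An extract file does not match its declared schema."""


def read_extract_csv(path, kind: str) -> pd.DataFrame:
    expected = EXTRACT_SCHEMAS[kind]
    df = pd.read_csv(path, dtype={"patient_id": str, "icd9_code": str})
    missing = set(expected) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)} for {kind}")
    for col in DATE_COLUMNS[kind]:
        try:
            df[col] = pd.to_datetime(df[col], format="ISO8601").dt.date
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column {col} is not ISO-8601 ({exc})") from exc
    return df[expected]


def read_extract_dir(path) -> dict[str, pd.DataFrame]:
    path = Path(path)
    return {kind: read_extract_csv(path / f"{kind}.csv", kind) for kind in EXTRACT_SCHEMAS}


def write_extract_dir(path, patients, prescriptions, diagnoses, measurements, truth=None) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    patients.to_csv(path / "patients.csv", index=False)
    prescriptions.to_csv(path / "prescriptions.csv", index=False)
    diagnoses.to_csv(path / "diagnoses.csv", index=False)
    measurements.to_csv(path / "measurements.csv", index=False)
    if truth is not None:
        truth.to_csv(path / "truth.csv", index=False)


def load_lms_tables(weight_path=None, height_path=None, combined_path=None) -> dict[str, LmsTable]:
    """Load LMS references from one long-format file or per-measure files."""
    if combined_path is not None:
        return {
            "weight": LmsTable.from_csv(combined_path, "weight"),
            "height": LmsTable.from_csv(combined_path, "height"),
        }
    tables = {}
    if weight_path is not None:
        tables["weight"] = LmsTable.from_csv(weight_path, "weight")
    if height_path is not None:
        tables["height"] = LmsTable.from_csv(height_path, "height")
    if not tables:
        raise ValueError("no LMS table paths given")
    return tables
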