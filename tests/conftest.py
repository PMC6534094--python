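"""Shared fixtures: small synthetic extracts and reference tables."""

from __future__ import annotations

from datetime import date

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from growthtraj.exposure import PrescriptionRecord
from growthtraj.synthetic import SimulationConfig, make_synthetic_lms_table, simulate_population


@pytest.fixture(scope="session")
def lms_tables():
    return {
        "weight": make_synthetic_lms_table("weight"),
        "height": make_synthetic_lms_table("height"),
    }


@pytest.fixture(scope="session")
def small_population(lms_tables):
    """300-patient extract with a regimen mix rich enough to populate every
    cohort and guanfacine subgroup."""
    cfg = SimulationConfig(
        n_patients=300,
        seed=20230615,
        cohort_mix={
            "first_line_guanfacine": 0.15,
            "nonfirst_line_guanfacine": 0.15,
            "combined": 0.20,
            "first_line_stimulant": 0.30,
            "unmedicated": 0.20,
        },
    )
    patients, rx, dx, meas, truth = simulate_population(cfg, lms_tables)
    return dict(config=cfg, patients=patients, prescriptions=rx, diagnoses=dx,
                measurements=meas, truth=truth)


def rx_record(start: date, days: int, drug="GXR", drug_class="guanfacine",
              dose="4 mg/day", patient="p1") -> PrescriptionRecord:
    return PrescriptionRecord(
        patient_id=patient, drug_name=drug, drug_class=drug_class,
        dose_label=dose, start_date=start, days_supply=days,
    )


@pytest.fixture
def make_rx():
    return rx_record
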