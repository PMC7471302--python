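import numpy as np
import pandas as pd
import pytest

from lifehorizon import generate_life_table

WINDOW = ("2006-01-01", "2015-12-31")
WASHOUT = ("2002-01-01", "2005-12-31")


@pytest.fixture(scope="session")
def life_table():
    return generate_life_table(2002, 2015)


@pytest.fixture(scope="session")
def constant_table():
    """q = 0.5 in every cell (closed-form geometric survival)."""
    return generate_life_table(2002, 2015, hazard_shape={"kind": "constant", "q": 0.5})


def claim_line(pid, date, setting="inpatient", dx="I63", procs="CT01",
               insurer=0.0, copay=0.0, sex="M", birth_year=1950,
               insurance="employed", residence="other", death=""):
    return {
        "patient_id": pid, "date": date, "setting": setting, "primary_dx": dx,
        "procedure_codes": procs, "insurer_paid": insurer, "copay": copay,
        "sex": sex, "birth_year": birth_year, "insurance_type": insurance,
        "residence": residence, "death_date": death,
    }


@pytest.fixture
def toy_claims():
    """Six patients, each designed to exercise exactly one cascade rule.

    A: prevalent case (washout I69 record), B: outpatient only,
    C: no imaging, D: aged 17 at index, E: conflicting I60 + I63 primary
    codes on the index date, F: clean -> the only one retained (NIH).
    """
    rows = [
        claim_line("A", "2003-05-01", setting="outpatient", dx="I69", procs=""),
        claim_line("A", "2007-03-01", dx="I60"),
        claim_line("B", "2007-04-01", setting="outpatient", dx="I63", procs=""),
        claim_line("C", "2007-05-01", dx="I61", procs=""),
        claim_line("D", "2007-06-01", dx="I63", birth_year=1990),
        claim_line("E", "2007-07-01", dx="I60"),
        claim_line("E", "2007-07-01", dx="I63"),
        claim_line("F", "2007-08-01", dx="I62"),
    ]
    return pd.DataFrame(rows)


def make_patients(durations, events, age=65, sex="M", year=2006):
    """Minimal PatientRecord table for survival-stage tests."""
    n = len(durations)
    return pd.DataFrame({
        "patient_id": [f"T{i}" for i in range(n)],
        "sex": sex, "age_at_index": age,
        "index_date": pd.Timestamp(f"{year}-01-01"),
        "subtype": "CI",
        "followup_months": durations, "event": events,
    })
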