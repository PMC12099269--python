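import datetime as dt

import pandas as pd
import pytest

import efrailty as ef


@pytest.fixture(scope="session")
def seed_dict() -> ef.TerminologyDictionary:
    return ef.seed_dictionary()


@pytest.fixture
def window() -> ef.ObservationWindow:
    return ef.ObservationWindow(dt.date(2017, 7, 1), dt.date(2022, 6, 30))


def make_cohort(
    patients=(), diagnoses=(), labs=(), medications=()
) -> ef.EmrCohort:
    """Build an in-memory cohort from plain tuples (dates as datetime.date)."""
    return ef.EmrCohort(
        patients=pd.DataFrame(patients, columns=["patient_id", "birth_date", "sex"]),
        diagnoses=pd.DataFrame(
            diagnoses, columns=["patient_id", "encounter_date", "code_system", "code", "text"]
        ),
        labs=pd.DataFrame(labs, columns=["patient_id", "date", "loinc_code", "value", "unit"]),
        medications=pd.DataFrame(
            medications, columns=["patient_id", "prescribed_date", "atc_code", "drug_name"]
        ),
    )


@pytest.fixture
def elderly_patient():
    """One eligible patient row (aged 80 at the default index date)."""
    return ("P1", dt.date(1942, 1, 15), "F")
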