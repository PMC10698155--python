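import numpy as np
import pandas as pd
import pytest

import pafcc


@pytest.fixture
def toy_records():
    """Three hand-written subjects covering case/control and missingness."""
    return [
        pafcc.SubjectRecord(
            subject_id="c1", status="case", sex="male", age_years=70,
            onset_age_years=60, survey_year=2019, family_history="positive",
            mtbi_event="yes", mtbi_event_year=1980, repeated_blows_head="no",
            pesticide_exposure="yes", pesticide_start_year=1975,
            pesticide_duration_years=5.0, military_chemical_exposure="no",
            constipation="yes", rbd="no", weight_loss="no",
            ethnicity_hispanic="no", race="white", spousal_pair_id="p1"),
        pafcc.SubjectRecord(
            subject_id="c2", status="case", sex="female", age_years=65,
            onset_age_years=64, survey_year=2019, family_history="unknown",
            mtbi_event="no", pesticide_exposure="no",
            military_chemical_exposure="no", constipation="no", rbd="yes",
            weight_loss="yes", ethnicity_hispanic="no", race="white"),
        pafcc.SubjectRecord(
            subject_id="n1", status="control", sex="male", age_years=68,
            survey_year=2019, family_history="negative", mtbi_event="yes",
            mtbi_event_year=2000, pesticide_exposure="no",
            military_chemical_exposure="no", constipation="no", rbd="no",
            weight_loss="no", ethnicity_hispanic="no", race="white",
            spousal_pair_id="p1"),
    ]


@pytest.fixture
def toy_csv(tmp_path, toy_records):
    path = tmp_path / "cohort.csv"
    pafcc.write_subject_csv(toy_records, path)
    return path


@pytest.fixture
def fixed_cohort():
    """A deterministic single-exposure cohort for estimator-level tests."""
    spec = pafcc.CohortSpec(
        n_cases=600, n_controls=600,
        exposures=(pafcc.ExposureSpec("e", 0.15, 2.5),),
        seed=42)
    return pafcc.generate_cohort(spec)
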