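import numpy as np
import pytest

import ctrisk as ck


@pytest.fixture(scope="session")
def tables() -> ck.ReferenceTables:
    return ck.default_tables()


@pytest.fixture(scope="session")
def chest_exam(tables) -> ck.ExamRecord:
    """A 70-year-old male chest exam with a dose to every chest-protocol organ."""
    template = ck.default_protocols()[0]
    return ck.ExamRecord(
        patient_id="P1",
        sex="male",
        age_at_exam=70.0,
        region="chest",
        dlp=400.0,
        organ_doses={o: v * 400.0 for o, v in template.unit_organ_doses.items()},
    )


@pytest.fixture(scope="session")
def uniform_exam(tables) -> ck.ExamRecord:
    """10 mGy to every organ compatible with a female patient."""
    doses = {
        o: 10.0
        for o in tables.organs
        if o not in ("prostate", "testes")
    }
    return ck.ExamRecord(
        patient_id="P2",
        sex="female",
        age_at_exam=40.0,
        region="chest",
        dlp=100.0,
        organ_doses=doses,
    )


@pytest.fixture(scope="session")
def small_cohort_frame(tables):
    """Mixed-protocol synthetic cohort (exam table), fixed seed."""
    return ck.generate_cohort(ck.CohortConfig(seed=11, n_patients=150))


@pytest.fixture(scope="session")
def small_patient_frame(tables, small_cohort_frame):
    metrics = ck.compute_exam_metrics_frame(small_cohort_frame, tables)
    return ck.accumulate_patients_frame(metrics)
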