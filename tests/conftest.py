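import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import mnemoscreen as ms

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def reference_cohort() -> ms.CohortTable:
    """Deterministic 3,400-row cohort matching the reference per-symptom margins."""
    return ms.make_reference_cohort()


@pytest.fixture(scope="session")
def reference_profiles(reference_cohort) -> dict[str, ms.DiagnosticProfile]:
    return {
        s: ms.diagnostic_profile(ms.cross_tabulate(reference_cohort, s))
        for s in ms.SYMPTOMS
    }


@pytest.fixture(scope="session")
def fully_recorded_cohort() -> ms.CohortTable:
    """Synthetic cohort with every symptom recorded on every visit."""
    params = ms.default_cohort_params()
    params.record_rate = {s: 1.0 for s in params.record_rate}
    return ms.generate(params, seed=20_240_101)


def make_cohort(rows: list[dict], symptoms: tuple[str, ...]) -> ms.CohortTable:
    """Tiny in-memory cohort from dicts; symptom values True/False/None."""
    df = pd.DataFrame(rows)
    for s in symptoms:
        df[s] = pd.array([None if v is None else bool(v) for v in df[s]],
                         dtype="boolean")
    return ms.CohortTable(df, symptom_names=symptoms)


@pytest.fixture
def tiny_csv(tmp_path):
    """A 5-row cohort CSV exercising all three symptom states."""
    text = (
        "visit_id,chest_pain,sweating,outcome\n"
        "v1,1,0,ACS\n"
        "v2,0,NA,non_ACS\n"
        "v3,NA,1,ACS\n"
        "v4,1,1,non_ACS\n"
        "v5,0,0,non_ACS\n"
    )
    path = tmp_path / "tiny.csv"
    path.write_text(text)
    return path
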