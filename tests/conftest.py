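import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ages57():
    rng = np.random.default_rng(0)
    return np.sort(rng.integers(14, 72, 57)).astype(float)


@pytest.fixture(scope="session")
def sex57():
    rng = np.random.default_rng(1)
    return rng.choice(["male", "female"], 57, p=[41 / 57, 16 / 57])


@pytest.fixture(scope="session")
def default_cohort():
    from frontolimbic import GeneratorConfig, simulate_cohort

    cohort, truth = simulate_cohort(GeneratorConfig(seed=1))
    return cohort, truth


def make_toy_cohort(values_by_subject, region="thalamus", measure="volume_mm3",
                    etiv=1.0e6):
    """Tiny cohort from {subject_id: (left, right)} value pairs."""
    from frontolimbic import CohortTable

    subjects, measures = [], []
    for i, (sid, (lv, rv)) in enumerate(values_by_subject.items()):
        subjects.append(
            {"subject_id": sid, "age_months": 20.0 + 5 * i, "sex": "male",
             "etiv": etiv, "age_group": 1}
        )
        measures.append({"subject_id": sid, "region_name": region,
                         "hemisphere": "left", "measure_kind": measure, "value": lv})
        measures.append({"subject_id": sid, "region_name": region,
                         "hemisphere": "right", "measure_kind": measure, "value": rv})
    return CohortTable(pd.DataFrame(subjects), pd.DataFrame(measures))
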