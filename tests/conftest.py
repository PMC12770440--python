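import pandas as pd
import pytest

from moaclin import SyntheticConfig, simulate_cohort


def make_long_frame(rows):
    """rows: iterable of (patient_id, arm, visit, variable, value)."""
    return pd.DataFrame(
        rows, columns=["patient_id", "arm", "visit", "variable", "value"]
    )


def two_visit_rows(pid, arm, scores):
    """scores: {variable: (baseline, v2)} -> long-form rows for one patient."""
    rows = []
    for var, (b, v2) in scores.items():
        rows.append((pid, arm, "baseline", var, b))
        rows.append((pid, arm, "V2", var, v2))
    return rows


@pytest.fixture(scope="session")
def study_cohort():
    """72-patient synthetic cohort in the default study shape, fixed seed."""
    cohort, truth = simulate_cohort(SyntheticConfig(seed=20260929))
    return cohort, truth
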