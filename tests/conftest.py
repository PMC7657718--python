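import io

import numpy as np
import pandas as pd
import pytest

import userjourney as uj

from userjourney.experiments import study_config  # noqa: F401  (shared by tests)


@pytest.fixture
def tiny_log() -> uj.TouchPointLog:
    """Hand-written six-touchpoint log for transformation unit tests."""
    csv = io.StringIO(
        "user_id,timestamp,variable,value,source\n"
        "a,2021-01-01T09:00:00,mood,2,self_report\n"
        "a,2021-01-01T20:00:00,mood,4,self_report\n"
        "a,2021-01-01T08:00:00,login,,system\n"
        "a,2021-01-03T08:00:00,login,,system\n"
        "b,2021-01-02T09:00:00,mood,5,self_report\n"
        "b,2021-01-02T10:00:00,color,blue,self_report\n"
    )
    return uj.parse_touchpoints(csv)


@pytest.fixture(scope="session")
def small_cohort():
    """Session-wide simulated cohort for pipeline-level tests."""
    params = uj.preset("shuti_like", n_users=70, seed=7)
    log, labels, truth = uj.simulate_cohort(params)
    return log, labels, truth


@pytest.fixture(scope="session")
def small_core5_table(small_cohort):
    """Finalized (imputed) core-5 user table from the small cohort."""
    from userjourney.modeling import build_core_table, finalize_table

    log, labels, _ = small_cohort
    cfg = study_config(seed=7)
    uft = build_core_table(log, labels, cfg, 5)
    table, _report = finalize_table(uft, cfg.missingness_policy())
    return table
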