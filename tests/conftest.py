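import numpy as np
import pandas as pd
import pytest

from rxmsm import SimulationConfig, simulate_cohort, run_pipeline
from rxmsm.config import PipelineConfig


@pytest.fixture(scope="session")
def small_cohort():
    """Deterministic mid-size cohort reused across tests."""
    cfg = SimulationConfig(n_patients=800, horizon_days=2556, seed=11,
                           true_log_hr={("llt", "consistent"): np.log(0.6)})
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_result(small_cohort):
    return run_pipeline(small_cohort.tables, small_cohort.config.horizon_days,
                        PipelineConfig(), endpoints=["death"],
                        fit_unweighted=True, screen=False)


def make_fills(records):
    """records: iterable of (day, supply, drug, drug_class)."""
    rows = [{"patient_id": 1, "pid": 0, "fill_day": d, "days_supply": s,
             "drug_code": drug, "drug_class": cls}
            for d, s, drug, cls in records]
    return pd.DataFrame(rows, columns=["patient_id", "pid", "fill_day",
                                       "days_supply", "drug_code",
                                       "drug_class"])


def make_stays(records):
    rows = [{"patient_id": 1, "pid": 0, "admit_day": a, "discharge_day": d}
            for a, d in records]
    return pd.DataFrame(rows, columns=["patient_id", "pid", "admit_day",
                                       "discharge_day"])
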