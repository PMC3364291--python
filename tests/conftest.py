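import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import devvar as dv

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """A small simulated raw study with ground truth (seeded)."""
    cfg = dv.SimulationConfig(n_probes=500, frac_dv=0.1, sd_ratio=3.0, seed=11)
    return dv.simulate_expression_study(cfg)


@pytest.fixture(scope="session")
def processed_study(small_study):
    matrix, samples, truth = small_study
    cfg = dv.StudyConfig(simulation=dv.SimulationConfig(n_probes=10), seed=11)
    m, s, _ = dv.preprocess_study(matrix, samples, cfg)
    return m, s, truth


def make_matrix(values, probe_ids=None, sample_ids=None, scale="log2", detection=None):
    values = np.asarray(values, dtype=float)
    probe_ids = probe_ids or [f"P{i:03d}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"S{j:03d}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    det = None
    if detection is not None:
        det = pd.DataFrame(np.asarray(detection, float), index=probe_ids, columns=sample_ids)
    return dv.ExpressionMatrix(values=df, detection_p=det, scale=scale)


def make_samples(ages, sexes=None, subjects=None, sample_ids=None, delay=None):
    n = len(ages)
    sample_ids = sample_ids or [f"S{j:03d}" for j in range(n)]
    subjects = subjects or sample_ids
    sexes = sexes or ["female"] * n
    delay = delay if delay is not None else [False] * n
    return dv.SampleTable(
        pd.DataFrame(
            {
                "subject_id": subjects,
                "age_years": ages,
                "sex": sexes,
                "dev_delay": delay,
                "region": ["temporal"] * n,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )


@pytest.fixture
def helpers():
    class H:
        matrix = staticmethod(make_matrix)
        samples = staticmethod(make_samples)

    return H
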