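import numpy as np
import pytest

from cprstress import GeneratorConfig, IBISeries, generate_cohort


def ibi_from_intervals(intervals, start_time=0.0):
    """Build an IBISeries from a plain list of intervals in ms."""
    intervals = np.asarray(intervals, dtype=float)
    offsets = np.cumsum(np.maximum(intervals, 1.0)) / 1000.0
    return IBISeries(start_time, offsets, intervals)


@pytest.fixture(scope="session")
def small_cohort():
    """Small rendered cohort shared by aggregation and model tests."""
    cfg = GeneratorConfig(
        n_participants=8,
        seed=42,
        phase_durations={"pre": 120.0, "Sim": 120.0, "post": 120.0},
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def truth_table(small_cohort):
    return small_cohort.truth.to_cohort_table()
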