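import numpy as np
import pytest

from polconn.fc import assemble_dataset
from polconn.synthetic import (
    PlantedTruth,
    SignalEdge,
    generate_bold_timeseries,
    generate_cohort,
)


@pytest.fixture(scope="session")
def cohort174():
    """Study-scale cohort with the default ideology histogram."""
    return generate_cohort(seed=42)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny cohort for fast end-to-end runs."""
    return generate_cohort(n=30, ideology_counts=(5, 9, 8, 6, 1, 1), seed=7)


@pytest.fixture(scope="session")
def small_fc_dataset(small_cohort):
    """FC matrices for 30 subjects, 2 tasks, 12 ROIs, no planted signal."""
    truth = PlantedTruth(seed=7)
    series = generate_bold_timeseries(
        small_cohort,
        truth,
        n_rois=12,
        n_timepoints=60,
        missing_roi=None,
        task_ids=("affect", "empathy"),
    )
    matrices, _ = assemble_dataset(series)
    return matrices


@pytest.fixture
def rng():
    return np.random.default_rng(0)
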