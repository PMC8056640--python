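import pandas as pd
import pytest

from lncflow.expression import compute_fpkm
from lncflow.models import Sample, SampleSheet
from lncflow.simulate import SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def study():
    """Default toy study, fixed seed, shared across the suite."""
    return simulate_study(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def study_fpkm(study):
    return compute_fpkm(study.counts, study.feature_lengths)


@pytest.fixture
def two_group_sheet():
    """3 + 3 design for two-condition DE tests."""
    return SampleSheet(
        [Sample(f"SD1_{i}", "SD1", i) for i in (1, 2, 3)]
        + [Sample(f"SD2_{i}", "SD2", i) for i in (1, 2, 3)]
    )


def make_counts(array, sheet, prefix="f"):
    return pd.DataFrame(
        array,
        index=[f"{prefix}{i}" for i in range(len(array))],
        columns=sheet.sample_ids,
    )
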