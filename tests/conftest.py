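import numpy as np
import pandas as pd
import pytest

from lfpdecode.bands import FeatureSpec
from lfpdecode.labeling import BehaviorIntervals
from lfpdecode.synth import CohortConfig, cohort_table, generate_feature_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def spec():
    return FeatureSpec()


@pytest.fixture(scope="session")
def feature_names(spec):
    return spec.feature_names()


def small_cohort_config(**overrides) -> CohortConfig:
    """A 4-animal, Base-only configuration sized for unit tests."""
    kwargs = dict(
        n_animals=4,
        conditions=("Base",),
        n_base_sessions=1,
        session_length_s=1800.0,
        sampling_rate_hz=250.0,
        seed=101,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def small_feature_table(feature_names):
    """Labeled bin-level feature table for a small planted-effect cohort."""
    sessions = generate_feature_cohort(small_cohort_config())
    return cohort_table(sessions)


@pytest.fixture
def simple_intervals():
    """One feeding epoch [100, 160) with rest [300, 500)."""
    df = pd.DataFrame(
        [(100.0, 160.0, "feeding"), (300.0, 500.0, "rest")],
        columns=["start_s", "end_s", "label"],
    )
    return BehaviorIntervals(df, session_length_s=600.0)


def stub_bins(session_length_s: float, bin_length_s: float = 5.0) -> pd.DataFrame:
    n = int(session_length_s / bin_length_s)
    return pd.DataFrame({"bin_start_s": np.arange(n) * bin_length_s})
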