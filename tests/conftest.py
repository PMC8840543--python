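import numpy as np
import pandas as pd
import pytest

from privhar import GeneratorConfig, generate_dataset, sequences_to_matrix
from privhar.features import FEATURE_NAMES
from privhar.types import Window


@pytest.fixture(scope="session")
def tiny_config():
    return GeneratorConfig(
        n_subjects=4, n_activities=3, reps_per_activity=2, n_age_bins=4, seed=7
    )


@pytest.fixture(scope="session")
def tiny_sequences(tiny_config):
    return generate_dataset(tiny_config)


@pytest.fixture(scope="session")
def tiny_matrix(tiny_sequences):
    """168 windows, 4 subjects x 3 activities x 2 reps x 7 windows."""
    return sequences_to_matrix(tiny_sequences)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_window(rng, n=160, rate=32.0, **labels):
    defaults = dict(
        subject_id="S00", gender="M", age_group=0, activity="walking",
        sequence_id="S00-walking-r0", start=0,
    )
    defaults.update(labels)
    return Window(
        samples=rng.normal(0.0, 0.5, size=(n, 3)),
        sample_rate_hz=rate,
        **defaults,
    )


@pytest.fixture()
def make_window(rng):
    def _make(n=160, **labels):
        return random_window(rng, n=n, **labels)

    return _make


def synthetic_feature_frame(rng, n, labels: dict) -> pd.DataFrame:
    """A feature matrix with random feature values and caller-given labels."""
    df = pd.DataFrame(
        rng.normal(size=(n, len(FEATURE_NAMES))), columns=list(FEATURE_NAMES)
    )
    for col, values in labels.items():
        df[col] = values
    for col, default in (
        ("subject_id", "S00"), ("gender", "M"), ("age_group", 0), ("activity", "a"),
    ):
        if col not in df.columns:
            df[col] = default
    return df
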