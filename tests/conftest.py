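"""Shared fixtures.

Tests run on scaled-down synthetic sessions (1 kHz, 1.5 s repetitions) so
the whole suite stays fast; the signal structure (8 channels, 27 labels,
band-limited noise with class-dependent amplitudes) is the same as at full
scale.
"""

import numpy as np
import pytest

from emgpr.coding import enumerate_labels
from emgpr.evaluation import EvalConfig
from emgpr.features import extract_features
from emgpr.synth import SynthConfig, generate_session


def small_synth_config(seed=0, snr=10.0, **overrides):
    """Scaled-down session: 1 kHz, 1.5 s x 3 reps -> 54 windows/movement."""
    kwargs = dict(
        sampling_rate=1000.0,
        contraction_time=1.5,
        n_repetitions=3,
        band=(20.0, 450.0),
        snr=snr,
        rng_seed=seed,
    )
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


def small_eval_config(**overrides):
    """Split protocol matched to the 18 windows/movement of small sessions."""
    kwargs = dict(
        n_repetitions=3,
        train_windows_per_movement=36,
        test_windows_per_movement=18,
        rng_seed=0,
    )
    kwargs.update(overrides)
    return EvalConfig(**kwargs)


@pytest.fixture(scope="session")
def label_table():
    return enumerate_labels(3)


@pytest.fixture(scope="session")
def small_session():
    return generate_session(small_synth_config(seed=11, snr=10.0))


@pytest.fixture(scope="session")
def small_features(small_session):
    return extract_features(small_session)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
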