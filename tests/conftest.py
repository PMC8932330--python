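"""Shared fixtures: synthetic study datasets built once per session.

The two "study" fixtures reproduce the package's reference experimental
conditions (100 windows per state, 30 s windows at 2 kHz, low-pass + notch
preprocessing) for the two generator profiles; they are session-scoped
because generating and featurizing 300 windows takes tens of seconds.
"""

from __future__ import annotations

import numpy as np
import pytest

from fatiguefuse import features, synthgen
from fatiguefuse.preprocess import PreprocessConfig, preprocess_record
from fatiguefuse.records import feature_matrix

LIGHT_PREPROCESS = PreprocessConfig(denoise=False)


def build_study_features(profile, n_per_state: int, seed: int):
    """Generate → filter (low-pass + notch) → featurize one study dataset."""
    records = synthgen.generate_dataset(
        n_per_state=n_per_state, window_s=30.0, profile=profile, seed=seed)
    processed = [preprocess_record(r, LIGHT_PREPROCESS) for r in records]
    vectors = features.extract_dataset(processed)
    X, y = feature_matrix(vectors)
    return X, y.astype(int)


@pytest.fixture(scope="session")
def study_complementary():
    """Complementary-information study: ECG resolves relaxed, sEMG tired."""
    return build_study_features(synthgen.complementary_profile(), 100, seed=7)


@pytest.fixture(scope="session")
def study_default():
    """Monotone fatigue-trend study (the default generator profile)."""
    return build_study_features(synthgen.default_profile(), 100, seed=11)


@pytest.fixture(scope="session")
def small_records():
    """30 raw 10 s windows per state for generator-level batch statistics."""
    return synthgen.generate_dataset(n_per_state=30, window_s=10.0, seed=5)


@pytest.fixture(scope="session")
def blobs_3class():
    """Well-separated 2-D Gaussian blobs, 20 points per state."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.normal(c, 0.5, (20, 2))
                   for c in ([0, 0], [3, 0], [0, 3])])
    y = np.repeat([-1, 0, 1], 20)
    return X, y
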