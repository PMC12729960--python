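"""Shared fixtures: one small synthetic study reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from fatiguecg.preprocess import preprocess_study
from fatiguecg.synth import generate_study


@pytest.fixture(scope="session")
def small_study():
    """2 subjects x 2 days (12 sessions of 600 s) with default noise."""
    return generate_study(n_subjects=2, n_days=2, seed=11)


@pytest.fixture(scope="session")
def small_segments(small_study):
    manifest, _ = small_study
    segments, report = preprocess_study(manifest)
    return segments, report


@pytest.fixture(scope="session")
def small_features(small_segments):
    from fatiguecg.hrv import features_table

    segments, _ = small_segments
    table, unusable = features_table(segments)
    return table, unusable


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
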