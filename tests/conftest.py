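"""Shared fixtures: synthetic corpora and cached feature extractions.

The 60-file corpus (15 per severity level, seed 1) and its two feature
extractions are session-scoped because they back several slow tests.
"""

import numpy as np
import pytest

from msmorph import (ExperimentConfig, corpus_features, load_preset,
                     make_corpus)

RATE = 25000


@pytest.fixture(scope="session")
def corpus60():
    """Balanced 4-class synthetic corpus, 15 files per level."""
    return make_corpus(15, seed=1, duration=1.0, sample_rate=RATE)


@pytest.fixture(scope="session")
def grade_config():
    return load_preset("best_grade")


@pytest.fixture(scope="session")
def roughness_config():
    return load_preset("best_roughness")


@pytest.fixture(scope="session")
def grade_features(corpus60, grade_config):
    return corpus_features(corpus60.waveforms, grade_config)


@pytest.fixture(scope="session")
def roughness_features(corpus60, roughness_config):
    return corpus_features(corpus60.waveforms, roughness_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_tone(freq=1000.0, duration=0.2, rate=RATE, amplitude=1.0):
    t = np.arange(int(duration * rate)) / rate
    return amplitude * np.sin(2 * np.pi * freq * t)


def make_am_tone(carrier=1000.0, mod=40.0, depth=0.5, duration=0.2,
                 rate=RATE):
    t = np.arange(int(duration * rate)) / rate
    return (1.0 + depth * np.cos(2 * np.pi * mod * t)) \
        * np.cos(2 * np.pi * carrier * t)
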