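"""Shared fixtures: small synthetic sessions and corpora, built once."""
import numpy as np
import pytest
from hypothesis import settings

import seegphrase as sp
from seegphrase.spectral import compute_tfr, divisive_baseline

settings.register_profile("deterministic", derandomize=True, database=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config():
    return sp.SynthConfig(
        n_channels=4,
        responsive_channel_ids=(0,),
        auditory_channel_ids=(1,),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_session(small_config):
    """One 4-channel session: responsive, auditory and two noise channels."""
    rec, events, truth = sp.generate_session(small_config)
    return rec, events, truth


@pytest.fixture(scope="session")
def warped_epochs(small_session):
    rec, events, _ = small_session
    return sp.preprocess_session(rec, events)


@pytest.fixture(scope="session")
def responsive_tfr(warped_epochs):
    """Normalized TFR of the planted responsive channel."""
    return divisive_baseline(compute_tfr(warped_epochs, 0, decim=5))


@pytest.fixture(scope="session")
def noise_tfr(warped_epochs):
    """Normalized TFR of a pure-noise channel."""
    return divisive_baseline(compute_tfr(warped_epochs, 3, decim=5))


@pytest.fixture(scope="session")
def planted_corpus():
    cfg = sp.CorpusConfig(surprisal_gap=1.0, seed=7)
    return sp.generate_corpus(cfg)
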