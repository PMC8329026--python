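import dataclasses

import numpy as np
import pytest

import dyadload as dl


@pytest.fixture(scope="session")
def small_corpus():
    """Three synthetic interactions under benchmark conditions."""
    cfg = dataclasses.replace(dl.SimConfig(), n_interactions=3, seed=42)
    return dl.generate(cfg)


@pytest.fixture(scope="session")
def small_metrics(small_corpus):
    recordings, _ = small_corpus
    df, log = dl.extract_corpus(recordings)
    assert not log
    return df


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
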