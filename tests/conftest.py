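"""Shared fixtures: small synthetic datasets reused across test modules.

Everything is generated at test time from seeds; there are no stored data
files.  The scenario fixtures are session-scoped because simulation and
preprocessing of even a desk-scale dataset takes a few seconds.
"""

from __future__ import annotations

import numpy as np
import pytest

import seegspeech as sp
from seegspeech.evaluate import EvalData
from seegspeech.preprocess import preprocess_session


def make_eval_data(config: sp.SimConfig) -> EvalData:
    recordings, events, emap = sp.simulate(config)
    features = {r.session_id: preprocess_session(r) for r in recordings}
    return EvalData(features, events, emap)


@pytest.fixture(scope="session")
def scenario_data() -> EvalData:
    """Default scenario: strong high-gamma coding (place/manner in STG,
    manner/tone in thalamus), effect size 3."""
    return make_eval_data(sp.default_scenario(effect_size=3.0, seed=2026))


@pytest.fixture(scope="session")
def tiny_decoder_config() -> sp.DecoderConfig:
    """Very small decoder for tests that exercise mechanics, not accuracy."""
    return sp.DecoderConfig(hidden_units=8, layers=1, dropout=0.2,
                            batch_size=256, max_epochs=6, patience=2, seed=0)


@pytest.fixture(scope="session")
def desk_decoder_config() -> sp.DecoderConfig:
    return sp.DecoderConfig.desk_scale()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
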