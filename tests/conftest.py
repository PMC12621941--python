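"""Shared fixtures.

Small synthetic objects are built per-module; the expensive trained models
used by the acceptance tests are session-scoped so several tests can share
one fit.
"""

from __future__ import annotations

import numpy as np
import pytest

import clfads as cl


@pytest.fixture(scope="session")
def tiny_dataset():
    """Two-condition pendulum set, small enough for fast unit tests."""
    pcfg = cl.PendulumConfig(gravity_values=(1.0, 4.0),
                             n_trials_per_condition=8,
                             n_steps=40, seed=1)
    emb = cl.EmbeddingConfig(n_neurons=24, seed=2)
    return cl.make_pendulum_dataset(pcfg, emb, (0.5, 0.25, 0.25))


@pytest.fixture(scope="session")
def tiny_model(tiny_dataset):
    """Untrained small model matching the tiny dataset."""
    train, _, _ = tiny_dataset
    cfg = cl.ModelConfig(n_channels=train.n_channels, gen_dim=12, bias_dim=3,
                         encoder_dim=10, bin_width=train.bin_width, seed=7)
    return cl.GeneratorModel(cfg)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
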