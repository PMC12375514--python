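"""Shared fixtures: the default model is expensive enough to build once."""

import pytest

from ymhsim.defaults import default_config
from ymhsim.engine import simulate
from ymhsim.model import build_model, settings_from_config


@pytest.fixture(scope="session")
def base_config():
    return default_config()


@pytest.fixture(scope="session")
def base_model(base_config):
    return build_model(base_config)


@pytest.fixture(scope="session")
def base_settings(base_config):
    return settings_from_config(base_config)


@pytest.fixture(scope="session")
def baseline_trajectory(base_model, base_settings):
    return simulate(base_model, base_settings)
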