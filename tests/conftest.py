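"""Shared fixtures: small synthetic scenes reused across the unit tests."""
import pytest

from mtpi import SceneParams, generate_survey

TOY_PARAMS = dict(height=64, width=64, min_size=64, blob_scale=8.0,
                  class_mix=(0.30, 0.25, 0.25, 0.20), color_sd=28.0)


@pytest.fixture(scope="session")
def toy_params():
    return SceneParams(**TOY_PARAMS)


@pytest.fixture(scope="session")
def toy_scenes(toy_params):
    return generate_survey(toy_params, 12, seed=900)
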