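"""Shared fixtures: the default synthetic scene is built once per session."""

import pytest

from dicpipe import pipeline, synthio


@pytest.fixture(scope="session")
def default_cfg():
    return pipeline.validate_config({})


@pytest.fixture(scope="session")
def default_scene():
    """The reference scene: seed 1, 2 x 20 Mb, 300 genes, ~3000 sites."""
    return synthio.simulate_scene(synthio.SimulationParams(seed=1))


@pytest.fixture(scope="session")
def diff_table(default_scene, default_cfg):
    return pipeline.run_diffpeaks(default_scene, default_cfg)


@pytest.fixture(scope="session")
def dic_calls(default_scene, diff_table, default_cfg):
    return pipeline.run_dic_extraction(default_scene, diff_table, default_cfg)
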