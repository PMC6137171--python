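import pytest

from bovitf import pipeline
from bovitf.synthetic_data import WorldConfig, generate_world


@pytest.fixture(scope="session")
def tiny_world(tmp_path_factory):
    """A generated tiny synthetic world: (config, paths, truth)."""
    out = tmp_path_factory.mktemp("tiny_world")
    cfg = WorldConfig.tiny(seed=7)
    paths, truth = generate_world(cfg, out)
    return cfg, paths, truth


@pytest.fixture(scope="session")
def tiny_run(tiny_world):
    """Pipeline outputs and manifest for the tiny world."""
    _, paths, _ = tiny_world
    outputs, manifest = pipeline.run_pipeline(paths)
    return outputs, manifest


@pytest.fixture(scope="session")
def paper_world(tmp_path_factory):
    """The paper-scale synthetic world (generated once per session)."""
    out = tmp_path_factory.mktemp("paper_world")
    cfg = WorldConfig.paper_scale(seed=11)
    paths, truth = generate_world(cfg, out)
    return cfg, paths, truth


@pytest.fixture(scope="session")
def paper_run(paper_world):
    _, paths, _ = paper_world
    outputs, manifest = pipeline.run_pipeline(paths)
    return outputs, manifest
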