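import pytest

from rfitrial.pipeline import RunConfig, run_pipeline
from rfitrial.simulate import default_config, generate_trial


@pytest.fixture(scope="session")
def default_trial():
    """The default 7-group, 186-heifer synthetic trial at seed 1."""
    return generate_trial(default_config(), seed=1)


@pytest.fixture(scope="session")
def pipeline_result(tmp_path_factory):
    """A full pipeline run (seed 1, default config) shared across tests."""
    outdir = tmp_path_factory.mktemp("bundle")
    return run_pipeline(RunConfig(outdir=outdir, seed=1))


@pytest.fixture(scope="session")
def growth_table(pipeline_result):
    return pipeline_result.growth
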