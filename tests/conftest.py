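import warnings

import pytest

from interolog.bp import ModelParams
from interolog.pipeline import run_from_fixtures
from interolog.simulate import WorldConfig, emit_fixtures, generate_world


@pytest.fixture(scope="session")
def world():
    """Default synthetic world (n=300 source proteins, seed 7)."""
    return generate_world(WorldConfig())


@pytest.fixture(scope="session")
def fixture_dir(world, tmp_path_factory):
    out = tmp_path_factory.mktemp("world")
    emit_fixtures(world, out)
    return out


@pytest.fixture(scope="session")
def manifest(world, tmp_path_factory):
    out = tmp_path_factory.mktemp("world_manifest")
    return emit_fixtures(world, out)


@pytest.fixture(scope="session")
def pipeline_fixed(fixture_dir):
    """Full pipeline run at the reference parameters (beta=0.2, epsilon=0.02)."""
    return run_from_fixtures(fixture_dir, seed=11, params=ModelParams(epsilon=0.02, beta=0.2))


@pytest.fixture(scope="session")
def pipeline_fitted(fixture_dir):
    """Full pipeline run with (beta, epsilon) fitted by grid search."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_from_fixtures(fixture_dir, seed=11)
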