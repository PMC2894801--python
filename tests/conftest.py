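import logging

import pytest

from oligomap.fixtures import FixtureConfig, generate_fixture, write_fixture
from oligomap.pipeline import PipelineConfig, run_all

logging.getLogger("oligomap").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic study: all planted intents, seed 0."""
    return generate_fixture(FixtureConfig())


@pytest.fixture(scope="session")
def fixture_dir(default_fixture, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    paths = write_fixture(default_fixture, outdir)
    return paths


@pytest.fixture(scope="session")
def pipeline_result(fixture_dir, tmp_path_factory):
    """Full pipeline run over the default fixture (file round trip included)."""
    outdir = tmp_path_factory.mktemp("pipeline_out")
    config = PipelineConfig(
        genome=fixture_dir["genome"],
        gtf=fixture_dir["gtf"],
        probes=fixture_dir["probes"],
        outdir=outdir,
        vcf=fixture_dir["vcf"],
        paralogs=fixture_dir["paralogs"],
    )
    return run_all(config)


@pytest.fixture(scope="session")
def truth_by_id(default_fixture):
    return {t.probeset_id: t for t in default_fixture.truth}
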