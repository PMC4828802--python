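"""Shared fixtures: one small synthetic dataset reused across modules."""

from __future__ import annotations

import pytest

from sitamir import pipeline, synthio


SMALL = synthio.SyntheticConfig(
    seed=42,
    read_depth=120_000,
    degradome_depth=10_000,
    n_mirna_loci=12,
)


@pytest.fixture(scope="session")
def small_config():
    return SMALL


@pytest.fixture(scope="session")
def small_world(small_config):
    """(genome, truth, annotations) for the small test configuration."""
    return synthio.gen_genome(small_config)


@pytest.fixture(scope="session")
def small_libraries(small_world, small_config):
    genome, truth, ann = small_world
    return synthio.gen_srna_libraries(truth, small_config, genome, ann)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory, small_config):
    """Materialized on-disk fixture + pipeline config."""
    outdir = tmp_path_factory.mktemp("fixture")
    pc = pipeline.make_fixture(small_config, outdir)
    return outdir, pc


@pytest.fixture(scope="session")
def small_bundle(small_fixture_dir):
    """Full pipeline run over the small fixture (computed once)."""
    _, pc = small_fixture_dir
    return pipeline.run_pipeline(pc)
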