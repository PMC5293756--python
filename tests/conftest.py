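import pytest
from hypothesis import settings

from amfsecretome import (
    GeneratorConfig,
    apply_secretome_filter,
    default_design,
    generate_counts,
    generate_proteomes,
    resolve_consensus,
    run_comparisons,
)

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_config():
    """The default synthetic study conditions (fixed seed)."""
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def study(default_config):
    return generate_proteomes(default_config)


@pytest.fixture(scope="session")
def merged(study):
    return resolve_consensus(study.catalog_a, study.catalog_b, study.crossmap)


@pytest.fixture(scope="session")
def secretome(merged):
    return apply_secretome_filter(merged)


@pytest.fixture(scope="session")
def secretome2(study):
    return apply_secretome_filter(study.species2_catalog)


@pytest.fixture(scope="session")
def counts1(default_config, study):
    return generate_counts(default_config, study.truth, species=1)


@pytest.fixture(scope="session")
def calls1(default_config, counts1):
    return run_comparisons(counts1, default_design(default_config, 1))


@pytest.fixture(scope="session")
def small_config():
    """A fast, small-proteome configuration for unit-scale checks."""
    return GeneratorConfig(seed=11, n_genes=200)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_proteomes(small_config)
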