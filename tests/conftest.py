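import numpy as np
import pytest

from ppimod import SyntheticConfig, generate_counts, generate_interactome, write_fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down synthetic study used across integration-style tests."""
    return SyntheticConfig(
        n_genes=300, planted_module_size=12, n_pathways=15, rng_seed=11
    )


@pytest.fixture(scope="session")
def small_study(small_cfg):
    """(graph, planted, counts, meta, truth) for the scaled-down study."""
    g, planted = generate_interactome(small_cfg)
    counts, meta, truth = generate_counts(small_cfg, planted)
    return g, planted, counts, meta, truth


@pytest.fixture(scope="session")
def fixture_dir(small_cfg, tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    paths = write_fixtures(small_cfg, out)
    return out, paths
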