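import numpy as np
import pytest

from modsplice import build_module_set, load_annotation, load_genome
from modsplice.synthetic_fixtures import generate_mini_genome


@pytest.fixture(scope="session")
def mini_genome_paths(tmp_path_factory):
    out = tmp_path_factory.mktemp("mini")
    mini = generate_mini_genome(out, n_genes=12, exons_per_gene=3, seed=0)
    return mini


@pytest.fixture(scope="session")
def genome(mini_genome_paths):
    return load_genome(mini_genome_paths.fasta_path)


@pytest.fixture(scope="session")
def annotation(mini_genome_paths):
    return load_annotation(mini_genome_paths.gtf_path)


@pytest.fixture(scope="session")
def module_set():
    """Seeded, untrained modules: deterministic scores, cheap to build."""
    return build_module_set(seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
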