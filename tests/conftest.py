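import pytest

from msynet.synthetic_data import (
    simulate_haplotypes,
    two_haplogroup_tree,
    write_example_fixture,
)

SEED = 11


@pytest.fixture(scope="session")
def reference_matrix():
    """Genotype matrix of the bundled two-haplogroup genealogy (596 sites, 8 samples)."""
    matrix, truth = simulate_haplotypes(two_haplogroup_tree(), seed=SEED)
    return matrix, truth


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The on-disk reference fixture, written once per session."""
    outdir = tmp_path_factory.mktemp("fixture")
    return write_example_fixture(outdir, seed=SEED)
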