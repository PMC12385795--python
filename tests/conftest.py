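import pytest

from rgakit.classify import classify_genome
from rgakit.io import load_reference_counts
from rgakit.synthetic import SpeciesProfile, generate_genome

CLUSTER_SPEC = [("Chr01", 4, 8000), ("Chr02", 3, 5000), ("Chr05", 5, 9000)]


@pytest.fixture(scope="session")
def small_genome():
    """A 300-RGA synthetic genome with planted clusters and homologues."""
    profile = SpeciesProfile(
        seed=11, n_rga=300, n_non_rga=60, cluster_spec=CLUSTER_SPEC,
        n_rga_homologues=10, n_non_rga_homologues=4,
    )
    return generate_genome(profile)


@pytest.fixture(scope="session")
def small_annotations(small_genome):
    assembly, genes, domains, _ = small_genome
    annotations, table = classify_genome(
        genes, domains, assembly_order=[c.name for c in assembly]
    )
    return annotations, table


@pytest.fixture(scope="session")
def reference_counts():
    """The packaged per-chromosome RGA count table for the three genomes."""
    return load_reference_counts()
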