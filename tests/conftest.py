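import numpy as np
import pytest
from hypothesis import settings

from reducto import orthology, pipeline, simulate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

STUDY_LABELS = ("lactis_like", "bulgaricus_like")
DATASET_SEED = 3


@pytest.fixture(scope="session")
def dataset():
    """The default two-clade synthetic study dataset (10 strains)."""
    return simulate.simulate_clades(seed=DATASET_SEED)


@pytest.fixture(scope="session")
def ortholog_groups(dataset):
    proteins = pipeline.intact_proteins(dataset.strains)
    edges = orthology.similarity_edges(proteins)
    return proteins, edges, orthology.cluster_single_linkage(proteins, edges)


@pytest.fixture(scope="session")
def core_partition(dataset, ortholog_groups):
    _, _, groups = ortholog_groups
    return orthology.partition_core(groups, dataset.meta, STUDY_LABELS)


@pytest.fixture(scope="session")
def pseudo_calls(dataset):
    """Pseudogene scan of every strain against the other strains' proteins."""
    from reducto.pseudogenes import PseudoParams
    return pipeline.pseudo_scan_all(dataset.strains, PseudoParams())


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(42)
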