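import numpy as np
import pytest

from cnndlp.netio import DiseaseOntology, HeterogeneousNetwork
from cnndlp.synthetic import SyntheticSpec, generate_network, generate_ontology


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_network():
    """Hand-sized network: 2 lncRNAs, 2 diseases, 1 miRNA."""
    return HeterogeneousNetwork(
        lncrna_ids=["l1", "l2"],
        disease_ids=["d1", "d2"],
        mirna_ids=["m1"],
        A=np.array([[0.0, 1.0], [1.0, 0.0]]),
        B=np.array([[1.0], [0.0]]),
        C=np.array([[1.0, 0.0]]),
    )


@pytest.fixture
def two_branch_ontology():
    """root with two leaf children; two diseases on separate leaves."""
    return DiseaseOntology(
        terms={"root", "t1", "t2"},
        parent_edges={("t1", "root"), ("t2", "root")},
        disease_to_term={"d1": "t1", "d2": "t2"},
    )


@pytest.fixture(scope="session")
def small_spec():
    """A fast planted-signal network for pipeline smoke tests."""
    return SyntheticSpec(
        n_lncrna=18,
        n_disease=12,
        n_mirna=14,
        n_groups=3,
        p_in=0.6,
        p_out=0.05,
        ontology_depth=3,
        ontology_branching=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    net, truth = generate_network(small_spec)
    onto = generate_ontology(
        small_spec.n_disease,
        small_spec.ontology_depth,
        small_spec.ontology_branching,
        small_spec.seed + 1,
        groups=truth.disease,
    )
    return net, onto, truth
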