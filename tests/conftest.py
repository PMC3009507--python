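import pytest

from funcoherence.coherence import Module
from funcoherence.fixtures import WORKED_EXAMPLE_MODULES, build_worked_example, generate_corpus, generate_ontology


@pytest.fixture(scope="session")
def worked_example():
    """(ontology, corpus) of the six-molecule worked example."""
    return build_worked_example()


@pytest.fixture(scope="session")
def example_modules(worked_example):
    """The three worked-example modules keyed R1/R2/R3."""
    _, corpus = worked_example
    return {
        name: Module.from_corpus(corpus, mols)
        for name, mols in WORKED_EXAMPLE_MODULES.items()
    }


@pytest.fixture(scope="session")
def random_world():
    """A factory for small random (ontology, corpus) pairs, seeded."""

    def make(seed, n_terms=15, n_molecules=20, terms_per_molecule=2, max_parents=2):
        ontology = generate_ontology(n_terms, max_parents=max_parents, seed=seed)
        corpus = generate_corpus(
            ontology, n_molecules, terms_per_molecule=terms_per_molecule, seed=seed + 1
        )
        return ontology, corpus

    return make
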