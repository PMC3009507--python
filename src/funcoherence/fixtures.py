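"""Deterministic worked-example data and seeded synthetic generators.

``build_worked_example`` reconstructs the six-molecule, six-term toy ontology
used as the worked example throughout the package: a root ``r`` with
three children ``c1``, ``c2``, ``c3``, a leaf ``c4`` under ``c2`` and a
leaf ``c6`` under ``c3``; molecules ``S1``..``S6`` annotated so that
``I(c4) = I(c6) = I(c2) = I(c3) = 1`` bit, ``I(c1) = log2 3`` and
``I(r) = 0``.  Every coherence measure has a hand-computable value on
this fixture, asserted at construction.

The generators build random rooted DAG ontologies, leaf-biased
annotation corpora, planted-family test/control module collections
(emulating known-complex vs random protein sets), and planted-partition
interaction networks whose topological blocks coincide with functional
families — so that proximity-vs-similarity and detectability analyses
can be exercised end to end without external data.  All generators are
pure functions of their seed and parameters.
"""

from __future__ import annotations

import math

import numpy as np

from .coherence import Module
from .network import InteractionGraph
from .ontology import AnnotationCorpus, OntologyDAG

__all__ = [
    "build_worked_example",
    "WORKED_EXAMPLE_MODULES",
    "generate_ontology",
    "generate_corpus",
    "generate_test_control_modules",
    "generate_modular_network",
    "generate_functional_benchmark",
]

#: The three worked-example modules: the full bridged complex R1, and the
#: two sub-complexes R2 (shared term c4) and R3 (shared term c6).
WORKED_EXAMPLE_MODULES = {
    "R1": ["S1", "S2", "S3", "S4"],
    "R2": ["S1", "S2", "S3"],
    "R3": ["S3", "S4"],
}


def build_worked_example() -> tuple[OntologyDAG, AnnotationCorpus]:
    """The worked-example ontology and annotation corpus.

    Construction asserts the information-content invariants the example
    arithmetic depends on.
    """
    ontology = OntologyDAG(
        [("c1", "r"), ("c2", "r"), ("c3", "r"), ("c4", "c2"), ("c6", "c3")]
    )
    corpus = AnnotationCorpus(
        ontology,
        {
            "S1": {"c4"},
            "S2": {"c4"},
            "S3": {"c4", "c6"},
            "S4": {"c1", "c6"},
            "S5": {"c1"},
            "S6": {"c6"},
        },
    )
    for term in ("c2", "c3", "c4", "c6"):
        assert math.isclose(corpus.info_content(term), 1.0), term
    assert math.isclose(corpus.info_content("c1"), math.log2(3))
    assert corpus.info_content("r") == 0.0
    assert len(corpus) == 6
    return ontology, corpus


def generate_ontology(
    n_terms: int, max_parents: int = 2, seed: int | None = None
) -> OntologyDAG:
    """Random rooted DAG: term i (in creation order) draws 1..max_parents
    parents uniformly among earlier terms, so acyclicity holds by
    construction.  Deterministic per seed."""
    if n_terms < 2:
        raise ValueError("an ontology needs at least a root and one term")
    if max_parents < 1:
        raise ValueError("max_parents must be >= 1")
    rng = np.random.default_rng(seed)
    names = ["r"] + [f"c{i}" for i in range(1, n_terms)]
    edges = []
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        parents = rng.choice(i, size=k, replace=False)
        edges.extend((names[i], names[int(p)]) for p in parents)
    return OntologyDAG(edges)


def generate_corpus(
    ontology: OntologyDAG,
    n_molecules: int,
    terms_per_molecule: int = 2,
    seed: int | None = None,
) -> AnnotationCorpus:
    """Random corpus with leaf-biased annotations.

    Each molecule samples ``terms_per_molecule`` distinct terms with
    probability proportional to term depth (size of the reflexive
    ancestor set), mimicking the specificity bias of curated annotation;
    the sample is then reduced to its non-redundant form, which may
    shrink it.  Deterministic per seed.
    """
    if n_molecules < 1 or terms_per_molecule < 1:
        raise ValueError("n_molecules and terms_per_molecule must be positive")
    rng = np.random.default_rng(seed)
    terms = sorted(ontology.terms)
    weights = np.array([len(ontology.ancestors(t)) for t in terms], dtype=float)
    probs = weights / weights.sum()
    k = min(terms_per_molecule, len(terms))
    annotations = {}
    for i in range(n_molecules):
        picked = rng.choice(len(terms), size=k, replace=False, p=probs)
        annotations[f"m{i}"] = {terms[int(j)] for j in picked}
    return AnnotationCorpus(ontology, annotations)


def _planted_terms(corpus: AnnotationCorpus, min_support: int) -> list[str]:
    """Candidate family-defining terms: informative (non-root) terms whose
    true-path closure covers at least ``min_support`` molecules."""
    ontology = corpus.ontology
    return sorted(
        t
        for t in ontology.terms
        if t != ontology.root and len(corpus.molecules_for(t)) >= min_support
    )


def generate_test_control_modules(
    corpus: AnnotationCorpus,
    sizes: tuple[int, ...] = (4, 5, 6, 7, 8, 9, 10, 11),
    n_per_size: int = 25,
    coherence_bias: float = 0.8,
    seed: int | None = None,
) -> tuple[list[Module], list[Module]]:
    """Planted-coherent test modules and uniform-random control modules.

    Each test module picks a planted family term (an informative term
    whose closure covers at least ``max(sizes)`` molecules); every member
    is drawn, with probability ``coherence_bias``, from that family
    (without replacement) and otherwise uniformly from the whole corpus.
    Control modules are uniform random molecule subsets — the structure
    of known-complex vs wildtype benchmark sets.  ``coherence_bias = 0``
    makes the two collections statistically indistinguishable.

    Returns ``n_per_size`` test and ``n_per_size`` control modules for
    every requested size, in order.
    """
    if not 0.0 <= coherence_bias <= 1.0:
        raise ValueError("coherence_bias must lie in [0, 1]")
    mols = sorted(corpus.molecules)
    if max(sizes) > len(mols):
        raise ValueError("corpus too small for the largest requested module size")
    rng = np.random.default_rng(seed)
    candidates = _planted_terms(corpus, min_support=max(sizes))
    if not candidates:
        raise ValueError(
            "corpus has no informative term supporting the largest module size"
        )
    test: list[Module] = []
    control: list[Module] = []
    for size in sizes:
        for _ in range(n_per_size):
            planted = candidates[int(rng.integers(len(candidates)))]
            family = sorted(corpus.molecules_for(planted))
            chosen: list[str] = []
            for _ in range(size):
                pool = [m for m in family if m not in chosen]
                if pool and rng.random() < coherence_bias:
                    chosen.append(pool[int(rng.integers(len(pool)))])
                else:
                    rest = [m for m in mols if m not in chosen]
                    chosen.append(rest[int(rng.integers(len(rest)))])
            test.append(Module.from_corpus(corpus, chosen))
            picked = rng.choice(len(mols), size=size, replace=False)
            control.append(Module.from_corpus(corpus, (mols[int(i)] for i in picked)))
    return test, control


def generate_modular_network(
    families: list[list[str]],
    p_in: float,
    p_out: float,
    seed: int | None = None,
) -> InteractionGraph:
    """Planted-partition interaction network over the given node blocks.

    Every within-block node pair is joined with probability ``p_in``,
    every cross-block pair with probability ``p_out`` (requires
    ``p_in > p_out``).  With ``p_out = 0`` the connected components are
    exactly the blocks.  Deterministic per seed.
    """
    if not 0.0 <= p_out < p_in <= 1.0:
        raise ValueError("need 0 <= p_out < p_in <= 1")
    rng = np.random.default_rng(seed)
    block_of = {}
    nodes: list[str] = []
    for b, fam in enumerate(families):
        for node in fam:
            if node in block_of:
                raise ValueError(f"node {node!r} appears in more than one family")
            block_of[node] = b
            nodes.append(node)
    edges = []
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            p = p_in if block_of[nodes[i]] == block_of[nodes[j]] else p_out
            if rng.random() < p:
                edges.append((nodes[i], nodes[j]))
    return InteractionGraph(edges, nodes=nodes)


def generate_functional_benchmark(
    n_families: int = 12,
    family_size: int = 8,
    leaves_per_family: int = 6,
    terms_per_molecule: int = 2,
    p_in: float = 0.6,
    p_out: float = 0.05,
    seed: int | None = None,
) -> tuple[OntologyDAG, AnnotationCorpus, InteractionGraph, list[list[str]]]:
    """A complete synthetic benchmark where topology matches function.

    Builds a two-level ontology (root -> family terms -> leaf terms), a
    corpus in which the molecules of family k are annotated with random
    leaves under family term ``b{k}``, and a planted-partition network
    whose blocks are exactly those families.  Within-family molecule
    pairs therefore share an informative ancestor and sit in the same
    dense network block, so functional similarity and topological
    proximity are positively coupled by construction.

    Returns ``(ontology, corpus, graph, families)`` with
    ``families[k]`` listing the molecule identifiers of block k.
    """
    rng = np.random.default_rng(seed)
    edges = []
    for k in range(n_families):
        edges.append((f"b{k}", "r"))
        for j in range(leaves_per_family):
            edges.append((f"b{k}.l{j}", f"b{k}"))
    ontology = OntologyDAG(edges)
    annotations = {}
    families: list[list[str]] = []
    k_terms = min(terms_per_molecule, leaves_per_family)
    for k in range(n_families):
        leaves = [f"b{k}.l{j}" for j in range(leaves_per_family)]
        fam = []
        for i in range(family_size):
            mol = f"f{k}m{i}"
            picked = rng.choice(leaves_per_family, size=k_terms, replace=False)
            annotations[mol] = {leaves[int(j)] for j in picked}
            fam.append(mol)
        families.append(fam)
    corpus = AnnotationCorpus(ontology, annotations)
    net_seed = int(rng.integers(2**31))
    graph = generate_modular_network(families, p_in, p_out, seed=net_seed)
    return ontology, corpus, graph, families
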