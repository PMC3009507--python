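"""Ontology DAG, ancestor machinery and information content.

The ontology is a finite partially ordered set of terms related by
"is a"/"part of" edges, with a single terminal root ``r`` that every term
can reach.  A molecule annotated with a term is implicitly annotated with
every ancestor of that term (the true path rule), which is what makes
information content well defined: ``I(c) = -log2(|G_c| / |G_r|)`` where
``G_c`` is the set of molecules associated with ``c`` or any of its
descendants and ``G_r`` is the whole annotated corpus.

Ancestor sets here are *reflexive* — ``ancestors(c)`` contains ``c``
itself — because every downstream formula (graph information content,
weighted information content) sums information over ancestor DAGs that
include the annotated terms themselves.
"""

from __future__ import annotations

import logging
import math
from typing import Dict, FrozenSet, Iterable, Iterator, Mapping, Set

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["OntologyDAG", "AnnotationCorpus", "TermSet"]


class OntologyDAG:
    """A rooted DAG of ontology terms.

    Parameters
    ----------
    edges
        Iterable of ``(child, parent)`` pairs meaning *child is-a/part-of
        parent*.  "is a" and "part of" are deliberately collapsed into a
        single edge kind; none of the implemented measures distinguish them.
    terms
        Optional extra isolated terms (besides those appearing in edges).
        Only the root may legitimately be isolated.

    Raises
    ------
    ValueError
        If the edge set contains a cycle, if no unique root (a term with
        no parents reachable from every term) exists.
    """

    def __init__(self, edges: Iterable[tuple[str, str]], terms: Iterable[str] = ()) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        g.add_edges_from(edges)  # child -> parent orientation
        if g.number_of_nodes() == 0:
            raise ValueError("ontology must contain at least one term")
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle: {cycle}")
        roots = [n for n in g.nodes if g.out_degree(n) == 0]
        if len(roots) != 1:
            raise ValueError(
                f"ontology must have exactly one root (term with no parents); found {sorted(roots)}"
            )
        self._graph = g
        self.root: str = roots[0]
        # reflexive ancestor closure, computed once; ontologies here are small
        self._ancestors: Dict[str, FrozenSet[str]] = {}
        for node in reversed(list(nx.topological_sort(g))):
            anc: Set[str] = {node}
            for parent in g.successors(node):
                anc |= self._ancestors[parent]
            self._ancestors[node] = frozenset(anc)
        unreachable = [t for t in g.nodes if self.root not in self._ancestors[t]]
        if unreachable:
            raise ValueError(f"terms cannot reach the root: {sorted(unreachable)[:5]}")

    # -- basic container protocol -------------------------------------------------

    @property
    def terms(self) -> FrozenSet[str]:
        return frozenset(self._graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self._graph

    def __len__(self) -> int:
        return self._graph.number_of_nodes()

    def __iter__(self) -> Iterator[str]:
        return iter(self._graph.nodes)

    @property
    def graph(self) -> nx.DiGraph:
        """The underlying child->parent digraph (read-only by convention)."""
        return self._graph

    def _check(self, term: str) -> None:
        if term not in self._graph:
            raise KeyError(f"unknown ontology term: {term!r}")

    # -- order relations ----------------------------------------------------------

    def ancestors(self, term: str) -> FrozenSet[str]:
        """Reflexive ancestor set: the term itself plus everything above it.

        Always contains the root.
        """
        self._check(term)
        return self._ancestors[term]

    def is_ancestor(self, ci: str, cj: str) -> bool:
        """True iff ``cj`` is a (reflexive) ancestor of ``ci``."""
        self._check(ci)
        self._check(cj)
        return cj in self._ancestors[ci]

    def comparable(self, ci: str, cj: str) -> bool:
        """True iff one term is an ancestor of the other (or they are equal)."""
        return self.is_ancestor(ci, cj) or self.is_ancestor(cj, ci)

    def path_length(self, ci: str, cj: str) -> int:
        """Minimum number of edges along directed ancestor paths between
        two comparable terms.  Zero for a term and itself.

        Raises
        ------
        ValueError
            If the terms are not comparable (no directed path either way).
        """
        self._check(ci)
        self._check(cj)
        if cj in self._ancestors[ci]:
            lo, hi = ci, cj
        elif ci in self._ancestors[cj]:
            lo, hi = cj, ci
        else:
            raise ValueError(f"terms {ci!r} and {cj!r} are not comparable")
        return nx.shortest_path_length(self._graph, lo, hi)

    # -- minimum common ancestors & non-redundancy --------------------------------

    def reduce_nonredundant(self, terms: Iterable[str]) -> "TermSet":
        """Drop every term that is a strict ancestor of another member.

        This is the generalized-union reduction: only the most specific
        terms survive.  Idempotent and order-independent.
        """
        pool = set(terms)
        for t in pool:
            self._check(t)
        keep = {
            t
            for t in pool
            if not any(u != t and t in self._ancestors[u] for u in pool)
        }
        return TermSet(self, keep)

    def min_common_ancestors(self, *terms: str) -> "TermSet":
        """Most specific terms ancestral (reflexively) to every input term.

        On a DAG the result may contain more than one term; on a tree it is
        a single term.  ``min_common_ancestors(c) == {c}``.
        """
        if not terms:
            raise ValueError("min_common_ancestors requires at least one term")
        common: Set[str] = set(self.ancestors(terms[0]))
        for t in terms[1:]:
            common &= self.ancestors(t)
        # the root is an ancestor of everything, so common is never empty
        minimal = {
            t
            for t in common
            if not any(u != t and t in self._ancestors[u] for u in common)
        }
        return TermSet(self, minimal)


class TermSet:
    """A non-redundant set of terms from one ontology.

    No member is a (strict) ancestor of another member.  Construction
    verifies this; use :meth:`OntologyDAG.reduce_nonredundant` to build one
    from an arbitrary collection.
    """

    __slots__ = ("ontology", "terms")

    def __init__(self, ontology: OntologyDAG, terms: Iterable[str]) -> None:
        tset = frozenset(terms)
        for t in tset:
            if t not in ontology:
                raise KeyError(f"unknown ontology term: {t!r}")
        for t in tset:
            for u in tset:
                if t != u and ontology.is_ancestor(u, t):
                    raise ValueError(
                        f"redundant term set: {t!r} is an ancestor of {u!r}"
                    )
        self.ontology = ontology
        self.terms = tset

    def __iter__(self) -> Iterator[str]:
        return iter(self.terms)

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def __eq__(self, other: object) -> bool:
        if isinstance(other, TermSet):
            return self.terms == other.terms and self.ontology is other.ontology
        if isinstance(other, (set, frozenset)):
            return self.terms == other
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.terms)

    def __repr__(self) -> str:
        return f"TermSet({sorted(self.terms)})"

    def ancestor_union(self) -> FrozenSet[str]:
        """Union of the reflexive ancestor sets of all members: the
        ancestor DAG induced by this annotation set."""
        out: Set[str] = set()
        for t in self.terms:
            out |= self.ontology.ancestors(t)
        return frozenset(out)


class AnnotationCorpus:
    """Molecule -> term-set annotations over one ontology.

    Stored term sets are reduced to their most specific (non-redundant)
    form.  A closure index maps every term to the molecules associated with
    it *or any of its descendants*, satisfying the true path rule; the root
    indexes every annotated molecule.

    Parameters
    ----------
    ontology
        The DAG the annotations refer to.
    annotations
        Mapping of molecule identifier to an iterable of term identifiers.
        Terms absent from the ontology are dropped with a logged warning
        (annotation corpora routinely contain obsolete terms); molecules
        left with no valid term are omitted entirely.
    """

    def __init__(
        self,
        ontology: OntologyDAG,
        annotations: Mapping[str, Iterable[str]],
    ) -> None:
        self.ontology = ontology
        self._annotations: Dict[str, TermSet] = {}
        self.n_dropped_terms = 0
        for mol, terms in annotations.items():
            valid = []
            for t in terms:
                if t in ontology:
                    valid.append(t)
                else:
                    self.n_dropped_terms += 1
                    logger.warning("dropping unknown term %r for molecule %r", t, mol)
            if valid:
                self._annotations[mol] = ontology.reduce_nonredundant(valid)
        # closure index: term -> molecules annotated at or below the term
        self._index: Dict[str, Set[str]] = {t: set() for t in ontology}
        for mol, tset in self._annotations.items():
            for term in tset:
                for anc in ontology.ancestors(term):
                    self._index[anc].add(mol)

    # -- container protocol --------------------------------------------------------

    @property
    def molecules(self) -> FrozenSet[str]:
        return frozenset(self._annotations)

    def __len__(self) -> int:
        return len(self._annotations)

    def __contains__(self, molecule: str) -> bool:
        return molecule in self._annotations

    def __getitem__(self, molecule: str) -> TermSet:
        try:
            return self._annotations[molecule]
        except KeyError:
            raise KeyError(f"unknown molecule: {molecule!r}") from None

    def items(self) -> Iterable[tuple[str, TermSet]]:
        return self._annotations.items()

    def molecules_for(self, term: str) -> FrozenSet[str]:
        """Molecules associated with ``term`` via the true-path closure."""
        if term not in self._index:
            raise KeyError(f"unknown ontology term: {term!r}")
        return frozenset(self._index[term])

    # -- information content --------------------------------------------------------

    def info_content(self, terms: str | TermSet | Iterable[str]) -> float:
        """Information content in bits.

        For a single term ``c``: ``-log2(|G_c| / |G_r|)``.  For a term set,
        the fraction is over molecules associated with *all* terms in the
        set.  ``I(root) = 0``.  A set supported by no molecule yields
        ``math.inf`` — callers decide whether that is an error.
        """
        if len(self._annotations) == 0:
            raise ValueError("corpus is empty; information content undefined")
        if isinstance(terms, str):
            term_iter: Iterable[str] = (terms,)
        else:
            term_iter = terms
        support: Set[str] | None = None
        for t in term_iter:
            mols = self._index.get(t)
            if mols is None:
                raise KeyError(f"unknown ontology term: {t!r}")
            support = set(mols) if support is None else support & mols
        if support is None:
            raise ValueError("information content of an empty term set is undefined")
        if not support:
            return math.inf
        return -math.log2(len(support) / len(self._annotations)) + 0.0
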