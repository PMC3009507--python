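"""Semantic similarity of terms and of annotated molecules.

Term-level measures
-------------------
``delta_I``   Resnik-style: the information content of the most informative
              minimum common ancestor of the two terms.
``delta_JC``  A self-normalized variant bounded in (0, 1]:
              ``1 / (I(ci) + I(cj) - 2 delta_I(ci, cj) + 1)`` — the
              reciprocal of the Jiang-Conrath distance plus one, so that
              identical (or equally informative, comparable) terms score 1.

Molecule-level measures (between two non-redundant term sets)
-------------------------------------------------------------
``rho_A``   average of the term measure over all term pairs
``rho_M``   maximum over all term pairs
``rho_H``   average of best-match scores, symmetrized over both directions
``rho_I``   information content of the minimum-common-ancestor set
            Lambda(Si, Sj): all pairwise minimum common ancestors, reduced
            to their most specific representatives, scored as a set
            (molecules supporting *all* terms in the set)
``rho_JC``  self-normalized rho_I:
            ``1 / (rho_I(Si,Si) + rho_I(Sj,Sj) - 2 rho_I(Si,Sj) + 1)``
"""

from __future__ import annotations

from statistics import fmean
from typing import Callable, Iterable

from .ontology import AnnotationCorpus, OntologyDAG, TermSet

__all__ = [
    "delta_I",
    "delta_JC",
    "mca_set",
    "pair_similarity",
    "combine_subontology",
    "PAIR_MEASURES",
    "TERM_MEASURES",
]


def delta_I(ci: str, cj: str, corpus: AnnotationCorpus) -> float:
    """Resnik term similarity: IC of the most informative minimum common
    ancestor.  Symmetric; ``delta_I(c, c) == I(c)``.

    On a DAG there may be several minimal common ancestors; the maximum IC
    among them is taken (standard Resnik convention).
    """
    mcas = corpus.ontology.min_common_ancestors(ci, cj)
    return max(corpus.info_content(t) for t in mcas)


def delta_JC(ci: str, cj: str, corpus: AnnotationCorpus) -> float:
    """Self-normalized term similarity in (0, 1], equal to 1 iff the
    Jiang-Conrath distance ``I(ci) + I(cj) - 2 delta_I`` is zero."""
    d = corpus.info_content(ci) + corpus.info_content(cj) - 2.0 * delta_I(ci, cj, corpus)
    return 1.0 / (d + 1.0)


TERM_MEASURES: dict[str, Callable[[str, str, AnnotationCorpus], float]] = {
    "delta_I": delta_I,
    "delta_JC": delta_JC,
}


def mca_set(si: TermSet | Iterable[str], sj: TermSet | Iterable[str], ontology: OntologyDAG) -> TermSet:
    """Lambda(Si, Sj): the generalized-union-reduced set of all pairwise
    minimum common ancestors between the two term sets."""
    pool: set[str] = set()
    for ci in si:
        for cj in sj:
            pool |= ontology.min_common_ancestors(ci, cj).terms
    return ontology.reduce_nonredundant(pool)


def _as_termset(s: TermSet | Iterable[str], ontology: OntologyDAG) -> TermSet:
    if isinstance(s, TermSet):
        return s
    return ontology.reduce_nonredundant(s)


def _rho_I(si: TermSet, sj: TermSet, corpus: AnnotationCorpus) -> float:
    return corpus.info_content(mca_set(si, sj, corpus.ontology))


def pair_similarity(
    si: TermSet | Iterable[str],
    sj: TermSet | Iterable[str],
    measure: str,
    corpus: AnnotationCorpus,
    term_measure: str = "delta_I",
) -> float:
    """Similarity between two molecules' non-redundant term sets.

    Parameters
    ----------
    si, sj
        Non-redundant term sets (arbitrary term collections are reduced).
        Must be non-empty.
    measure
        One of ``rho_A``, ``rho_M``, ``rho_H`` (aggregates of a term
        measure) or ``rho_I``, ``rho_JC`` (set-level information content).
    term_measure
        ``delta_I`` or ``delta_JC``; used only by the aggregating measures.
    """
    ontology = corpus.ontology
    a = _as_termset(si, ontology)
    b = _as_termset(sj, ontology)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("pair similarity requires non-empty term sets")
    if measure in ("rho_A", "rho_M", "rho_H"):
        try:
            delta = TERM_MEASURES[term_measure]
        except KeyError:
            raise ValueError(f"unknown term measure: {term_measure!r}") from None
        scores = {(ci, cj): delta(ci, cj, corpus) for ci in a for cj in b}
        if measure == "rho_A":
            return fmean(scores.values())
        if measure == "rho_M":
            return max(scores.values())
        # rho_H: best match per term, averaged within each direction,
        # then averaged over the two directions for symmetry
        fwd = fmean(max(scores[(ci, cj)] for cj in b) for ci in a)
        rev = fmean(max(scores[(ci, cj)] for ci in a) for cj in b)
        return 0.5 * (fwd + rev)
    if measure == "rho_I":
        return _rho_I(a, b, corpus)
    if measure == "rho_JC":
        d = _rho_I(a, a, corpus) + _rho_I(b, b, corpus) - 2.0 * _rho_I(a, b, corpus)
        return 1.0 / (d + 1.0)
    raise ValueError(f"unknown pair measure: {measure!r}")


PAIR_MEASURES = ("rho_A", "rho_M", "rho_H", "rho_I", "rho_JC")


def combine_subontology(
    score_bp: float, score_mf: float, max_bp: float, max_mf: float
) -> float:
    """Combine biological-process and molecular-function scores into one
    value in [0, 1]: half the sum of the squared normalized scores
    (the funsim combination).

    ``max_bp`` / ``max_mf`` are the maximum attainable (in practice, the
    corpus-wide maximum observed) scores for the two sub-ontologies.
    """
    if max_bp <= 0 or max_mf <= 0:
        raise ValueError("sub-ontology maxima must be positive")
    return 0.5 * ((score_bp / max_bp) ** 2 + (score_mf / max_mf) ** 2)
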