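"""Module-level functional coherence and detectability.

A *module* is an ordered collection of molecules, each carrying its own
non-redundant term set: R = {S_1, ..., S_n} — a protein complex, a dense
network neighborhood, a candidate pathway.  Four measures score how
functionally homogeneous the module is:

``sigma_A``
    mean of a chosen pairwise similarity over all n(n-1)/2 member pairs.
``sigma_I``
    information content of Lambda(R), the non-redundant set of minimum
    common ancestors taken over tuples drawn one term per member.  Very
    conservative: only rewards functions shared by *every* member.
``sigma_G``
    graph information content — total IC of the intersection of the
    members' ancestor DAGs divided by the total IC of their union.
    Bounded in [0, 1]; one outlier member can drive it to zero.
``sigma_W``
    weighted information content — each term in the combined ancestor DAG
    is weighted by the number of members n_t whose ancestor DAG contains
    it; the score is the weighted IC of terms shared by at least two
    members over the weighted IC of all terms.  Rewards partial sharing,
    so bridged complexes made of overlapping sub-complexes still score
    high; in [0, 1].

Raw scores depend on module size; ``size_adjust`` centers a score on the
mean over random modules of the same size drawn from the corpus.  The
``detectability`` index D summarizes how well a measure separates a
collection of known-coherent (test) modules from random (control) ones:
``D = (mean_T - mean_C) / sqrt(var_T + var_C)``, monotone in the area
under the binormal ROC curve via the normal CDF.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .ontology import AnnotationCorpus, TermSet
from .similarity import mca_set, pair_similarity

__all__ = [
    "Module",
    "DetectabilityReport",
    "sigma_A",
    "sigma_I",
    "sigma_G",
    "sigma_W",
    "score_module",
    "size_adjust",
    "detectability",
    "MODULE_MEASURES",
]


class Module:
    """An ordered collection of (molecule identifier, term set) members."""

    def __init__(self, members: Iterable[tuple[str, TermSet]]) -> None:
        self.members: list[tuple[str, TermSet]] = list(members)
        if not self.members:
            raise ValueError("a module must have at least one member")
        for mol, tset in self.members:
            if len(tset) == 0:
                raise ValueError(f"member {mol!r} has an empty term set")

    @classmethod
    def from_corpus(cls, corpus: AnnotationCorpus, molecules: Iterable[str]) -> "Module":
        """Build a module from molecules annotated in the corpus."""
        return cls((m, corpus[m]) for m in molecules)

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def molecules(self) -> list[str]:
        return [m for m, _ in self.members]

    @property
    def term_sets(self) -> list[TermSet]:
        return [s for _, s in self.members]

    def __len__(self) -> int:
        return len(self.members)

    def __repr__(self) -> str:
        return f"Module({self.molecules})"


def sigma_A(
    module: Module,
    corpus: AnnotationCorpus,
    pair_measure: str = "rho_A",
    term_measure: str = "delta_I",
) -> float:
    """Average pairwise similarity over all unordered member pairs.

    Requires at least two members.  Any pair measure accepted by
    :func:`funcoherence.similarity.pair_similarity` can be plugged in;
    the classical choice is ``rho_A`` over ``delta_I``.
    """
    sets = module.term_sets
    n = len(sets)
    if n < 2:
        raise ValueError("sigma_A requires a module with at least two members")
    total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            total += pair_similarity(sets[i], sets[j], pair_measure, corpus, term_measure)
    return total / (n * (n - 1) / 2)


def module_mca_set(module: Module, corpus: AnnotationCorpus) -> TermSet:
    """Lambda(R): minimum common ancestors over all members, computed by
    iterative pairwise folding (Lambda of the running result with each
    next member, reduced after every step).

    Equivalent to the tuple enumeration — one term per member, minimum
    common ancestors of each tuple, generalized union — but polynomial
    instead of exponential in the module size.
    """
    ontology = corpus.ontology
    acc = module.term_sets[0]
    for tset in module.term_sets[1:]:
        acc = mca_set(acc, tset, ontology)
    return acc


def sigma_I(module: Module, corpus: AnnotationCorpus) -> float:
    """Generalized information content: IC of the module's minimum common
    ancestor set, as a set (molecules supporting all its terms).

    For a single-member module this degenerates to the IC of that
    member's own term set.
    """
    return corpus.info_content(module_mca_set(module, corpus))


def sigma_G(module: Module, corpus: AnnotationCorpus) -> float:
    """Graph information content: summed IC of terms in the intersection
    of all members' ancestor DAGs over the summed IC of their union.

    In [0, 1].  When the union carries zero total information (all
    members annotated at the root only) the module is trivially coherent
    and the score is 1 by convention.
    """
    ancestor_sets = [s.ancestor_union() for s in module.term_sets]
    inter = frozenset.intersection(*ancestor_sets)
    union = frozenset.union(*ancestor_sets)
    denom = sum(corpus.info_content(t) for t in union)
    if denom == 0.0:
        return 1.0
    num = sum(corpus.info_content(t) for t in inter)
    return num / denom


def sigma_W(module: Module, corpus: AnnotationCorpus) -> float:
    """Weighted information content.

    Let n_t be the number of members whose (reflexive) ancestor DAG
    contains term t.  The score is

        sum_{t : n_t >= 2} n_t I(t)  /  sum_{t in union} n_t I(t)

    i.e. shared information over total information, with each term
    weighted by how many members carry it.  In [0, 1]; requires n >= 2.
    The root contributes zero weight (I(r) = 0), so it needs no special
    casing.
    """
    if module.size < 2:
        raise ValueError("sigma_W requires a module with at least two members")
    counts: Counter[str] = Counter()
    for tset in module.term_sets:
        counts.update(tset.ancestor_union())
    shared = 0.0
    total = 0.0
    for term, n_t in counts.items():
        w = n_t * corpus.info_content(term)
        total += w
        if n_t >= 2:
            shared += w
    if total == 0.0:
        return 1.0
    return shared / total


MODULE_MEASURES: dict[str, Callable[[Module, AnnotationCorpus], float]] = {
    "sigma_A": sigma_A,
    "sigma_I": sigma_I,
    "sigma_G": sigma_G,
    "sigma_W": sigma_W,
}


def score_module(module: Module, corpus: AnnotationCorpus, measure: str, **kwargs) -> float:
    """Dispatch a named module measure (``sigma_A``/``sigma_I``/``sigma_G``/``sigma_W``)."""
    try:
        fn = MODULE_MEASURES[measure]
    except KeyError:
        raise ValueError(f"unknown module measure: {measure!r}") from None
    return fn(module, corpus, **kwargs)


def sample_random_module(
    corpus: AnnotationCorpus, size: int, rng: np.random.Generator
) -> Module:
    """Uniformly sample ``size`` distinct annotated molecules as a module."""
    mols = sorted(corpus.molecules)
    if size > len(mols):
        raise ValueError(
            f"module size {size} exceeds number of annotated molecules {len(mols)}"
        )
    picked = rng.choice(len(mols), size=size, replace=False)
    return Module.from_corpus(corpus, (mols[i] for i in picked))


def size_adjust(
    score: float,
    module_size: int,
    corpus: AnnotationCorpus,
    score_fn: Callable[[Module], float],
    n_random: int = 1000,
    seed: int | np.random.Generator | None = None,
    method: str = "difference",
) -> float:
    """Center a coherence score on a same-size random background.

    Draws ``n_random`` random modules of ``module_size`` molecules from
    the corpus, scores each with ``score_fn``, and returns the score
    minus the background mean (``method="difference"``, default; keeps
    score units and is zero-centered under the null) or the score over
    the mean (``method="ratio"``).  Deterministic given a seed.
    """
    if n_random < 30:
        raise ValueError("n_random must be at least 30 for a stable background")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    background = np.array(
        [score_fn(sample_random_module(corpus, module_size, rng)) for _ in range(n_random)]
    )
    mean = float(background.mean())
    if method == "difference":
        return score - mean
    if method == "ratio":
        if mean == 0.0:
            raise ValueError("background mean is zero; ratio adjustment undefined")
        return score / mean
    raise ValueError(f"unknown adjustment method: {method!r}")


@dataclass
class DetectabilityReport:
    """Separation between test and control coherence-score distributions.

    ``d`` is the binormal separation index
    ``(mean_T - mean_C) / sqrt(var_T + var_C)`` (sample variances);
    ``norm.cdf(d)`` equals the area under the binormal ROC curve for the
    two fitted normals.  ``threshold`` is the value of d at which that
    area reaches 0.95, i.e. the p < 0.05 significance line.
    """

    test_mean: float
    test_var: float
    control_mean: float
    control_var: float
    d: float
    threshold: float = field(default=float(norm.ppf(0.95)))

    @property
    def auc(self) -> float:
        """Area under the binormal ROC curve implied by d."""
        return float(norm.cdf(self.d))

    @property
    def significant(self) -> bool:
        """True when the separation exceeds the p < 0.05 threshold."""
        return self.d > self.threshold


def detectability(
    test_scores: Sequence[float], control_scores: Sequence[float]
) -> DetectabilityReport:
    """Index of detectability between two score collections.

    Both collections need at least two values (sample variances).  With
    zero pooled variance the index is 0 for equal means and signed
    infinity otherwise.
    """
    t = np.asarray(test_scores, dtype=float)
    c = np.asarray(control_scores, dtype=float)
    if t.size < 2 or c.size < 2:
        raise ValueError("detectability requires at least two scores per group")
    mt, mc = float(t.mean()), float(c.mean())
    vt, vc = float(t.var(ddof=1)), float(c.var(ddof=1))
    pooled = vt + vc
    if pooled == 0.0:
        d = 0.0 if mt == mc else math.copysign(math.inf, mt - mc)
    else:
        d = (mt - mc) / math.sqrt(pooled)
    return DetectabilityReport(mt, vt, mc, vc, d)
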