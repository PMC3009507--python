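# Methods

## Ontology model

An ontology is a finite partially ordered set of terms with directed
"is a"/"part of" edges pointing from child to parent and a single terminal
root `r` reachable from every term. The two relation kinds are collapsed
into one edge kind: none of the implemented measures distinguishes them.
Ancestor sets are **reflexive** — `ancestors(c)` contains `c` itself —
because every formula that consumes ancestor sets (graph and weighted
information content, minimum-common-ancestor construction) needs the
annotated terms in the DAG they induce. The strict relation is recoverable
through `comparable(ci, cj)` plus an identity check. Raw directed edge
counts between comparable terms are exposed as `path_length`; no
implemented measure consumes a path-length-based similarity, so no +1
convention is imposed on it.

Annotation corpora store each molecule's *most specific* terms (no member
ancestral to another); the association with all ancestors is implied by the
true path rule and materialized in a closure index
`term -> molecules at or below the term`. Corpus terms absent from the
ontology (obsolete identifiers are routine in real annotation files) are
dropped with a logged warning and counted, never remapped.

Information content uses log base 2 throughout, so scores are in bits.
The IC of a term *set* counts the molecules associated with **all** terms
of the set. A set supported by no molecule has IC `+inf`; the minimum-
common-ancestor sets produced by the similarity machinery are supported
whenever their inputs are genuine annotation sets (the annotating molecule
itself supports them), so the sentinel only surfaces on contrived inputs,
where it propagates rather than being silently clamped.

## Similarity measures

- `delta_I(ci, cj)`: IC of the minimum common ancestor. On a DAG there can
  be several minimal common ancestors; the one with maximum IC is taken
  (ties are impossible on tree fixtures, so worked-example arithmetic is
  unaffected).
- `delta_JC(ci, cj) = 1 / (I(ci) + I(cj) - 2 delta_I + 1)`: the reciprocal
  of the Jiang–Conrath distance plus one. This form is bounded in (0, 1],
  attains 1 exactly when the distance is zero, and mirrors the set-level
  `rho_JC` structurally.
- Set-level: `rho_A` (mean over term pairs), `rho_M` (max), `rho_H`
  (best-match average). `rho_H` is symmetrized by averaging the two
  directions, since downstream correlation code assumes symmetric scores.
- `rho_I(Si, Sj) = I(Lambda(Si, Sj))` where `Lambda` collects all pairwise
  minimum common ancestors and reduces them with the generalized union
  (keep only most specific terms). `rho_JC` normalizes it by the self
  similarities exactly as `delta_JC` does.
- Sub-ontology combination follows the funsim form: half the sum of the
  squared normalized scores, `((s_bp/max_bp)^2 + (s_mf/max_mf)^2) / 2`.
  The normalizing maxima default to the corpus-wide observed maxima and
  are explicit parameters. Module coherence is conventionally computed on
  the biological-process ontology alone (process annotations span wider
  network neighborhoods than function annotations).

## Module coherence

`sigma_A` averages any pair measure over all unordered pairs. `sigma_I`
needs `Lambda(R)` over n-tuples, which is exponential if enumerated; it is
computed by iterative pairwise folding (`Lambda` of the running result with
each next member, reducing after every step). The fold is equivalent on
trees and matches an exhaustive tuple oracle on all random DAG fixtures
tested (n ≤ 4). `sigma_G` is the IC ratio of the intersection to the union
of the members' ancestor DAGs; an all-root union (zero total IC) returns 1
by convention — members with no information are trivially coherent.
`sigma_W` weights each term of the combined ancestor DAG by the number of
members carrying it and takes shared (n_t ≥ 2) over total weighted IC; the
root has zero IC and therefore needs no exclusion.

Size adjustment subtracts the mean score of `n_random` same-size modules
drawn uniformly (without replacement, from annotated molecules only). The
difference form preserves score units and is zero-centered under the null;
a ratio variant sits behind a flag. The default background of 1000 draws
puts the standard error of the mean well below typical score differences;
the CLI default of 200 trades a little of that for speed.

Detectability between test (known-coherent) and control (random) score
collections is the binormal separation `D = (mean_T - mean_C) /
sqrt(var_T + var_C)` with sample variances; `Phi(D)` is exactly the area
under the ROC curve of the two fitted normals (verified against numerical
integration in the tests). The p < 0.05 reference line is `Phi^-1(0.95) ≈
1.645`. Zero pooled variance yields 0 for equal means and a signed
infinity otherwise.

## Network proximity

The transition matrix row-normalizes the weighted adjacency (transition
probability proportional to edge weight). Each source iterates
`p <- (1-c) W^T p + c e_i` to an L1 change below 1e-10 (configurable,
1000 iterations max; non-convergence raises with the residual). Rows of
degree-zero nodes are absorbing at the source: mass reaching them restarts.
Pairs spanning different components are excluded from correlation, matching
the shortest-path unreachable sentinel (`inf`). The default restart
probability is c = 0.3, the empirical optimum of the restart sweep; the
sweep utility recomputes the correlation over c in {0.1, ..., 0.9}.

Similarity scores are z-normalized (population standard deviation;
parameterized) before binning. Equal-count bins are assigned after a
stable sort on (proximity, node-pair label), so ties resolve
lexicographically and repeated runs are byte-identical. Binning operates
on the symmetrized proximity matrix.

## Synthetic data: what it emulates and what it does not

The generators replace external interaction and annotation databases:

- `generate_ontology` grows a rooted random DAG (each term takes 1..k
  parents among earlier terms — acyclic by construction).
- `generate_corpus` annotates molecules with depth-biased random terms,
  mimicking curation's preference for specific terms.
- `generate_test_control_modules` emulates known-complex vs random
  benchmark sets: test modules draw members from a planted family (the
  closure of an informative term) with probability `coherence_bias`
  (default 0.8 — complexes share most but not all membership), controls
  are uniform; sizes span 4–11 as complex catalogs typically do.
- `generate_modular_network` is a planted-partition graph over functional
  families (default within-block edge probability 0.6, cross-block 0.05:
  dense but incomplete modules over a sparse background, the regime where
  diffusion-based proximity is expected to beat shortest paths).
- `generate_functional_benchmark` ties these together on a two-level
  ontology (root → family terms → leaves, 12 families of 8 molecules with
  2 leaf annotations each by default) so topological blocks coincide with
  functional families.

These benchmarks establish *internal correctness and qualitative behavior*:
that the measures separate planted structure, that diffusion proximity
correlates with similarity where modules are dense but incomplete, and that
weighted IC tolerates sub-complex structure where graph IC does not. They
do not reproduce the degree distributions, annotation sparsity, evidence
heterogeneity or noise structure of real PPI/DDI data, so passing tests do
not quantify performance on any real interactome.

## Numerical and design choices

- Problem sizes: correlation analyses run on 96-node networks
  (~4.5k annotated pairs); detectability runs 40 test + 40 control modules
  per size across sizes 4–11, and the null check 70 + 70 at three sizes.
  These sizes give stable qualitative orderings at sub-minute runtimes.
- The worked-example DAG is reconstructed uniquely from its printed
  arithmetic; a hypothetical extra sibling term used by no annotation
  would change no computed value and is omitted.
- Stochastic routines accept integer seeds and are pure functions of
  (seed, parameters); repeated calls with one `numpy.random.Generator`
  deliberately continue its stream.
- Evidence-code filtering of annotation files is available but off by
  default; cellular-component annotations parse like any namespace but are
  unused by the default analyses owing to their sparsity.

## Known limitations

- `sigma_I`'s pairwise fold is proven equivalent to tuple enumeration only
  empirically on random DAGs (and exactly on trees); pathological DAGs
  could in principle differ.
- The RWR solver is dense per source (O(n^2) memory per matrix); networks
  beyond ~10^4 nodes would need a sparse/solver-based backend.
- Relation-type semantics (regulates etc.), obsolete-term remapping and
  directed networks are out of scope.
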