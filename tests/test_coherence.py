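"""Module coherence measures, size adjustment and detectability."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import norm

from funcoherence.coherence import (
    Module,
    detectability,
    sample_random_module,
    sigma_A,
    sigma_G,
    sigma_I,
    sigma_W,
    size_adjust,
)
from funcoherence.fixtures import generate_functional_benchmark


class TestWorkedExample:
    def test_sigma_A(self, worked_example, example_modules):
        _, corpus = worked_example
        assert sigma_A(example_modules["R1"], corpus) == pytest.approx(3 / 8)
        assert sigma_A(example_modules["R2"], corpus) == pytest.approx(2 / 3)
        pair = Module.from_corpus(corpus, ["S1", "S2"])
        assert sigma_A(pair, corpus) == 1.0

    def test_sigma_I(self, worked_example, example_modules):
        _, corpus = worked_example
        assert sigma_I(example_modules["R1"], corpus) == 0.0
        assert sigma_I(example_modules["R2"], corpus) == 1.0
        singleton = Module.from_corpus(corpus, ["S3"])
        assert sigma_I(singleton, corpus) == pytest.approx(math.log2(6))

    def test_sigma_G(self, worked_example, example_modules):
        _, corpus = worked_example
        assert sigma_G(example_modules["R1"], corpus) == 0.0
        assert sigma_G(example_modules["R2"], corpus) == pytest.approx(1 / 2)
        pair = Module.from_corpus(corpus, ["S1", "S2"])
        assert sigma_G(pair, corpus) == 1.0

    def test_sigma_W(self, worked_example, example_modules):
        _, corpus = worked_example
        # shared: 3 I(c4) + 3 I(c2) + 2 I(c6) + 2 I(c3) = 10; unique: I(c1)
        assert sigma_W(example_modules["R1"], corpus) == pytest.approx(
            10 / (10 + math.log2(3))
        )
        assert round(sigma_W(example_modules["R1"], corpus), 2) == 0.86
        assert sigma_W(example_modules["R2"], corpus) == pytest.approx(3 / 4)
        pair = Module.from_corpus(corpus, ["S1", "S2"])
        assert sigma_W(pair, corpus) == 1.0

    def test_small_modules_rejected(self, worked_example):
        _, corpus = worked_example
        single = Module.from_corpus(corpus, ["S1"])
        with pytest.raises(ValueError):
            sigma_A(single, corpus)
        with pytest.raises(ValueError):
            sigma_W(single, corpus)


def _random_module(corpus, size, rng):
    return sample_random_module(corpus, size, rng)


class TestInvariants:
    @pytest.mark.parametrize("seed", [51, 52, 53])
    def test_bounds_and_order_invariance(self, random_world, seed):
        _, corpus = random_world(seed, n_molecules=25)
        rng = np.random.default_rng(seed)
        for _ in range(8):
            module = _random_module(corpus, 4, rng)
            g = sigma_G(module, corpus)
            w = sigma_W(module, corpus)
            assert 0.0 <= g <= 1.0
            assert 0.0 <= w <= 1.0
            assert sigma_I(module, corpus) >= 0.0
            shuffled = Module(list(reversed(module.members)))
            assert sigma_I(shuffled, corpus) == pytest.approx(sigma_I(module, corpus))
            assert sigma_G(shuffled, corpus) == pytest.approx(g)
            assert sigma_A(shuffled, corpus) == pytest.approx(sigma_A(module, corpus))

    def test_sigma_I_bounded_by_member_self_similarity(self, random_world):
        from funcoherence.similarity import pair_similarity

        _, corpus = random_world(61, n_molecules=25)
        rng = np.random.default_rng(61)
        for _ in range(8):
            module = _random_module(corpus, 3, rng)
            bound = min(
                pair_similarity(s, s, "rho_I", corpus) for s in module.term_sets
            )
            assert sigma_I(module, corpus) <= bound + 1e-12

    def test_duplicating_a_member_never_decreases_sigma_G_or_W(self, random_world):
        _, corpus = random_world(71, n_molecules=25)
        rng = np.random.default_rng(71)
        for _ in range(8):
            module = _random_module(corpus, 3, rng)
            bigger = Module(module.members + [module.members[0]])
            assert sigma_G(bigger, corpus) >= sigma_G(module, corpus) - 1e-12
            assert sigma_W(bigger, corpus) >= sigma_W(module, corpus) - 1e-12

    @pytest.mark.parametrize("seed", [81, 82, 83])
    def test_sigma_I_fold_matches_tuple_bruteforce(self, random_world, seed):
        """The iterative pairwise fold equals the exponential tuple
        enumeration (one term per member, minimum common ancestors per
        tuple, generalized union) for modules of up to four members."""
        ontology, corpus = random_world(seed, n_molecules=25)
        rng = np.random.default_rng(seed)
        for size in (2, 3, 4):
            module = _random_module(corpus, size, rng)
            pool = set()
            for combo in itertools.product(*(s.terms for s in module.term_sets)):
                pool |= ontology.min_common_ancestors(*combo).terms
            lam = ontology.reduce_nonredundant(pool)
            assert sigma_I(module, corpus) == pytest.approx(corpus.info_content(lam))

    @pytest.mark.parametrize("seed", [91, 92])
    def test_sigma_W_matches_shared_unique_classification(self, random_world, seed):
        """Oracle: build every member's ancestor DAG explicitly and
        classify each term of the combined DAG as shared or unique."""
        _, corpus = random_world(seed, n_molecules=25)
        rng = np.random.default_rng(seed)
        for _ in range(6):
            module = _random_module(corpus, 4, rng)
            dags = [set(s.ancestor_union()) for s in module.term_sets]
            counts = Counter(t for d in dags for t in d)
            shared = sum(
                counts[t] * corpus.info_content(t) for t in counts if counts[t] >= 2
            )
            total = sum(counts[t] * corpus.info_content(t) for t in counts)
            expected = 1.0 if total == 0 else shared / total
            assert sigma_W(module, corpus) == pytest.approx(expected)


class TestSizeAdjustment:
    def test_against_exhaustive_background(self, worked_example, example_modules):
        """All C(6,3) = 20 size-3 modules of the worked example give the
        exact background mean; the sampled adjustment must land near the
        exact one and be positive for the coherent sub-complex."""
        _, corpus = worked_example
        mols = sorted(corpus.molecules)
        exact = [
            sigma_W(Module.from_corpus(corpus, combo), corpus)
            for combo in itertools.combinations(mols, 3)
        ]
        exact_mean = float(np.mean(exact))
        score = sigma_W(example_modules["R2"], corpus)
        adjusted = size_adjust(
            score, 3, corpus, lambda m: sigma_W(m, corpus), n_random=1000, seed=1
        )
        assert adjusted > 0.0
        assert adjusted == pytest.approx(score - exact_mean, abs=0.03)

    def test_deterministic_given_seed(self, worked_example):
        _, corpus = worked_example
        args = (0.5, 3, corpus, lambda m: sigma_W(m, corpus))
        a = size_adjust(*args, n_random=50, seed=42)
        b = size_adjust(*args, n_random=50, seed=42)
        assert a == b

    def test_oversized_module_rejected(self, worked_example):
        _, corpus = worked_example
        with pytest.raises(ValueError, match="exceeds"):
            size_adjust(0.5, 7, corpus, lambda m: 0.0, n_random=30, seed=0)

    def test_tiny_background_rejected(self, worked_example):
        _, corpus = worked_example
        with pytest.raises(ValueError, match="at least 30"):
            size_adjust(0.5, 3, corpus, lambda m: 0.0, n_random=5, seed=0)


class TestDetectability:
    def test_identical_distributions_give_zero(self):
        x = [0.1, 0.5, 0.9, 0.3]
        assert detectability(x, x).d == 0.0

    def test_hand_computed_separation(self):
        # means 3 and 1, sample variances 2 and 2: (3 - 1)/sqrt(4) = 1
        report = detectability([2, 4], [0, 2])
        assert report.d == 1.0
        assert report.threshold == pytest.approx(norm.ppf(0.95))

    def test_zero_variance_sentinels(self):
        assert detectability([1, 1], [1, 1]).d == 0.0
        assert detectability([2, 2], [1, 1]).d == math.inf
        assert detectability([0, 0], [1, 1]).d == -math.inf

    def test_auc_matches_binormal_roc_quadrature(self):
        """Phi(D) must equal the area under the binormal ROC curve,
        computed independently as P(T > C) by numerical integration."""
        report = detectability([1.0, 2.0, 3.5, 2.5], [0.0, 1.0, 0.5, -0.5])
        mt, vt = report.test_mean, report.test_var
        mc, vc = report.control_mean, report.control_var
        auc, _ = integrate.quad(
            lambda x: norm.pdf(x, mc, math.sqrt(vc)) * norm.sf(x, mt, math.sqrt(vt)),
            -20,
            20,
        )
        assert report.auc == pytest.approx(auc, abs=1e-8)

    def test_requires_two_scores_per_group(self):
        with pytest.raises(ValueError):
            detectability([1.0], [0.0, 1.0])


class TestPlantedSeparation:
    def test_planted_modules_outscore_random_ones(self):
        """Size-6 modules sampled from one planted functional family beat
        uniform random modules under sigma_W and sigma_A in > 90% of
        paired draws."""
        _, corpus, _, families = generate_functional_benchmark(seed=3)
        rng = np.random.default_rng(3)
        wins_w = wins_a = n = 60
        wins_w = wins_a = 0
        for _ in range(n):
            fam = families[int(rng.integers(len(families)))]
            pick = rng.choice(len(fam), size=6, replace=False)
            planted = Module.from_corpus(corpus, (fam[i] for i in pick))
            random_mod = sample_random_module(corpus, 6, rng)
            if sigma_W(planted, corpus) > sigma_W(random_mod, corpus):
                wins_w += 1
            if sigma_A(planted, corpus) > sigma_A(random_mod, corpus):
                wins_a += 1
        assert wins_w / n > 0.9
        assert wins_a / n > 0.9
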