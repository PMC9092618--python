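import numpy as np
import pandas as pd
import pytest

from odorqspr.gfa_selection import (
    GFAConfig,
    GFAError,
    ModelGenome,
    TermSpec,
    crossover,
    descriptor_pool,
    evolve,
    initialize_population,
    lof_score,
    mutate,
)
from odorqspr.gfa_selection import _fit


@pytest.fixture()
def pool(rng):
    X = pd.DataFrame(
        rng.standard_normal((50, 10)), columns=[f"x{j}" for j in range(10)]
    )
    y = 2.0 * X["x1"].to_numpy() + rng.normal(0, 0.2, 50)
    return X, y


class TestLofScore:
    def test_perfect_fit_is_zero(self):
        assert lof_score(0.0, c=3, p=4, M=50, d=1.0) == 0.0

    def test_d_zero_closed_form(self):
        assert lof_score(10.0, c=2, p=2, M=10, d=0.0) == pytest.approx(15.625)

    def test_d_one_closed_form(self):
        assert lof_score(10.0, c=2, p=2, M=10, d=1.0) == pytest.approx(10 / 0.36)

    def test_overparameterized_is_infinite(self):
        assert lof_score(1.0, c=5, p=6, M=10, d=1.0) == float("inf")

    def test_strictly_increasing_in_size(self):
        base = lof_score(5.0, c=2, p=3, M=40, d=1.0)
        assert lof_score(6.0, c=2, p=3, M=40, d=1.0) > base
        assert lof_score(5.0, c=3, p=3, M=40, d=1.0) > base
        assert lof_score(5.0, c=2, p=4, M=40, d=1.0) > base


class TestTermSpec:
    def test_spline_needs_knot(self):
        with pytest.raises(GFAError):
            TermSpec("x", "spline")

    def test_linear_refuses_knot(self):
        with pytest.raises(GFAError):
            TermSpec("x", "linear", 1.0)

    def test_spline_evaluation_truncates(self):
        X = pd.DataFrame({"x": [-1.0, 0.0, 2.0]})
        t = TermSpec("x", "spline", 1.0)
        assert t.evaluate(X).tolist() == [2.0, 1.0, 0.0]


class TestInitializePopulation:
    def test_deterministic_for_seed(self, pool):
        X, y = pool
        cfg = GFAConfig(population_size=12, seed=9)
        a = initialize_population(X, y, cfg)
        b = initialize_population(X, y, cfg)
        assert [g.terms for g in a] == [g.terms for g in b]
        assert [g.lof for g in a] == [g.lof for g in b]

    def test_initial_length_respected(self, pool):
        X, y = pool
        pop = initialize_population(X, y, GFAConfig(population_size=20, initial_length=4, seed=1))
        assert all(len(g.terms) == 4 for g in pop)
        # no duplicate descriptors within a genome at initialization
        assert all(len({t.descriptor for t in g.terms}) == 4 for g in pop)

    def test_pool_of_exactly_initial_length_forced(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 4)), columns=list("abcd"))
        y = rng.standard_normal(30)
        pop = initialize_population(X, y, GFAConfig(population_size=5, initial_length=4, seed=0))
        assert all(sorted(t.descriptor for t in g.terms) == list("abcd") for g in pop)

    def test_small_pool_rejected(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=list("ab"))
        with pytest.raises(GFAError):
            initialize_population(X, rng.standard_normal(30), GFAConfig(initial_length=4))

    def test_lse_matches_independent_least_squares(self, pool):
        X, y = pool
        pop = initialize_population(X, y, GFAConfig(population_size=10, seed=3))
        for g in pop:
            A = g.design(X)
            beta, *_ = np.linalg.lstsq(A, y, rcond=None)
            rss = float(np.sum((y - A @ beta) ** 2))
            assert g.lse == pytest.approx(rss, abs=1e-8)


class TestCrossoverMutate:
    def _genomes(self, X, y):
        a = _fit(ModelGenome(terms=[TermSpec("x0", "linear"), TermSpec("x1", "linear"),
                                    TermSpec("x2", "linear")]), X, y, 1.0)
        b = _fit(ModelGenome(terms=[TermSpec("x3", "linear"), TermSpec("x4", "linear"),
                                    TermSpec("x5", "linear")]), X, y, 1.0)
        return a, b

    def test_child_terms_come_from_parents(self, pool, rng):
        X, y = pool
        a, b = self._genomes(X, y)
        child = crossover(a, b, rng, X, y, 1.0)
        parent_terms = set(a.terms) | set(b.terms)
        assert set(child.terms) <= parent_terms
        assert len(child.terms) >= 1

    def test_identical_parents_subset(self, pool, rng):
        X, y = pool
        a, _ = self._genomes(X, y)
        child = crossover(a, a, rng, X, y, 1.0)
        assert set(child.terms) <= set(a.terms)

    def test_shared_term_deduplicated(self, pool, rng):
        X, y = pool
        shared = TermSpec("x7", "linear")
        a = _fit(ModelGenome(terms=[shared, TermSpec("x0", "linear")]), X, y, 1.0)
        b = _fit(ModelGenome(terms=[shared, TermSpec("x1", "linear")]), X, y, 1.0)
        for _ in range(10):
            child = crossover(a, b, rng, X, y, 1.0)
            assert child.terms.count(shared) <= 1

    def test_mutate_p0_identity(self, pool, rng):
        X, y = pool
        a, _ = self._genomes(X, y)
        assert mutate(a, X, y, 0.0, rng, 1.0) is a

    def test_mutate_p1_changes_genome(self, pool, rng):
        X, y = pool
        a, _ = self._genomes(X, y)
        out = mutate(a, X, y, 1.0, rng, 1.0)
        assert out.terms != a.terms

    def test_mutate_never_empties_single_term_genome(self, pool, rng):
        X, y = pool
        g = _fit(ModelGenome(terms=[TermSpec("x0", "linear")]), X, y, 1.0)
        for _ in range(30):
            g2 = mutate(g, X, y, 1.0, rng, 1.0)
            assert len(g2.terms) >= 1


class TestEvolve:
    def test_zero_iterations_returns_scored_initial(self, pool):
        X, y = pool
        cfg = GFAConfig(population_size=15, iterations=0, seed=2)
        out = evolve(X, y, cfg)
        assert len(out) == 15
        assert all(np.isfinite(g.lof) for g in out)
        assert [g.lof for g in out] == sorted(g.lof for g in out)

    def test_noise_free_linear_signal_found(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 8)), columns=[f"x{j}" for j in range(8)])
        y = 3.0 * X["x1"].to_numpy()
        out = evolve(X, y, GFAConfig(population_size=60, iterations=300, seed=4,
                                     term_kind="linear", initial_length=2))
        best = out[0]
        assert "x1" in best.descriptors
        assert best.lse < 1e-10

    def test_best_lof_non_increasing(self, pool):
        X, y = pool
        # evolve asserts elitism internally each generation; also check end vs start
        cfg = GFAConfig(population_size=20, iterations=100, seed=8)
        start = min(g.lof for g in initialize_population(
            X, y, cfg, np.random.default_rng(cfg.seed)))
        out = evolve(X, y, cfg)
        assert out[0].lof <= start + 1e-9

    def test_lof_ranking_equals_lse_ranking_when_d_zero(self, pool):
        X, y = pool
        cfg = GFAConfig(population_size=25, iterations=0, d=0.0, seed=6,
                        initial_length=3)
        out = evolve(X, y, cfg)
        same_size = [g for g in out if len(g.terms) == 3 and g.n_knots == 0]
        lofs = [g.lof for g in same_size]
        lses = [g.lse for g in same_size]
        assert np.argsort(lofs).tolist() == np.argsort(lses).tolist()

    def test_degenerate_response_rejected(self, pool):
        X, _ = pool
        with pytest.raises(GFAError):
            evolve(X, np.ones(len(X)), GFAConfig(iterations=1))


class TestDescriptorPool:
    def _genome(self, *names):
        return ModelGenome(terms=[TermSpec(n, "linear") for n in names])

    def test_single_model(self):
        assert descriptor_pool([self._genome("A", "B")], m=1) == ["A", "B"]

    def test_union_preserves_rank_order(self):
        models = [self._genome("A", "B"), self._genome("B", "C")]
        assert descriptor_pool(models, m=2) == ["A", "B", "C"]

    def test_spline_and_linear_count_once(self):
        g = ModelGenome(terms=[TermSpec("A", "linear"), TermSpec("A", "spline", 1.0)])
        assert descriptor_pool([g], m=1) == ["A"]

    def test_empty_rejected(self):
        with pytest.raises(GFAError):
            descriptor_pool([], m=1)
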