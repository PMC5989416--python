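"""Term probabilities, fuzzy densities, the lambda-measure and FMS similarity."""

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mgogp import (GoKnowledge, GoSimilarity, SeedGeneSet, build_density_set,
                   fms_similarity, fuzzy_density, gene_basic_importance,
                   solve_lambda, sugeno_measure, term_probability)
from mgogp.go_fuzzy import TermProbabilityTable, _lambda_residual

from conftest import diamond_go


def chain_go():
    """t3 is_a t2 is_a t1; 10 annotation records, the leaf annotated once."""
    dag = nx.DiGraph([("t2", "t1"), ("t3", "t2")])
    annotations = {
        "gleaf": frozenset({"t3"}),
        **{f"gmid{i}": frozenset({"t2"}) for i in range(4)},
        **{f"groot{i}": frozenset({"t1"}) for i in range(5)},
    }
    return GoKnowledge(annotations=annotations, dag=dag)


class TestTermProbability:
    def test_root_covers_everything(self):
        probs = term_probability(chain_go())
        assert probs["t1"] == pytest.approx(1.0)

    def test_leaf_direct_count(self):
        probs = term_probability(chain_go())
        assert probs.corpus_size == 10
        assert probs["t3"] == pytest.approx(0.1)

    def test_diamond_record_counted_once_for_root(self):
        go = diamond_go()
        probs = term_probability(go)
        # 4 records; t4's single record reaches t1 via two paths but counts once.
        assert probs["t1"] == pytest.approx(1.0)
        assert probs["t4"] == pytest.approx(0.25)

    def test_monotone_up_the_dag(self):
        probs = term_probability(chain_go())
        assert probs["t1"] >= probs["t2"] >= probs["t3"]

    def test_literal_one_step_children_option(self):
        probs = term_probability(chain_go(), children_depth=1)
        # t1's one-step closure is {t1, t2}: 9 of 10 records.
        assert probs["t1"] == pytest.approx(0.9)


class TestFuzzyDensity:
    def _table(self, p):
        return TermProbabilityTable(p=p, corpus_size=100)

    def test_single_term_self_normalizes(self):
        d = fuzzy_density(["a"], self._table({"a": 0.3}))
        assert d == {"a": 1.0}

    def test_information_content_ratio(self):
        d = fuzzy_density(["a", "b"], self._table({"a": math.exp(-2), "b": math.exp(-1)}))
        assert d["a"] == pytest.approx(1.0)
        assert d["b"] == pytest.approx(0.5)

    def test_probability_one_gives_zero_density(self):
        d = fuzzy_density(["a", "b"], self._table({"a": 1.0, "b": 0.5}))
        assert d["a"] == 0.0
        assert d["b"] == 1.0

    def test_all_uninformative_terms_flagged_degenerate(self):
        fds = build_density_set(["a"], self._table({"a": 1.0}))
        assert fds.degenerate


class TestSolveLambda:
    def test_sum_one_gives_zero(self):
        assert solve_lambda([0.5, 0.5]) == 0.0

    def test_quadratic_case_positive(self):
        # prod(1 + 0.2 l)(1 + 0.3 l) = 1 + l  =>  0.06 l^2 = 0.5 l  =>  l = 25/3
        assert solve_lambda([0.2, 0.3]) == pytest.approx(25.0 / 3.0, abs=1e-9)

    def test_quadratic_case_negative(self):
        # 0.36 l^2 = -0.2 l  =>  l = -5/9
        assert solve_lambda([0.6, 0.6]) == pytest.approx(-5.0 / 9.0, abs=1e-9)

    def test_single_unit_density_returns_zero(self):
        assert solve_lambda([1.0]) == 0.0

    def test_unit_density_with_others_returns_zero(self):
        # (1+l) is a common factor; the remaining product is 1 only at l = 0.
        assert solve_lambda([1.0, 0.5, 0.3]) == 0.0

    @settings(derandomize=True, deadline=None, max_examples=150)
    @given(st.lists(st.floats(0.01, 0.999), min_size=2, max_size=30))
    def test_residual_small_on_random_sets(self, densities):
        lam = solve_lambda(densities)
        assert lam > -1.0
        assert abs(_lambda_residual(lam, np.asarray(densities))) < 1e-10

    def test_uniqueness_by_grid_scan(self):
        rng = np.random.default_rng(12)
        for _ in range(50):
            d = rng.uniform(0.05, 0.95, size=rng.integers(2, 8))
            if abs(d.sum() - 1) < 1e-3:
                continue
            lam = solve_lambda(d)
            grid = np.concatenate([
                -1 + np.logspace(-6, 0, 300)[:-1],
                np.logspace(-6, 6, 300),
            ])
            res = np.array([_lambda_residual(g, d) for g in grid])
            sign_changes = np.flatnonzero(np.diff(np.sign(res)) != 0)
            # Every bracketed root is either the trivial 0 or the solved lambda.
            for k in sign_changes:
                lo, hi = grid[k], grid[k + 1]
                assert (lo <= 0.0 <= hi) or (lo <= lam <= hi)


class TestSugenoMeasure:
    def _fds(self, densities):
        table = TermProbabilityTable(
            p={t: math.exp(-v * 5) for t, v in densities.items()}, corpus_size=10)
        fds = build_density_set(list(densities), table)
        return fds

    def test_empty_subset_is_zero(self):
        fds = build_density_set(
            ["a", "b"], TermProbabilityTable(p={"a": 0.1, "b": 0.3}, corpus_size=10))
        assert sugeno_measure([], fds) == 0.0

    def test_full_set_is_one(self):
        fds = build_density_set(
            ["a", "b", "c"],
            TermProbabilityTable(p={"a": 0.05, "b": 0.3, "c": 0.6}, corpus_size=10))
        assert sugeno_measure(["a", "b", "c"], fds) == pytest.approx(1.0, abs=1e-9)

    def test_lambda_rule_hand_evaluation(self):
        from mgogp.go_fuzzy import FuzzyDensitySet
        fds = FuzzyDensitySet(terms=("a", "b"), density={"a": 0.2, "b": 0.3},
                              lam=25.0 / 3.0)
        # 0.2 + 0.3 + (25/3)*0.06 = 1
        assert sugeno_measure(["a", "b"], fds) == pytest.approx(1.0, abs=1e-9)
        assert sugeno_measure(["a"], fds) == pytest.approx(0.2)

    def test_unknown_term_rejected(self):
        fds = build_density_set(
            ["a"], TermProbabilityTable(p={"a": 0.1}, corpus_size=10))
        with pytest.raises(KeyError):
            sugeno_measure(["zz"], fds)

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(st.data())
    def test_monotone_under_inclusion(self, data):
        terms = ["a", "b", "c", "d", "e"]
        probs = TermProbabilityTable(
            p={t: p for t, p in zip(
                terms, data.draw(st.lists(st.floats(0.01, 0.99), min_size=5, max_size=5)))},
            corpus_size=10)
        fds = build_density_set(terms, probs)
        subset = data.draw(st.sets(st.sampled_from(terms)))
        superset = subset | data.draw(st.sets(st.sampled_from(terms)))
        assert sugeno_measure(subset, fds) <= sugeno_measure(superset, fds) + 1e-12

    def test_additive_limit_near_sum_one(self):
        # When densities sum to 1 +/- 1e-6, the lambda rule is additive to
        # first order.
        for eps in (-1e-6, 1e-6):
            d = [0.5, 0.5 + eps]
            lam = solve_lambda(d)
            from mgogp.go_fuzzy import FuzzyDensitySet
            fds = FuzzyDensitySet(terms=("a", "b"), density={"a": d[0], "b": d[1]},
                                  lam=lam)
            assert sugeno_measure(["a"], fds) == pytest.approx(d[0], abs=1e-6)


class TestFmsSimilarity:
    def _table(self):
        return TermProbabilityTable(
            p={"A": 0.25, "B": 0.5, "C": 0.25, "R": 1.0}, corpus_size=4)

    def test_identical_sets_give_one(self):
        t = self._table()
        assert fms_similarity(["A", "B"], ["A", "B"], t) == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_sets_give_zero(self):
        t = self._table()
        assert fms_similarity(["A"], ["C"], t) == 0.0

    def test_symmetry_exact(self):
        t = self._table()
        assert fms_similarity(["A", "B"], ["B", "C"], t) == fms_similarity(
            ["B", "C"], ["A", "B"], t)

    def test_hand_built_shared_term_trace(self):
        # gene1 terms {A, B}: densities A = 1 (most specific), B = ln2/ln4 = 0.5
        # gene2 terms {B, C}: densities C = 1, B = 0.5
        # Each side's measure on the shared {B} is its density 0.5;
        # the average is 0.5.
        t = self._table()
        assert fms_similarity(["A", "B"], ["B", "C"], t) == pytest.approx(0.5, abs=1e-9)

    def test_unusable_gene_gives_zero(self):
        t = TermProbabilityTable(p={"R": 1.0, "A": 0.5}, corpus_size=4)
        assert fms_similarity(["R"], ["A"], t) == 0.0


class TestGeneBasicImportance:
    def _similarity(self):
        return GoSimilarity(diamond_go())

    def test_module_without_seeds_is_zero(self):
        sim = self._similarity()
        seeds = SeedGeneSet(genes=frozenset({"zz"}))
        assert gene_basic_importance("gA", ["gA", "gB"], seeds, sim) == 0.0

    def test_seed_gene_itself_is_one(self):
        sim = self._similarity()
        seeds = SeedGeneSet(genes=frozenset({"gA"}))
        assert gene_basic_importance("gA", ["gA", "gB"], seeds, sim) == 1.0

    def test_mean_over_module_seeds(self):
        sim = self._similarity()

        class Fixed:
            def similarity(self, a, b):
                return {"s1": 0.4, "s2": 0.8}[b]

        seeds = SeedGeneSet(genes=frozenset({"s1", "s2"}))
        val = gene_basic_importance("gX", ["gX", "s1", "s2"], seeds, Fixed())
        assert val == pytest.approx(0.6)

    def test_unannotated_gene_contributes_zero(self):
        sim = self._similarity()
        seeds = SeedGeneSet(genes=frozenset({"gA"}))
        assert gene_basic_importance("ghost", ["ghost", "gA"], seeds, sim) == 0.0
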