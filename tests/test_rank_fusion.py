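"""The expectation-driven rank-fusion recursion against a brute-force oracle."""

import numpy as np
import pytest

from mgogp import fuse, normalize_module_probs
from mgogp.rank_fusion import assemble_global_ranking
from mgogp.scoring import GeneScore, LocalRanking, ModuleScore


def make_ranking(name, genes):
    scores = [GeneScore(g, name, 0.0, 0.0, 0.0, float(len(genes) - k))
              for k, g in enumerate(genes)]
    return LocalRanking(module_name=name, scores=scores)


def make_module_score(name, p):
    return ModuleScore(module_name=name, ncr=0, ecr=0, info=0, p_module=p,
                       n_genes=0, n_seeds=0)


def oracle_fuse(rankings: dict[str, list[str]], probs: dict[str, float]) -> list[str]:
    """Independent straight-line re-implementation for DISJOINT modules:
    literal bookkeeping of i, m(i,j) and e(i,j) = (i+1) p_j - m(i,j)."""
    names = list(rankings)
    m = dict.fromkeys(names, 0)
    out: list[str] = []
    total = sum(len(g) for g in rankings.values())
    while len(out) < total:
        candidates = [n for n in names if probs[n] > 0 and m[n] < len(rankings[n])]
        if not candidates:
            for n in names:
                out.extend(rankings[n][m[n]:])
                m[n] = len(rankings[n])
            break
        i = len(out)
        evals = [((i + 1) * probs[n] - m[n], probs[n], names.index(n)) for n in candidates]
        best = None
        for n, (e, p, k) in zip(candidates, evals):
            if best is None:
                best = (n, e, p, k)
            else:
                if (e, p, -k) > (best[1], best[2], -best[3]):
                    best = (n, e, p, k)
        name = best[0]
        out.append(rankings[name][m[name]])
        m[name] += 1
    return out


class TestNormalizeProbs:
    def test_proportional(self):
        probs = normalize_module_probs([make_module_score("a", 0.09),
                                        make_module_score("b", 0.01)])
        assert probs == pytest.approx({"a": 0.9, "b": 0.1})

    def test_single_module(self):
        assert normalize_module_probs([make_module_score("a", 0.3)]) == {"a": 1.0}

    def test_all_zero_falls_back_to_uniform(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            probs = normalize_module_probs([make_module_score(n, 0.0) for n in "abc"])
        assert probs == pytest.approx({"a": 1 / 3, "b": 1 / 3, "c": 1 / 3})
        assert "uniform" in caplog.text


class TestFuse:
    def test_single_module_is_identity(self):
        lr = make_ranking("m", ["x", "y", "z"])
        rows = fuse([lr], {"m": 1.0})
        assert [r.gene for r in rows] == ["x", "y", "z"]
        assert [r.local_rank for r in rows] == [1, 2, 3]

    def test_equal_probs_alternate(self):
        a = make_ranking("A", ["a1", "a2"])
        b = make_ranking("B", ["b1", "b2"])
        rows = fuse([a, b], {"A": 0.5, "B": 0.5})
        assert [r.gene for r in rows] == ["a1", "b1", "a2", "b2"]

    def test_three_quarters_module_leads(self):
        # Hand trace of the recursion at probs (0.75, 0.25):
        # i=0: e=(0.75, 0.25) -> a1; i=1: e=(0.5, 0.5), tie -> larger prob -> a2
        # i=2: e=(0.25, 0.75) -> b1; i=3: e=(1.0, 0.0) -> a3; then b2, b3.
        a = make_ranking("A", ["a1", "a2", "a3"])
        b = make_ranking("B", ["b1", "b2", "b3"])
        rows = fuse([a, b], {"A": 0.75, "B": 0.25})
        got = [r.gene for r in rows]
        assert got == ["a1", "a2", "b1", "a3", "b2", "b3"]
        assert got == oracle_fuse({"A": ["a1", "a2", "a3"], "B": ["b1", "b2", "b3"]},
                                  {"A": 0.75, "B": 0.25})

    def test_matches_oracle_on_random_disjoint_instances(self):
        rng = np.random.default_rng(1234)
        for _ in range(300):
            n_modules = int(rng.integers(1, 8))
            rankings = {}
            gid = 0
            for j in range(n_modules):
                size = int(rng.integers(1, 9))
                rankings[f"m{j}"] = [f"g{gid + k}" for k in range(size)]
                gid += size
            raw = rng.uniform(0, 1, size=n_modules)
            raw[rng.uniform(size=n_modules) < 0.2] = 0.0
            if raw.sum() == 0:
                raw[0] = 1.0
            probs = {f"m{j}": float(raw[j] / raw.sum()) for j in range(n_modules)}
            local = [make_ranking(n, g) for n, g in rankings.items()]
            got = [r.gene for r in fuse(local, probs)]
            assert got == oracle_fuse(rankings, probs)

    def test_round_robin_within_one_position(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_modules = int(rng.integers(2, 7))
            size = int(rng.integers(2, 8))
            rankings = {f"m{j}": [f"g{j}_{k}" for k in range(size)]
                        for j in range(n_modules)}
            probs = {n: 1.0 / n_modules for n in rankings}
            local = [make_ranking(n, g) for n, g in rankings.items()]
            pos = {r.gene: i for i, r in enumerate(fuse(local, probs), start=1)}
            for j in range(n_modules):
                for k in range(size):
                    perfect = k * n_modules + j + 1
                    assert abs(pos[f"g{j}_{k}"] - perfect) <= 1

    def test_local_order_preserved_globally(self):
        rng = np.random.default_rng(11)
        rankings = {f"m{j}": [f"g{j}_{k}" for k in range(6)] for j in range(4)}
        raw = rng.uniform(0.1, 1, size=4)
        probs = {f"m{j}": float(raw[j] / raw.sum()) for j in range(4)}
        local = [make_ranking(n, g) for n, g in rankings.items()]
        pos = {r.gene: i for i, r in enumerate(fuse(local, probs))}
        for j in range(4):
            ranks = [pos[f"g{j}_{k}"] for k in range(6)]
            assert ranks == sorted(ranks)

    def test_overlapping_gene_claimed_once(self):
        a = make_ranking("A", ["shared", "a2"])
        b = make_ranking("B", ["shared", "b2"])
        rows = fuse([a, b], {"A": 0.5, "B": 0.5})
        genes = [r.gene for r in rows]
        assert genes.count("shared") == 1
        assert set(genes) == {"shared", "a2", "b2"}

    def test_zero_probability_modules_processed_last_in_order(self):
        a = make_ranking("A", ["a1"])
        z1 = make_ranking("Z1", ["z1a"])
        z2 = make_ranking("Z2", ["z2a"])
        rows = fuse([z2, a, z1], {"A": 1.0, "Z1": 0.0, "Z2": 0.0})
        assert [r.gene for r in rows] == ["a1", "z2a", "z1a"]

    def test_output_is_permutation_of_union(self):
        rng = np.random.default_rng(3)
        universe = [f"g{k}" for k in range(40)]
        rankings = {
            f"m{j}": list(rng.choice(universe, size=10, replace=False))
            for j in range(5)
        }
        probs = {n: 0.2 for n in rankings}
        local = [make_ranking(n, g) for n, g in rankings.items()]
        genes = [r.gene for r in fuse(local, probs)]
        union = set().union(*rankings.values())
        assert sorted(genes) == sorted(union)


class TestAssemble:
    def test_unmoduled_appended_by_score(self):
        lr = make_ranking("m", ["x"])
        rows = fuse([lr], {"m": 1.0})
        ms = {"m": make_module_score("m", 0.5)}
        gs = {("m", "x"): GeneScore("x", "m", 0, 0, 0, 1.0)}
        ranking = assemble_global_ranking(rows, ms, gs,
                                          unmoduled=[("u1", 0.2), ("u2", 0.9)])
        assert ranking.genes() == ["x", "u2", "u1"]
        assert list(ranking.table["module"])[1:] == ["(unmoduled)", "(unmoduled)"]
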