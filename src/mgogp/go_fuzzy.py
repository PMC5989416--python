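"""GO-based fuzzy-measure similarity between genes.

Each GO term of a gene gets a fuzzy density: its information content
-ln p(T) normalized by the gene's most informative term, so densities lie
in [0, 1] with the most specific term at exactly 1.  The term probability
p(T) is the fraction of annotation records carried by T or any of its
descendants (descendant-closure counting keeps p monotone up the DAG).

The densities induce a Sugeno lambda-measure: lambda is the unique root
greater than -1 of

    (1 + lambda) = prod_k (1 + lambda * Sm_k)

and the measure of a subset A is (prod_{k in A}(1 + lambda*Sm_k) - 1) /
lambda (additive, capped at 1, when lambda = 0).  The similarity of two
genes is the average of their two measures evaluated on the shared term
intersection.  Because the density normalization puts a density of exactly
1 in every usable term set, the within-pipeline lambda is 0 and the measure
reduces to the capped additive one; the general solver is still provided
and exercised for arbitrary density sets.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .io_formats import GoKnowledge, SeedGeneSet

logger = logging.getLogger(__name__)

LAMBDA_TOL = 1e-12
LAMBDA_MAX_ITER = 200


@dataclass
class TermProbabilityTable:
    """p(T) per term: descendant-inclusive annotation frequency in the corpus."""

    p: dict[str, float]
    corpus_size: int

    def __contains__(self, term: str) -> bool:
        return term in self.p

    def __getitem__(self, term: str) -> float:
        return self.p[term]


@dataclass
class FuzzyDensitySet:
    """Per-term densities of one gene plus the solved lambda.

    ``degenerate`` marks sets where every density is zero (all terms have
    p = 1); similarities involving such a set fall back to 0.
    """

    terms: tuple[str, ...]
    density: dict[str, float]
    lam: float
    degenerate: bool = False


def term_probability(go: GoKnowledge, children_depth: int | None = None) -> TermProbabilityTable:
    """Annotation-frequency probability per GO term.

    p(T) = (# records whose term is T or a descendant of T) / (total
    records), each record counted once regardless of how many DAG paths
    connect it to T.  ``children_depth=1`` restricts the closure to direct
    children (the non-default, literal one-step reading).  Terms never
    observed even through descendants have no defined probability and are
    excluded.
    """
    record_counts: Counter[str] = Counter()
    for terms in go.annotations.values():
        for t in terms:
            record_counts[t] += 1
    total = sum(record_counts.values())
    if total == 0:
        raise ValueError("annotation corpus is empty")
    p: dict[str, float] = {}
    unobserved = 0
    for term in go.dag.nodes:
        if children_depth == 1:
            closure = {term} | set(go.dag.predecessors(term))
        else:
            closure = {term} | set(go.descendants.get(term, frozenset()))
        count = sum(record_counts[t] for t in closure)
        if count > 0:
            p[term] = count / total
        else:
            unobserved += 1
    if unobserved:
        logger.warning("%d GO terms never observed in the corpus; excluded", unobserved)
    return TermProbabilityTable(p=p, corpus_size=total)


def fuzzy_density(terms, probs: TermProbabilityTable) -> dict[str, float]:
    """Normalized information content per term: (-ln p) / max(-ln p).

    Terms without a defined probability are dropped with a warning; terms
    with p = 1 carry no information and get density 0.  When every usable
    term has p = 1 the result is all-zero (the caller treats the gene as
    unusable for similarity).
    """
    usable = [t for t in terms if t in probs]
    dropped = len(list(terms)) - len(usable)
    if dropped:
        logger.warning("%d terms without defined probability dropped from density set", dropped)
    neglog = {t: -math.log(probs[t]) for t in usable}
    if not neglog:
        return {}
    top = max(neglog.values())
    if top <= 0.0:
        return {t: 0.0 for t in neglog}
    return {t: v / top for t, v in neglog.items()}


def _lambda_residual(lam: float, densities: np.ndarray) -> float:
    return float(np.prod(1.0 + lam * densities) - (1.0 + lam))


def _log_residual(lam: float, densities: np.ndarray) -> float:
    """Same roots as ``_lambda_residual`` on lam > -1, but numerically
    stable near lam = 0: sum log1p(lam*d) - log1p(lam)."""
    return float(np.sum(np.log1p(lam * densities)) - math.log1p(lam))


def solve_lambda(densities) -> float:
    """Unique root lambda > -1 of (1+lambda) = prod(1 + lambda*Sm_k).

    lambda = 0 exactly when the densities sum to 1; the nontrivial root is
    bracketed in (-1, 0) when the sum exceeds 1 and in (0, inf) otherwise,
    and found by bisection.  Degenerate sets — fewer than two positive
    densities, or a density of exactly 1 alongside others (where only the
    trivial root exists) — return 0.
    """
    d = np.asarray([x for x in np.asarray(densities, dtype=float).ravel() if x > 0.0])
    if np.any((d < 0) | (d > 1)):
        raise ValueError("densities must lie in [0, 1]")
    if d.size == 0:
        raise ValueError("need at least one positive density")
    if d.size == 1:
        # (1+lambda) = (1+lambda*d) forces lambda = 0 unless d = 1, where
        # the identity holds for every lambda; 0 by convention either way.
        return 0.0
    s = float(d.sum())
    if abs(s - 1.0) < 1e-12:
        return 0.0
    if s > 1.0 and np.any(d >= 1.0):
        # A unit density makes (1+lambda) a common factor; the remaining
        # product equals 1 only at lambda = 0.
        return 0.0
    if s > 1.0:
        lo, hi = -1.0 + 1e-15, -1e-15
    else:
        lo = 1e-15
        hi = 1.0
        while _log_residual(hi, d) < 0:
            hi *= 2.0
            if hi > 1e12:  # pragma: no cover - cannot happen for >= 2 positive densities
                raise RuntimeError("failed to bracket lambda root")
    flo = _log_residual(lo, d)
    for _ in range(LAMBDA_MAX_ITER):
        mid = 0.5 * (lo + hi)
        fmid = _log_residual(mid, d)
        if fmid == 0.0 or (hi - lo) < LAMBDA_TOL * max(1.0, abs(mid)):
            return mid
        if (flo < 0) == (fmid < 0):
            lo, flo = mid, fmid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_density_set(terms, probs: TermProbabilityTable) -> FuzzyDensitySet:
    """Densities plus lambda for one gene's term set."""
    density = fuzzy_density(terms, probs)
    values = [v for v in density.values() if v > 0]
    if not values:
        return FuzzyDensitySet(terms=tuple(sorted(density)), density=density,
                               lam=0.0, degenerate=True)
    lam = solve_lambda(list(density.values()))
    return FuzzyDensitySet(terms=tuple(sorted(density)), density=density, lam=lam)


def sugeno_measure(subset, densities: FuzzyDensitySet) -> float:
    """Sugeno lambda-measure of a term subset.

    Sm(empty) = 0 and Sm(full set) = 1; intermediate subsets follow the
    lambda rule (or the capped additive sum when lambda = 0) and the result
    is monotone under inclusion.
    """
    subset = set(subset)
    unknown = subset - set(densities.terms)
    if unknown:
        raise KeyError(f"terms outside the density set: {sorted(unknown)[:5]}")
    if not subset:
        return 0.0
    if densities.degenerate:
        return 0.0
    vals = np.array([densities.density[t] for t in subset])
    if densities.lam == 0.0:
        return min(1.0, float(vals.sum()))
    m = (np.prod(1.0 + densities.lam * vals) - 1.0) / densities.lam
    return float(np.clip(m, 0.0, 1.0))


def fms_similarity(terms_a, terms_b, probs: TermProbabilityTable) -> float:
    """Fuzzy-measure similarity of two genes' GO term sets.

    Each gene's Sugeno measure is evaluated on the shared term
    intersection and the two values are averaged, so the result is
    symmetric, 1 for identical annotation and 0 for disjoint annotation.
    Genes whose densities are all zero are unusable and yield 0.
    """
    fds_a = build_density_set(terms_a, probs)
    fds_b = build_density_set(terms_b, probs)
    if fds_a.degenerate or fds_b.degenerate or not fds_a.terms or not fds_b.terms:
        return 0.0
    shared = set(fds_a.terms) & set(fds_b.terms)
    return 0.5 * (sugeno_measure(shared, fds_a) + sugeno_measure(shared, fds_b))


class GoSimilarity:
    """Memoizing facade: per-gene density sets are pure functions of the
    term set, so they are computed once and reused across modules."""

    def __init__(self, go: GoKnowledge, probs: TermProbabilityTable | None = None,
                 children_depth: int | None = None):
        self.go = go
        self.probs = probs if probs is not None else term_probability(go, children_depth)
        self._density_cache: dict[frozenset[str], FuzzyDensitySet] = {}
        self._sim_cache: dict[frozenset[str], float] = {}

    def density_set(self, gene: str) -> FuzzyDensitySet:
        terms = self.go.terms_of(gene)
        if terms not in self._density_cache:
            self._density_cache[terms] = build_density_set(sorted(terms), self.probs)
        return self._density_cache[terms]

    def similarity(self, gene_a: str, gene_b: str) -> float:
        key = frozenset((gene_a, gene_b))
        if key not in self._sim_cache:
            fds_a = self.density_set(gene_a)
            fds_b = self.density_set(gene_b)
            if fds_a.degenerate or fds_b.degenerate or not fds_a.terms or not fds_b.terms:
                sim = 0.0
            else:
                shared = set(fds_a.terms) & set(fds_b.terms)
                sim = 0.5 * (sugeno_measure(shared, fds_a) + sugeno_measure(shared, fds_b))
            self._sim_cache[key] = sim
        return self._sim_cache[key]


def gene_basic_importance(
    gene: str,
    module: list[str],
    seeds: SeedGeneSet,
    similarity: GoSimilarity,
) -> float:
    """Module-specific basic importance of a gene.

    0 when the module holds no seed genes; 1 when the gene is itself a
    seed; otherwise the mean fuzzy-measure similarity between the gene and
    the module's seed genes (an unannotated gene contributes 0 per seed).
    """
    module_seeds = [g for g in module if g in seeds]
    if not module_seeds:
        return 0.0
    if gene in seeds:
        return 1.0
    sims = [similarity.similarity(gene, d) for d in module_seeds]
    return float(np.mean(sims))
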