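"""Fusion of per-module local rankings into one global gene ranking.

Module importance values act as the probability that the next
disease-related gene comes from each module.  The recursion tracks, after i
genes have been globally ranked, how many came from module j (m(i,j)) and
the expected number t(i,j) = i * p(m_j); the next global position goes to
the module maximizing

    e(i, j) = t(i+1, j) - m(i, j) = (i+1) * p(m_j) - m(i, j)

and that module's highest-ranked not-yet-emitted local gene is appended.
Gene-set collections overlap, so the first module to emit a gene claims it;
a later module skips the claimed gene, advancing both its local pointer and
its m(i,j) count so the expectation bookkeeping stays consistent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .io_formats import GlobalRanking, RANKING_COLUMNS
from .scoring import GeneScore, LocalRanking, ModuleScore

logger = logging.getLogger(__name__)

UNMODULED = "(unmoduled)"


def normalize_module_probs(scores: list[ModuleScore]) -> dict[str, float]:
    """Selection probabilities proportional to module importance.

    Zero-importance modules get probability 0 (they become eligible only
    after every positive-probability module is exhausted).  If every module
    has zero importance, probabilities fall back to uniform with a warning.
    """
    if not scores:
        raise ValueError("no module scores")
    total = sum(s.p_module for s in scores)
    if total <= 0:
        logger.warning("all modules have zero importance; using uniform probabilities")
        return {s.module_name: 1.0 / len(scores) for s in scores}
    return {s.module_name: s.p_module / total for s in scores}


@dataclass
class FusionRow:
    gene: str
    module: str
    local_rank: int


def fuse(
    local_rankings: list[LocalRanking],
    probs: dict[str, float],
    p_module: dict[str, float] | None = None,
    trace: list | None = None,
) -> list[FusionRow]:
    """Run the expectation-driven recursion until every gene is ranked.

    ``p_module`` (unnormalized importances) only breaks ties in the argmax;
    remaining ties fall back to module input order.  Pass a list as
    ``trace`` to capture (step, chosen module, e-value) tuples for audit.
    """
    if p_module is None:
        p_module = dict(probs)
    order = {lr.module_name: k for k, lr in enumerate(local_rankings)}
    rankings = {lr.module_name: lr for lr in local_rankings}
    missing = set(rankings) - set(probs)
    if missing:
        raise ValueError(f"modules without a probability: {sorted(missing)[:5]}")

    pointer = {name: 0 for name in rankings}
    m_count = {name: 0 for name in rankings}
    emitted: set[str] = set()
    out: list[FusionRow] = []

    def has_unconsumed(name: str) -> bool:
        return pointer[name] < len(rankings[name].genes)

    def emit_from(name: str) -> None:
        """Advance past already-claimed genes (incrementing m) and emit the
        next unclaimed one, if any."""
        lr = rankings[name]
        while pointer[name] < len(lr.genes) and lr.genes[pointer[name]] in emitted:
            pointer[name] += 1
            m_count[name] += 1
        if pointer[name] >= len(lr.genes):
            return
        gene = lr.genes[pointer[name]]
        out.append(FusionRow(gene=gene, module=name, local_rank=pointer[name] + 1))
        emitted.add(gene)
        pointer[name] += 1
        m_count[name] += 1

    positive = [n for n in rankings if probs[n] > 0]
    while True:
        active = [n for n in positive if has_unconsumed(n)]
        if not active:
            break
        i = len(out)
        best = max(
            active,
            key=lambda n: (
                (i + 1) * probs[n] - m_count[n],
                probs[n],
                p_module.get(n, 0.0),
                -order[n],
            ),
        )
        if trace is not None:
            trace.append((i, best, (i + 1) * probs[best] - m_count[best]))
        emit_from(best)

    # Exhausted every positive-probability module; process the rest in
    # module input order.
    for name in sorted(rankings, key=order.get):
        if probs[name] > 0:
            continue
        while has_unconsumed(name):
            emit_from(name)
    return out


def assemble_global_ranking(
    fused: list[FusionRow],
    module_scores: dict[str, ModuleScore],
    gene_scores: dict[tuple[str, str], GeneScore],
    unmoduled: list[tuple[str, float]] | None = None,
) -> GlobalRanking:
    """Build the output table: fused module genes first, then any genes
    outside every module ordered by (1 - padj) descending, gene id as the
    tie-break, flagged with the ``(unmoduled)`` pseudo-module."""
    rows = []
    for rank, fr in enumerate(fused, start=1):
        gs = gene_scores[(fr.module, fr.gene)]
        ms = module_scores[fr.module]
        rows.append((rank, fr.gene, fr.module, fr.local_rank, gs.p_gene, ms.p_module))
    if unmoduled:
        ordered = sorted(unmoduled, key=lambda t: (-t[1], t[0]))
        base = len(rows)
        for k, (gene, score) in enumerate(ordered, start=1):
            rows.append((base + k, gene, UNMODULED, k, score, 0.0))
    table = pd.DataFrame(rows, columns=list(RANKING_COLUMNS))
    return GlobalRanking(table=table)
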