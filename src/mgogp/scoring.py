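"""Module importance and module-specific gene importance.

Module importance combines the fraction of consensus DE genes (Ncr), the
fraction of consensus differential correlations among the module's gene
pairs (Ecr), and a seed-density prior info = (num seeds + 1)/N:

    p(m) = ((Ncr + Ecr) / 2) * info

Gene importance inside a module adds a differential-expression term, the
gene's differential-correlation fraction CorC, and the GO-similarity prior
from the seed genes:

    p(g) = de_term + CorC(g) + info(g)

The DE term defaults to 1 - padj so that more significant genes score
higher; the literal raw-padj sum is kept as an option.  CorC defaults to
the consensus DEE indicator (internally consistent with Ecr); the literal
single-round Sc variant, evaluated on the full sample set, is available as
``corc_indicator="sc"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .diffcorr import ModuleDiffCorr
from .go_fuzzy import GoSimilarity, gene_basic_importance
from .io_formats import SeedGeneSet
from .sampling_de import DeResult

logger = logging.getLogger(__name__)


@dataclass
class ModuleScore:
    module_name: str
    ncr: float
    ecr: float
    info: float
    p_module: float
    n_genes: int
    n_seeds: int


@dataclass
class GeneScore:
    gene_id: str
    module_name: str
    de_term: float
    corc: float
    info: float
    p_gene: float


@dataclass
class LocalRanking:
    """One module's genes ordered by descending importance."""

    module_name: str
    scores: list[GeneScore]

    @property
    def genes(self) -> list[str]:
        return [s.gene_id for s in self.scores]


def module_ncr(module_genes: list[str], de: DeResult) -> float:
    """Fraction of the module's genes called consensus-DE."""
    if not module_genes:
        raise ValueError("module is empty")
    deg = de.deg.reindex(module_genes).fillna(0)
    return float(deg.sum() / len(module_genes))


def module_ecr(diffcorr: ModuleDiffCorr) -> float:
    """Fraction of the module's K = N(N-1)/2 pairs called DEE."""
    if diffcorr.n_pairs < 1:
        raise ValueError("module has no gene pairs")
    return float(diffcorr.dee.sum() / diffcorr.n_pairs)


def module_basic_importance(module_genes: list[str], seeds: SeedGeneSet) -> float:
    """(num seeds in module + 1) / N; may exceed 1 for tiny seed-dense modules."""
    if not module_genes:
        raise ValueError("module is empty")
    n_seeds = sum(1 for g in module_genes if g in seeds)
    info = (n_seeds + 1) / len(module_genes)
    if info > 1:
        logger.warning("module info = %.3f exceeds 1 (N=%d, seeds=%d)",
                       info, len(module_genes), n_seeds)
    return info


def module_importance(ncr: float, ecr: float, info: float) -> float:
    return ((ncr + ecr) / 2.0) * info


def score_module(
    module_name: str,
    module_genes: list[str],
    de: DeResult,
    diffcorr: ModuleDiffCorr,
    seeds: SeedGeneSet,
) -> ModuleScore:
    ncr = module_ncr(module_genes, de)
    ecr = module_ecr(diffcorr)
    info = module_basic_importance(module_genes, seeds)
    return ModuleScore(
        module_name=module_name,
        ncr=ncr,
        ecr=ecr,
        info=info,
        p_module=module_importance(ncr, ecr, info),
        n_genes=len(module_genes),
        n_seeds=sum(1 for g in module_genes if g in seeds),
    )


def gene_corc(gene: str, diffcorr: ModuleDiffCorr, indicator: str = "dee") -> float:
    """Fraction of the gene's N-1 within-module pairs flagged as
    differentially correlated (consensus ``dee`` or full-data ``sc``)."""
    if gene not in diffcorr.genes:
        raise ValueError(f"gene {gene!r} not in module {diffcorr.module_name!r}")
    idx = diffcorr.pair_indices_of(gene)
    if not idx:
        return 0.0
    flags = diffcorr.dee if indicator == "dee" else diffcorr.sc_full
    if indicator not in ("dee", "sc"):
        raise ValueError("indicator must be 'dee' or 'sc'")
    return float(np.asarray(flags)[idx].sum() / len(idx))


def gene_importance(de_padj: float, corc: float, info: float,
                    padj_mode: str = "complement") -> float:
    """Sum of the three addends; complement mode uses 1 - padj."""
    if padj_mode == "complement":
        de_term = 1.0 - de_padj
    elif padj_mode == "raw":
        de_term = de_padj
    else:
        raise ValueError("padj_mode must be 'complement' or 'raw'")
    return de_term + corc + info


def score_module_genes(
    module_name: str,
    module_genes: list[str],
    de: DeResult,
    diffcorr: ModuleDiffCorr,
    seeds: SeedGeneSet,
    similarity: GoSimilarity,
    padj_mode: str = "complement",
    corc_indicator: str = "dee",
) -> list[GeneScore]:
    scores = []
    for gene in module_genes:
        padj = float(de.padj.get(gene, 1.0))
        corc = gene_corc(gene, diffcorr, corc_indicator)
        info = gene_basic_importance(gene, module_genes, seeds, similarity)
        de_term = (1.0 - padj) if padj_mode == "complement" else padj
        scores.append(GeneScore(
            gene_id=gene,
            module_name=module_name,
            de_term=de_term,
            corc=corc,
            info=info,
            p_gene=de_term + corc + info,
        ))
    return scores


def rank_module_genes(scores: list[GeneScore]) -> LocalRanking:
    """Descending by p_gene; ties by higher info, higher corc, then gene id."""
    if not scores:
        raise ValueError("no gene scores to rank")
    module_name = scores[0].module_name
    ordered = sorted(scores, key=lambda s: (-s.p_gene, -s.info, -s.corc, s.gene_id))
    return LocalRanking(module_name=module_name, scores=ordered)
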