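"""Readers, writers and validated in-memory containers.

Every external format the pipeline touches is handled here: the expression
matrix (genes x samples TSV) with its sample->condition map, GMT gene-set
modules, gene->GO annotations (GAF 2.x or two-column TSV), the GO term
hierarchy (OBO, ``is_a`` relations only), seed gene lists, and the output
ranking table.  Gene identifiers are matched as exact strings after
whitespace trimming; no alias resolution is attempted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

NORMAL = "normal"
TUMOR = "tumor"
CONDITIONS = (NORMAL, TUMOR)

#: Fisher's z-test needs L-3 > 0 and Q-3 > 0; four samples per condition is
#: the smallest size every stage (subsampling included) can operate on.
MIN_SAMPLES_PER_CONDITION = 4

RANKING_COLUMNS = ("rank", "gene", "module", "local_rank", "gene_score", "module_score")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Expression data
# ---------------------------------------------------------------------------


@dataclass
class ExpressionData:
    """Gene x sample expression values with a binary condition design.

    Parameters
    ----------
    values
        Non-negative expression values, genes as rows, samples as columns.
    condition
        Maps every sample id to ``"normal"`` or ``"tumor"``.
    zero_genes
        Genes whose row is identically zero (kept, but flagged).
    """

    values: pd.DataFrame
    condition: pd.Series
    zero_genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        if self.values.isna().to_numpy().any():
            raise FormatError("expression matrix contains NaN values")
        if (self.values.to_numpy() < 0).any():
            raise FormatError("expression matrix contains negative values")
        missing = set(self.values.columns) - set(self.condition.index)
        if missing:
            raise FormatError(f"samples without a condition label: {sorted(missing)[:5]}")
        self.condition = self.condition.loc[self.values.columns]
        bad = set(self.condition.unique()) - set(CONDITIONS)
        if bad:
            raise FormatError(f"unknown condition labels: {sorted(bad)}")
        for cond in CONDITIONS:
            n = int((self.condition == cond).sum())
            if n < MIN_SAMPLES_PER_CONDITION:
                raise FormatError(
                    f"condition {cond!r} has {n} samples; "
                    f"at least {MIN_SAMPLES_PER_CONDITION} are required"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def normal_samples(self) -> list[str]:
        return list(self.condition.index[self.condition == NORMAL])

    @property
    def tumor_samples(self) -> list[str]:
        return list(self.condition.index[self.condition == TUMOR])

    @property
    def n_normal(self) -> int:
        """L, the normal sample count."""
        return len(self.normal_samples)

    @property
    def n_tumor(self) -> int:
        """Q, the tumor sample count."""
        return len(self.tumor_samples)


def read_expression(matrix_path: str | Path, conditions_path: str | Path) -> ExpressionData:
    """Load an expression TSV plus a two-column sample->condition TSV.

    The matrix file has a header row of sample ids and gene ids in the first
    column.  The conditions file maps every sample id to ``normal`` or
    ``tumor``; a header line is tolerated and skipped.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str).str.strip()
    values.columns = values.columns.astype(str).str.strip()
    non_numeric = [c for c in values.columns if not pd.api.types.is_numeric_dtype(values[c])]
    if non_numeric:
        raise FormatError(f"non-numeric expression columns: {non_numeric[:5]}")

    cond_raw = pd.read_csv(conditions_path, sep="\t", header=None, dtype=str)
    if cond_raw.shape[1] != 2:
        raise FormatError("conditions file must have exactly two columns (sample, condition)")
    cond_raw = cond_raw.apply(lambda col: col.str.strip())
    # Tolerate a header line such as "sample<TAB>condition".
    if cond_raw.iloc[0, 1] not in CONDITIONS:
        cond_raw = cond_raw.iloc[1:]
    if cond_raw[0].duplicated().any():
        raise FormatError("duplicate sample id in conditions file")
    condition = pd.Series(cond_raw[1].to_numpy(), index=cond_raw[0].to_numpy())
    unknown = set(condition.index) - set(values.columns)
    if unknown:
        raise FormatError(f"conditions file names unknown samples: {sorted(unknown)[:5]}")

    zero = tuple(values.index[(values == 0).all(axis=1)])
    if zero:
        logger.warning("%d genes have all-zero expression rows", len(zero))
    return ExpressionData(values=values, condition=condition, zero_genes=zero)


# ---------------------------------------------------------------------------
# Gene modules (GMT)
# ---------------------------------------------------------------------------


@dataclass
class ModuleSet:
    """Named, possibly overlapping gene modules in file order."""

    modules: dict[str, list[str]]

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    @property
    def names(self) -> list[str]:
        return list(self.modules)

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.modules.values():
            out.update(genes)
        return out

    def restrict_to(self, universe: Iterable[str], min_size: int = 2) -> "ModuleSet":
        """Intersect every module with ``universe``; drop modules that fall
        below ``min_size`` genes (pair correlations need at least two).

        Logs the gene-universe coverage: the fraction of distinct module
        genes that have expression information.
        """
        universe = set(universe)
        all_genes = self.gene_universe()
        covered = len(all_genes & universe)
        if all_genes:
            logger.info(
                "module gene universe coverage: %d/%d (%.1f%%) genes present in expression matrix",
                covered, len(all_genes), 100.0 * covered / len(all_genes),
            )
        kept: dict[str, list[str]] = {}
        dropped = 0
        for name, genes in self.modules.items():
            inter = [g for g in genes if g in universe]
            if len(inter) >= min_size:
                kept[name] = inter
            else:
                dropped += 1
        if dropped:
            logger.info("dropped %d modules with < %d genes after intersection", dropped, min_size)
        return ModuleSet(modules=kept)


def read_gmt(path: str | Path) -> ModuleSet:
    """Parse a GMT file: ``name TAB description TAB gene TAB gene ...``.

    Module order and per-module gene order follow the file; duplicate genes
    within one line are removed (first occurrence wins) with a warning.
    """
    modules: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3")
            name = fields[0].strip()
            if not name:
                raise FormatError(f"{path}:{lineno}: empty module name")
            if name in modules:
                raise FormatError(f"{path}:{lineno}: duplicate module name {name!r}")
            genes: list[str] = []
            seen: set[str] = set()
            ndup = 0
            for g in fields[2:]:
                g = g.strip()
                if not g:
                    continue
                if g in seen:
                    ndup += 1
                    continue
                seen.add(g)
                genes.append(g)
            if ndup:
                logger.warning("%s:%d: module %s has %d duplicate genes (deduplicated)",
                               path, lineno, name, ndup)
            modules[name] = genes
    return ModuleSet(modules=modules)


def write_gmt(modules: ModuleSet, path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in modules.modules.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# GO knowledge: annotations + term DAG
# ---------------------------------------------------------------------------


@dataclass
class GoKnowledge:
    """Gene->GO annotations plus the ``is_a`` term DAG and its closure.

    ``dag`` stores child->parent edges; ``descendants[t]`` is the full set of
    terms below ``t`` (transitive closure, each term counted once however
    many paths reach it).
    """

    annotations: dict[str, frozenset[str]]
    dag: nx.DiGraph
    descendants: dict[str, frozenset[str]] = field(default_factory=dict)
    quarantined: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.dag):
            raise FormatError("GO is_a graph is cyclic")
        if not self.descendants:
            self.descendants = descendant_closure(self.dag)

    def terms_of(self, gene: str) -> frozenset[str]:
        return self.annotations.get(gene, frozenset())


def descendant_closure(dag: nx.DiGraph) -> dict[str, frozenset[str]]:
    """Transitive descendant sets for a child->parent DAG.

    Children are processed before their parents (topological order of the
    child->parent orientation), so each node's closure is the union of its
    children's closures plus the children themselves.
    """
    closure: dict[str, set[str]] = {}
    for node in nx.topological_sort(dag):
        acc: set[str] = set()
        for child in dag.predecessors(node):
            acc.add(child)
            acc.update(closure[child])
        closure[node] = acc
    return {n: frozenset(s) for n, s in closure.items()}


def _read_obo_isa(path: str | Path) -> nx.DiGraph:
    multi = obonet.read_obo(path)  # obsolete terms are skipped by obonet
    dag = nx.DiGraph()
    dag.add_nodes_from(multi.nodes)
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            dag.add_edge(child, parent)
    return dag


def _read_annotation_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Yield (gene, term) records from either GAF 2.x or a 2-column TSV."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("!", "#")):
                continue
            fields = line.split("\t")
            if len(fields) >= 15:  # GAF 2.x body line
                gene, term = fields[2].strip(), fields[4].strip()
            elif len(fields) == 2:
                gene, term = fields[0].strip(), fields[1].strip()
            else:
                raise FormatError(
                    f"{path}:{lineno}: annotation line has {len(fields)} fields "
                    "(expected 2-column TSV or GAF 2.x)"
                )
            if gene and term:
                pairs.append((gene, term))
    return pairs


def read_go(annotations_path: str | Path, obo_path: str | Path) -> GoKnowledge:
    """Load annotations and the OBO hierarchy into a :class:`GoKnowledge`.

    Annotations referencing terms absent from the OBO (including obsolete
    terms, which the OBO reader drops) are quarantined with a warning rather
    than failing the load.
    """
    dag = _read_obo_isa(obo_path)
    known = set(dag.nodes)
    annotations: dict[str, set[str]] = {}
    quarantined: dict[str, set[str]] = {}
    for gene, term in _read_annotation_pairs(annotations_path):
        if term in known:
            annotations.setdefault(gene, set()).add(term)
        else:
            quarantined.setdefault(gene, set()).add(term)
    if quarantined:
        n_terms = len({t for ts in quarantined.values() for t in ts})
        logger.warning(
            "quarantined annotations to %d terms absent from the OBO (obsolete or unknown)",
            n_terms,
        )
    return GoKnowledge(
        annotations={g: frozenset(t) for g, t in annotations.items()},
        dag=dag,
        quarantined={g: frozenset(t) for g, t in quarantined.items()},
    )


# ---------------------------------------------------------------------------
# Seed genes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeedGeneSet:
    """Known disease genes used as prior knowledge."""

    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.genes:
            raise FormatError("seed gene set is empty")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


def read_seed_genes(path: str | Path) -> SeedGeneSet:
    genes = set()
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.add(g)
    return SeedGeneSet(genes=frozenset(genes))


# ---------------------------------------------------------------------------
# Global ranking
# ---------------------------------------------------------------------------


@dataclass
class GlobalRanking:
    """A strict permutation of ranked genes with provenance columns."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.table.columns) != list(RANKING_COLUMNS):
            raise FormatError(f"ranking columns must be {RANKING_COLUMNS}")
        n = len(self.table)
        ranks = self.table["rank"].to_numpy()
        if n and not np.array_equal(np.sort(ranks), np.arange(1, n + 1)):
            raise FormatError("ranks must be exactly 1..R with no gaps or duplicates")
        if self.table["gene"].duplicated().any():
            raise FormatError("a gene appears more than once in the ranking")
        self.table = self.table.sort_values("rank").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def genes(self) -> list[str]:
        return list(self.table["gene"])


def write_ranking(ranking: GlobalRanking, path: str | Path) -> None:
    ranking.table.to_csv(path, sep="\t", index=False)


def read_ranking(path: str | Path) -> GlobalRanking:
    table = pd.read_csv(
        path, sep="\t",
        dtype={"rank": int, "gene": str, "module": str, "local_rank": int,
               "gene_score": float, "module_score": float},
    )
    return GlobalRanking(table=table)
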