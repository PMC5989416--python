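"""Consensus differential-expression calling by repeated subsampling.

A gene is a consensus DE gene (DEG = 1) when its per-round adjusted p-value
falls at or below mu in at least a fraction omega of S stratified random
subsamples.  The per-round test is a two-sided Welch t-test on log2(x+1)
with Benjamini-Hochberg adjustment across genes; a precomputed per-gene padj
table (e.g. exported from DESeq2) may replace the built-in full-data test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionData, FormatError, MIN_SAMPLES_PER_CONDITION

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeParams:
    """Settings for the consensus DE call.

    s is the number of sampling rounds, omega the vote-fraction threshold,
    mu the per-round padj threshold, subsample_fraction the fraction of each
    condition's samples drawn (without replacement) per round.
    """

    s: int = 1000
    omega: float = 0.9
    mu: float = 0.01
    subsample_fraction: float = 0.8
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("s must be a positive integer")
        if not 0 < self.omega <= 1:
            raise ValueError("omega must lie in (0, 1]")
        if not 0 < self.mu < 1 and self.mu != 1.0:
            raise ValueError("mu must lie in (0, 1]")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")


@dataclass
class DeResult:
    """Per-gene outputs: full-data padj, vote fraction over rounds, DEG call."""

    padj: pd.Series
    vote_fraction: pd.Series
    deg: pd.Series

    def deg_set(self) -> set[str]:
        return set(self.deg.index[self.deg == 1])


def log_transform(values: pd.DataFrame) -> pd.DataFrame:
    return np.log2(values + 1.0)


def _welch_padj(log_values: np.ndarray, normal_cols: np.ndarray, tumor_cols: np.ndarray) -> np.ndarray:
    """Vectorized Welch t-test + BH across genes on log-scale values.

    Genes with zero variance in both groups carry no evidence and get p = 1.
    """
    a = log_values[:, normal_cols]
    b = log_values[:, tumor_cols]
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    pvals[degenerate] = 1.0
    pvals[~np.isfinite(pvals)] = 1.0
    return multipletests(pvals, method="fdr_bh")[1]


def _condition_columns(expr: ExpressionData) -> tuple[np.ndarray, np.ndarray]:
    cols = pd.Index(expr.sample_ids)
    normal = np.array([cols.get_loc(s) for s in expr.normal_samples])
    tumor = np.array([cols.get_loc(s) for s in expr.tumor_samples])
    return normal, tumor


def de_test_once(expr: ExpressionData, sample_subset: set[str] | list[str], mu: float) -> pd.Series:
    """Single-round DE indicator: Se(g) = 1 iff padj(g) <= mu on the subset."""
    subset = [s for s in expr.sample_ids if s in set(sample_subset)]
    cond = expr.condition.loc[subset]
    n_n = int((cond == "normal").sum())
    n_t = int((cond == "tumor").sum())
    if min(n_n, n_t) < MIN_SAMPLES_PER_CONDITION:
        raise FormatError(
            f"subset has {n_n} normal / {n_t} tumor samples; "
            f"need >= {MIN_SAMPLES_PER_CONDITION} of each"
        )
    logv = log_transform(expr.values[subset]).to_numpy()
    cols = pd.Index(subset)
    normal = np.array([cols.get_loc(s) for s in subset if cond[s] == "normal"])
    tumor = np.array([cols.get_loc(s) for s in subset if cond[s] == "tumor"])
    padj = _welch_padj(logv, normal, tumor)
    return pd.Series((padj <= mu).astype(np.int8), index=expr.gene_ids)


def read_padj_table(path: str | Path) -> pd.Series:
    """Read a precomputed per-gene padj TSV (gene TAB padj), header optional."""
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if raw.shape[1] != 2:
        raise FormatError("padj table must have two columns: gene, padj")
    try:
        float(raw.iloc[0, 1])
    except ValueError:
        raw = raw.iloc[1:]
    s = pd.Series(raw[1].astype(float).to_numpy(), index=raw[0].str.strip().to_numpy())
    if ((s < 0) | (s > 1)).any():
        raise FormatError("padj values must lie in [0, 1]")
    return s


def consensus_de(
    expr: ExpressionData,
    params: DeParams,
    padj_table: pd.Series | None = None,
) -> DeResult:
    """Run S subsampling rounds and form the consensus DEG call.

    Each round draws ``subsample_fraction`` of each condition's samples
    without replacement (stratified, preserving class balance), reruns the
    built-in test, and votes Se in {0, 1} per gene.  ``padj_table``, when
    supplied, provides the full-data padj used downstream in the gene score;
    the per-round voting always reruns the built-in test on the subsample.
    """
    normal_cols, tumor_cols = _condition_columns(expr)
    n_take = int(np.floor(params.subsample_fraction * len(normal_cols)))
    t_take = int(np.floor(params.subsample_fraction * len(tumor_cols)))
    if min(n_take, t_take) < MIN_SAMPLES_PER_CONDITION:
        raise ValueError(
            f"subsample_fraction={params.subsample_fraction} leaves "
            f"{n_take} normal / {t_take} tumor samples; need >= "
            f"{MIN_SAMPLES_PER_CONDITION} of each per round"
        )
    logv = log_transform(expr.values).to_numpy()

    if padj_table is not None:
        missing = [g for g in expr.gene_ids if g not in padj_table.index]
        if missing:
            logger.warning("padj table lacks %d genes; treated as padj = 1", len(missing))
        full_padj = padj_table.reindex(expr.gene_ids).fillna(1.0)
    else:
        full_padj = pd.Series(_welch_padj(logv, normal_cols, tumor_cols), index=expr.gene_ids)

    rng = np.random.default_rng(params.rng_seed)
    votes = np.zeros(len(expr.gene_ids), dtype=np.int64)
    for _ in range(params.s):
        sub_n = rng.choice(normal_cols, size=n_take, replace=False)
        sub_t = rng.choice(tumor_cols, size=t_take, replace=False)
        padj = _welch_padj(logv, sub_n, sub_t)
        votes += padj <= params.mu

    vote_fraction = pd.Series(votes / params.s, index=expr.gene_ids)
    deg = pd.Series((vote_fraction >= params.omega).astype(np.int8), index=expr.gene_ids)
    return DeResult(padj=full_padj, vote_fraction=vote_fraction, deg=deg)
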