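"""Per-module differential-correlation detection.

For every unordered gene pair inside a module, condition-specific Pearson
correlations are compared through the Fisher z-transform:

    Z = (arctanh(r_normal) - arctanh(r_tumor)) / sqrt(1/(L-3) + 1/(Q-3))

which is approximately standard normal when the two population correlations
are equal.  Pairs are flagged per subsampling round when their local false
discovery rate falls at or below upsilon (Sc = 1), and a pair is a consensus
differential correlation (DEE = 1) when Sc = 1 in at least a fraction delta
of S rounds.

The local fdr uses a simplified empirical-null estimator: the null is
Normal(0, sigma-hat) with sigma-hat matched to the central 50% of the z
values, the marginal density comes from a kernel estimate, and
fdr(z) = min(1, pi0 * f0(z) / f(z)).  Benjamini-Hochberg q-values on normal
p-values are available as a transparent alternative and are the automatic
fallback below 200 z values, where a density estimate is unreliable.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionData, MIN_SAMPLES_PER_CONDITION

logger = logging.getLogger(__name__)

#: correlations at |r| >= 1 are clamped before arctanh
CLAMP = 1.0 - 1e-7

#: below this many z values the local-fdr density fit is refused
LOCAL_FDR_MIN_N = 200


@dataclass(frozen=True)
class CorrParams:
    """Settings for the consensus differential-correlation call."""

    s: int = 1000
    delta: float = 0.9
    upsilon: float = 0.05
    subsample_fraction: float = 0.8
    rng_seed: int = 0
    fdr_method: str = "local_fdr"

    def __post_init__(self) -> None:
        if self.s < 1:
            raise ValueError("s must be a positive integer")
        if not 0 < self.delta <= 1:
            raise ValueError("delta must lie in (0, 1]")
        if not 0 < self.upsilon < 1:
            raise ValueError("upsilon must lie in (0, 1)")
        if not 0 < self.subsample_fraction <= 1:
            raise ValueError("subsample_fraction must lie in (0, 1]")
        if self.fdr_method not in ("local_fdr", "bh"):
            raise ValueError("fdr_method must be 'local_fdr' or 'bh'")


@dataclass
class ModuleDiffCorr:
    """Differential-correlation results for one module.

    Arrays are aligned with ``pairs`` (all N*(N-1)/2 unordered pairs of the
    module's expression-present genes).  ``sc_full`` is the single-round Sc
    indicator evaluated on the full sample set; ``dee`` is the consensus
    indicator over the S subsampling rounds.
    """

    module_name: str
    genes: tuple[str, ...]
    pairs: list[tuple[str, str]]
    r_normal: np.ndarray
    r_tumor: np.ndarray
    z_stat: np.ndarray
    fdr_full: np.ndarray
    sc_full: np.ndarray
    sc_fraction: np.ndarray
    dee: np.ndarray
    degenerate: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def pair_indices_of(self, gene: str) -> list[int]:
        return [i for i, (a, b) in enumerate(self.pairs) if gene in (a, b)]

    def dee_lookup(self) -> dict[frozenset[str], int]:
        return {frozenset(p): int(d) for p, d in zip(self.pairs, self.dee)}


# ---------------------------------------------------------------------------
# Elementary statistics
# ---------------------------------------------------------------------------


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; 0 when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.std() <= 1e-12 * (np.abs(x).mean() + 1.0) or \
            y.std() <= 1e-12 * (np.abs(y).mean() + 1.0):
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def fisher_z(r):
    """Variance-stabilizing arctanh transform; |r| >= 1 is clamped."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) >= 1):
        logger.warning("correlation(s) with |r| >= 1 clamped before arctanh")
        r = np.clip(r, -CLAMP, CLAMP)
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def diffcorr_z(r_normal, r_tumor, n_normal: int, n_tumor: int):
    """Standardized difference of Fisher-transformed correlations."""
    if n_normal <= 3 or n_tumor <= 3:
        raise ValueError("both sample counts must exceed 3")
    denom = np.sqrt(1.0 / (n_normal - 3) + 1.0 / (n_tumor - 3))
    out = (fisher_z(r_normal) - fisher_z(r_tumor)) / denom
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# Local fdr / BH on z statistics
# ---------------------------------------------------------------------------


def _local_fdr(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if np.ptp(z) == 0:
        return np.ones_like(z)
    q25, q75 = np.percentile(z, [25, 75])
    # Central matching: the middle half of the z values is assumed
    # null-dominated; its IQR fixes the empirical-null scale.
    sigma = max((q75 - q25) / (2.0 * stats.norm.ppf(0.75)), 1e-8)
    expected_central = stats.norm.cdf(q75 / sigma) - stats.norm.cdf(q25 / sigma)
    pi0 = min(1.0, 0.5 / max(expected_central, 1e-12))
    grid = np.linspace(z.min() - 3 * sigma, z.max() + 3 * sigma, 2048)
    kde = stats.gaussian_kde(z)
    f = np.interp(z, grid, kde(grid))
    f = np.maximum(f, 1e-300)
    fdr = pi0 * stats.norm.pdf(z, loc=0.0, scale=sigma) / f
    return np.clip(fdr, 0.0, 1.0)


def _bh_qvalues(z: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(np.asarray(z, dtype=float)))
    return multipletests(p, method="fdr_bh")[1]


def pair_fdr(z_stats: np.ndarray, method: str = "local_fdr") -> np.ndarray:
    """Per-pair false-discovery quantity for a vector of z statistics.

    ``local_fdr`` needs at least ``LOCAL_FDR_MIN_N`` values; smaller inputs
    automatically fall back to BH with a warning.
    """
    z = np.asarray(z_stats, dtype=float)
    if z.size == 0:
        raise ValueError("need at least one z value")
    if method == "local_fdr":
        if z.size < LOCAL_FDR_MIN_N:
            logger.warning(
                "local_fdr needs >= %d z values, got %d; falling back to BH",
                LOCAL_FDR_MIN_N, z.size,
            )
            return _bh_qvalues(z)
        return _local_fdr(z)
    if method == "bh":
        return _bh_qvalues(z)
    raise ValueError(f"unknown fdr method {method!r}")


# ---------------------------------------------------------------------------
# Consensus over subsampling rounds
# ---------------------------------------------------------------------------


def _pair_correlations(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle correlations of the rows of ``x``.

    Returns (r, degenerate) where constant rows yield r = 0 flagged.
    """
    n = x.shape[0]
    iu = np.triu_indices(n, k=1)
    # Constant rows can carry O(eps) rounding noise after mean subtraction.
    constant = x.std(axis=1) <= 1e-12 * (np.abs(x).mean(axis=1) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.corrcoef(x)
    r = c[iu]
    bad = ~np.isfinite(r) | constant[iu[0]] | constant[iu[1]]
    r = np.where(bad, 0.0, r)
    return r, bad


def consensus_diffcorr_many(
    expr: ExpressionData,
    modules: dict[str, list[str]],
    params: CorrParams,
) -> dict[str, ModuleDiffCorr]:
    """Consensus differential-correlation call for several modules at once.

    All modules share the per-round condition-stratified subsamples.  The
    fdr is estimated within a module when it has at least
    ``LOCAL_FDR_MIN_N`` pairs; smaller modules are pooled into one joint z
    vector per round (a local fdr needs a distribution to fit a null to).
    Genes absent from the expression matrix are ignored; zero-variance pairs
    get Z = 0, fdr = 1, Sc = 0 for the affected round.
    """
    logv = np.log2(expr.values.to_numpy() + 1.0)
    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    cols = pd.Index(expr.sample_ids)
    normal_cols = np.array([cols.get_loc(s) for s in expr.normal_samples])
    tumor_cols = np.array([cols.get_loc(s) for s in expr.tumor_samples])

    n_take = int(np.floor(params.subsample_fraction * len(normal_cols)))
    t_take = int(np.floor(params.subsample_fraction * len(tumor_cols)))
    if min(n_take, t_take) < MIN_SAMPLES_PER_CONDITION:
        raise ValueError("subsample leaves fewer than 4 samples in a condition")

    prepared: dict[str, dict] = {}
    for name, genes in modules.items():
        present = [g for g in genes if g in gene_pos]
        if len(present) < 2:
            logger.warning("module %s has < 2 expression-present genes; skipped", name)
            continue
        idx = np.array([gene_pos[g] for g in present])
        pairs = list(itertools.combinations(present, 2))
        prepared[name] = {
            "genes": tuple(present),
            "idx": idx,
            "pairs": pairs,
            "sc_count": np.zeros(len(pairs), dtype=np.int64),
        }
    if not prepared:
        return {}

    def round_z(sub_n: np.ndarray, sub_t: np.ndarray) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        L, Q = len(sub_n), len(sub_t)
        out = {}
        for name, prep in prepared.items():
            rn, bad_n = _pair_correlations(logv[np.ix_(prep["idx"], sub_n)])
            rt, bad_t = _pair_correlations(logv[np.ix_(prep["idx"], sub_t)])
            z = diffcorr_z(rn, rt, L, Q)
            bad = bad_n | bad_t
            z = np.where(bad, 0.0, z)
            out[name] = (z, bad)
        return out

    def apply_fdr(z_by_module: dict[str, tuple[np.ndarray, np.ndarray]]) -> dict[str, np.ndarray]:
        fdrs: dict[str, np.ndarray] = {}
        pooled_names = []
        pooled_z = []
        for name, (z, _bad) in z_by_module.items():
            if params.fdr_method == "local_fdr" and z.size >= LOCAL_FDR_MIN_N:
                fdrs[name] = pair_fdr(z, "local_fdr")
            else:
                pooled_names.append(name)
                pooled_z.append(z)
        if pooled_names:
            allz = np.concatenate(pooled_z)
            method = params.fdr_method if (
                params.fdr_method == "bh" or allz.size >= LOCAL_FDR_MIN_N
            ) else "bh"
            allf = pair_fdr(allz, method)
            start = 0
            for name, z in zip(pooled_names, pooled_z):
                fdrs[name] = allf[start:start + z.size]
                start += z.size
        for name, (_z, bad) in z_by_module.items():
            fdrs[name] = np.where(bad, 1.0, fdrs[name])
        return fdrs

    rng = np.random.default_rng(params.rng_seed)
    for _ in range(params.s):
        sub_n = rng.choice(normal_cols, size=n_take, replace=False)
        sub_t = rng.choice(tumor_cols, size=t_take, replace=False)
        z_by_module = round_z(sub_n, sub_t)
        fdr_by_module = apply_fdr(z_by_module)
        for name, prep in prepared.items():
            prep["sc_count"] += fdr_by_module[name] <= params.upsilon

    # Full-data pass: correlations, z, fdr, single-round Sc.
    full = round_z(normal_cols, tumor_cols)
    full_fdr = apply_fdr(full)
    results: dict[str, ModuleDiffCorr] = {}
    for name, prep in prepared.items():
        rn, bad_n = _pair_correlations(logv[np.ix_(prep["idx"], normal_cols)])
        rt, bad_t = _pair_correlations(logv[np.ix_(prep["idx"], tumor_cols)])
        z_full, bad = full[name]
        fdr = full_fdr[name]
        sc_fraction = prep["sc_count"] / params.s
        results[name] = ModuleDiffCorr(
            module_name=name,
            genes=prep["genes"],
            pairs=prep["pairs"],
            r_normal=rn,
            r_tumor=rt,
            z_stat=z_full,
            fdr_full=fdr,
            sc_full=(fdr <= params.upsilon).astype(np.int8),
            sc_fraction=sc_fraction,
            dee=(sc_fraction >= params.delta).astype(np.int8),
            degenerate=bad,
        )
    return results


def consensus_diffcorr(
    expr: ExpressionData,
    module_genes: list[str],
    params: CorrParams,
    module_name: str = "module",
) -> ModuleDiffCorr:
    """Single-module convenience wrapper around :func:`consensus_diffcorr_many`."""
    out = consensus_diffcorr_many(expr, {module_name: list(module_genes)}, params)
    if module_name not in out:
        raise ValueError("module has fewer than 2 expression-present genes")
    return out[module_name]
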