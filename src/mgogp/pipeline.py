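"""End-to-end orchestration: inputs -> scores -> fused global ranking.

A run is fully reproducible from its config plus input files: one master
seed deterministically derives independent per-stage seed streams for the
DE and correlation subsampling loops.  Stage outputs (the two expensive
consensus stages) can be cached under a config-content hash and reused.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io_formats as iof
from .diffcorr import CorrParams, consensus_diffcorr_many
from .go_fuzzy import GoSimilarity
from .rank_fusion import assemble_global_ranking, fuse, normalize_module_probs
from .sampling_de import DeParams, consensus_de, read_padj_table
from .scoring import (LocalRanking, ModuleScore, rank_module_genes,
                      score_module, score_module_genes)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    expr_path: str
    conditions_path: str
    modules_path: str
    go_annotations_path: str
    go_obo_path: str
    seeds_path: str
    out_dir: str
    s: int = 1000
    omega: float = 0.9
    delta: float = 0.9
    mu: float = 0.01
    upsilon: float = 0.05
    subsample_fraction: float = 0.8
    padj_mode: str = "complement"
    corc_indicator: str = "dee"
    fdr_method: str = "local_fdr"
    padj_table_path: str | None = None
    children_depth: int | None = None
    seed: int = 17
    cache_dir: str | None = None


@dataclass
class RunResult:
    ranking: iof.GlobalRanking
    module_scores: pd.DataFrame
    gene_scores: pd.DataFrame
    report: dict


def derive_stage_seeds(master: int) -> dict[str, int]:
    """Per-stage seeds spawned from one master seed (kept below 2**31)."""
    ss = np.random.SeedSequence(master)
    children = ss.spawn(2)
    return {
        "de": int(children[0].generate_state(1)[0] % (2 ** 31)),
        "corr": int(children[1].generate_state(1)[0] % (2 ** 31)),
    }


def _config_hash(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    payload.pop("out_dir", None)
    payload.pop("cache_dir", None)
    for key in ("expr_path", "conditions_path", "modules_path",
                "go_annotations_path", "go_obo_path", "seeds_path",
                "padj_table_path"):
        path = payload.get(key)
        if path:
            payload[key + "_sha"] = hashlib.sha256(Path(path).read_bytes()).hexdigest()
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def _cached(cache_dir: str | None, key: str, compute):
    if cache_dir is None:
        return compute()
    path = Path(cache_dir) / f"{key}.pkl"
    if path.exists():
        logger.info("cache hit: %s", path.name)
        with open(path, "rb") as fh:
            return pickle.load(fh)
    value = compute()
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        pickle.dump(value, fh)
    return value


def run(config: RunConfig) -> RunResult:
    """Execute the full prioritization and write outputs into ``out_dir``.

    Outputs: ``ranking.tsv`` (the global gene ranking), ``module_scores.tsv``,
    ``gene_scores.tsv``, ``report.json`` (coverage, dropped modules,
    parameter echo), ``config.yaml`` and ``run.log``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mgogp")
    root.addHandler(handler)
    t0 = time.time()
    try:
        return _run_inner(config, out_dir)
    finally:
        logger.info("run finished in %.1f s", time.time() - t0)
        root.removeHandler(handler)
        handler.close()


def _run_inner(config: RunConfig, out_dir: Path) -> RunResult:
    stage_seeds = derive_stage_seeds(config.seed)
    cfg_hash = _config_hash(config)

    def stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    expr = stage("read_expression", iof.read_expression,
                 config.expr_path, config.conditions_path)
    raw_modules = stage("read_gmt", iof.read_gmt, config.modules_path)
    modules = raw_modules.restrict_to(expr.gene_ids)
    go = stage("read_go", iof.read_go, config.go_annotations_path, config.go_obo_path)
    seeds = stage("read_seed_genes", iof.read_seed_genes, config.seeds_path)

    de_params = DeParams(s=config.s, omega=config.omega, mu=config.mu,
                         subsample_fraction=config.subsample_fraction,
                         rng_seed=stage_seeds["de"])
    padj_table = read_padj_table(config.padj_table_path) if config.padj_table_path else None
    de = stage("consensus_de", lambda: _cached(
        config.cache_dir, f"de_{cfg_hash}",
        lambda: consensus_de(expr, de_params, padj_table)))

    corr_params = CorrParams(s=config.s, delta=config.delta, upsilon=config.upsilon,
                             subsample_fraction=config.subsample_fraction,
                             rng_seed=stage_seeds["corr"],
                             fdr_method=config.fdr_method)
    diffcorr = stage("consensus_diffcorr", lambda: _cached(
        config.cache_dir, f"corr_{cfg_hash}",
        lambda: consensus_diffcorr_many(expr, modules.modules, corr_params)))

    similarity = stage("go_similarity", GoSimilarity, go,
                       children_depth=config.children_depth)

    module_scores: dict[str, ModuleScore] = {}
    gene_scores = {}
    local_rankings: list[LocalRanking] = []
    for name in modules.names:
        if name not in diffcorr:
            continue
        genes = modules.modules[name]
        ms = stage("score_module", score_module, name, genes, de, diffcorr[name], seeds)
        module_scores[name] = ms
        gss = stage("score_genes", score_module_genes, name, genes, de,
                    diffcorr[name], seeds, similarity,
                    config.padj_mode, config.corc_indicator)
        for gs in gss:
            gene_scores[(name, gs.gene_id)] = gs
        local_rankings.append(rank_module_genes(gss))

    if not module_scores:
        raise StageError("stage 'scoring' failed: no scorable modules")

    probs = normalize_module_probs(list(module_scores.values()))
    fused = stage("rank_fusion", fuse, local_rankings, probs,
                  {n: s.p_module for n, s in module_scores.items()})
    moduled_genes = {fr.gene for fr in fused}
    de_term = (1.0 - de.padj) if config.padj_mode == "complement" else de.padj
    unmoduled = [(g, float(de_term[g])) for g in expr.gene_ids if g not in moduled_genes]
    ranking = assemble_global_ranking(fused, module_scores, gene_scores, unmoduled)

    module_table = pd.DataFrame(
        [dataclasses.asdict(s) for s in module_scores.values()]
    )[["module_name", "n_genes", "n_seeds", "ncr", "ecr", "info", "p_module"]]
    gene_table = pd.DataFrame(
        [dataclasses.asdict(s) for s in gene_scores.values()]
    )[["module_name", "gene_id", "de_term", "corc", "info", "p_gene"]]

    all_module_genes = raw_modules.gene_universe()
    covered = len(all_module_genes & set(expr.gene_ids))
    report = {
        "parameters": {
            "S": config.s, "omega": config.omega, "delta": config.delta,
            "mu": config.mu, "upsilon": config.upsilon,
            "subsample_fraction": config.subsample_fraction,
            "padj_mode": config.padj_mode, "corc_indicator": config.corc_indicator,
            "fdr_method": config.fdr_method, "seed": config.seed,
        },
        "stage_seeds": stage_seeds,
        "config_hash": cfg_hash,
        "n_genes": len(expr.gene_ids),
        "n_normal": expr.n_normal,
        "n_tumor": expr.n_tumor,
        "n_modules_input": raw_modules.n_modules,
        "n_modules_scored": len(module_scores),
        "n_modules_dropped": raw_modules.n_modules - modules.n_modules,
        "module_gene_universe": len(all_module_genes),
        "module_genes_with_expression": covered,
        "coverage_fraction": covered / len(all_module_genes) if all_module_genes else 0.0,
        "n_unmoduled_genes": len(unmoduled),
        "n_ranked": len(ranking),
    }

    iof.write_ranking(ranking, out_dir / "ranking.tsv")
    module_table.to_csv(out_dir / "module_scores.tsv", sep="\t", index=False)
    gene_table.to_csv(out_dir / "gene_scores.tsv", sep="\t", index=False)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    return RunResult(ranking=ranking, module_scores=module_table,
                     gene_scores=gene_table, report=report)
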