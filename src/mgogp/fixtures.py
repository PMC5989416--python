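"""Deterministic synthetic generator for every pipeline input.

Emulates a two-condition expression study with planted signal so each
pipeline stage can be tested without any download:

* expression TSV — baseline log-normal noise per gene; planted DE genes
  are shifted by ``de_log2_fold`` in tumor samples; planted correlation
  blocks share a latent factor per condition, with loading sqrt(rho) so
  the expected within-block pairwise correlation is ``r_normal`` in normal
  samples and ``r_tumor`` in tumor samples;
* conditions TSV, GMT modules (signal modules carry DE genes, a
  correlation block, seeds and seed-related genes; the rest are pure
  background), a toy GO DAG (balanced tree written as OBO), a two-column
  annotation TSV in which seeds and their designated related genes share a
  leaf subtree, a seed gene list, and a ground-truth JSON manifest.

Outputs are byte-identical for identical seeds.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

FILES = {
    "expression": "expression.tsv",
    "conditions": "conditions.tsv",
    "modules": "modules.gmt",
    "obo": "go.obo",
    "annotations": "annotations.tsv",
    "seeds": "seeds.txt",
    "manifest": "manifest.json",
}


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic data.

    Defaults: 500 genes, 50 normal + 50 tumor samples, 20 modules of 10-30
    genes, 50 DE genes at fold change 4 (log2 fold 2), five correlation
    blocks of 8 genes with within-block correlation 0.9 in normal samples
    and 0.0 in tumor samples, 10 seed genes, and a depth-3 branching-3 GO
    tree with 3 terms per gene.
    """

    n_genes: int = 500
    n_normal: int = 50
    n_tumor: int = 50
    n_modules: int = 20
    module_size_range: tuple[int, int] = (10, 30)
    n_de_genes: int = 50
    de_log2_fold: float = 2.0
    n_corr_blocks: int = 5
    corr_block_size: int = 8
    r_normal: float = 0.9
    r_tumor: float = 0.0
    n_seeds: int = 10
    go_depth: int = 3
    go_branching: int = 3
    terms_per_gene: int = 3
    noise_sd: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.module_size_range
        if self.corr_block_size > hi:
            raise ValueError("corr_block_size exceeds the largest module size")
        if self.n_corr_blocks > self.n_modules:
            raise ValueError("more correlation blocks than modules")
        needed = self.n_de_genes + self.n_corr_blocks * self.corr_block_size + self.n_seeds
        if needed > self.n_genes:
            raise ValueError("planted gene sets exceed the gene universe")
        if min(self.n_normal, self.n_tumor) < 4:
            raise ValueError("need at least 4 samples per condition")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{i:0{width}d}" for i in range(1, n + 1)]


def _go_tree(depth: int, branching: int) -> tuple[list[str], dict[str, str]]:
    """Balanced term tree; returns (terms in BFS order, child -> parent)."""
    terms = ["GO:1"]
    parent: dict[str, str] = {}
    frontier = ["GO:1"]
    for _d in range(depth):
        nxt = []
        for t in frontier:
            for b in range(branching):
                child = f"{t}.{b + 1}"
                parent[child] = t
                terms.append(child)
                nxt.append(child)
        frontier = nxt
    return terms, parent


def _correlated_block(rng: np.random.Generator, n_genes: int, n_samples: int,
                      rho: float, sd: float) -> np.ndarray:
    """Latent-factor block: gene = sqrt(rho)*factor + sqrt(1-rho)*noise,
    scaled to sd; expected pairwise correlation is rho."""
    factor = rng.normal(size=n_samples)
    noise = rng.normal(size=(n_genes, n_samples))
    return sd * (np.sqrt(rho) * factor[None, :] + np.sqrt(max(0.0, 1.0 - rho)) * noise)


def generate(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write every input file plus a ground-truth manifest; returns the
    manifest (also stored as ``manifest.json``)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.rng_seed)

    genes = _gene_names(spec.n_genes)
    samples = [f"N{i:03d}" for i in range(1, spec.n_normal + 1)] + \
              [f"T{i:03d}" for i in range(1, spec.n_tumor + 1)]
    conditions = ["normal"] * spec.n_normal + ["tumor"] * spec.n_tumor
    normal_slice = slice(0, spec.n_normal)
    tumor_slice = slice(spec.n_normal, spec.n_normal + spec.n_tumor)

    # --- planted gene sets (disjoint: DE, correlation blocks, seeds) ------
    perm = rng.permutation(spec.n_genes)
    cursor = 0
    de_genes = [genes[i] for i in perm[cursor:cursor + spec.n_de_genes]]
    cursor += spec.n_de_genes
    blocks: list[list[str]] = []
    for _b in range(spec.n_corr_blocks):
        blocks.append([genes[i] for i in perm[cursor:cursor + spec.corr_block_size]])
        cursor += spec.corr_block_size
    seeds = [genes[i] for i in perm[cursor:cursor + spec.n_seeds]]
    cursor += spec.n_seeds
    background = [genes[i] for i in perm[cursor:]]

    # --- expression matrix (log2 scale, then exponentiated) ---------------
    baseline = rng.uniform(3.0, 8.0, size=spec.n_genes)
    log2v = baseline[:, None] + rng.normal(scale=spec.noise_sd,
                                           size=(spec.n_genes, len(samples)))
    pos = {g: i for i, g in enumerate(genes)}
    for block in blocks:
        idx = [pos[g] for g in block]
        log2v[idx, normal_slice] = baseline[idx][:, None] + _correlated_block(
            rng, len(idx), spec.n_normal, spec.r_normal, spec.noise_sd)
        log2v[idx, tumor_slice] = baseline[idx][:, None] + _correlated_block(
            rng, len(idx), spec.n_tumor, spec.r_tumor, spec.noise_sd)
    de_idx = [pos[g] for g in de_genes]
    log2v[de_idx, tumor_slice] += spec.de_log2_fold
    values = np.power(2.0, log2v)

    # --- modules -----------------------------------------------------------
    lo, hi = spec.module_size_range
    sizes = rng.integers(lo, hi + 1, size=spec.n_modules)
    n_signal = spec.n_corr_blocks
    modules: dict[str, list[str]] = {}
    signal_modules: list[str] = []
    related_genes: list[str] = []
    de_pool = list(de_genes)
    bg_pool = list(background)
    seeds_cycle = itertools.cycle(seeds)
    for j in range(spec.n_modules):
        name = f"module_{j + 1:02d}"
        size = int(sizes[j])
        if j < n_signal:
            block = blocks[j]
            module_seeds = [next(seeds_cycle) for _ in range(2)]
            n_de = min(len(de_pool), max(4, (size - len(block) - len(module_seeds)) // 2))
            module_de = de_pool[:n_de]
            de_pool = de_pool[n_de:]
            members = list(dict.fromkeys(block + module_seeds + module_de))
            n_fill = max(0, size - len(members))
            members += bg_pool[:n_fill]
            bg_pool = bg_pool[n_fill:]
            modules[name] = members
            signal_modules.append(name)
            # Seed-adjacent "disease" genes: planted signal genes that will
            # also share a GO subtree with this module's seeds.
            related_genes.extend(block[:2] + module_de[:2])
        else:
            members = bg_pool[:size]
            bg_pool = bg_pool[size:]
            if len(members) < 2:
                members = list(rng.choice(background, size=size, replace=False))
            modules[name] = members
    related_genes = list(dict.fromkeys(related_genes))

    # --- GO tree + annotations --------------------------------------------
    terms, parent = _go_tree(spec.go_depth, spec.go_branching)
    leaves = [t for t in terms if t not in set(parent.values())]
    # One leaf-parent subtree per seed; the seed and its related genes draw
    # their terms from that subtree's leaves.
    subtree_parents = sorted({parent[leaf] for leaf in leaves})
    annotations: list[tuple[str, str]] = []

    def subtree_leaves(par: str) -> list[str]:
        return [l for l in leaves if parent[l] == par]

    seed_subtree: dict[str, str] = {}
    for k, s in enumerate(seeds):
        par = subtree_parents[k % len(subtree_parents)]
        seed_subtree[s] = par
        pool = subtree_leaves(par)
        for t in pool[:spec.terms_per_gene]:
            annotations.append((s, t))

    # Map related genes to the subtree of a seed sharing their module.
    gene_module_seeds: dict[str, list[str]] = {}
    for name in signal_modules:
        mseeds = [g for g in modules[name] if g in set(seeds)]
        for g in modules[name]:
            gene_module_seeds.setdefault(g, []).extend(mseeds)
    for g in related_genes:
        anchors = gene_module_seeds.get(g, []) or seeds[:1]
        pool = subtree_leaves(seed_subtree[anchors[0]])
        for t in pool[:spec.terms_per_gene]:
            annotations.append((g, t))
    annotated = set(seeds) | set(related_genes)
    for g in genes:
        if g in annotated:
            continue
        chosen = rng.choice(len(leaves), size=min(spec.terms_per_gene, len(leaves)),
                            replace=False)
        for c in chosen:
            annotations.append((g, leaves[c]))

    # --- write files --------------------------------------------------------
    expr_df = pd.DataFrame(values, index=genes, columns=samples)
    expr_df.index.name = "gene"
    expr_df.to_csv(out_dir / FILES["expression"], sep="\t", float_format="%.6f")
    with open(out_dir / FILES["conditions"], "w") as fh:
        fh.write("sample\tcondition\n")
        for s, c in zip(samples, conditions):
            fh.write(f"{s}\t{c}\n")
    with open(out_dir / FILES["modules"], "w") as fh:
        for name, members in modules.items():
            fh.write("\t".join([name, "synthetic", *members]) + "\n")
    with open(out_dir / FILES["obo"], "w") as fh:
        fh.write("format-version: 1.2\nontology: toy\n")
        for t in terms:
            fh.write(f"\n[Term]\nid: {t}\nname: synthetic term {t}\n")
            if t in parent:
                fh.write(f"is_a: {parent[t]} ! parent\n")
    with open(out_dir / FILES["annotations"], "w") as fh:
        for g, t in sorted(annotations):
            fh.write(f"{g}\t{t}\n")
    with open(out_dir / FILES["seeds"], "w") as fh:
        for s in seeds:
            fh.write(s + "\n")

    block_pairs = [
        [sorted(p) for p in itertools.combinations(block, 2)] for block in blocks
    ]
    manifest = {
        "spec": {**asdict(spec), "module_size_range": list(spec.module_size_range)},
        "files": {k: v for k, v in FILES.items() if k != "manifest"},
        "de_genes": sorted(de_genes),
        "corr_blocks": blocks,
        "corr_block_pairs": block_pairs,
        "seeds": seeds,
        "related_genes": sorted(related_genes),
        "signal_modules": signal_modules,
        "noise_modules": [n for n in modules if n not in set(signal_modules)],
    }
    with open(out_dir / FILES["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def null_spec(n_genes: int = 1000, n_normal: int = 50, n_tumor: int = 50,
              rng_seed: int = 0, **kw) -> FixtureSpec:
    """A no-signal configuration: no DE genes and identical cross-condition
    correlation, for null-calibration suites."""
    return FixtureSpec(
        n_genes=n_genes, n_normal=n_normal, n_tumor=n_tumor,
        n_de_genes=0, n_corr_blocks=0, r_normal=0.0, r_tumor=0.0,
        rng_seed=rng_seed, **kw,
    )


def empirical_correlation_check(expr_values: pd.DataFrame, manifest: dict) -> pd.DataFrame:
    """Achieved mean within-block pairwise correlations per condition,
    reported against the planted (r_normal, r_tumor)."""
    spec = manifest["spec"]
    n_normal = spec["n_normal"]
    logv = np.log2(expr_values + 1.0)
    rows = []
    for b, block in enumerate(manifest["corr_blocks"]):
        sub = logv.loc[block]
        for cond, sl in (("normal", slice(0, n_normal)),
                         ("tumor", slice(n_normal, None))):
            c = np.corrcoef(sub.iloc[:, sl])
            iu = np.triu_indices(len(block), k=1)
            planted = spec["r_normal"] if cond == "normal" else spec["r_tumor"]
            rows.append({
                "block": b, "condition": cond,
                "mean_r": float(c[iu].mean()),
                "planted_r": planted,
                "n_samples": sub.iloc[:, sl].shape[1],
            })
    return pd.DataFrame(rows)
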