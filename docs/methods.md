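# Methods

This note documents the statistical model behind `mgogp`, the parameter
defaults and their rationale, the numerical choices, what the synthetic
generator does and does not emulate, and the design decisions taken where
the construction was genuinely open.

## Model and assumptions

The pipeline assumes a two-condition design (labels `normal` / `tumor`)
with at least four samples per condition — Fisher's z-test requires
L−3 > 0 and Q−3 > 0, and subsampling must preserve that margin. Gene
identifiers are matched as exact strings across all inputs; no alias
resolution is attempted. Modules are arbitrary, possibly overlapping gene
sets; they are intersected with the expression gene universe at load time
and dropped below two genes (pair correlations need a pair).

### Consensus differential expression

Per subsampling round, a fraction (default 0.8) of each condition's
samples is drawn without replacement — stratified, so class balance is
preserved — and every gene is tested with a two-sided Welch t-test on
log2(x+1), BH-adjusted across genes. A gene votes Se = 1 when padj ≤ μ.
After S rounds, DEG = 1 iff the mean vote ≥ ω. The Welch-on-log test is a
deliberately simple, self-contained per-round test; a per-gene padj table
computed externally (e.g. by a negative-binomial DE tool) can be supplied
and is then used as the full-data padj entering the gene score, while the
voting loop still reruns the built-in test per subsample. Genes with zero
variance in both groups carry no evidence and get p = 1.

### Consensus differential correlation

Within each module, all K = N(N−1)/2 pairs get condition-specific Pearson
correlations on the same stratified subsamples (an independent seed
stream), compared via the Fisher transform and the z statistic above. The
per-round significance quantity is a local false discovery rate:

* empirical null f0 = Normal(0, σ̂), σ̂ matched to the interquartile range
  of the central 50% of the z values (IQR / (2·Φ⁻¹(0.75)));
* π0 = min(1, 0.5 / (Φ(q75/σ̂) − Φ(q25/σ̂))), the null fraction consistent
  with the central mass;
* marginal density f by Gaussian KDE evaluated on a 2048-point grid;
* fdr(z) = min(1, π0·f0(z)/f(z)).

A density estimate needs data: below 200 z values the method falls back to
BH q-values on two-sided normal p-values (also selectable outright with
`fdr_method="bh"`). Modules with ≥ 200 pairs get their own fit; smaller
modules are pooled into one joint z vector per round, because a local fdr
fitted inside a 45-pair module is meaningless. Sc = 1 iff fdr ≤ υ, and
DEE = 1 iff the Sc vote over S rounds ≥ δ. Zero-variance pairs get Z = 0,
fdr = 1, Sc = 0 for the affected round.

### GO fuzzy-measure similarity

Term probability p(T) is the fraction of annotation records (gene, term)
whose term is T or any descendant of T, over all records in the loaded
annotation corpus; descendant counting uses the transitive closure of
`is_a` edges, so each record is counted once however many paths connect
it, and p is monotone up the DAG. Counting the full closure rather than
one-step children is the conventional information-content reading and the
default; `children_depth=1` reproduces literal one-step counting. Only
`is_a` relations build the DAG; `part_of` is ignored as the conservative
choice. All three GO aspects are pooled.

A gene's fuzzy density per term is Sm_k = (−ln p(T_k)) / max_j(−ln p(T_j));
densities lie in [0, 1] with the most specific term at exactly 1, and terms
with p = 1 carry density 0. The Sugeno λ-measure over the gene's terms
solves (1+λ) = Π(1+λ·Sm_k); subsets evaluate via the λ-rule
(Π(1+λ·Sm_k) − 1)/λ, or the additive sum capped at 1 when λ = 0. Similarity
between two genes is the average of their two measures on the shared term
intersection: symmetric, 1 for identical annotation, 0 for disjoint.

One consequence of the max-normalization deserves emphasis: because every
usable density set contains a density of exactly 1, (1+λ) is a common
factor of both sides of the defining equation and λ = 0 is the only
admissible solution, so the in-pipeline measure is effectively
min(1, Σ Sm_k) over the shared terms. The general solver handles arbitrary
density sets (λ bracketed in (−1, 0) when Σ Sm > 1, in (0, ∞) when
Σ Sm < 1) and is exercised on its own; the degenerate unit-density case is
detected analytically rather than searched for.

λ-root finding is bisection on the analytically determined bracket, at
most 200 iterations, relative tolerance 1e−12 on λ. Sign tests use the
log-form residual Σ log1p(λ·Sm_k) − log1p(λ), which has the same roots on
λ > −1 but keeps full precision near λ = 0 where the product form loses
all significant digits; the achieved product-form residual is below 1e−10
across random density sets (measured by the acceptance script). Densities
and λ are memoized per term set — they are pure functions of it.

### Scores and fusion

Module and gene scores follow the formulas in the README. Two readings in
the construction are ambiguous and both are shipped:

* **CorC's indicator.** The pair-level flag could be the consensus DEE or
  a single-round Sc. The default is the consensus `dee` — internally
  consistent with Ecr and robust to sampling noise; `corc_indicator="sc"`
  uses the single-round Sc evaluated on the full sample set (the only
  deterministic single round available).
* **The DE addend of the gene score.** Summing padj literally rewards
  non-significant genes; the default `padj_mode="complement"` uses
  1 − padj so that stronger DE evidence increases importance, and
  `padj_mode="raw"` preserves the literal sum.

Module info = (num seeds + 1)/N can exceed 1 for tiny seed-dense modules;
the formula is kept literal and such modules are flagged in the log.

Local rankings order genes by p(g) descending with deterministic
tie-breaks (higher info, higher CorC, lexicographic id). Fusion follows
the expectation recursion e(i,j) = (i+1)·p(m_j) − m(i,j) with ties broken
by larger probability, larger unnormalized importance, then module input
order. Zero-importance modules become eligible only after all
positive-probability modules are exhausted, in input order. Overlap is
resolved first-claim-wins: a later module skips an already-ranked gene,
advancing both its local pointer and its m(i,j) count so the bookkeeping
stays consistent. Genes in the expression matrix but in no module are
appended after all module genes, ordered by DE evidence — a genome-wide
prioritization should not silently drop genes.

## Parameters

| parameter | default | meaning |
|---|---|---|
| S | 1000 | subsampling rounds (both consensus loops) |
| ω | 0.9 | DEG vote-fraction threshold |
| δ | 0.9 | DEE vote-fraction threshold |
| μ | 0.01 | per-round padj threshold |
| υ | 0.05 | local-fdr threshold |
| subsample fraction | 0.8 | per-condition fraction drawn per round |
| seed | 17 | master seed; per-stage streams are spawned from it |

The thresholds are the conventional operating point for this method; the
subsample fraction of 0.8 preserves class balance while giving rounds
enough independence to make the vote meaningful. One master seed
deterministically spawns independent DE and correlation seed streams, so
each stage is reproducible in isolation and two identically configured
runs are bit-identical.

## The synthetic generator

`mgogp.fixtures` emulates all inputs with planted ground truth: log-normal
expression with a mean log2 shift of 2 (fold change 4) for 50 of 500 DE
genes; five 8-gene correlation blocks built from a shared latent factor
per condition (gene = √ρ·factor + √(1−ρ)·noise, giving expected pairwise
correlation ρ — 0.9 in normal, 0.0 in tumor); 20 modules of 10–30 genes of
which five are signal modules carrying a block, DE genes and two seeds
each; a balanced depth-3 branching-3 GO tree in which each seed and its
designated related genes are annotated to the same leaf subtree while
background genes draw random leaves; 50 + 50 samples. These defaults are
the study conditions of the test suite; the planted effects are chosen
well above the respective detection boundaries, so recovery failures
indicate implementation errors, not statistical bad luck.

What the generator does **not** emulate: library-size and batch effects,
count overdispersion (values are continuous log-normal by default),
realistic GO annotation depth and redundancy, module size distributions of
curated collections, and correlated DE/co-expression structure between
modules. Passing tests therefore demonstrate correctness of the machinery
and sane statistical calibration — not performance on real tumor cohorts,
where normalization quality, annotation bias and seed-list curation
dominate.

## Problem sizes and runtime choices

The automated checks run the consensus loops at S = 100 (DE) and S = 50
(correlation, with 100 + 100 samples so the planted blocks are far above
the detection boundary), and the end-to-end run at S = 100 on the default
fixture. These sizes make the full suite complete in about a minute while
keeping every vote threshold meaningfully exercised; S = 1000 remains the
default for real runs.

## Known limitations

* The per-round DE test is Welch-on-log, not a count model; for raw RNA-seq
  counts an external padj table from a negative-binomial tool is the better
  full-data input.
* The local-fdr estimator is a deliberately simple empirical-null fit
  (central matching + KDE); it assumes the null dominates the central 50%
  of z values and will over-call π0 when more than half the pairs are
  truly differential.
* With max-normalized densities, the Sugeno machinery reduces to a capped
  additive measure (see above); the similarity is then driven by the
  information content of shared terms, which is sensible but less rich
  than the general λ-measure would allow.
* The fusion recursion assumes module importances are meaningful relative
  probabilities; modules with zero DEG and zero DEE are only ranked by
  seed density.
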