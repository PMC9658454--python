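# Methods

## Experimental model

The package targets a three-condition perturbation design on a hub
transcription factor (TF): a wild-type **reference**, a **hypomorph** allele
expressing the hub at a reduced dosage, and a **null** allele with no
functional hub. The canonical replicate structure is 3 / 4 / 2 biological
replicates for the three conditions; all statistics are computed on a
gene-by-sample count matrix, so alignment and quantification are upstream
of the package.

Two contrasts are analyzed, reference-vs-hypomorph and reference-vs-null.
The driving biological expectation — encoded in the generator and tested as
a property of the model, not asserted about any organism — is that a deeper
dosage loss perturbs more genes and yields a larger regulatory network.

## Synthetic data generator

`generate_truth` plants a circuit with these defaults:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | transcriptome size (scaled down from a full genome) |
| `n_tfs` | 50 | TFs, including the hub |
| `n_direct_targets` | 61 | hub's ChIP-like direct targets (a 1:10 scale-down of a ~610-gene binding repertoire) |
| `repression_fraction` | 0.7 | fraction of hub edges with sign −1; the hub is predominantly a repressor |
| `effect_log2` | 2.0 | per-edge effect β, log2 units (constant, not drawn) |
| dosage | 1.0 / 0.3 / 0.0 | hub activity in reference / hypomorph / null |
| `dispersion` | 0.05 | NB dispersion α (variance μ + αμ²) |
| `baseline_log_mean`, `baseline_log_sd` | 4.0, 1.0 | log-normal per-gene baseline means (median ≈ 55 counts) |
| `lib_size_range` | (0.8, 1.2) | uniform per-sample library factors, exercising normalization |

Mean model, for a condition with hub dosage *d*:

* hub mean: μ_hub · d (so null-condition hub counts are exactly zero);
* hub-target mean: μ · 2^(−s·β·(1−d)) — losing a repressor (s = −1)
  *raises* the target, four-fold at β = 2 and d = 0;
* cascade targets: a TF→target edge propagates only if the TF is itself a
  hub direct target; the target then shifts by −s_h·s·β·(1−d) log2 units
  (s_h the hub→TF sign). Cascade depth is one level; deeper chains are
  emergent, never generated. Non-hub TFs are drawn preferentially from the
  hub's targets so cascades respond to the perturbation by default.

Effects are constant per edge rather than drawn from a distribution: the
generator defines a regime in which recovery is expected, and a single β
makes sensitivity statements interpretable. The generator does **not**
emulate isoforms, batch effects, read-level noise, GC/length biases, or
correlated baseline expression between genes; passing recovery tests
therefore demonstrates the pipeline's correctness under its stated model,
not its performance on real libraries.

Determinism: baseline means are a function of the truth seed; sampling
noise and library factors are a function of the simulation seed. Identical
seeds give bitwise-identical outputs.

The fixture writer emits the count matrix, design sheet, a motif-evidence
catalog (the cascade edges), the ChIP-evidence direct-target list, five GMT
pathway sets named for the developmental events the analysis tracks
(chloroplast development, oxidation reduction, cell cycle, meiosis, tapetum
differentiation; members carved deterministically from the perturbed
genes), and the truth as JSON.

## Differential expression

**Normalization** is median-of-ratios: each sample's size factor is the
median, over genes with nonzero counts in every sample, of the gene's count
divided by its across-sample geometric mean. Normalization fails loudly if
no gene is expressed everywhere.

**Testing** runs on log2(normalized + 1) (pseudocount configurable). The
default engine is a trended empirical-Bayes moderated t-test:

1. pooled per-gene residual variance s²_g with df = n₁ + n₂ − 2;
2. a lowess trend of log s² against mean log2 expression, debiased by
   ψ(df/2) − log(df/2) (the expectation of log of a scaled chi-square, so
   the trend estimates σ² itself rather than E[log s²]);
3. prior df d₀ estimated by moments on the log ratio s²/trend (the
   standard scaled-inverse-chi-square moment match); gene variances are
   squeezed to (d₀·s₀² + df·s²)/(d₀ + df) and the t statistic referred to
   t with d₀ + df degrees of freedom (normal when d₀ = ∞).

With 2–4 replicates per group, borrowing variance strength across genes is
what makes FDR-controlled calls possible at all: a plain per-gene test has
heavy t tails (df ≈ 2–5) that cannot reach Benjamini–Hochberg thresholds at
m = 2000, and measures essentially zero recall on planted four-fold
effects. A per-gene Welch t-test is retained behind the same interface
(`engine="welch"`) for large-replicate designs, and the test suite
cross-checks the moderated engine against an independent negative-binomial
Wald analysis (DESeq2 via pydeseq2) on a simulated instance. On null
simulations the moderated engine's raw p < 0.05 fraction sits at 0.035–0.06
for both contrasts.

Fold change is log2((mean_B + 1)/(mean_A + 1)) on normalized linear means.
Genes with zero counts in both groups are dropped before testing; a gene
with identical values everywhere gets p = 1. BH adjustment implements the
step-up closed form min_{j≥i}(m·p_(j)/j) directly in numpy so it agrees
with the formula to the last ulp. DE calls use strict inequalities:
padj < 0.05 **and** linear |FC| > 2. "Fold change > 2" is read on the
linear scale (equivalently |log2FC| > 1); the log2 reading would coincide
only at threshold 1, and the linear reading is the conventional one.

## Network construction

Candidate edges: catalog (motif) edges require both endpoints DE *in the
contrast under analysis* (each contrast is gated on its own DE flags, which
is what makes the two contrast networks differ); hub→target (chip) edges
require only the target DE. On duplicate pairs the chip evidence class
wins. The correlation filter computes Spearman's ρ between the two genes'
log2 normalized profiles across **all** nine samples — pooling conditions is
deliberate, since the dosage gradient across conditions is the signal — and
retains an edge iff ρ ≥ 0.25 or ρ ≤ −0.25. The boundary is inclusive by
default and exposed as `correlation_inclusive` because strict-vs-inclusive
at exactly 0.25 is a genuine convention choice. Rank correlation is
invariant to monotone transforms, so the log2 transform standardizes the
code path rather than changing results. Edges with an undefined ρ (a
constant profile) are dropped with a warning, not errored.

The node set is the retained-edge endpoints, plus every DE direct target
(even when its edge fell to the correlation filter — the target's response
is still evidence), plus the hub itself. Nodes carry `de_flag`,
`is_direct_target` and `degree`; output ordering is lexicographic
throughout, making every export deterministic.

## Pathway sub-networks and comparison

A sub-TRN's seeds are the pathway members that are DE in *at least one*
contrast and present in the parent TRN; nodes are seeds plus their direct
predecessors/successors. By default only edges incident to a seed are kept
— the neighborhood is defined by adjacency to pathway genes, not as a full
induced subgraph — with `include_neighbor_edges=True` available since the
alternative reading is also defensible. The sub-network hub is the
maximum-degree node (in+out), ties broken lexicographically for
determinism; "hubness" has no other formal definition here.

The contrast comparison is pure set algebra: per-direction shared counts,
contrast-specific fractions |AΔB|/|A∪B| (0 when both sets are empty), and
node/edge Jaccard indices (1 when both networks are empty, as identical).
Enrichment is the hypergeometric upper tail (one-sided Fisher) per set, BH
across sets, sorted by p and truncated to the top 10 by default. The
heatmap matrix averages expression within each condition and z-scores each
row with the sample standard deviation; zero-variance rows map to zeros.

## Numerical and degenerate-input conventions

* Spearman ρ needs ≥ 3 observations; constant vectors give NaN (edge
  dropped, not errored).
* BH validates p ∈ [0, 1] and is permutation-equivariant; ties need no
  special handling.
* Welch engine: zero variance in both groups gives p = 1 at equal means,
  p = 0 otherwise.
* The moderated engine falls back to an untrended prior below 10 genes
  (lowess is meaningless there).
* Enrichment clips query genes and set members to the universe with a
  warning; an empty universe is an error.
* All identifiers are opaque case-sensitive strings; readers report parse
  errors with file and line number, deduplicate catalog edges, and drop
  self-edges with a warning.

## Problem sizes in the test suite

Recovery and severity properties run at the generator's default scale
(2000 genes, 10 seeds); oracle-equivalence checks run on 100 random
instances of ≤ 50 genes; calibration uses one 2000-gene null simulation.
These sizes give stable averages while keeping the whole suite fast.

## Known limitations

* The moderated t on log2 counts is a simplification of a count-model GLM;
  it is calibrated and powerful in the simulated regime but is not a DESeq2
  re-implementation, and very low counts (< ~5) are handled only through
  the pseudocount.
* Edge direction comes entirely from the catalog and target list; the
  correlation filter cannot orient edges.
* The severity ordering (null ≥ hypomorph) is a property of the generative
  model at its default dosages, verified over seeds — not a biological law.
* Planted-recovery precision is measured against the hub's edge list; with
  the fixture bundle's direct-target file derived from the truth, hub-edge
  false positives can only arise from DE false calls, so recall and sign
  agreement are the more informative scores.
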