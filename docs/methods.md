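# Methods

## Overview

phytonet re-implements, as composable library functions, the inference
chain from seed phytic-acid (IP6) phenotype screening to candidate-gene
nomination: germplasm contrast screening, expression normalization and
differential-expression (DE) calling, metabolite-weighted co-expression
network analysis, lossless power-graph compression, rule-based candidate
screening, and plant miRNA target scoring. Because the study's expression
and metabolite matrices are not available in tabular form, validation is
by parameter recovery on synthetic data whose generators plant known
structure and emit it as truth, plus one worked input — the nine
published module–metabolite correlation records (`phytonet.reference`).

## Synthetic-data model

**Expression.** Each planted module m has a latent per-sample factor f_m;
a member gene's latent profile is
`x = loading * f_m + sqrt(1 - loading^2) * eps`, eps i.i.d. standard
normal, so `loading` is exactly the gene–factor correlation and
`loading^2` the within-module gene–gene correlation. Two generator
choices matter:

- drawn factors are standardized to zero mean and unit sample variance,
  so `loading` sets the correlation scale rather than being confounded by
  the variance of one finite draw;
- factors of different modules are mutually orthogonalized (QR). Planted
  modules are distinct latent programs, and the emitted truth must remain
  recoverable in principle: two independently drawn factors can correlate
  ~0.5 at n = 24 by chance, which would merge their modules in any
  correct clustering and falsify the planted labels rather than the
  method.

Latent values are mapped affinely into positive "arbitrary expression
units" (`10 + 2x`, floored at 1e-3); an affine map changes neither
Pearson nor Spearman structure. The default design is 2 genotypes x 3
developmental stages x a configurable replicate count (the replication of
the emulated experiment is not knowable from published information, so
`replicates` is an explicit, defaulted parameter); the default recovery
benchmark uses 5 modules x 50 genes, loading 0.85, 350 background
(pure-noise) genes and 24 samples.

**Metabolites.** A metabolite targeting (module m, r0) is
`r0 * f_m + sqrt(1 - r0^2) * eps` — generated against the *factor*, not
the estimated eigengene, so recovery error honestly includes eigengene
estimation error. Negative r0 plants anticorrelated metabolites; r0 = 0
an independent control.

**Counts.** Negative-binomial with gene-wise means log-uniform on
[10, 1000] (spanning the realistic dynamic range without zero-inflation
machinery) and variance mu + alpha mu^2; planted DE genes multiply the
second group's mean by the fold change; alpha = 0 degenerates to Poisson.

**Germplasm.** Background lines sit in a narrow band around 3 mg/g (the
published low/high range is 2.4–4.0 mg/g); each planted pair has a
per-environment log2 content difference of log2(ratio) plus Gaussian
noise. Note that with several planted pairs, *cross* pairs (the high line
of one pair against the low line of another) are genuinely large, stable
contrasts and are legitimately retained by the screen; recovery is
therefore scored on planted-pair retention and decoy-pair rejection, not
exact set equality.

**miRNA duplexes.** The target site is the reverse complement of a random
21-mer carrying exactly the planned edits (core mismatches at positions
2–13, tail mismatches, tail G:U wobbles), so the truth score is
`2*core + tail + 0.5*gu` by construction.

**Candidate benchmark.** A hand-built ~70-node network: one guide, one
true candidate satisfying all three mandatory principles plus both bonus
criteria, and ten decoys — four lacking the shared hub, three lacking
power-node co-membership with a guide-correlated gene, three at guide
distance 5. A decoy violating *only* the distance rule cannot exist on a
graph metric (a hub adjacent to both gene and guide forces distance <= 2),
so the distance decoys necessarily also lack the shared hub. The seed
permutes gene identifiers (exercising rank tie-breaking); the topology is
fixed.

What the generators do **not** emulate: mean–variance trends across
genes in expression data, batch effects, correlated noise between
background genes, zero-inflation, genotype-by-environment interaction
beyond pair noise, and gapped miRNA alignment. Passing recovery tests
demonstrates correctness of the algorithms under the stated model, not
robustness to those real-data features.

## Stage-by-stage choices

**Germplasm screen.** Q = |log2(x_i/x_j)|, threshold 0.58 (= log2 1.5).
Stability is read as "mean per-environment Q significantly above the
threshold": a one-sided one-sample t-test (p < alpha, default 0.05)
combined with an all-environments Q > threshold gate. Other readings of
the stability test (contrasts across environments, or between raw
contents) are possible; this one is well-defined, and retains exactly the
intended pairs (~2-fold in every environment). Pairs with fewer than two
shared environments are skipped with a warning; degenerate zero-variance
Q vectors get p = 0 or 1 by the sign of the mean contrast. No outlier
removal is applied.

**DE calling.** Heavyweight DE machinery is deliberately not
re-implemented; the decision rule of interest is the FC >= 2 & FDR < 0.01
gate. P-values come from a two-sided exact negative-binomial test on the
two group count sums, conditional on their total: group-sum null means
and variances follow from a shared per-gene mean (library-size-normalized
by total counts, consistent with RPKM) and a gene-wise method-of-moments
dispersion estimated per group against its own group mean (unbiased under
the alternative, unlike normalizing by the pooled mean) and averaged,
floored at 1e-8. Fold changes add a symmetric pseudo-count of 0.5 to both
normalized group means. Under the global null the caller flags ~1% of
genes at FDR < 0.01; with 4-fold changes, dispersion 0.05 and n = 3 per
group it recovers >= 90% of planted genes.

**Network.** Unsigned adjacency |rho|^beta (signed mode available);
Spearman by default, computed blockwise (row blocks of <= 3500 genes,
bit-identical to the whole-matrix result). `select_soft_threshold`
follows the scale-free convention — smallest beta whose log-log
frequency/connectivity regression over 10 bins reaches R^2 0.8, else 6
with a warning — but planted factor networks are *not* scale-free, so the
recovery benchmarks fix beta = 6, the package's standard unsigned power
(also the fallback). Module detection is a static height cut (default
0.99) of the average-linkage tree on 1 − TOM with a minimum module size
of 30 — a deterministic simplification of dynamic tree cutting, adequate
for well-separated modules; noisy background genes that genuinely
correlate with a module at finite n are absorbed into it, which inflates
module size but does not disturb planted-gene recovery. Colors are
assigned from a fixed vocabulary in decreasing size order (ties by lowest
gene index); "grey" is unassigned. Eigengenes are the leading right
singular vector of the gene-standardized module submatrix, unit variance,
sign-oriented to correlate non-negatively with the module mean profile.
Module–trait p-values use the t approximation with df = n − 2 for both
correlation types; selection is strict: |r| > 0.8 AND p < 0.01.

**Per-module export.** Selected module sub-networks are exported at the
output threshold 0.5 applied to the TOM of the module's *unpowered*
correlation strengths (|rho|): the soft-threshold power exists to expose
global modular structure, and applying it again inside an established
module would penalize the same correlations twice and empty the export.

**Power graph.** Exact minimum power-graph construction is NP-hard; a
deterministic greedy edge-coverage heuristic is used. Candidate gene sets
are all branches of the average-linkage dendrogram under
Jaccard-of-neighborhoods distance (open and closed neighborhoods, so both
biclique sides and clique members look alike); the candidate power edge
abstracting the most uncovered edges is committed repeatedly (ties by
lexicographically smallest gene-set pair) subject to laminarity of the
committed sets, until no candidate abstracts >= 2 edges; the rest are
residual edges. Losslessness (decompress = original edge set) is
guaranteed by construction and verified on random and structured suites.
The compression ratio is defined as
`1 − (#power edges + #residual edges) / #original edges`; an optional
minimum-degree pre-filter drops low-connectivity nodes first.

**Candidate screen.** "Sharing a key node" is operationalized as common
adjacency to a top-k hub (degree or Maximal Clique Centrality, default
degree, k = 10; in the pipeline hubs are pooled per module sub-network so
small modules are not shadowed by large ones). "Guide-correlated" means
connected to a guide by an edge heavier than the export threshold.
Distance is hop distance on the thresholded export network. Domain and DE
criteria are ranking bonuses, not gates; the full rank key is (bonus
count desc, guide distance asc, max guide correlation desc, gene id), a
total order, so output is deterministic.

**miRNA scoring.** Additive plant-style penalties: mismatch 1, G:U 0.5,
indels out of scope (ungapped windows only), penalties doubled at miRNA
positions 2–13; predicted iff score < 4 (strict). The threshold is the
anchored value; the penalty scheme is the convention of the plant
target-prediction tool family. T and U are equivalent; site coordinates
are 0-based half-open.

## Numerical notes

Correlations are clipped to [−1, 1] after the blockwise product; TOM
forces a zero diagonal during computation and a unit diagonal after;
zero-variance genes are excluded from correlation with a warning;
single-gene modules return their standardized profile as eigengene with a
warning. BH adjustment delegates to statsmodels. Exact-test tie handling
includes splits within a 1e-7 relative tolerance of the observed
probability. All generators are pure functions of their arguments
including the seed (PCG64).

## Benchmark problem sizes

Recovery benchmarks run at: 600-gene networks x 24 samples (5 seeds),
650-gene networks x 20 samples (10 seeds), 2000-gene count tables (10
null + 1 alternative seed), 100 random 30-node graphs plus structured
graphs, 20-line panels (20 seeds), ~70-node candidate benchmarks (10
seeds) — sizes chosen so the whole validation suite completes in well
under a minute while leaving the measured rates stable.

## Known limitations

No dynamic tree cut hybrid, no module merging by eigengene similarity,
no dispersion shrinkage or multi-factor DE designs, no gapped duplex
alignment, no non-laminar power nodes, and no attempt to reproduce the
study's data-dependent headline numbers (DEG counts, 75–92% compression
ratios, specific Table correlations beyond the selection rule), which
depend on unpublished matrices.
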