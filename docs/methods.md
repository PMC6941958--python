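# Methods

## Overview

driverlens classifies candidate cancer driver genes as tumor suppressors
(TSG) or oncogenes (OCG) from a two-condition expression experiment and a
curated knowledge base of gene/biological-process literature directions.
The chain is:

1. **DPA** — differential phenotype analysis: call differentially
   expressed genes (DEGs) and, for methylation data, differentially
   methylated regions (DMRs).
2. **GRN** — infer each DEG's *regulon* (the genes it plausibly
   regulates) by k-nearest-neighbor mutual information on tumor-condition
   samples, filtered by a permutation null.
3. **Scoring** — FEA (process over-representation among DEGs, signed by a
   process Z-score) and URA (a gene Z-score for every regulator × process
   pair).
4. **PRA** — pattern-based role calls, dual-role detection across
   conditions, and promotion to *critical* drivers with secondary
   evidence (methylation direction, copy number, cell-line expression,
   prognosis).
5. **role_ml** — alternatively, a random forest trained on a two-source
   gold standard predicts roles from the Z-score matrix, evaluated by
   multi-class log loss and one-vs-all AUC under leave-one-out
   cross-validation with label-randomization significance.

## Differential calling

Counts are upper-quartile normalized between samples: each sample is
scaled so the 75th percentile of its positive counts equals the geometric
mean of all samples' upper quartiles. Within-sample GC-content correction
is not applied (it needs per-gene GC annotations the package does not
ship); callers may pre-normalize externally.

The DEG test is a two-sided Welch t on log2(normalized + 1) — a
deterministic, dependency-light choice in place of negative-binomial
machinery; the pseudocount bounds fold changes for zero counts, and genes
with all-zero counts are dropped (logged) because their fold change is
undefined. logFC is the mean log2 difference (condition B − A). A gene is
a DEG when |logFC| > 1 and Benjamini–Hochberg FDR < 0.01 (defaults,
exposed). BH is applied within each invocation over exactly the tested
features. DMRs use a two-sided rank-sum test on non-missing beta values
with the |Δβ| ≥ 0.2 and FDR < 0.01 rule; regions with fewer than two
usable values in a group are excluded, not fatal.

## Mutual information and regulons

`mi_knn` is the Kraskov k-nearest-neighbor estimator (first variant,
Chebyshev metric), k = 3 by default:

    MI = ψ(k) + ψ(n) − ⟨ψ(n_x + 1) + ψ(n_y + 1)⟩,

with n_x, n_y counting points strictly inside each point's distance to
its k-th joint-space neighbor. Estimates are in nats, may be slightly
negative, and are not clipped. Exact ties (integer counts) would make the
neighbor counts ill-defined, so seeded uniform jitter of amplitude
1e-10 × (data range) is added before the search; for continuous data this
perturbation is far below inter-point margins and leaves counts
unchanged. The kernel is O(n²k) per pair (numba-compiled), which beats
tree-based search at the sample sizes involved (tens to a few hundred)
and makes the permutation nulls affordable.

For each DEG (regulator), MI is computed against every other gene on
tumor-condition samples. The null pools, per regulator, `nboot = 100`
permutations of the regulator vector each scored against up to
`n_genes_perm = 1000` genes drawn without replacement — one shared null
per regulator rather than per edge, mirroring the nboot × nGenesPerm
structure at a tractable cost. The edge p-value uses the add-one rule
p = (1 + #{null ≥ MI}) / (1 + |null|), so p > 0 always; edges are kept at
raw p ≤ 0.05 (no multiplicity adjustment across edges — the filter is
intentionally per-edge). Per-regulator random streams derive from the
matrix row position, not the gene name, so results are invariant under
identifier relabeling.

## Z-scores

For target k and process j with literature direction L_kj ∈ {Increased,
Decreased, Affected}, the agreement score is y_kj = +1 when the direction
and the observed logFC sign concur, −1 when they conflict, and 0 for
Affected or a zero logFC. "Affected" carries no directional information,
so it scores 0 regardless of logFC — any ±1 assignment would be
unfounded. The gene Z-score of regulator i for process j is

    z_ij = Σ_{k ∈ S_i} y_kj / √n,

where n counts regulon targets with directional (Increased/Decreased)
support; z is missing when n = 0. Under a symmetric null (y = ±1
equiprobable) z is asymptotically standard normal, and |z| ≤ √n always.

FEA's process Z-score uses the same construction over DEGs annotated to
the process (no formula is fixed by convention, so the package reuses the
one Z-score it defines). Enrichment p is the one-sided hypergeometric
tail; the universe defaults to all genes tested by DPA — the set actually
eligible to be a DEG. Significance: |process z| ≥ 1 and FDR ≤ 0.01.

## Role patterns and evidence

With a growth-like process (cancer-promoting, e.g. proliferation) and a
death-like process (cancer-reducing, e.g. apoptosis):

* OCG: z_growth > t and z_death < −t
* TSG: z_growth < −t and z_death > t

with threshold t = 0 by default (any sign-consistent pair classifies);
t is exposed so users can tighten the pattern, and classification is not
gated on FEA significance. Genes with a missing z on either process are
unclassified. Dual-role genes are OCG in at least one condition and TSG
in another. Evidence flags accrue without ever changing a role:
TSG + hypermethylation or OCG + hypomethylation → critical_epigenetic;
OCG + amplification or TSG + deletion → critical_copy_number; cell-line
concordance (OCG high / TSG low, against the pooled 25th/75th
percentiles of the all-genes × all-lines distribution, linear
interpolation) and prognosis concordance (OCG poor / TSG good)
analogously. Evidence integration is idempotent.

## Machine-learning role prediction

The gold standard intersects two sources ("verified by at least two
sources"): OCG = A∩B oncogenes, TSG = A∩B tumor suppressors; genes on
source A's dual list are excluded from training entirely (their label is
context-dependent by definition); neutral is a user-supplied background
minus all of the above. A limitation of the literal rule: a gene on only
one source's driver list may fall into the neutral background.

The forest uses 500 trees, √p candidate features per split, seeded
(exposed as parameters). Missing z entries are imputed as 0 — absence of
evidence, not invented signal. Evaluation: leave-one-out cross-validation
with the two majority classes undersampled (without replacement) to the
minority size, repeated (default 10×) with fresh draws; log loss
(natural log, probabilities clipped at 1e-15) and the unweighted mean of
OCG-vs-rest and TSG-vs-rest rank-based AUC (ties 0.5). Randomization p:
gene identities are reassigned to feature rows n_random = 100 times, the
metric recomputed each time, and the p is the literal count fraction
(≥ for log loss, ≤ for AUC), so p = 0 is possible.

## Synthetic data

`simulate_dataset` emulates a normal/tumor RNA-seq comparison with
planted truth. Counts are Poisson draws around lognormal rates: per-gene
log2 baselines ~ Uniform(6 + |effect|, 13) plus N(0, noise_sd) per
sample. The baseline floor keeps Poisson count noise (≤ 0.18 log2 sd at
rate 2⁶) subordinate to the stated latent noise even for genes shifted
down by the effect size, as holds for expression-filtered genes in real
data; with lower baselines, count noise would silently dominate the
nominal noise level. Planted oncogenes are shifted up by `effect_logfc`
(default 2) log2 units in the tumor group, tumor suppressors down; each
regulator's targets (default 8, half with negative dependence) track
`±dependence_strength` times its latent level plus noise, in the tumor
group only, matching tumor-only network inference. The knowledge base has
one cancer-promoting and one cancer-reducing process; each target's
directions are chosen so the planted role patterns hold at infinite
sample size, and 30% of background genes carry non-directional
"Affected" entries. Defaults: 200 genes, 40+40 samples, 10 OCG, 10 TSG,
noise sd 0.3.

What the generator does **not** emulate: library-size and GC biases,
negative-binomial dispersion trends, correlated background co-expression,
methylation arrays, copy-number segments, or survival times. Passing
tests therefore demonstrate the machinery's correctness and calibration
under its stated assumptions, not performance on real tumor cohorts.

`simulate_zmatrix` draws class-conditional Gaussian Z features directly
(means ±separation on the two informative processes, 0 elsewhere) as a
harness for the classifier; per-entry support counts are set so
|z| ≤ √n holds.

## Numerical and reproducibility choices

* BH via statsmodels; Welch t, rank-sum, hypergeometric via scipy;
  forests via scikit-learn; the MI estimator, permutation null, Z-scores,
  pattern rules, and evaluation statistics are implemented here.
* One global seed derives per-stage seeds by hashing the stage name, so
  stages are individually reproducible; identical configs reproduce
  every output bit-for-bit (the manifest records parameters, stage seeds
  and output digests, and supports exact rerun).
* Degenerate inputs: constant vectors give MI 0 with a warning;
  zero-variance DEG tests give p = 1; empty DEG sets give an empty
  network with a warning rather than an error.

## Problem sizes used by the checks

The test suite and `scripts/acceptance.py` size their computations to be
decisive on one CPU in minutes: MI accuracy at n = 2000 × 10 replicates;
edge calibration on a 20-gene × 200-sample null matrix; the planted
regulon at n = 100; the full pipeline at the generator defaults
(200 × 80); the ML evaluation at 15 genes/class with 50-tree forests and
100 label randomizations (the API defaults remain 500 trees — the
statistics involved saturate well below that at these feature counts).
The shuffled-label null AUC is reported as the mean over 10 independent
shuffles, since a single shuffle's AUC carries ~0.09 Monte-Carlo sd at
45 genes while the quantity of interest is the null expectation.

## Known limitations

* The DEG test is a Welch t on transformed counts, not an exact
  count-model test; with very few replicates its p-values are
  approximate.
* The permutation p is raw per edge; regulon sizes grow with the number
  of candidate genes at fixed α.
* The rank-sum DMR p uses the normal approximation at the default scipy
  settings for group sizes above the exact-method cutoff.
* Cell-line and prognosis evidence are consumed as labels; the package
  does not compute survival statistics or copy-number calls.
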