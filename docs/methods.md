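# Methods

This note documents the statistical procedures, the synthetic-data
model behind the test-bed, the defaults and why they were chosen, and
the known limits of what the tests demonstrate.

## PTA classification

A gene × tissue atlas is binarized into expressed / not-expressed
calls, the per-gene breadth is the count of expressed tissues, and a
gene is a PTA when `1 ≤ breadth < breadth_threshold` (default 5,
strict: breadth 4 passes, 5 fails). Breadth-0 genes are excluded by
definition — a never-expressed gene is not a tissue-restricted
*antigen*; the flag is configurable only through the threshold, not the
lower bound.

Two call rules are provided. The default, **global-median** (expressed
iff value > median of all atlas entries), is scale-free and appropriate
whenever on/off expression is strongly bimodal, which is how the
synthetic atlas is built; an **absolute** cutoff is available for
atlases with a known noise floor. No published rule exists for the
upstream atlas this workflow emulates, so the choice is an
implementation default, not a data claim.

A gene is flagged `in_target_tissue` when it is called expressed in at
least one designated target tissue. The default target list is the
nine unique chronic-GVHD target organs (skin epidermis, cornea,
lacrimal gland, gut, liver, salivary gland, tongue epidermis, lung,
skeletal muscle — one duplicate in the published list is removed); the
list is user-configurable and, for synthetic atlases, the first
`n_target_tissues` simulated tissues are used instead.

## Subset enrichment

Candidates are first restricted to the **pooled top quartile**: genes
whose mean expression across all stromal samples is at or above the
75th linear-interpolation percentile of pooled means *over the
candidate universe*. The cutoff is inclusive so a fully tied input
passes intact, and it is defined relative to the candidate universe —
re-running the filter on its own output recomputes the cutoff, so the
operation is deliberately not idempotent across universes.

The enrichment call then requires, for **every** non-focal subset
separately (the conservative reading of "compared with the other
subsets"; a pooled-others mode is available):

- pseudocounted fold `(mean_focal + 1)/(mean_other + 1)` strictly
  greater than `fold_threshold` (default 3), and
- Welch two-sample test on `log2(x + 1)`, Benjamini–Hochberg adjusted
  across candidate genes within each comparison, adjusted p ≤ `alpha`
  (default 0.05).

Welch-on-log2 with BH is the standard small-replicate expression
contrast; the source workflow names only "adjusted P value", so test
and adjustment are implementation decisions. Zero-variance rows
(possible at zero simulation noise) bypass the t statistic: p is 0
when the group means differ and 1 when they do not, which keeps the
zero-noise recovery contract exact. The pseudocount of 1 on the linear
scale bounds folds at zero expression.

Fold-change gene sets (e.g. a DEAF1-dependent set defined as genes
more than 3-fold higher in wild-type than knockout stroma) use the
same strict pseudocounted fold on per-gene means.

The subset correlation matrix is the Pearson correlation between
per-subset mean `log2(x + 1)` profiles over a gene set; zero-variance
profiles yield missing entries rather than an error.

## Set statistics

`fisher_exact_2x2` is the two-sided Fisher exact test in the
minimum-likelihood convention (sum of all conditional table
probabilities not exceeding the observed one), with the
conditional-MLE odds ratio computed lazily. Tables with a zero margin
raise a degeneracy error rather than returning p = 1. The test suite
proves equivalence with a direct hypergeometric enumeration oracle on
every table with total ≤ 40.

`tissue_representation_test` draws a size-matched control set
uniformly without replacement from a disjoint pool of non-enriched
PTAs under a recorded seed — a reproducible version of the published
"random set of 356 PTAs" design — and applies the Fisher test to the
target-tissue × membership table. An optional repeated-draw mode
reports the median-p draw over k seeds for users worried about
single-draw luck.

`hypergeometric_overlap` reports observed, expected `|A||B|/|U|`,
fold over expected and the upper-tail p `P(X ≥ obs)` (enrichment is
the question asked). The module always reports the arithmetic implied
by its own inputs; for the published set sizes (6611 universe,
283 × 356, 8 shared genes) that arithmetic gives expected ≈ 15.2 and
fold ≈ 0.52, and no choice of tail reproduces the externally printed
fold/p pair for that comparison, which is therefore not a target of
this package.

## GSEA

Preranked GSEA is implemented from scratch. Ranking metrics on
`log2(x + 1)`:

- **signal-to-noise** `(μ_A − μ_B)/(σ_A + σ_B)` with each group σ
  floored at `max(0.2·|μ|, 0.2)`; requires ≥ 3 samples per group
  (the error message instructs the fallback);
- **log2-fold-change** `log2((μ_A + 1)/(μ_B + 1))` for smaller designs.

Ties are broken lexicographically by gene id so rankings are
deterministic.

The enrichment score walks the ranking: hits add
`|s|^w / Σ_hits |s|^w` (weight w = 1 by default; w = 0 reduces to the
classical Kolmogorov–Smirnov form, verified against a direct KS
computation), misses subtract `1/(N − N_hits)`; ES is the signed
maximum deviation and the leading edge collects hits at or before
(positive ES) / at or after (negative ES) the extremum. If all hit
scores are exactly zero the increments fall back to equal weights
rather than 0/0.

The null is **gene-set permutation** (ES of uniformly random same-size
sets, vectorized, seeded): the motivating contrasts have 2–3
replicates per condition, far too few for phenotype permutation.
`n_perm ≥ 100` is enforced; tiny instances can use `exhaustive_null`,
the complete C(N, k) enumeration. Then

- `NES = ES / mean(|null ES of the same sign|)`;
- `p_nominal = (1 + #{same-sign null, |null| ≥ |ES|}) / (1 + #same-sign)`
  (add-one smoothing; p is never exactly 0; an ES with no same-sign
  null values yields p = 1 plus an `UnstableEstimateWarning`);
- FDR q across a batch compares the sign-matched tail fraction of the
  pooled normalized null NES with the same tail fraction of the
  observed NES distribution, clipped to [0, 1]; q = 0 is reported only
  when no null value is as extreme.

One test cross-checks the ES against an independent reference
implementation (gseapy) on a random instance; they agree to 1e-9.

## Synthetic data model

All generators build expression on the log2 scale — gene-level
baseline plus planted offsets plus i.i.d. Gaussian noise of sd
`noise_sd_log2` — and exponentiate, i.e. log-normal multiplicative
noise on positive linear values. Gene baselines are drawn from a
normal with deviations clipped at `±min(3σ, 0.49·on_offset)`: the
clipping keeps the gene-to-gene baseline range strictly below the
atlas on/off offset, so at zero noise the "on" and "off" populations
cannot overlap and the global-median call is exact by construction.

**Atlas.** A fraction `frac_restricted` of genes receives a planted
breadth uniform in `breadth_range` (default 1–4); the rest are "on" in
more than `breadth_range.max` tissues. On entries sit `on_offset_log2`
(default 5) above the gene's baseline. Broad-gene breadths are nudged
so that on and off entries each make up half of the matrix; the sample
median of all entries then falls inside the on/off gap, which is what
makes the scale-free global-median call reliable. The generator
emulates clean bimodal on/off atlas structure — it does not model
graded expression, probe saturation or cross-tissue correlation.

**Stromal matrix.** `n_frc_enriched` genes (drawn among the restricted
genes, so the end-to-end signature is recoverable) carry a
`high_expression_offset_log2` (default 3) baseline boost in every
subset — the real signature is *defined* on highly expressed stromal
genes, and the boost makes the planted genes clear the top-quartile
filter — plus `log2(enrichment_fold)` (default fold 4) in the first
subset only.

**Condition experiment.** The planted set (default 50 genes of 2000)
is shifted down by `effect_size_log2` (default 1.0) in the second
condition; samples are labelled `GVHDneg`/`GVHDpos`.

Determinism: every generator draws from its own substream derived from
`(seed, tag)`, and the gene-role assignment is a shared substream, so
identical configs give byte-identical serialized outputs and the three
matrices plant mutually consistent roles.

### Default study conditions

The defaults are the conditions the test-bed is specified to exercise:
2000 genes, 20 tissues, 30% restricted genes, 30 subset-enriched genes
at 4-fold, noise sd 0.25 log2 for the discovery arm; 1000 genes with a
50-gene set at −1.0 log2 and noise 0.5 for the GSEA arm. Two
parameters are not fixed by that specification and were set once by an
up-front power analysis: `n_replicates_per_subset = 5` (at 3
replicates the Welch branch recovers only ~81% of planted genes at
4-fold/0.25-noise, at 5 replicates ~99.8%; five replicates per subset
is typical of consortium-scale profiling) and `baseline_log2_sd =
0.75` (keeps the on/off separation above 4 combined standard
deviations so breadth calls are near-perfect at the stated noise).

## Numerical choices and degenerate inputs

- Quantile definition: numpy linear interpolation; inclusive cutoff.
- Running-sum extremum ties: first position (numpy argmax) wins.
- ES = 0 is treated as positive-signed for p/NES bookkeeping.
- BH adjustment via `scipy.stats.false_discovery_control`; NaN
  p-values (identical constant groups) are set to 1 beforehand.
- Contingency tables with a zero margin, gene sets with empty or
  full-cover intersections, sub-2-replicate subsets, and candidate
  sets outside the matrix all raise typed errors naming the offender;
  the CLI maps configuration, input-format and degeneracy errors to
  exit codes 2, 3 and 4.
- Seeds: a single integer per run; internal substreams come from
  `numpy` `SeedSequence` children, all below 2^31.

## Problem sizes

The shipped tests and the acceptance script use the default study
conditions: 10 discovery seeds at 2000 genes, 20 GSEA seeds at 1000
genes with 200–500 permutations, and 500 replicates for each null
calibration — sizes at which every quantity is stable to within the
asserted tolerances while the whole suite stays desk-scale.

## Limitations

- The generators do not model count noise (negative binomial), batch
  effects, probe-level artifacts or read-level data; passing recovery
  tests demonstrates correctness of the selection logic and
  calibration of the tests under the stated noise model, not
  robustness to real microarray/RNA-seq pathologies.
- Published headline quantities that depend on the original external
  datasets (the deposited RNA-seq contrast, the public tissue atlas
  and stromal microarrays) — specific NES/q values and the published
  candidate counts — are out of reach by design; the package instead
  proves the machinery on planted-truth data and on the published
  printed tables.
- The tissue-representation test performs a single comparison; no
  multiplicity correction across tissue tests is applied or needed.
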