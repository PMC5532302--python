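# Methods

This note documents the models and procedures implemented in
`omidriver`, the assumptions behind them, and the design choices made
where the underlying study left the method open.

## Problem setting

The package targets small multi-omics tumor/normal cohorts (the design
point is ~20 tumors and ~10 normals) measured at four gene-level layers:
log2 mRNA expression ratios, copy-number log ratios (LR), a signed
log-scale differential methylation signal, and log2 miRNA expression,
plus a miRNA→target map. The goal is to separate *driver candidates* —
genes whose expression change is mechanistically explained by concordant
alterations in the other layers — from *passenger candidates*, then to
place drivers in the context of co-expression modules they may regulate.

## Per-layer differential calling

Each layer keeps its own published decision rule rather than a pooled
model:

* **Expression** — per-gene effect is the tumor−normal difference of
  mean log2 ratios. A gene is called differentially expressed when
  |effect| ≥ 0.6 **and** the Welch 95% confidence interval of the
  difference excludes zero. The CI clause is our reading of the
  criterion "within a 95% confidence interval"; under a pure-noise
  cohort (N(0,1), 10 vs 10) the joint rule calls ≲ 7% of genes, which
  the suite checks by direct simulation.
* **Copy number** — calls are per tumor sample: gain at LR ≥ +0.15,
  loss at ≤ −0.15. The gene-level `altered_fraction` is the frequency of
  the dominant call; significance requires ≥ 20% of tumors. The reported
  effect (LR) is the mean log ratio over the tumors carrying the
  dominant call — the published tables do not state whether the mean is
  taken over altered samples or all tumors, and the carrier mean is the
  choice here. Frequency ties resolve by the sign of the overall mean; a
  zero mean is called not significant.
* **Methylation** — Welch test per gene at P < 0.05, positive effect =
  hypermethylated in tumor.
* **miRNA** — Welch t-test with the joint criterion P < 0.01 and
  Benjamini–Hochberg q < 0.05. The FDR procedure is not named in the
  source protocol; BH is the field default and is what we use
  (implemented via statsmodels, with hand-computed step-up oracles in
  the tests).

All tests are Welch (unequal-variance) statistics on gene-level
matrices. Moderated (empirical-Bayes) statistics of the limma type are
deliberately not used: at the matrix level the Welch test is exact,
self-contained and easier to verify; the thresholds above were designed
for two-group comparisons of this size. Zero-variance degenerate genes
resolve by the limiting behaviour (identical constants → P = 1; distinct
constants → separation, P = 0).

## Integrative score

For a differentially expressed gene with expression effect Ge and layer
effects CNA, Me, Mi (the miRNA effect is the signed sum over significant
targeting miRNAs whose direction *opposes* the expression change —
absent when no opposing regulator exists):

* concordance: CNA agrees with Ge on sign; Me and Mi agree on the
  *opposite* sign (hypomethylated & up, targeted-by-down-miRNA & up, and
  mirror images);
* bonuses: β = 1 + (number of concordant non-expression layers), so
  β = 4 when all three agree; α = 2 when the gene's alteration meets the
  20%-of-patients frequency criterion, else 1;
* score = (|Ge| + Σ concordant |layer effect|) × α × β. Discordant
  layers contribute nothing.

The published equation renders the score as a product with a summation
index; a product form cannot reproduce any of the 47 printed scores,
whereas the additive concordant-magnitude form above reproduces all 47
to within two-decimal input rounding (max deviation 0.08, with rows such
as AR = (0.35+4.84+8.01)×2×3 = 79.20 exact). The additive form is
therefore the implemented ("table-consistent") mode, and the packaged
47-row table is the regression oracle for it.

Genes supported by fewer than two concordant non-expression layers are
*ineligible* (configurable). Among eligible genes the driver/passenger
cutoff is either numeric (the study printed 48.72) or the midpoint
between the lowest and highest eligible score. The printed cutoff does
not equal the midpoint of the printed extremes; since its derivation is
not recoverable, the numeric override exists and the midpoint is the
default.

## Module discovery

Standardized tumor-sample expression profiles are clustered with a
Chinese-restaurant-process mixture of diagonal Gaussians: concentration
γ = 1, and per sample dimension a Normal–Gamma prior (μ0 = 0, λ0 = 1,
a0 = 2, b0 = 1) chosen weakly informative for z-scored data (prior mean
variance b0/(a0−1) = 1). Component parameters are integrated out; a
collapsed Gibbs sweep resamples each gene's module from Student-t
posterior predictives of every existing module plus a new one. The chain
is initialized with every gene in its own module — merges mix much
faster than splits from a single block, and the initialization is
exchangeable. The reported partition is the post-burn-in sample with the
highest joint log posterior (MAP-sample reporting: one deterministic
output per seed, no consensus averaging). Defaults are 500 sweeps with
250 burn-in; the end-to-end benchmarks use 150/75, which is past
apparent convergence for cohorts of a few hundred genes.

Two contracts make results reproducible and order-invariant: genes are
swept in sorted-id order, and every gene draws from its own random
stream keyed by (seed, CRC32(gene id)) — permuting input rows cannot
change the partition. Modules smaller than 5 genes are filtered out
afterwards, their genes marked unassigned.

The reference method clusters genes and conditions two-way; here only
genes are clustered, and the condition side is deferred to the
regression tree of the regulator-assignment stage, which preserves the
pipeline's information flow while keeping the sampler small enough to
verify against planted block structure.

## Regulator assignment

Each retained module is summarized by the mean profile of its
(per-gene standardized) members over tumor samples. A regression tree
partitions the samples by thresholding this profile at the split
maximizing the sum-of-squares reduction (exhaustive midpoint scan,
min 5 samples per leaf, depth ≤ 3); leaves are expression "states" with
a mean and standard deviation.

The regulator score of a candidate gene against a module tree is
Σ over internal nodes of w·|t|, where t is the Welch t-statistic of the
candidate's expression between the left and right sample sets and w the
fraction of samples under the node. This stand-in for the original
Bayesian hierarchical score preserves the property that matters —
monotone in how sharply the regulator separates the module's states —
is scale-free in the regulator (affine invariance), and is exactly
testable against planted truth. Published assignment-score *values* are
therefore not reproduction targets; the packaged association table is
used for structural consistency only (22 associations, 19 modules, 16
regulators, passenger fractions).

Associations are ranked (score descending, ties broken by regulator
then module id) and the top 1% kept by default. At desk scale the 1%
rule degenerates (1% of a few hundred pairs is fewer associations than
there are true regulators), so end-to-end runs keep `top_k` = 3× the
planted pair count instead — the same kept-to-reported ratio as the
original genome-scale analysis (66 kept vs 22 reported). Finally,
modules with fewer than 10% passenger candidates among their members
are dropped: modules that accumulate secondary alterations are the ones
of interest.

## Downstream statistics

* **Over-representation** — modules are unranked gene sets, so
  enrichment is the one-sided hypergeometric upper tail
  P(X ≥ overlap), BH-corrected across all (module, set) pairs. This is
  an explicit substitution for the weighted running-sum enrichment
  statistic, which requires a ranked list.
* **Expression dichotomization** — "high"/"low" tumor labels are Tukey
  fences on the *normal-tissue reference* distribution: below
  Q1 − 1.5·IQR or above Q3 + 1.5·IQR (type-7 percentiles). A constant
  reference collapses the fences onto the constant, so any deviation is
  an outlier.
* **Survival** — Kaplan–Meier curves and the two-group log-rank
  chi-square U²/V (via lifelines), validated in the tests against
  hand-computed risk tables. No events at all → statistic 0, P = 1.
* **Mann–Whitney** — exact U by rank sum with a tie-corrected normal
  approximation for P (scipy), checked against brute-force pair counts.
* **Pfaffl quantification** — ratio = E_t^ΔCt_t / E_ref^ΔCt_ref with
  ΔCt = control − sample and efficiencies in [1, 2].

## Synthetic cohorts

The generator (`omidriver.simulate`) emulates the study conditions with
planted ground truth; its defaults are the conditions under which the
package's recovery guarantees are stated:

| parameter | default | meaning |
|---|---|---|
| n_tumor / n_normal | 20 / 10 | cohort size |
| n_genes / n_mirnas | 1000 / 150 | features per layer |
| n_modules, size | 8, 10–40 | planted co-expression modules |
| n_drivers | 16 | planted drivers (first 8 are module regulators, fully concordant; the rest cycle two-layer patterns) |
| driver Ge shift | \|N(2, 0.5)\| signed | log2 expression effect |
| member Ge shift | \|N(1.2, 0.3)\| | module members are differentially expressed |
| CNA LR / penetrance | ±0.4 / 50% | planted copy-number events (noise sd 0.05) |
| Me shift | ∓1.5 | opposite sign to expression (concordant) |
| miRNA shift | ∓2.5 ×2 miRNAs | opposing regulators, planted into the target map |
| noise sd | 0.5 | per-entry Gaussian noise |
| module coupling | 0.8 | member loading on the module latent profile |
| passenger fraction | 30% of members | weak concordant CNA (±0.2 at 40%) + Me (∓0.8) → eligible but low-scoring |
| prognostic HR | 3.0 | per-SD hazard ratio on the prognostic gene |

Module members load linearly on a per-module latent tumor profile that
the module's regulator also carries — the "monotone link" between
regulator and members. Survival times are exponential with hazard
h0·exp(log(HR)·z), h0 = ln2/10 months, z the standardized prognostic
expression; censoring is independent uniform over a 45-month window
(~30% censored), consistent with follow-up horizons of about one to
three years. A `CohortSpec.null()` cohort zeroes every planted
magnitude — including the dedicated miRNA→driver target edges, which
exist only to implement planted regulation.

What the generator does **not** emulate: probe-level array noise, batch
and dye effects, within-tumor heterogeneity, copy-number segmentation
artifacts, correlated missingness, or HPV stratification. Passing the
recovery benchmarks therefore demonstrates the pipeline's internal
consistency under its own assumptions, not performance on real arrays.

## Evaluation benchmarks and problem sizes

`omidriver.benchmarks` fixes the evaluation designs used by the test
suite and `scripts/acceptance.py`:

* module recovery: 2 planted blocks × 30 genes, 20 samples, block
  correlation ≈ 0.9 (latent + noise sd 0.3); measured by adjusted Rand
  index against planted labels;
* regulator ranking: 1 true regulator (2 SD state separation) vs 30
  decoys over 3 modules of 10 genes, 40 samples; success = rank 1 on
  every module;
* end-to-end: a reduced cohort (220 genes, 60 miRNAs, 4 modules of
  12–20 genes, 8 drivers, Gibbs 150/75) so that a 20-seed evaluation
  completes in a few minutes on one CPU; recovery counts a planted
  (regulator, module) pair when the discovered module containing the
  majority of the planted members appears with that regulator in the
  final filtered association list;
* null specificity: 5 zero-effect cohorts; the expected driver count is
  0 because eligibility (differential expression plus two concordant
  significant layers) is already a ~10⁻⁵-per-gene event under the null.

## Numerical choices and degenerate inputs

* Duplicate feature rows collapse by mean on read (probe-to-gene
  collapsing is not specified by any source; mean is our choice); genes
  with > 20% missing values are dropped per layer, with logged counts.
* BH q-values: step-up with capping at 1; inputs outside [0,1] are
  errors.
* Welch statistics on zero-variance pairs resolve by limits (above).
* CNA tie rule uses a 1e-9 tolerance on the mean to recognize exact
  gain/loss symmetry in floating point.
* Regression trees refuse to split below 5 samples per leaf or when no
  threshold reduces the SS; perfectly separated constant sides cap the
  t-statistic at 10⁶ to keep association scores finite.
* The sampler reports the MAP over sampled states and falls back to the
  initial partition if (pathologically) nothing better is visited, so
  the reported log posterior is never below the initial one.

## Known limitations

* The integrative score treats layer effects as exchangeable evidence
  magnitudes; it has no notion of measurement uncertainty per layer.
* One-way gene clustering cannot represent modules that only cohere in
  a subset of tumors (the condition side is only recovered later, by
  the tree).
* The regulator score is correlational; it cannot orient regulator →
  module causality and will rank a strongly co-expressed member highly
  (self-association is in fact its upper bound).
* The passenger filter depends on the driver/passenger cutoff; with the
  midpoint rule a single extreme score moves the cutoff and hence the
  passenger sets of all modules.
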