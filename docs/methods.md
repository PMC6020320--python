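# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `eqtlnet`.

## Association scan

The per-pair model is ordinary least squares of gene expression on
`[intercept | contemporary-group dummies | lane dummies | age | dosage]`,
with the dosage coefficient tested two-sided against Student t on
n − p − 1 residual degrees of freedom (p = covariate design columns). The
exhaustive scan does not loop over pairs: expression and dosage are
residualized on the covariate design once (QR projection) and all pairs are
scored through one matrix product of normalized residuals. By the
Frisch–Waugh–Lovell theorem this is algebraically identical to the per-pair
fit; the test suite asserts agreement with per-pair `statsmodels` OLS to
1e-10. Missing dosages are mean-imputed per variant at fit time (never at
I/O time, so QC filters see the true call rate); constant variants are
dropped and logged; rank-deficient covariate designs lose collinear columns
with a log message.

Assumptions: additive allelic effects, homoscedastic Gaussian errors,
fixed-effect covariate adjustment only (no kinship/mixed model — appropriate
when no population stratification is present), expression already
normalized to an approximately Gaussian scale. A rank-based inverse-normal
transform per gene is available (`inverse_normal=True`) but off by default.

**cis/trans rule.** Distance is measured to the nearest gene-span boundary
(0 inside the span), not to the TSS; a pair at exactly the 1 Mb window
boundary is cis ("within" read as inclusive), and different chromosomes are
always trans (distance reported as −1). FDR is Benjamini–Hochberg applied
separately within the cis and the trans candidate streams (a pooled mode
exists behind `pooled_fdr=True`); BH itself wraps the `statsmodels`
step-up implementation, cross-checked against the closed form in tests.

**Variant QC.** Variants with call rate ≤ 0.95 or MAF ≤ 0.05 are removed
(boundary values removed; strictly greater survives), along with
sex-chromosome and unmapped variants. Thresholds are parameters.

## Hotspot detection

The statistic is the per-variant count of *distinct* significantly
associated trans genes. The null reassigns each significant association to
a variant drawn uniformly with replacement from all tested variants; the
default threshold is ceil of the 95th percentile of the per-permutation
*maximum* count over 1000 permutations — a family-wise bound on the most-hit
variant, which is the quantity a hotspot claim is about. A pooled
alternative (percentile of all per-variant counts pooled over permutations)
is available via `null="pooled"`. For toy instances
`exact_max_count_distribution` enumerates the null exactly and is used as
the oracle for the sampled version.

Candidates at or above the threshold are refined greedily: visit by
decreasing count (ties: smaller best association p, then position), absorb
remaining candidates with dosage r² ≥ 0.5 (`r2_merge`, a parameter; no
field-standard value exists, 0.5 marks "same signal" conservatively). The
anchor keeps its own target list; absorbed ids are recorded. Windows are
anchor ± 2 Mb, clipped at chromosome ends with a flag.

D′ uses haplotype frequencies estimated by EM on the 3×3 genotype table
(only double heterozygotes are phase-ambiguous); 100 iterations or change
< 1e-10. r² is the squared Pearson correlation of dosages.

## Region overlap test

Observed statistic: total basewise overlap in Mb between the merged unions
of the two sets (merging first prevents double counting; a brute-force
per-base oracle checks the interval arithmetic). The null redraws each
A-interval uniformly on its own chromosome with its own length, so the
permutation distribution is matched on size and chromosomal composition.
p = (1 + #{perm ≥ obs})/(1 + n_perm) (add-one estimator; never 0, lower
bound 1/(n_perm+1)). Random placements may overlap each other — no
rejection — matching a plain permutation sampler. With heavily tied
statistics (e.g. frequent full containment) the add-one estimator is
conservative, which is visible in calibration checks; partial-overlap
geometries give uniform null p-values. Overlap categories (AinB, BinA,
AleftB, ArightB) are assigned per unmerged pair; identical intervals count
as AinB (containment non-strict for A, strict for B).

## Hotspot–phenotype ANOVA

Genotype enters as an unordered factor (AA/AB/BB by minor-allele count),
fitted after the covariates; the F statistic is the sequential
(genotype-last) sum-of-squares drop, so for a two-level factor F = t² of the
corresponding dummy regression — asserted against the eQTL fitter to 1e-10.
Levels with fewer than 2 observations are dropped with their samples and
logged. An exact fit (zero residual SS) reports the smallest positive float
as p and sets an `exact_fit` flag rather than dividing by zero. BH is
applied across the trait panel within each hotspot (a global mode exists).
Phenotype adjustment for the network stage is fixed-effects residualization
on the same covariate design — the residuals are numerically orthogonal to
any effect in the design span, which the tests exploit.

## Promoter scanning

PSSMs: probs = (counts + pseudocount)/(colsum + 4·pseudocount), log₂ odds
against a uniform background by default (promoter-composition backgrounds
can be passed). Pseudocount 0.25 per cell. Scores are sums of per-position
log-odds in bits; an `N` base contributes 0 (the background expectation).

Exact p-values come from convolving the per-position score distributions.
Instead of a fixed coarse grid, the convolution tracks exact achievable
sums (keys merged at 1e-9 bits) while the state count stays below 4^11,
which covers every motif up to 11 bp exactly — for such motifs the DP
equals full 4^L enumeration to float precision, asserted for L ≤ 6 in the
tests. Longer motifs fall back to a 1e-3-bit grid. −∞ per-position scores
(zero probability with pseudocount 0) are mapped to a −1e6-bit sentinel;
a window score of −∞ has p = 1 by definition.

Promoters are 1500 bp; both strands are scanned (minus strand = the
reverse-complement PSSM on the forward sequence, which the strand-symmetry
tests pin down). Per-window p-values are *not* multiplicity-corrected
within a promoter, matching the per-site p ≤ 0.05 convention of web TFBS
scanners; at that threshold essentially every 1500 bp promoter contains a
"significant" site (1 − (1−p)^(2·1493) ≈ 1), so the per-gene hit indicator
is only informative at much stricter thresholds — a property the tests
verify against the closed-form null rather than hide.

## Co-expression networks

Unsigned adjacency |cor|^power with power 6 (the standard soft threshold
when the scale-free fit index reaches ~0.9; `pick_soft_power` reports the
index over powers 1–20 but never auto-selects). TOM as in the README; the
matrix formula is checked against a brute-force triple sum to 1e-12.

Module detection is an adaptive "tree" cut: average-linkage clustering of
1 − TOM, cut at a deep-split-controlled fraction of the dendrogram's
merge-height range ({0: 0.99, 1: 0.97, 2: 0.95, 3: 0.92, 4: 0.88}), with
branches of ≥ `min_module_size` leaves becoming modules and everything else
grey. The hybrid PAM-stage variant of dynamic tree cutting is deliberately
not reproduced; planted-block recovery (adjusted Rand ≥ 0.9), not exact
module boundaries, is the accuracy contract. Module ids are stable color
names assigned by decreasing size.

Eigengenes are the first right-singular vector of the standardized module
expression (unit norm over samples), sign-oriented so the mean member
correlation is positive — a convention required for reproducibility.
Modules merge iteratively when their eigengenes cluster below dissimilarity
0.25 (correlation > 0.75), recomputing eigengenes to a fixed point.
Cross-group comparability: the smaller genotype group's TOM is raised to
the power log(q_ref)/log(q_small) so its 95th off-diagonal percentile
matches the larger group's; a power map on (0,1) preserves entry order.

Module–trait correlation uses Pearson r with the two-sided Student
asymptotic p on n − 2 df. GS = |cor(gene, trait)|, MM = signed
cor(gene, eigengene); hubs are the top 20 by |MM| (ties by gene id for
determinism); modules correlated with ≥ 3 traits at p < 0.1 go to
enrichment. Enrichment backgrounds are the genes that entered that group's
network, never the genome; sets smaller than 3 after background
intersection are skipped.

## Synthetic-data generator

The generator emulates a chip-genotyped, RNA-seq-profiled cohort of a few
hundred animals with batch covariates and a fat-deposition trait panel.
Defaults: 300 samples, 4 chromosomes × 50 Mb, 400 variants, 200 genes, MAF
uniform on (0.1, 0.5), allele-copying probability 0.8, 30 cis pairs with
β = 1, a hotspot variant driving a TF gene (β = 1) whose expression drives
50 target genes (γ = 0.8), noise sd 1, 4 contemporary groups × 2 lanes,
age uniform on 1.5–2.5 years, 15 traits with loading 1 (alternating sign),
motif planting probability 0.9 per target promoter.

* **Genotypes**: two haplotypes per sample; along each chromosome an allele
  is copied from the previous variant with probability `ld_copy_prob`,
  otherwise drawn fresh Bernoulli(f). Dosage = haplotype sum, so genotypes
  are HWE in expectation and adjacent-variant r² is tunable (1 at copy
  probability 1, ~1/n at 0).
* **Expression**: baseline N(8, 2²) per gene on an arbitrary log-like
  scale; cis and background genes add the shared covariate effect
  (per-level N(0,1) draws plus an age slope, all stored in the truth
  bundle); the TF and its targets follow the mechanistic path only, so
  target–genotype association is genuinely *mediated*. The optional
  `target_gamma_alt` makes the TF→target coupling depend on hotspot
  genotype, planting the network rewiring the stratified analysis is meant
  to detect.
* **Traits**: loading × mean standardized target-gene expression +
  covariate effect + noise.
* **Promoters**: i.i.d. uniform background, one PFM-sampled site inserted
  per selected target promoter at a recorded offset/strand.
* **Regions / gene sets**: a synthetic "known QTL" BED (the true hotspot
  window plus random background intervals) and a GMT with the planted
  target program plus random decoy sets, so overlap and enrichment have a
  planted positive.

Every stage draws from a child stream of one master seed (fixed
per-component offsets), so each output is a pure function of (config, seed).

What the generator does **not** emulate: read-level RNA-seq noise and
normalization artifacts, realistic recombination maps or LD decay beyond
first-order copying, pedigree/family structure, population stratification,
non-additive (dominance/epistatic) effects, and promoter base composition
bias. Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability of planted structure under the stated model —
not robustness to those real-data complications.

## Calibration-study design choices

* FDR/recall simulations use `ld_copy_prob = 0`: with LD, proxies of a
  causal variant carry genuine association, so "false positive" is only
  well defined against the truth list when variants are independent.
* The association-scan null calibration also uses independent variants so
  pooled p-values are (nearly) independent and the Kolmogorov–Smirnov null
  applies.
* The module–trait null calibration uses single-level batch factors and
  covariate-adjusted traits: with shared batch structure, covariate-driven
  modules are *genuinely* related to raw traits (a true signal), while
  adjusted traits against unadjusted expression are anti-conservative in
  the other direction; neither is a p-value calibration failure.
* Problem sizes throughout the suite (hundreds of samples, hundreds of
  variants, 100–250 genes, 150–1000 permutations, 5–20 replicates per
  property) were chosen as the smallest instances at which the tested
  properties are statistically meaningful.

## Numerical details

* BH, hypergeometric tails, t/F tails: `statsmodels` / `scipy`.
* OLS via QR/lstsq; exact-fit detection at relative residual SS ≤ 1e-12.
* EM for haplotype frequencies: tolerance 1e-10, max 100 iterations.
* Permutation p-values use the add-one estimator everywhere.
* Candidate ordering, hub ranking and color assignment all have
  deterministic tie-breaks so identical inputs give byte-identical outputs.

## Limitations

* No mixed-model/kinship correction; cohorts with stratification need
  external pre-correction.
* The hotspot permutation null treats significant associations as
  exchangeable units; correlated expression among a hotspot's targets makes
  the null conservative for per-variant counts below the maximum.
* Dynamic tree cutting is the simple height-cut variant; very unbalanced
  or nested module structures may split differently than the hybrid
  algorithm would.
* The exact-p-value scanner assumes an i.i.d. background; strong promoter
  composition bias shifts the effective null (a composition-matched
  background can be supplied to `pfm_to_pssm`).
* Multi-allelic variants are rejected rather than split.
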