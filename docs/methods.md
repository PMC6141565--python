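# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `bgfx`. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## The mapping model

All mapping is done with fixed-effects linear models fit jointly to
wild-type and knockout segregants of a haploid two-parent cross. Loci are
coded BY = 0, 3S = 1; the genetic background (wild type plus the knockout
panels) enters as a treatment-coded factor with the wild type as reference,
so mean growth differences between backgrounds are always absorbed before
any locus term is evaluated.

The scan models, in the order their terms are fit:

| scan | mode | model (focal term last) |
|---|---|---|
| 1-locus | independent | `background + locus` |
| 1-locus | responsive | `background + locus + background:locus` |
| 2-locus | independent | `background + l1 + l2 + l1:l2` |
| 2-locus | responsive | `background + l1 + l2 + background:l1 + background:l2 + l1:l2 + background:l1:l2` |
| 3-locus | independent | `background + l1 + l2 + l3 + pairwise + l1:l2:l3` |
| 3-locus | responsive | all lower-order terms + `background:l1:l2:l3` |

In forward-regression one-locus scans, previously detected loci enter later
iterations as covariates — in responsive mode with both their additive and
background-interaction terms — so variance already explained can never be
re-attributed to a new candidate.

**One p-value per term.** With B backgrounds the focal interaction has B−1
degrees of freedom. We test the whole term with a sequential (type-I)
F-test: the term's sum of squares is the squared norm of the response
projected onto the term's orthonormalized columns after all preceding
terms, and F = (SS/df) / (SS_resid/df_resid). This gives the single
decision statistic per term that permutation thresholding requires.
Rank-deficient terms (empty joint genotype classes) are reported untestable
(df = 0), never silently dropped.

## Permutation thresholds and their exact level

Genome-wide significance uses a permutation null: the phenotype vector is
shuffled across all segregants (background labels stay attached to
genotype rows; a background-stratified shuffle is available as a
sensitivity option), the scan is re-run, and the minimum focal-term p is
retained. The threshold is the 5% quantile — type-7, linear interpolation,
fixed and documented — of the permuted minima; 1000 permutations per
iteration by default, re-derived at every forward-regression iteration.
Two-locus permutations evaluate 10,000 random pairs rather than all pairs;
three-locus permutations draw a random cross-chromosome anchor pair plus
random third sites.

A rank argument fixes the procedure's exact level: the real scan and n_perm
permuted scans are exchangeable under the null, so the familywise
false-positive rate is roughly (q·n_perm + 1)/(n_perm + 1) plus an
interpolation term — about 0.059 at n_perm = 100 and about 0.051 at
n_perm = 1000 for q = 0.05. The calibration test (200 null crosses of 400
segregants × 200 markers at n_perm = 100) observes this level; it is a
property of quantile estimation from finitely many permutations, not a
defect of the implementation.

Empirical FDR is computed by comparing discovery rates: FDR(p) = (mean
permutation discovery rate at p) / (real discovery rate at p), capped at 1,
with per-test-count scaling when permutations subsample pairs/trios.

## Post-scan characterization

* **Knockout assignment.** The detection model is refit on the full data
  and, for each knockout, the treatment-coded coefficient of
  `background[k]:locus…` — exactly the difference between knockout k's and
  the wild type's locus-interaction effect — is t-tested against the model
  residual. Nominally significant knockouts (p < 0.05, uncorrected) are
  assigned; each assignment counts as a separate effect.
* **Variance partitioning.** On the wild-type + one-knockout subset, the
  sequential sums of squares of the mutation-responsive terms are
  normalized into shares (for two loci: KO×L1, KO×L2, KO×L1×L2; for three
  loci grouped into individual / pairwise / three-way classes). Shares are
  invariant to phenotype rescaling and sum to 1 by construction.
* **Enhanced vs reduced.** Within each single background the effect's
  top-order term is refit without any background term
  (`y ~ l1 [* l2 [* l3]]`); partial R² = SS(term)/SS(total). Enhanced iff
  the knockout's partial R² strictly exceeds the wild type's; the
  measure-zero tie goes to reduced for determinism.
* **Cross-environment testing.** The detection model is refit on the
  wild-type + knockout subset in each of the other environments;
  Bonferroni family = (other environments) × (assigned knockouts), with
  significance at raw p ≤ α/m.
* **Allele-frequency bias.** 2^k × B contingency tables of joint genotype
  class against background, Pearson χ² (no continuity correction),
  Bonferroni over the tested locus sets; structurally empty rows or
  columns skip the test with a diagnostic.
* **Variance-change attribution.** Per knockout × environment cell the
  summary records V_P.Mut, V_P.WT (sample variances), ΔV, and the counts of
  enhanced and reduced effects; Spearman's ρ relates ΔV to
  Δcount = n_enhanced − n_reduced, over all cells or per background. The
  joint per-background test permutes ΔV across environments within each
  background independently — preserving each background's count structure —
  and bounds the probability that every background clears the observed
  minimum correlation.

## Genotype correction

Initial calls threshold the per-SNP 3S-read fraction at 0.5 (above → 3S,
below → BY; exactly 0.5 → BY by a documented, configurable tie rule).
Each chromosome's call vector is then decoded with a 2-state HMM — stay
0.9999 / switch 0.0001, emission fidelity 0.75, uniform initial
distribution — taking the maximum-probability (Viterbi) path as the
corrected genotype; ties break toward BY. Missing sites (coverage 0) emit
likelihood 1 under both states, so they are imputed from their neighbors.

These transition probabilities presume densely spaced markers (per-interval
recombination far below the switch penalty). Consequences worth knowing:
the log switch penalty (≈9.2) is much larger than a single miscall's
log-likelihood cost (≈1.1), so on chromosomes shorter than ~9 markers the
decoded path is effectively constant, and an isolated miscall is guaranteed
to be corrected only when the rest of the chromosome is self-consistent
(exhaustively enumerated for lengths ≤ 12 in the test suite). On genuinely
ambiguous inputs — e.g. perfectly alternating calls, where the two parental
assignments tie — the corrected side is a tie-break, not an inference.

QC removes segregants with mean per-site coverage < 1.5× and flags
heterozygous excess (fraction of covered sites with allele fractions in
(0.2, 0.8) above 5%; the threshold is an explicit stand-in for qualitative
aneuploidy/contamination criteria and is configurable). Adjacent markers
whose call columns are identical across all segregants are collapsed to
their leftmost member, with a block table recording membership.

## The synthetic cross generator

`simcross` generates the study's statistical structure, not its biology:

* **Genotypes.** Each chromosome is an independent 2-state Markov chain
  over {BY, 3S}: first marker Bernoulli(0.5), each interval switching with
  its per-interval recombination probability (Haldane-like, no
  interference, no tetrad structure, no segregation distortion). The
  default map has 16 chromosomes, mirroring the *S. cerevisiae* karyotype,
  with uniform marker spacing.
* **Phenotypes.** phenotype = background mean shift + planted increments +
  N(0, noise_sd). A planted k-locus effect adds its absolute effect size to
  the single designated joint genotype class (≈2^−k of targeted
  individuals at balanced allele frequencies), restricted to one target
  background for responsive effects or applied in every background for
  independent ones. Background shifts default to 0 (they are absorbed
  exactly by the background term and do not affect focal-term inference); a
  knockout-style preset exists for demos. Noise defaults to sd 0.25 in the
  units of control-normalized growth, a magnitude chosen so planted
  "3× noise" effects sit in the informative power range of the study-sized
  panel.
* **Allele fractions.** Per site: coverage ~ Poisson(mean), 3S-supporting
  reads ~ Binomial(coverage, 1 − error) at true 3S sites and
  Binomial(coverage, error) at true BY sites; fraction undefined (missing)
  at coverage 0. The defaults of the pipeline demo (mean 3×, error 5%) and
  the correction benchmark (mean 1×, error 25%, matching the HMM's 0.75
  emission fidelity) bracket the realistic low-coverage regime.

What passing tests on this generator do **not** show: robustness to linked
real-world marker maps with variable density, non-Gaussian growth noise,
plate artifacts beyond control normalization, segregation distortion, or
loci falling between markers. Truth records are serialized with the data so
detection scoring never re-derives them.

## Power analysis

Per grid cell (order, mode, absolute effect size), each replicate simulates
a fresh cross — by default 1411 segregants split over the eight study
backgrounds (164 wild type; 210/122/215/220/177/141/162 for the knockouts)
— draws random distinct loci and a random incremented genotype class (and,
for responsive effects, a random non-wild-type target background), plants
the increment, adds noise, fits the matching detection model, and records
whether the focal-term p ≤ 0.05. Power is the fraction of replicates that
succeed; at effect size 0 it estimates the nominal α. The acceptance script
uses 500 replicates per cell, sizes {0, 0.3} at noise sd 0.25, which
resolves the one- ≥ two- ≥ three-locus power ordering well outside
Monte-Carlo error.

## Numerical choices

* Rank detection: a projected column is dependent below a 1e-8 relative
  tolerance; a second orthogonalization pass guards against cancellation.
* p-value floor 1e-300; perfect fits (residual SS numerically 0 with a
  nonzero focal SS) report the floor rather than dividing by zero.
* Quantile rule for thresholds: type-7 (linear interpolation), fixed.
* Tie on the iteration's minimum p: leftmost genomic position wins.
* Forward scans cap at 30 iterations; detected markers are excluded from
  later iterations (no distance window — locus identity is the collapsed
  representative marker, with no positional fuzzy matching).
* Contrast estimation admits design columns left to right, so aliased
  (later) columns are the ones reported inestimable, matching R's `lm`.
* All randomness flows through numpy Generators seeded from explicit
  integers; spawned SeedSequences keep derived seeds below 2^31.

## Problem sizes used in the shipped experiments

The test suite and acceptance script run scaled-down crosses chosen to
estimate each operating characteristic with useful precision: calibration
at 400 segregants × 200 markers × 100 permutations × 200 crosses; planted
two-locus recovery at 800 segregants (8 backgrounds) × 48 markers with
100 × 400-pair permutation nulls over 50 seeds; power at the full panel
size (1411) with small marker sets, 500 replicates per cell. These sizes
are the package's own experimental design; the machinery accepts
study-scale inputs (thousands of segregants, ~8311 collapsed markers)
through the same interfaces, with runtime dominated by the two- and
three-locus permutation scans.

## Known limitations

* The exhaustive two-locus scan is O(M²) model fits on the real data; at
  8311 markers that is ~34.5M pairs and demands either the subsampled-null
  trick plus hours of compute or chromosome-level parallelism (out of
  scope here).
* Mixed models, kinship corrections, and interval mapping between markers
  are deliberately absent — the analysis is fixed-effects and
  marker-based.
* The heterozygosity QC threshold and the joint-permutation scheme for the
  per-background correlation result are explicit stand-ins where the
  procedure is qualitative; both are configurable and documented.
* Levene screening defaults to mean centering (classic Levene);
  median-centered (Brown–Forsythe) is available via `center="median"`.
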