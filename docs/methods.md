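# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that make results reproducible.

## 1. Summary-statistics harmonization

Two per-protein cis-region association tables (variant id, alleles,
effect-allele frequency, β, SE, p, n) are reduced to a single aligned
variant universe. Identity is (chromosome, position, unordered allele
pair); rsIDs are treated as annotation. Where the second dataset's alleles
are swapped, β is negated and eaf replaced by 1 − eaf.

Palindromic variants (A/T, C/G) cannot be oriented by allele labels because
a strand flip is indistinguishable from an allele swap. We orient by
frequency when the minor-allele frequency is ≤ 0.40 in both datasets (the
minor sides must agree) and drop the variant when either frequency lies in
(0.40, 0.60). This is the standard practice of two-sample MR harmonization
tools and keeps behaviour deterministic.

Filters, applied before analysis and in either order (they commute):

* **cis window** — ±500 kb around the *gene body* (1-based inclusive
  boundaries). A TSS-anchored window is exposed by configuration; the gene
  body is the default because it is the most permissive reading of "within
  500 kb of the gene".
* **MAF** — min(eaf, 1 − eaf) > 0.05, strict.
* **eligibility** — minimum p < 5×10⁻⁸ in *both* tissues, strict. Loci
  failing this are reported untested rather than "not colocalized by lack
  of power".

## 2. LD reference panel

Pearson correlations of ALT-allele dosages from a reference genotype panel
(VCF with GT fields, or a plain dosage table). Missing genotypes are
mean-imputed per variant rather than dropped pairwise so the matrix remains
consistent with a single completed data matrix (pairwise-complete
correlation matrices need not be positive semidefinite). Allele orientation
is fixed at construction time: where the requested effect allele is the
panel's REF, the variant's row and column are sign-flipped, so the
colocalization stage never re-orients. Monomorphic variants are excluded
with a warning. The simulator's default panel size (n = 5,000) mirrors the
reference-panel scale typical of this analysis.

## 3. Multi-signal detection (approximate conditional analysis)

Working on the standardized scale b_j = z_j/√n_j (trait units cancel, so
datasets on arbitrary measurement scales are comparable), stepwise forward
selection picks the variant with the largest conditional |z| at each step:

* conditional effect: b_{j|S} = b_j − R_{jS}(R_{SS} + εI)⁻¹ b_S
* conditional SE: √((1 − q_j)/n_j), with q_j = R_{jS}(R_{SS} + εI)⁻¹R_{Sj}

Defaults: ridge ε = 10⁻⁶ (numerical stability of the selected-set
inverse), collinearity guard q_j ≤ 0.95 (variants nearly spanned by the
selected set are not selectable), stop threshold |z| ≥ 5.4513 (two-sided
p = 5×10⁻⁸), at most K = 10 signals. Ties in |cond z| break toward the
smaller genomic position for determinism. The conditional SE ignores
residual-variance shrinkage, the standard large-n summary-statistics
approximation; the exact per-signal residual variance is not identifiable
from marginal summaries.

Each reported signal carries conditional statistics conditioned on the
*other* selected leads only (leave-one-out), preserving its own association
while regressing out the rest. With a single signal this reduces exactly to
the marginal statistics.

If n is missing for some variants, the locus median n is substituted with a
warning; a singular selected-set LD block aborts the locus with a
diagnostic rather than returning silently wrong conditioning.

## 4. Colocalization

Per-variant Wakefield log approximate Bayes factors are computed from each
signal's leave-one-out conditional β and SE with prior effect variance
W = 0.15² on the standardized scale (a field-standard default for
molecular traits). The five-hypothesis enumeration is carried out in log
space with log-sum-exp:

* L1 = Σ_k A_k, L2 = Σ_k B_k, L12 = Σ_k A_k B_k,
  Lcross = Σ_{j≠k} A_j B_k (accumulated directly over j ≠ k pairs, so a
  single-variant locus gives Lcross = 0 and hence PP3 = 0 exactly)
* unnormalized weights {1, p1·L1, p2·L2, p1p2·Lcross, p12·L12} with
  p1 = p2 = 10⁻⁴, p12 = 10⁻⁵, normalized to PP0..PP4.

Posterior inclusion probabilities are pip_k = A_k B_k / Σ A B; the credible
set is the smallest pip-descending prefix reaching 0.95 mass; the lead is
the argmax-pip variant.

All cross-trait signal pairs are evaluated and matched one-to-one greedily
by descending PP4 (a signal feeds at most one pair, preventing
double-counting). The locus colocalization probability is the maximum PP4
over matched pairs; "colocalized" means strictly above 0.8. Discordance is
defined only at colocalized loci and compares the signs of the two traits'
*marginal* betas at the best pair's lead. Marginal (rather than
conditional) betas at the shared lead are a convention; both the per-pair
and per-locus leads are exposed. The cohort-level Spearman correlation of
lead-variant betas across colocalized loci uses the same convention.

The engine was validated two ways: against a brute-force single-causal
enumeration written independently in the test suite (agreement to 1e-9 at
K = 1 on simulated loci) and against planted multi-signal truth.

## 5. Tissue enrichment

* Detection filter: ≥ 5 reads in ≥ 20% of *all* samples (inclusive
  thresholds). The filter is global rather than per-tissue — the simplest
  literal reading — with a per-tissue option left to configuration.
* TMM normalization implemented natively (the reference implementation is
  an R package; a cross-check test verifies agreement with
  edgeR::calcNormFactors to 1e-6): reference sample = closest 75th
  percentile/library-size ratio to the mean; M and A over genes positive in
  both; double trim of 30% (M) and 5% (A) tails; inverse-(approximate)
  variance weights; factors rescaled to geometric mean 1. Normalized
  expression is counts/(library × factor) × 10⁶.
* Per-tissue medians over samples, then two-stage robust standardization
  using the median and 1.4826·MAD (the normal-consistency constant, so
  z is comparable to a Gaussian z; the source procedure does not state the
  scaling): stage 1 across genes within each tissue, stage 2 across
  tissues within each gene. A tissue with zero stage-1 MAD is excluded at
  error level; a gene with zero stage-2 MAD is excluded with a recorded
  reason (exclusion avoids infinite z and is auditable). Elevated means
  z > 2, strict.
* Contrasts: per tissue, 2×2 Pearson χ² (df = 1, no Yates correction —
  the large-sample default; the correction is available by configuration)
  of elevated × colocalization group; a zero marginal records the test as
  absent rather than zero.

## 6. Mendelian randomization

Instruments are the shared lead variants of colocalized matched signal
pairs (PP4 > 0.8). Proteins without colocalized loci are excluded: for
them, discrepant estimates could reflect power rather than biology. By
default both tissue sources use the *same* shared lead (closest reading of
a colocalized-credible-set instrument rule); a per-tissue-lead option
exists.

* Wald ratio: θ = β_y/β_x, SE = se_y/|β_x| (first-order delta method, the
  dominant convention; a second-order option exists).
* IVW (≥ 2 instruments): fixed-effect, w_i = se_i⁻²; random-effects
  heterogeneity is unidentifiable with two instruments, and no analysis
  here uses more than two.
* Significance: p < 10⁻⁵, strict; CI = estimate ± 1.959964·SE.
* Instrument independence is a hard contract: pairwise r² < 0.01 against
  the LD panel, and a violation raises an error instead of silently
  pruning.

## 7. Synthetic-data generator

What it emulates:

* **Genotypes** — dichotomized-Gaussian haplotypes: a latent AR(1) Gaussian
  per LD block (default 5 blocks over 100 variants, ρ = 0.9) thresholded at
  the MAF quantile (MAF ~ U(0.05, 0.5)), summed over two independent
  haplotypes. This gives exact control of block structure and frequency at
  desk scale, which coalescent realism would not improve for any property
  tested here. Dichotomization attenuates correlation: the tetrachoric
  expectation of adjacent dosage r at ρ = 0.9 is 0.583, and the tests check
  that value, not ρ itself.
* **Two-tissue summary statistics** — protein = Σ signed effects ×
  standardized causal dosages + Gaussian noise, each signal explaining
  h² (default 0.05) of variance; marginal per-variant OLS in independent
  cohorts (defaults n_A = 35,000, n_B = 1,000, mirroring the plasma/brain
  power asymmetry of the motivating datasets, so eligibility filtering is
  genuinely exercised). Scenarios: SHARED_CONCORDANT, SHARED_DISCORDANT
  (tissue-B sign flipped), DISTINCT (two causal variants, r² < 0.1, one per
  tissue), A_ONLY, NULL. Generated SNVs are non-palindromic so that common
  palindromic variants do not silently remove planted causal variants at
  harmonization (palindrome handling is tested separately on constructed
  fixtures).
* **Outcome GWAS** — outcome = θ × protein (tissue A's model by default)
  + noise in an independent cohort (default n = 100,000, default θ = 0.3:
  a moderate effect detectable at the stated power but not trivially so).
* **Expression counts** — negative binomial (dispersion 0.1) around
  per-gene log-normal baselines with log-normal library sizes (~5×10⁵);
  planted genes (5%) gain 8-fold expression in one tissue. The default
  geometry (2,000 genes × 50 tissues × 20 samples) mirrors a GTEx-like
  tissue panel at desk scale.
* **Default study** — 40 proteins mixed 40/10/25/15/10% across the five
  scenarios. Per-protein h² is drawn from U(0.04, 0.12) and the effect sign
  randomized, as in real pQTL panels; this heterogeneity is what makes the
  cohort-level rank correlation of lead betas a meaningful quantity (with
  constant effects it would be pure noise). The expression stage links
  planted enrichment to scenario (shared → blood-like tissue, non-shared →
  brain-like tissue, each with probability 0.5) so the contrast stage has
  signal of the kind the real analysis found.

What it does not emulate — and hence what passing tests do not show:
recombination-map LD (block-diagonal AR(1) only), imputation error,
platform measurement models (aptamer/antibody/mass-spectrometry
normalization), cross-dataset technical heterogeneity, sample overlap
between exposure and outcome GWAS, horizontal pleiotropy, and population
structure. Calibration measured here is calibration under a correctly
specified model; real-data operating characteristics will be worse in ways
these simulations cannot quantify.

All generators are pure functions of (configuration, seed); seeds are
forked per stage and per locus through `numpy.random.SeedSequence` spawning
so stage order cannot silently change draws, and analysis stages are fully
deterministic given inputs. Pipeline reruns with the same seed are
byte-identical.

## 8. Problem sizes and numerical conventions

Simulation studies use the cohort sizes above with 100-variant loci
(100–200 loci per calibration condition; 1,000 replicates for the MR
type-I bound with a single-variant locus, where larger loci add nothing to
the estimand). Tolerances: LD matrices symmetric with unit diagonal to
1e-12; posterior vectors normalized to 1e-9; TMM geometric mean 1 to 1e-9;
round-trip IO exact for identifiers and 1e-12 relative for numerics.
Degenerate inputs are handled explicitly: empty loci are ineligible,
single-variant loci force PP3 = 0, monomorphic variants and zero-MAD
tissues/genes are excluded with logged reasons, β_x = 0 rejects the Wald
ratio, and p-values below double-precision underflow are exempt from the
β/SE-vs-p consistency warning.

## 9. Known limitations

* The conditional-ABF colocalization is a fully specified substitute for
  variational multi-signal engines; it preserves the analytic contract
  (multi-signal, credible sets, PIPs, max-over-pairs probability, 0.8
  threshold) but is not a reimplementation of any specific published tool.
* Greedy one-to-one pair matching is not globally optimal when many
  signals overlap; with the locus statistic being the maximum PP4 this
  affects only secondary pairs.
* Standardized-scale conversion b = z/√n assumes large n and
  variance-1 phenotypes; very small cohorts would need the exact scale.
* The brain-like cohort size (n = 1,000) puts h² ≲ 0.03 signals below the
  eligibility threshold; this is faithful to the power asymmetry of the
  motivating design rather than a defect, but it means weak shared loci
  are reported as untested, not as non-colocalized.
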