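# pqtlx — cross-tissue cis-pQTL colocalization, enrichment, and MR

Circulating (plasma) protein levels are easy to measure at biobank scale,
but genetic effects on a protein in blood need not match its regulation in
the tissue where it acts. `pqtlx` implements the analysis used to quantify
that gap for protein quantitative trait loci (pQTLs): it colocalizes
cis-pQTL signals between two tissues (for example plasma versus dorsolateral
prefrontal cortex), compares effect directions at shared causal variants,
asks whether colocalization status tracks tissue-specific gene expression,
and propagates the consequences into two-sample Mendelian randomization
(MR) against an outcome trait. Because the consortium datasets behind such
studies are access-controlled, the package ships a synthetic-data generator
that emulates their statistical structure with recorded ground truth; every
operating characteristic reported here is measured against that truth.

It is aimed at statistical geneticists who work with GWAS summary
statistics and want a transparent, fully specified multi-signal
colocalization stack rather than a black box.

## Methods at a glance

**Harmonization.** Variants are matched across datasets on
(chrom, pos, unordered allele pair); swapped alleles negate β and mirror the
effect-allele frequency. Palindromic (A/T, C/G) variants are oriented by
allele frequency when the minor-allele frequency is ≤ 0.40 in both datasets
and dropped otherwise. Filters: MAF > 0.05, cis window ±500 kb around the
gene body, and genome-wide significance (p < 5×10⁻⁸) required in both
tissues before a locus is tested.

**Multi-signal detection.** Up to K = 10 conditionally independent signals
per trait by stepwise approximate conditional analysis on the standardized
scale b = z/√n against a reference-panel LD matrix R:

    b_{j|S} = b_j − R_{jS}(R_{SS} + εI)⁻¹ b_S,
    se_{j|S} = √((1 − q_j)/n_j),  q_j = R_{jS}(R_{SS} + εI)⁻¹ R_{Sj}

with ridge ε = 10⁻⁶, a collinearity guard q ≤ 0.95, and selection threshold
|z| ≥ 5.4513 (two-sided p = 5×10⁻⁸).

**Colocalization.** For each cross-trait signal pair, per-variant Wakefield
approximate Bayes factors from leave-one-out conditional statistics,

    log ABF = ½ log(V/(V+W)) + (z²/2)·W/(V+W),   W = 0.15²,

are combined by the classical five-hypothesis enumeration (H0–H4, priors
p1 = p2 = 10⁻⁴, p12 = 10⁻⁵). Signal pairs are matched one-to-one by
descending PP4; the locus is colocalized when max PP4 > 0.8. At colocalized
loci the lead variant (highest posterior inclusion probability) defines the
95% credible set and the cross-tissue effect-direction comparison.

**Tissue enrichment.** Counts are filtered (≥ 5 reads in ≥ 20% of samples),
TMM-normalized (trimmed mean of M-values, 30%/5% trims, weighted), reduced
to per-tissue medians, then standardized twice by median and 1.4826·MAD —
across genes within tissue, then across tissues within gene. z > 2 flags
elevated expression; per-tissue 2×2 Pearson χ² tests contrast elevated
proportions between colocalized and non-colocalized proteins.

**MR.** Shared lead variants of colocalized credible sets instrument the
protein: Wald ratio β_y/β_x (SE = se_y/|β_x|) for one instrument,
fixed-effect IVW for two or more; significance p < 10⁻⁵; estimates are
computed per tissue source and compared in sign.

## Worked example

The numbered scripts under `analysis/` run the default simulated study
(40 protein loci; plasma-like n = 35,000 vs brain-like n = 1,000; n = 5,000
LD panel; n = 100,000 outcome GWAS):

```bash
python analysis/01_simulate_study.py       # writes scratch/study/ + truth table
python analysis/02_colocalization.py
python analysis/03_tissue_enrichment.py
python analysis/04_mendelian_randomization.py
python analysis/05_cohort_summary.py
```

which prints (seed 20240917):

```
tested 40 proteins: 20 colocalized (50.0%), 4 discordant among colocalized (20.0%)
Spearman rho of lead betas: 0.353
20/20 colocalized calls are truly shared loci
...
  brain_cortex: 0.0% vs 65.0% elevated (chi2=19.26, p=1.1e-05 ***; higher in non-coloc)
  whole_blood: 50.0% vs 5.0% elevated (chi2=10.16, p=0.0014 **; higher in coloc)
...
20 proteins significantly associated with the outcome (p < 1e-5)
  consistent effect direction across tissues: 16
  discordant effect direction across tissues: 4 ['P016', 'P017', 'P018', 'P019']
...
calls vs truth: sensitivity 1.00, FPR 0.00 (tp=20 fn=0 fp=0 tn=20)
```

Reading this: all 20 truly-shared loci are called colocalized and none of
the distinct/single-tissue/null loci are; the four shared-discordant loci
are flagged by the lead-variant sign comparison (20% of colocalized calls);
proteins without colocalization are the ones enriched in brain tissue; and
MR returns the true protein→outcome effect (θ = 0.3) with the brain-derived
estimate sign-flipped exactly at the discordant loci — the tissue-context
effect the analysis is designed to expose.

The same machinery is available as a CLI (`pqtlx simulate|coloc|enrich|run`)
for file-based inputs.

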