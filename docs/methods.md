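# Methods

This note documents the statistical model behind `targetmr`, the
defaults and why they were chosen, the numerical decisions, and what
the simulation-based tests do and do not establish about real data.

## Generative model of the simulator

Genotypes are treated as standardized (unit variance), so a region
with LD correlation matrix **r** and per-allele causal effect vector
**b** has true marginal (single-SNP) effects **r·b**, and the vector
of estimated marginals from a study of n individuals is

  β̂ ~ MVN(r·b, r/n),  se_j = 1/√n,

with p-values from the two-sided normal tail. Exposure and outcome
studies are drawn independently (the two-sample design). A gene's
scenario fixes **b** for the two traits:

| scenario | exposure causal | outcome causal | meaning |
|---|---|---|---|
| H0 | – | – | no association with either trait |
| H1 | one SNP | – | eQTL only |
| H2 | – | one SNP | GWAS signal only |
| H3 | one SNP | a distinct SNP | both traits, different variants |
| H4 | one SNP | the same SNP | shared causal variant |

Under H4 the outcome causal effect is θ·β_eQTL, i.e. the outcome
signal is routed entirely through expression; θ is the quantity the
MR stage estimates. LD is an AR-1 kernel r_ij = ρ^|i−j| (repaired to
PSD by eigenvalue clipping at 1e-8 and rescaling to unit diagonal
when numerical noise demands it). Variant metadata — positions evenly
spanning the ±100 kb cis window, allele pairs drawn from the eight
non-palindromic ordered pairs, effect-allele frequencies
Uniform(0.05, 0.95) — comes from a sub-seed shared by every study of
the same region, so studies describe the same variants consistently.
Frequencies feed only harmonization logic; because genotypes are
standardized, effect sizes do not depend on them.

Sub-seeds are derived from the single study seed with a splitmix64
finalizer over (seed, token…), giving gene-, tissue- and
replicate-level reproducibility independent of execution order.

### Default study conditions

* Sample sizes: blood eQTL n = 31,684; brain (prefrontal cortex)
  eQTL n = 1,387; outcome GWAS n = 589,356 (case fraction 0.17,
  represented directly on the log-odds scale with the same normal
  summary-statistic approximation the MR stage assumes).
* Region: m = 50 SNPs, ρ = 0.5.
* Planted effects: β_eQTL = 0.5 SD per allele at the causal eQTL —
  the scale of a strong lead cis-eQTL in large blood studies — and
  identical in both tissues, since an eQTL's per-allele effect is a
  property of the biology while instrument strength (z) then differs
  between tissues only through sample size. θ = 0.4 log-odds per
  expression SD for shared-causal genes; direct outcome effects at
  H2/H3 variants are 0.02 log-odds per allele (z ≈ 15 at the GWAS
  sample size, a clear hit).
* Scenario proportions are apportioned by deterministic
  largest-remainder rounding and assigned to genes by a seeded
  permutation; if the requested mix has positive H4 mass that rounds
  to zero, one gene is reassigned so the cross-tissue intersection
  stage always has something to find.
* Each tissue carries its own outcome table (re-drawn from the same
  truth). A run config may instead point every tissue at one shared
  outcome file, which is the real-data situation.

The two druggable source lists are overlapping thirds of the gene
panel plus decoy symbols absent from the eQTL data, so the merge and
intersection stages do real work. The exclusion list names two flank
SNPs of the first gene (stand-ins for variants with known direct
outcome associations). One GMT set is enriched for the planted
shared-causal genes; the rest are random draws.

## Pipeline stages and defaults

* **Cis window**: closed interval [TSS − 100 kb, TSS + 100 kb],
  1-based positions, strand ignored. The same convention is used for
  instrument selection and colocalization extraction.
* **Instrument significance**: FDR < 0.05. A precomputed `fdr` column
  is used when present (consortium-supplied, genome-wide); otherwise
  Benjamini–Hochberg is applied within the gene's cis window.
* **Clumping**: greedy at r² < 0.001 against an explicit per-region
  LD matrix; ranking by p-value with lexicographic snp_id
  tie-breaks makes the output invariant to input order. SNPs missing
  from the LD matrix either abort (strict, default) or drop with a
  warning.
* **Harmonization**: allele swaps negate the outcome beta and mirror
  its frequency; strand flips complement alleles first. Palindromic
  variants are oriented by minor-allele agreement only when both
  frequencies lie outside [0.42, 0.58]; otherwise dropped. Standard
  errors are never modified. Harmonizing an already-harmonized pair
  is a no-op.
* **MR**: Wald ratio for k = 1 with first-order delta se (a
  second-order option including exposure error exists);
  IVW for k ≥ 2 with multiplicative random effects — the fixed
  se is scaled by √max(1, Q/(k−1)) so heterogeneity can only widen
  intervals. An additive DerSimonian–Laird flavor is available by
  config. The Egger intercept (k ≥ 3) is reported with a t reference
  on k − 2 df and residual over-dispersion floored at 1; genes with a
  significant intercept are flagged, never silently excluded.
* **FDR family**: all testable genes within one tissue (a `global`
  option pools tissues). Genes without instruments are excluded from
  the family rather than counted as tests.
* **Colocalization**: priors p1 = p2 = 1e-4, p12 = 1e-5; prior
  effect variances w = 0.15² for quantitative traits and 0.2² for
  case-control (log-odds) traits, both configurable. The decision
  threshold is PPH4 ≥ 0.75, inclusive. Coloc uses the full cis
  window (not just the clumped instruments) and by default runs only
  for MR-significant genes; a flag enables all-gene coloc for
  calibration work.
* **Significance**: a gene must pass both the MR FDR threshold and
  the PPH4 threshold; the cross-tissue table intersects the
  per-tissue significant sets.
* **Enrichment**: hypergeometric upper tail; universe = union of
  MR-tested genes across tissues (the defensible null — genes that
  never could have been hits are not part of the experiment);
  minimum set size 3 after universe intersection; BH across tested
  sets.

## Numerical choices

All colocalization arithmetic runs in log space with log-sum-exp
reductions. The H3 weight needs S1·S2 − S12; it is computed as a
guarded log-difference, clamped to −∞ when S12 ≥ S1·S2 within
rounding — for a single-SNP region this makes PPH3 exactly zero, as
the hypothesis enumeration requires. Posterior vectors are validated
to sum to 1 within 1e-12 at construction. BH adjustment delegates to
statsmodels; hypergeometric tails to scipy. Result files are written
with a fixed `%.10g` float format and sorted iteration everywhere, so
identical configurations reproduce byte-identical outputs, which the
run manifest's config hash makes checkable.

## Verification experiments

The calibration module defines the seeded experiments the test suite
and `scripts/acceptance.py` run. Problem sizes were chosen so the
whole battery completes in well under a minute:

* **Enumeration oracle** (100 regions, m ≤ 12): coloc posteriors
  against a brute-force enumeration of every per-trait causal-SNP
  configuration, computed with plain-float Bayes factors in an
  independent algebraic form. Agreement is at the 1e-8 log scale.
* **IVW ↔ WLS** (1,000 instances): the IVW estimate equals an
  origin-constrained weighted least-squares fit; the random-effects
  se never undercuts the fixed-effect se.
* **Coverage / type-I error** (200 replicates each): a single strong
  instrument (n_exp = 500,000, n_out = 100,000, β_eQTL = 0.5,
  θ = 0.4). The first-order Wald se ignores exposure uncertainty,
  whose share of the ratio variance is θ²·n_out/n_exp ≈ 3% here, so
  95% CIs are honestly near-nominal; with θ = 0 the raw-p rejection
  rate at 0.05 stays inside its binomial envelope.
* **Scenario discrimination** (200 replicates per scenario, m = 50,
  ρ = 0.5, |z| ≈ 8 at causal SNPs): median PPH4 under shared-causal
  truth clears the 0.75 decision threshold; distinct causal variants
  put the median mass on PPH3; nulls on PPH0.
* **End-to-end recovery** (50 genes, one planted shared-causal gene,
  two tissues): the pipeline's cross-tissue table contains the
  planted gene, with no false cross-tissue genes and conserved
  per-stage manifest counts.

## What the simulations do and do not show

The simulator reproduces the *statistical* structure the pipeline
consumes — LD-correlated marginal estimates, 1/√n standard errors,
shared vs. distinct causal variants, realistic sample-size ratios
between tissues. It does not emulate: multi-causal-variant regions
(the coloc model itself assumes at most one causal variant per
trait), allele-frequency-dependent effect variance, imputation
quality, population stratification, sample overlap between exposure
and outcome studies, or winner's-curse selection in the consortium
data. Passing tests therefore certify the estimators and the plumbing
under the stated model, not robustness to those real-data
violations. Two further caveats: instrument selection at FDR < 0.05
admits weak instruments whose heterogeneity can legitimately suppress
true signals through the random-effects correction (visible in the
simulator when planted eQTL effects are set near the detection
threshold), and the Egger intercept with few instruments has very low
power, so a non-significant intercept is weak evidence of no
pleiotropy.
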