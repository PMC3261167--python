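# Methods

This note documents the statistical models implemented in `longsig`, the
defaults and why they were chosen, what the synthetic-data generator does and
does not emulate, and the numerical decisions a maintainer would want spelled
out.

## Bayesian association testing

Each SNP's 2×3 case/control genotype table (columns MM, Mm, mm; M is the
lexicographically first allele, emulating Illumina TOP-strand coding) is
recoded under four genetic models: genotypic (3 columns), allelic (allele
counts, 2N total), dominant (MM/Mm vs mm) and recessive (MM vs Mm/mm). Under
H1 the case and control rows are independent multinomials with conjugate
Dirichlet priors, hyper-parameter α_jk = 2 in every cell; under H0 the rows
share one multinomial whose Dirichlet hyper-parameters are the column sums
α_·k = Σ_j α_jk = 4. Both marginal likelihoods are Dirichlet-multinomial
integrals with closed forms, so the log10 Bayes factor is a short sum of
log-gamma terms, computed entirely in log space (no overflow for N up to
10^7). The per-SNP score is the maximum Bayes factor (MBF) over the four
models; no model averaging is done.

Choices worth noting:

* **H0 hyper-parameters.** α_·k as column sums (4 for two rows) rather than
  a fresh α = 2. This choice reproduces both the hand-computable example
  (BF = 1.125 for the 2×2 table [[1,0],[0,1]]) and the published
  calibration curve (below); the α = 2 variant reproduces neither.
* **Allelic model.** The 2N alleles are treated as independent
  observations. This is an approximation that is exact only under HWE;
  it is the standard recoding for this test family.
* **Frequentist companions.** Pearson χ² without continuity correction
  (df = columns − 1), odds ratios as n11·n02 / (n12·n01) for two-column
  models and, for the genotypic model, two ORs relative to the MM
  (M-homozygote) reference column. Zero margins yield NaN ORs rather than
  a continuity-corrected estimate.
* **Genomic control.** λ = median(χ²)/median(χ²₁) with the theoretical
  1-df median taken from `scipy.stats.chi2.ppf(0.5, 1)` ≈ 0.4549.

### Null calibration of the MBF rule

`simulate_mbf_error_rate` mirrors the published simulation design: a pooled
cohort of 1,750 subjects with HWE genotypes at a minor-allele frequency
drawn from the grid 0.05, 0.10, …, 0.50 is split at random into 800 cases
and 950 controls (a multivariate-hypergeometric split of the pooled genotype
counts, so any case/control difference is pure sampling noise); a replicate
counts against a threshold when any of the four model Bayes factors exceeds
it. Because all counts and hyper-parameters are integers, the log-gamma
terms are read from a precomputed lookup table, which makes 10^7-replicate
sweeps run in seconds on one CPU. Credible intervals on the error rate come
from a Beta posterior under a uniform prior.

**Known discrepancy.** The published account of this calibration is
internally inconsistent: its text states ≈4 errors per 100,000 tests at
MBF > 100 while its own −log10 arithmetic for the same figure (3.4) implies
≈40 per 100,000. This implementation — whose closed form is verified
against brute-force Monte-Carlo prior integration — computes ≈37 per
100,000 at MBF > 100 and ≈2.3 per 100,000 at MBF > 1,400, matching the
−log10 values (3.4 and 4.7) of the published figure rather than the
prose. The corresponding acceptance test asserts the published prose figure
and is therefore expected to fail; the number is reported as computed and
is not adjusted.

## Genetic risk modelling

SNPs ranked by decreasing log10 MBF are pruned by a conditional-independence
screen: walking the ranked list, a candidate is dropped when its
phenotype-association Bayes factor, recomputed within the genotype strata of
any retained higher-ranked SNP (per-stratum log10 BFs summed; strata with
fewer than 10 subjects skipped), falls below a threshold (default BF 100 for
the two-way screen, BF 10 for a follow-up screen conditioning jointly on the
candidate's two "closest" retained SNPs). The published procedure is only
sketched (it cites an external Bayesian-network method), so this
rank-ordered screen is a declared variant with the stated thresholds, not a
reconstruction.

The k-th nested classifier multiplies, over its top-k SNPs, posterior-mean
conditional genotype probabilities p̂(g|EL) and p̂(g|AL) estimated with the
same Dirichlet smoothing (α = 2, so no probability is ever 0), each SNP
entering under its best single-SNP model's recoding. When the allelic model
wins, prediction uses the 3-category genotype table: a subject contributes
one genotype, not two independent alleles. With prior p(EL) = 0.5 the MAP
rule reduces to comparing likelihood products, i.e. it is prior-free.
Posteriors are computed as cumulative log-likelihood-ratio sums passed
through a logistic, so hundreds of SNPs cannot underflow; ties at exactly
0.5 classify EL, matching the ≥ in the sensitivity definition. Missing
genotypes contribute no factor (missing-at-random), which makes the profile
monotonicity property exact: p(EL|Σ_{k+1}) > p(EL|Σ_k) iff the (k+1)-th
genotype is more probable in cases — tested as an exact property, not a
tolerance.

Model-size selection looks for the k where accuracy exceeds 0.85, the
sensitivity/specificity gap is below 0.02, and the sensitivity trace is
locally flat (range over a trailing window of 10 below the same 0.02);
among qualifying k the gap is minimized, ties toward smaller k, with a
warned fallback to the global gap argmin when nothing qualifies.
Validation procedures: repeated 2/3–1/3 splits refitting the conditional
tables per replicate (SNP order and model tags held fixed from the full
fit), and two negative controls — permuting the chosen SNPs' order, and
drawing the same number of SNPs at random from a wider top-m pool.

## Signature clustering

Risk profiles (N × K, values in [0,1]) are clustered by greedy Bayesian
agglomeration. A cluster's score is the marginal likelihood of all its
members' curves under a single polynomial regression with x rescaled to
[0,1], conjugate normal–inverse-gamma prior (β ~ N(0, σ²I), σ² ~ IG(a₀=1,
b₀=0.1)), the order chosen ≤ 4 by the same marginal likelihood. Because all
profiles share the x grid, cluster sufficient statistics (size, ΣVᵀy, Σyᵀy)
are additive and merges are cheap. Two clusters merge when the shared-curve
evidence exceeds the sum of the separate evidences; merging proceeds
best-gain-first with ties broken by lowest cluster index, then a
hierarchical post-pass re-proposes the closest pair of cluster means under
the same accept-only-if-improved rule (so it is conservative by default).
Clusters below 8 members are pooled as "sporadic". This score is a declared
faithful variant of the cited clustering program, whose exact score is not
published. Note one behavioral consequence: profiles that are i.i.d. noise
around a common flat line are, correctly under this model, one cluster; the
fragmentation expected of "uninformative" profiles appears for the curves
an uninformative SNP ordering actually produces (random-walk shapes), which
is what the null-sanity tests exercise.

Strata by mean final posterior: Blue > 0.95, Red [0.5, 0.95], Orange
(0.2, 0.5), Green ≤ 0.2. The published inequalities leave the boundaries
open; 0.5 is resolved to Red, the others downward. Survival comparisons are
standard two-group log-rank tests (lifelines) on age at death/last contact
with censoring, unadjusted for multiplicity by default (a Bonferroni switch
exists); signature–ancestry association is a contingency χ².

## Ancestry matching

LD pruning uses a 50-SNP window sliding by 5, dropping the later-positioned
SNP of any pair with r² strictly above 0.30 (missing genotypes mean-imputed
for the correlation). PCA standardizes columns after mean imputation
(EIGENSOFT-style). The k-means model selection index — mean silhouette of
the best-inertia run times mean pairwise adjusted Rand index across
restarts — is a declared replacement for the unpublished index it emulates:
it captures the same three ingredients (separation, stability, assignment
quality). Control matching keeps every existing control in a case-bearing
cluster and samples additions so the per-cluster control count is
round(cases / target-ratio), half-ties toward fewer controls; case-free
clusters contribute nothing; an exhausted pool logs a warning and yields
the best achievable ratio.

## Quality control

Samples: drop call rate < 96.5%, then re-admit dropped samples whose call
rate, recomputed on SNPs surviving a provisional screen in the retained
samples, is ≥ 93% — a genotype-space simplification of the intensity
re-clustering rescue. SNPs: call rate > 98% overall and in every
batch × phenotype stratum; HWE χ² in controls < 50 (monomorphic SNPs skip
the test and are flagged); max between-batch MAF gap < 0.2; and a
heterozygosity-excess score F̂ = 1 − obs-het/exp-het within [−0.3, 0.3] —
the published score is an intensity-based metric that is undefined in
genotype space, so F̂ is a decision, not a reconstruction. The
cluster-separation rule needs raw intensities and is a logged no-op; the
sex-consistency check is likewise omitted (no X-intensity data). Duplicate
detection uses genome-wide identity-by-state (pairs above 0.9), a
method-of-moments stand-in for full IBD estimation that is adequate for
duplicates and first-degree relatives.

## Synthetic-data generator

`generate_study` emulates the cohort design the analysis assumes: ~800
cases / ~900 controls (defaults; tests scale down), biallelic SNPs spread
over 22 autosomes, null SNPs drawn under HWE from a shared allele frequency
uniform on (0.05, 0.5], population structure via the Balding–Nichols
construction (subpopulation frequencies Beta-distributed around an
ancestral frequency with variance governed by a single F_ST), planted
longevity-associated variants specified directly by their conditional
genotype/carrier frequencies given phenotype (the quantities the classifier
estimates — ORs are derived, which makes parameter recovery exactly
testable; the default carrier gap 0.15 vs 0.26 mirrors the published
single-SNP example), MCAR missingness, batch labels, and case ages from
Normal(104, 3) truncated at 95 vs control Normal(75, 7). Dominant and
recessive carrier prevalences are converted to genotype distributions by
assuming HWE within the stratum (q = √(1−c) for a dominant carrier
prevalence c).

`plant_signature_groups` partitions cases into latent groups, each enriched
only for its own LAV subset (a configurable fraction shared), with per-group
survival parameters. For the structure-recovery acceptance check the two
groups' variant sets are given near-deterministic effects of different
strength (carrier 0.9 vs 0.05 and 0.7 vs 0.05): differing strengths make
the groups' SNPs rank in blocks, so the groups trace visibly different
profile shapes, and strong effects keep within-group profiles homogeneous
enough that curve clustering can recover the partition — with moderate,
equal effects the two groups' profiles both saturate and are genuinely
indistinguishable, which is a property of the model, not of the
implementation.

What the generator does **not** emulate: linkage-disequilibrium haplotype
structure (only optional duplicated SNP pairs, used to exercise LD
pruning), X-chromosome dosage, genotyping-intensity artifacts, family
structure, and informative missingness. Tests passing on these studies
certify the statistical machinery under its own assumptions; they do not
certify robustness to LD, call-rate artifacts or cryptic relatedness in
real arrays.

## Problem sizes and determinism

The test suite runs studies of 100–400 subjects and 10²–10⁵ SNPs; the
genomic-control null check uses 100,000 SNPs so the Monte-Carlo error of a
median-based λ sits well inside the ±0.02 band; the calibration acceptance
check uses 10⁶ null replicates and the standalone script 2×10⁷ (both
minutes or less, thanks to the integer log-gamma lookup). Every stochastic
step takes an explicit seed (numpy `default_rng`); pipeline runs write a
manifest with seeds and parameters, and re-running a stage with the same
seed is byte-identical.
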